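"""Trial-dataset and map I/O.

Two interchangeable on-disk formats carry trial data:

* **long CSV** — one row per frame per trial, columns
  ``mouse, session, rep, row, col, ml_mm, ap_mm, power, frame, left_deg,
  right_deg`` (UTF-8, comma separator, '.' decimal, header row). Streams and
  diffs well.
* **HDF5** — a ``angles`` dataset of shape (n_trials, 2, n_frames)
  (left, right) plus per-trial metadata datasets; bit-exact round trips.

Motor maps are written as an ``n_rows x n_cols`` CSV matrix plus a JSON
sidecar holding the metric name, whisker, mouse/average, power, units,
Bregma-aligned cell coordinates, trial counts and the missing-site mask.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .grid import StimGrid
from .maps import AverageMap, MotorMap
from .trials import AngleTrace, Trial

__all__ = [
    "SchemaError",
    "LayoutError",
    "DatasetManifest",
    "build_manifest",
    "write_trials",
    "read_trials",
    "load_deposited_dataset",
    "write_map",
    "read_map",
]

logger = logging.getLogger(__name__)

CSV_COLUMNS = [
    "mouse", "session", "rep", "row", "col",
    "ml_mm", "ap_mm", "power", "frame", "left_deg", "right_deg",
]


class SchemaError(ValueError):
    """A trial file violates the documented schema."""


class LayoutError(FileNotFoundError):
    """A dataset directory does not match any recognized layout."""


@dataclass
class DatasetManifest:
    """Summary of a trial dataset: who, where, how often."""

    mice: list[str]
    sites: list[dict]  # row, col, ml_mm, ap_mm
    powers: list[str]
    counts: pd.DataFrame  # columns mouse, row, col, power, n_trials

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def count(self, mouse: str, row: int, col: int, power: str | None = None) -> int:
        c = self.counts
        sel = (c["mouse"] == mouse) & (c["row"] == row) & (c["col"] == col)
        if power is not None:
            sel &= c["power"] == power
        return int(c.loc[sel, "n_trials"].sum())


def build_manifest(trials: list[Trial]) -> DatasetManifest:
    rows = []
    site_coords = {}
    for t in trials:
        r, c = t.grid_site
        site_coords[(r, c)] = t.coord_mm
        rows.append({"mouse": t.mouse_id, "row": r, "col": c, "power": t.power})
    df = pd.DataFrame(rows)
    counts = (
        df.groupby(["mouse", "row", "col", "power"]).size().rename("n_trials").reset_index()
    )
    sites = [
        {"row": r, "col": c, "ml_mm": ml, "ap_mm": ap}
        for (r, c), (ml, ap) in sorted(site_coords.items())
    ]
    return DatasetManifest(
        mice=sorted({t.mouse_id for t in trials}),
        sites=sites,
        powers=sorted({t.power for t in trials}),
        counts=counts,
    )


def _check_duplicates(trials: list[Trial]) -> None:
    seen = set()
    for t in trials:
        if t.key in seen:
            raise SchemaError(f"duplicate trial key (mouse, row, col, rep, power) = {t.key}")
        seen.add(t.key)


def write_trials(trials: list[Trial], path: str | Path, fmt: str | None = None) -> Path:
    """Write trials as long CSV or HDF5 (format inferred from the suffix)."""
    path = Path(path)
    fmt = fmt or ("hdf5" if path.suffix in (".h5", ".hdf5") else "csv")
    _check_duplicates(trials)
    if fmt == "csv":
        frames = []
        for t in trials:
            n = t.left.n_frames
            r, c = t.grid_site
            frames.append(
                pd.DataFrame(
                    {
                        "mouse": t.mouse_id,
                        "session": t.session_id,
                        "rep": t.rep_index,
                        "row": r,
                        "col": c,
                        "ml_mm": t.coord_mm[0],
                        "ap_mm": t.coord_mm[1],
                        "power": t.power,
                        "frame": np.arange(n),
                        "left_deg": t.left.samples,
                        "right_deg": t.right.samples,
                    }
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    elif fmt == "hdf5":
        n_frames = trials[0].left.n_frames
        angles = np.stack(
            [np.stack([t.left.samples, t.right.samples]) for t in trials]
        )
        str_dt = h5py.string_dtype()
        with h5py.File(path, "w") as f:
            f.attrs["frame_rate_hz"] = trials[0].left.frame_rate_hz
            f.attrs["onset_frame"] = trials[0].left.onset_frame
            f.attrs["n_frames"] = n_frames
            f.create_dataset("angles", data=angles)
            f.create_dataset("mouse", data=[t.mouse_id for t in trials], dtype=str_dt)
            f.create_dataset("session", data=[t.session_id for t in trials], dtype=str_dt)
            f.create_dataset("power", data=[t.power for t in trials], dtype=str_dt)
            f.create_dataset("rep", data=[t.rep_index for t in trials])
            f.create_dataset("row", data=[t.grid_site[0] for t in trials])
            f.create_dataset("col", data=[t.grid_site[1] for t in trials])
            f.create_dataset("ml_mm", data=[t.coord_mm[0] for t in trials])
            f.create_dataset("ap_mm", data=[t.coord_mm[1] for t in trials])
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def _trial_from_arrays(mouse, session, rep, row, col, ml, ap, power, left, right,
                       frame_rate, onset) -> Trial:
    return Trial(
        mouse_id=str(mouse),
        session_id=str(session),
        rep_index=int(rep),
        grid_site=(int(row), int(col)),
        coord_mm=(float(ml), float(ap)),
        power=str(power),
        left=AngleTrace(left, frame_rate, onset),
        right=AngleTrace(right, frame_rate, onset),
    )


def read_trials(
    path: str | Path,
    fmt: str | None = None,
    *,
    frame_rate_hz: float = 500.0,
    onset_frame: int = 250,
) -> tuple[list[Trial], DatasetManifest]:
    """Read a trial file; validates schema, flags (keeps) untracked trials."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or ("hdf5" if path.suffix in (".h5", ".hdf5") else "csv")
    trials: list[Trial] = []
    if fmt == "csv":
        df = pd.read_csv(path)
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        n_frames = None
        keys = ["mouse", "session", "rep", "row", "col", "ml_mm", "ap_mm", "power"]
        for key, g in df.groupby(keys, sort=True):
            g = g.sort_values("frame")
            frames = g["frame"].to_numpy()
            if n_frames is None:
                n_frames = frames.size
            if frames.size != n_frames or not np.array_equal(frames, np.arange(n_frames)):
                raise SchemaError(f"inconsistent trace length/frames for trial {key}")
            mouse, session, rep, row, col, ml, ap, power = key
            trials.append(
                _trial_from_arrays(
                    mouse, session, rep, row, col, ml, ap, power,
                    g["left_deg"].to_numpy(float), g["right_deg"].to_numpy(float),
                    frame_rate_hz, onset_frame,
                )
            )
    elif fmt == "hdf5":
        with h5py.File(path, "r") as f:
            frame_rate = float(f.attrs.get("frame_rate_hz", frame_rate_hz))
            onset = int(f.attrs.get("onset_frame", onset_frame))
            angles = f["angles"][:]
            meta = {
                k: f[k][:]
                for k in ("mouse", "session", "rep", "row", "col", "ml_mm", "ap_mm", "power")
            }
        for i in range(angles.shape[0]):
            trials.append(
                _trial_from_arrays(
                    meta["mouse"][i].decode(), meta["session"][i].decode(),
                    meta["rep"][i], meta["row"][i], meta["col"][i],
                    meta["ml_mm"][i], meta["ap_mm"][i], meta["power"][i].decode(),
                    angles[i, 0], angles[i, 1], frame_rate, onset,
                )
            )
    else:
        raise ValueError(f"unknown format {fmt!r}")

    _check_duplicates(trials)
    n_untracked = sum(1 for t in trials if not t.tracked)
    if n_untracked:
        logger.info("read %d trials (%d untracked, retained)", len(trials), n_untracked)
    return trials, build_manifest(trials)


def load_deposited_dataset(root: str | Path) -> tuple[list[Trial], DatasetManifest]:
    """Load a local copy of a deposited dataset.

    Recognized layouts (angles in degrees, onset already at frame 250):

    1. ``root`` is itself a trial file (``*.csv`` / ``*.h5``);
    2. ``root`` contains ``trials.csv`` or ``trials.h5``;
    3. ``root`` contains per-mouse subdirectories, each with
       ``trials.csv`` or ``trials.h5``.

    Anything else raises :class:`LayoutError` listing what was found — the
    loader never guesses. Counts per mouse and power are logged.
    """
    root = Path(root)
    if root.is_file():
        trials, manifest = read_trials(root)
    else:
        if not root.exists():
            raise LayoutError(f"dataset root {root} does not exist")
        candidates = [root / "trials.h5", root / "trials.csv"]
        hit = next((c for c in candidates if c.exists()), None)
        if hit is not None:
            trials, manifest = read_trials(hit)
        else:
            mouse_files = sorted(
                p for d in root.iterdir() if d.is_dir()
                for p in (d / "trials.h5", d / "trials.csv") if p.exists()
            )
            if not mouse_files:
                found = sorted(str(p.relative_to(root)) for p in root.rglob("*"))[:50]
                raise LayoutError(
                    "unrecognized dataset layout under "
                    f"{root}; found: {found or '(empty directory)'}"
                )
            trials = []
            for p in mouse_files:
                sub, _ = read_trials(p)
                trials.extend(sub)
            _check_duplicates(trials)
            manifest = build_manifest(trials)

    for m in manifest.mice:
        for power in manifest.powers:
            n = int(
                manifest.counts.loc[
                    (manifest.counts["mouse"] == m) & (manifest.counts["power"] == power),
                    "n_trials",
                ].sum()
            )
            logger.info("mouse %s, %s power: %d trials", m, power, n)
    return trials, manifest


_MAP_UNITS = {
    "mean_change": "degrees",
    "early_peak": "degrees",
    "band_amp": "degrees",
    "latency_ms": "ms",
    "lr_difference": "degrees",
    "zero_lag_corr": "unitless",
}


def write_map(m: MotorMap | AverageMap, path: str | Path) -> Path:
    """Write a map as CSV matrix + JSON sidecar; exact round trip."""
    path = Path(path)
    if path.suffix != ".csv":
        path = path.with_suffix(".csv")
    np.savetxt(path, m.values, fmt="%.17g", delimiter=",")
    is_average = isinstance(m, AverageMap)
    counts = m.mouse_count if is_average else m.n_trials
    grid = m.grid
    sidecar = {
        "metric": m.metric,
        "whisker": m.whisker,
        "power": m.power,
        "mouse_id": None if is_average else m.mouse_id,
        "average": is_average,
        "units": _MAP_UNITS.get(m.metric.split("_")[0] if m.metric.startswith("bin") else m.metric, "degrees"),
        "grid": {
            "n_rows": grid.n_rows,
            "n_cols": grid.n_cols,
            "ml_extent_mm": grid.ml_extent_mm,
            "ap_extent_mm": grid.ap_extent_mm,
            "ap_origin_mm": grid.ap_origin_mm,
        },
        "ml_coords_mm": grid.ml_coords.tolist(),
        "ap_coords_mm": grid.ap_coords.tolist(),
        "missing_mask": m.missing.tolist(),
        "counts": np.asarray(counts).tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_map(path: str | Path) -> MotorMap | AverageMap:
    path = Path(path)
    if path.suffix != ".csv":
        path = path.with_suffix(".csv")
    values = np.loadtxt(path, delimiter=",", ndmin=2)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    g = sidecar["grid"]
    grid = StimGrid(
        n_rows=g["n_rows"], n_cols=g["n_cols"],
        ml_extent_mm=g["ml_extent_mm"], ap_extent_mm=g["ap_extent_mm"],
        ap_origin_mm=g["ap_origin_mm"],
    )
    counts = np.asarray(sidecar["counts"])
    if sidecar["average"]:
        return AverageMap(
            sidecar["metric"], sidecar["whisker"], sidecar["power"],
            values, counts, grid,
        )
    return MotorMap(
        sidecar["metric"], sidecar["whisker"], sidecar["mouse_id"], sidecar["power"],
        values, counts, grid,
    )
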