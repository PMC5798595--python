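"""Motor-map aggregation and hotspot statistics.

Per-trial metrics are aggregated site-by-site into per-mouse *median* maps
(robust to occasional outlier trials), which are then averaged across mice.
Region hotspots are localized as masked extrema, either per mouse (mean +/- SD
of peak coordinates and values across animals) or on the grand-average map
(values then read out per mouse at the fixed average-map peak site).
Cross-mouse SDs use the n-1 denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import StimGrid
from .metrics import BILATERAL_METRICS

__all__ = [
    "MotorMap",
    "AverageMap",
    "RegionSpec",
    "PeakSite",
    "RegionPeak",
    "REGIONS",
    "per_mouse_map",
    "per_mouse_maps",
    "average_across_mice",
    "masked_extremum",
    "locate_region_peak",
    "grand_peak_stats",
    "percent_amplitude_reduction",
    "percent_latency_increase",
    "compare_power",
    "bilateral_maps",
]


@dataclass
class MotorMap:
    """Per-site median of one metric for one mouse (NaN = missing site)."""

    metric: str
    whisker: str  # "left" | "right" | "bilateral"
    mouse_id: str
    power: str
    values: np.ndarray  # (n_rows, n_cols)
    n_trials: np.ndarray  # non-censored trial count per site
    grid: StimGrid = field(default_factory=StimGrid)

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.values)


@dataclass
class AverageMap:
    """Cross-mouse arithmetic mean of per-mouse median maps."""

    metric: str
    whisker: str
    power: str
    values: np.ndarray
    mouse_count: np.ndarray  # mice contributing per site
    grid: StimGrid = field(default_factory=StimGrid)

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.values)


@dataclass(frozen=True)
class RegionSpec:
    """Where and how to search for a region hotspot."""

    label: str
    mask: str = "whole"  # "whole" | "anterior" | "posterior"
    polarity: str = "max"  # "max" (protraction) | "min" (retraction)

    def mask_array(self, grid: StimGrid) -> np.ndarray:
        if self.mask == "whole":
            return np.ones((grid.n_rows, grid.n_cols), dtype=bool)
        if self.mask == "anterior":
            return grid.anterior_mask()
        if self.mask == "posterior":
            return grid.posterior_mask()
        raise ValueError(f"unknown mask {self.mask!r}")


#: The three canonical hotspot searches on contralateral mean-change maps:
#: wS1 = largest retraction anywhere; wM1/wM2 = largest protraction anterior
#: to Bregma; PtA = largest protraction posterior to Bregma.
REGIONS: dict[str, RegionSpec] = {
    "wS1": RegionSpec("wS1", "whole", "min"),
    "wM1_wM2": RegionSpec("wM1_wM2", "anterior", "max"),
    "PtA": RegionSpec("PtA", "posterior", "max"),
}


def _metric_column(metric: str, whisker: str) -> str:
    if metric in BILATERAL_METRICS:
        if whisker not in ("bilateral", ""):
            raise ValueError(f"{metric} is a bilateral metric; use whisker='bilateral'")
        return metric
    if whisker not in ("left", "right"):
        raise ValueError(f"whisker must be 'left' or 'right' for metric {metric!r}")
    return f"{metric}_{whisker}"


def per_mouse_map(
    metrics_df: pd.DataFrame,
    metric: str,
    whisker: str,
    *,
    mouse_id: str,
    power: str = "high",
    grid: StimGrid | None = None,
) -> MotorMap:
    """Site-wise median map of one metric for one mouse at one power.

    Censored / undefined trial values (NaN) are dropped before the median;
    a site with no usable trials is missing. Even trial counts use the
    midpoint of the two central order statistics.
    """
    grid = grid or StimGrid()
    col = _metric_column(metric, whisker)
    sub = metrics_df[(metrics_df["mouse"] == mouse_id) & (metrics_df["power"] == power)]
    values = np.full((grid.n_rows, grid.n_cols), np.nan)
    counts = np.zeros((grid.n_rows, grid.n_cols), dtype=int)
    grouped = sub.groupby(["row", "col"])[col]
    for (r, c), vals in grouped:
        finite = vals.to_numpy(dtype=float)
        finite = finite[np.isfinite(finite)]
        counts[int(r), int(c)] = finite.size
        if finite.size:
            values[int(r), int(c)] = np.median(finite)
    return MotorMap(metric, whisker, mouse_id, power, values, counts, grid)


def per_mouse_maps(
    metrics_df: pd.DataFrame,
    metric: str,
    whisker: str,
    *,
    power: str = "high",
    grid: StimGrid | None = None,
) -> list[MotorMap]:
    """One median map per mouse present in the metrics table."""
    mice = sorted(metrics_df["mouse"].unique())
    return [
        per_mouse_map(metrics_df, metric, whisker, mouse_id=m, power=power, grid=grid)
        for m in mice
    ]


def average_across_mice(maps: list[MotorMap]) -> AverageMap:
    """Per-site arithmetic mean over mice with a value at that site."""
    if not maps:
        raise ValueError("no maps to average")
    first = maps[0]
    for m in maps[1:]:
        if (m.metric, m.whisker, m.power) != (first.metric, first.whisker, first.power):
            raise ValueError("maps disagree in metric/whisker/power")
    stack = np.stack([m.values for m in maps])
    count = np.isfinite(stack).sum(axis=0)
    total = np.nansum(np.where(np.isfinite(stack), stack, 0.0), axis=0)
    mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return AverageMap(first.metric, first.whisker, first.power, mean, count, first.grid)


def masked_extremum(
    values: np.ndarray, mask: np.ndarray, polarity: str
) -> tuple[int, int, float]:
    """(row, col, value) of the masked min/max; NaNs treated as missing.

    Ties break toward the smallest row index, then the smallest column.
    """
    usable = mask & np.isfinite(values)
    if not usable.any():
        raise ValueError("all sites missing within the search mask")
    if polarity == "min":
        work = np.where(usable, values, np.inf)
        flat = int(np.argmin(work))
    elif polarity == "max":
        work = np.where(usable, values, -np.inf)
        flat = int(np.argmax(work))
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    row, col = np.unravel_index(flat, values.shape)
    return int(row), int(col), float(values[row, col])


@dataclass
class PeakSite:
    mouse_id: str
    row: int
    col: int
    ml_mm: float
    ap_mm: float
    value: float
    companion_value: float | None = None  # other whisker at the same site


@dataclass
class RegionPeak:
    """Localized hotspot with cross-mouse statistics.

    ``direction`` labels the sign of the mean value (protraction/retraction);
    ``magnitude_mean`` is reported positive either way. SD fields are None
    for a single mouse.
    """

    label: str
    polarity: str
    sites: list[PeakSite]
    ml_mean: float
    ml_sd: float | None
    ap_mean: float
    ap_sd: float | None
    value_mean: float
    value_sd: float | None
    fixed_site: tuple[int, int] | None = None  # set by grand_peak_stats

    @property
    def direction(self) -> str:
        return "retraction" if self.value_mean < 0 else "protraction"

    @property
    def magnitude_mean(self) -> float:
        return abs(self.value_mean)

    @property
    def n_mice(self) -> int:
        return len(self.sites)


def _peak_stats(label: str, polarity: str, sites: list[PeakSite], fixed=None) -> RegionPeak:
    ml = np.array([s.ml_mm for s in sites])
    ap = np.array([s.ap_mm for s in sites])
    vals = np.array([s.value for s in sites])
    n = len(sites)
    sd = (lambda a: float(np.std(a, ddof=1))) if n > 1 else (lambda a: None)
    return RegionPeak(
        label=label,
        polarity=polarity,
        sites=sites,
        ml_mean=float(ml.mean()),
        ml_sd=sd(ml),
        ap_mean=float(ap.mean()),
        ap_sd=sd(ap),
        value_mean=float(vals.mean()),
        value_sd=sd(vals),
        fixed_site=fixed,
    )


def locate_region_peak(
    maps: list[MotorMap],
    region: RegionSpec,
    *,
    companion_maps: list[MotorMap] | None = None,
) -> RegionPeak:
    """Per-mouse masked extremum, summarized as mean +/- SD across mice.

    ``companion_maps`` (e.g. the other whisker, same metric) are read out at
    each mouse's peak site when given; they must be ordered like ``maps``.
    """
    if companion_maps is not None and len(companion_maps) != len(maps):
        raise ValueError("companion_maps must pair one-to-one with maps")
    sites = []
    for i, m in enumerate(maps):
        mask = region.mask_array(m.grid)
        row, col, value = masked_extremum(m.values, mask, region.polarity)
        ml, ap = m.grid.site_coord(row, col)
        companion = None
        if companion_maps is not None:
            companion = float(companion_maps[i].values[row, col])
        sites.append(PeakSite(m.mouse_id, row, col, ml, ap, value, companion))
    return _peak_stats(region.label, region.polarity, sites)


def grand_peak_stats(
    average_map: AverageMap,
    per_mouse: list[MotorMap],
    region: RegionSpec,
) -> RegionPeak:
    """Hotspot on the grand-average map, valued per mouse at that fixed site."""
    mask = region.mask_array(average_map.grid)
    row, col, _ = masked_extremum(average_map.values, mask, region.polarity)
    ml, ap = average_map.grid.site_coord(row, col)
    sites = [
        PeakSite(m.mouse_id, row, col, ml, ap, float(m.values[row, col]))
        for m in per_mouse
        if np.isfinite(m.values[row, col])
    ]
    if not sites:
        raise ValueError("no mouse has a value at the average-map peak site")
    return _peak_stats(region.label, region.polarity, sites, fixed=(row, col))


def percent_amplitude_reduction(high: float, low: float) -> float:
    """(1 - low/high) * 100; positive when the low-power response is smaller.

    Signed values with matching direction divide out, so a retraction that
    shrinks from -14.3 to -6.6352 deg is a 53.6% reduction. A zero high-power
    response leaves the ratio undefined (NaN).
    """
    if high == 0 or not np.isfinite(high) or not np.isfinite(low):
        return float("nan")
    return float((1.0 - low / high) * 100.0)


def percent_latency_increase(high: float, low: float) -> float:
    """(low/high - 1) * 100; positive when low power is slower."""
    if high == 0 or not np.isfinite(high) or not np.isfinite(low):
        return float("nan")
    return float((low / high - 1.0) * 100.0)


def compare_power(
    high_map: AverageMap | MotorMap,
    low_map: AverageMap | MotorMap,
    site: tuple[int, int],
    mode: str = "amplitude",
) -> float:
    """Percent change at one site between high- and low-power maps."""
    h = float(high_map.values[site])
    l = float(low_map.values[site])
    if mode == "amplitude":
        return percent_amplitude_reduction(h, l)
    if mode == "latency":
        return percent_latency_increase(h, l)
    raise ValueError(f"unknown mode {mode!r}")


def bilateral_maps(
    metrics_df: pd.DataFrame,
    *,
    mouse_id: str,
    power: str = "high",
    grid: StimGrid | None = None,
) -> tuple[MotorMap, MotorMap]:
    """(left-minus-right difference map, zero-lag correlation map) for a mouse."""
    diff = per_mouse_map(
        metrics_df, "lr_difference", "bilateral", mouse_id=mouse_id, power=power, grid=grid
    )
    corr = per_mouse_map(
        metrics_df, "zero_lag_corr", "bilateral", mouse_id=mouse_id, power=power, grid=grid
    )
    return diff, corr
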