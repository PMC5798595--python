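"""Core per-trial containers: whisker angle traces and trial metadata.

Conventions used throughout the package:

* angles in degrees, protraction positive;
* 500 Hz sampling, 500-frame trials (500 ms prestimulus + 500 ms stimulation);
* stimulus onset is frame ``onset_frame`` (default 250), i.e. the first frame
  of the stimulation period;
* the stimulated hemisphere is the left one, so the *right* whisker is
  contralateral and the *left* whisker ipsilateral to the stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AngleTrace", "Trial", "DEFAULT_FRAME_RATE_HZ", "DEFAULT_ONSET_FRAME"]

DEFAULT_FRAME_RATE_HZ = 500.0
DEFAULT_ONSET_FRAME = 250


@dataclass
class AngleTrace:
    """One whisker's angle time series for one trial."""

    samples: np.ndarray
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ
    onset_frame: int = DEFAULT_ONSET_FRAME

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("angle trace must be one-dimensional")
        if not 0 < self.onset_frame < self.samples.size:
            raise ValueError("onset_frame must fall inside the trace")

    @property
    def n_frames(self) -> int:
        return int(self.samples.size)

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.frame_rate_hz

    @property
    def tracked(self) -> bool:
        """False when the whisker could not be tracked (non-finite samples)."""
        return bool(np.isfinite(self.samples).all())


@dataclass
class Trial:
    """Paired left/right whisker traces plus stimulation metadata."""

    mouse_id: str
    session_id: str
    rep_index: int
    grid_site: tuple[int, int]
    coord_mm: tuple[float, float]  # (ml_mm lateral-positive, ap_mm anterior-positive)
    power: str  # "high" | "low"
    left: AngleTrace
    right: AngleTrace
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.power not in ("high", "low"):
            raise ValueError(f"unknown power level {self.power!r}")
        if self.left.n_frames != self.right.n_frames:
            raise ValueError("left/right traces differ in length")

    @property
    def tracked(self) -> bool:
        return self.left.tracked and self.right.tracked

    @property
    def key(self) -> tuple[str, int, int, int, str]:
        """(mouse, row, col, rep, power) — unique per trial in a dataset."""
        row, col = self.grid_site
        return (self.mouse_id, row, col, self.rep_index, self.power)

    def whisker(self, side: str) -> AngleTrace:
        if side == "left":
            return self.left
        if side == "right":
            return self.right
        raise ValueError(f"unknown whisker side {side!r}")
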