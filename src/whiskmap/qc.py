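"""Trial inclusion rule: prestimulus quiescence.

A trial enters the analysis only if the whisker was still before the
stimulus: the sample standard deviation of the whisker angle over the 100
frames (200 ms) immediately preceding stimulus onset must be strictly below
1 degree. Untracked trials (non-finite angles) are partitioned out first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trials import Trial

__all__ = ["QCParams", "QCResult", "prestim_quiet", "filter_trials"]


@dataclass(frozen=True)
class QCParams:
    quiet_window: int = 100  # frames immediately before onset (200 ms at 500 Hz)
    quiet_sd_threshold: float = 1.0  # degrees, strict '<'
    apply_to: str = "both"  # "both" | "left" | "right"

    def __post_init__(self) -> None:
        if self.quiet_window <= 0:
            raise ValueError("quiet_window must be positive")
        if self.quiet_sd_threshold <= 0:
            raise ValueError("quiet_sd_threshold must be positive")
        if self.apply_to not in ("both", "left", "right"):
            raise ValueError(f"unknown apply_to {self.apply_to!r}")


def _window_sd(trace, window: int) -> float:
    onset = trace.onset_frame
    if window > onset:
        raise ValueError("quiet_window exceeds the prestimulus period")
    # Sample SD (n-1 denominator); the convention is fixed for reproducibility.
    return float(np.std(trace.samples[onset - window : onset], ddof=1))


def prestim_quiet(trial: Trial, params: QCParams | None = None) -> bool:
    """True iff the selected whisker(s) were quiet before the stimulus.

    Raises on untracked trials; callers must partition those out first
    (see :func:`filter_trials`).
    """
    params = params or QCParams()
    if not trial.tracked:
        raise ValueError("prestim_quiet requires a tracked trial")
    sides = ("left", "right") if params.apply_to == "both" else (params.apply_to,)
    return all(
        _window_sd(trial.whisker(s), params.quiet_window) < params.quiet_sd_threshold
        for s in sides
    )


@dataclass
class QCResult:
    included: list[Trial]
    excluded_untracked: list[Trial]
    excluded_moving: list[Trial]
    report: dict = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return len(self.included) + len(self.excluded_untracked) + len(self.excluded_moving)


def filter_trials(trials: list[Trial], params: QCParams | None = None) -> QCResult:
    """Partition trials into included / untracked / moving, with statistics.

    The report carries the untracked fraction of all trials and the moving
    fraction of *tracked* trials, pooled over trials and (because pooling vs
    per-animal averaging is an analysis choice) also as the unweighted mean of
    per-mouse fractions.
    """
    params = params or QCParams()
    included: list[Trial] = []
    untracked: list[Trial] = []
    moving: list[Trial] = []
    for t in trials:
        if not t.tracked:
            untracked.append(t)
        elif prestim_quiet(t, params):
            included.append(t)
        else:
            moving.append(t)

    mice = sorted({t.mouse_id for t in trials})
    per_mouse = {}
    for m in mice:
        n_all = sum(1 for t in trials if t.mouse_id == m)
        n_untracked = sum(1 for t in untracked if t.mouse_id == m)
        n_moving = sum(1 for t in moving if t.mouse_id == m)
        n_tracked = n_all - n_untracked
        per_mouse[m] = {
            "n_trials": n_all,
            "untracked_fraction": n_untracked / n_all if n_all else float("nan"),
            "moving_fraction": n_moving / n_tracked if n_tracked else float("nan"),
        }

    n_all = len(trials)
    n_tracked = n_all - len(untracked)
    report = {
        "n_trials": n_all,
        "n_included": len(included),
        "n_excluded_untracked": len(untracked),
        "n_excluded_moving": len(moving),
        "untracked_fraction_pooled": len(untracked) / n_all if n_all else float("nan"),
        "moving_fraction_pooled": len(moving) / n_tracked if n_tracked else float("nan"),
        "moving_fraction_mouse_mean": (
            float(np.mean([v["moving_fraction"] for v in per_mouse.values()]))
            if per_mouse
            else float("nan")
        ),
        "per_mouse": per_mouse,
    }
    return QCResult(included, untracked, moving, report)
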