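"""Shared fixtures: trace builders and a session-scoped default dataset run."""

from types import SimpleNamespace

import numpy as np
import pytest

from whiskmap import (
    AnalysisParams,
    GeneratorConfig,
    compute_metrics,
    filter_trials,
    simulate_dataset,
)
from whiskmap.synthetic import default_layout, layout_blocks

N_FRAMES = 500
ONSET = 250


def const_trace(value: float = 0.0, n: int = N_FRAMES) -> np.ndarray:
    return np.full(n, float(value))


def step_trace(level: float, at_frame: int, base: float = 0.0, n: int = N_FRAMES) -> np.ndarray:
    x = np.full(n, float(base))
    x[at_frame:] = base + level
    return x


@pytest.fixture
def params() -> AnalysisParams:
    return AnalysisParams()


@pytest.fixture
def noiseless_config() -> GeneratorConfig:
    return GeneratorConfig(
        rest_noise_sd=0.0,
        rest_angle_sd=0.0,
        prestim_whisk_prob=0.0,
        untracked_prob=0.0,
    )


@pytest.fixture(scope="session")
def default_run() -> SimpleNamespace:
    """Full default synthetic study (4 mice x 48 sites x 18 reps, fixed seed),
    QC-filtered, with the per-trial metrics table."""
    config = GeneratorConfig(seed=1)
    layout = default_layout(config.grid)
    trials = simulate_dataset(config, layout)
    qc = filter_trials(trials)
    metrics = compute_metrics(qc.included)
    return SimpleNamespace(
        config=config,
        layout=layout,
        blocks=layout_blocks(layout),
        trials=trials,
        qc=qc,
        metrics=metrics,
    )
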