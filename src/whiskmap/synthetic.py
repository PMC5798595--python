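"""Synthetic whisker-angle trial generator.

Produces datasets with the statistical structure the downstream analysis
assumes, so the whole pipeline is testable without recorded data. The
generative model for an evoked response is deliberately minimal:

* resting baseline: a per-trial rest angle plus stationary AR(1) Gaussian
  noise (whisker jitter at rest);
* evoked sustained component: signed exponential rise
  ``A_sust * (1 - exp(-(t - L) / tau))`` starting at latency ``L`` after the
  stimulus onset (negative ``A_sust`` = retraction);
* evoked rhythmic component: an 8-12 Hz sinusoid of amplitude ``A_rhy``
  ramping in over ``rhythm_ramp_ms``, emulating whisking;
* a fraction of trials carries injected *prestimulus* whisking (>= 2 deg,
  8-12 Hz) that violates the quiescence criterion, to exercise QC;
* a small fraction of trials is untracked (all-NaN traces).

The response classes follow the three qualitative cortical regions: wS1
(sustained contralateral retraction with ipsilateral whisking, anti-phase),
wM1/wM2 and PtA (bilateral in-phase rhythmic protraction, PtA the most
rhythmic), and quiet sites elsewhere. Region influence falls off smoothly
with a Gaussian spatial kernel, and a weak (1 deg) cortex-wide in-phase
rhythmic floor keeps bilateral movements positively correlated away from wS1,
as observed empirically.

Frame ``i`` of the stimulation window is stamped at ``(i - onset + 1) * dt``
ms after onset (end-of-frame), the same clock the latency metric uses.

Determinism: each trial's random stream is derived from
``(seed, mouse, row, col, rep, power)``, so any subset of the dataset is
reproducible independently of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .grid import StimGrid
from .trials import AngleTrace, Trial

__all__ = [
    "ResponseArchetype",
    "GeneratorConfig",
    "REGION_CENTERS_MM",
    "default_region_archetypes",
    "default_layout",
    "layout_blocks",
    "simulate_trace",
    "simulate_trial",
    "simulate_dataset",
    "simulate_intrinsic_stack",
]

#: Nominal stereotaxic centers (ml_mm, ap_mm) of the three response regions.
#: ``default_layout`` snaps these to the nearest grid site.
REGION_CENTERS_MM: dict[str, tuple[float, float]] = {
    "wS1": (3.0, -1.4),
    "wM1_wM2": (1.6, 2.1),
    "PtA": (0.8, -1.4),
}


@dataclass(frozen=True)
class ResponseArchetype:
    """Parametric description of the evoked response at one cortical site.

    Amplitudes are signed degrees (negative = retraction); ``contra`` refers
    to the right whisker (opposite the stimulated left hemisphere).
    """

    label: str
    sustained_amp_contra: float = 0.0
    sustained_amp_ipsi: float = 0.0
    rise_tau_ms: float = 20.0
    rhythm_amp_contra: float = 0.0
    rhythm_amp_ipsi: float = 0.0
    rhythm_freq_range_hz: tuple[float, float] = (8.0, 12.0)
    latency_mean_ms: float = 40.0
    latency_sd_ms: float = 0.0
    bilateral_phase: str = "in_phase"  # "in_phase" | "anti_phase"

    def __post_init__(self) -> None:
        values = (
            self.sustained_amp_contra,
            self.sustained_amp_ipsi,
            self.rise_tau_ms,
            self.rhythm_amp_contra,
            self.rhythm_amp_ipsi,
            *self.rhythm_freq_range_hz,
            self.latency_mean_ms,
            self.latency_sd_ms,
        )
        if not all(math.isfinite(v) for v in values):
            raise ValueError("archetype parameters must be finite")
        if self.rise_tau_ms <= 0:
            raise ValueError("rise_tau_ms must be > 0")
        lo, hi = self.rhythm_freq_range_hz
        if not (0.0 < lo <= hi < 250.0):
            raise ValueError("rhythm_freq_range_hz must lie within (0, 250) Hz")
        if self.latency_mean_ms < 0:
            raise ValueError("latency_mean_ms must be >= 0")
        if self.bilateral_phase not in ("in_phase", "anti_phase"):
            raise ValueError(f"unknown bilateral_phase {self.bilateral_phase!r}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design and noise parameters of the synthetic dataset."""

    n_mice: int = 4
    grid: StimGrid = field(default_factory=StimGrid)
    reps_high: int = 12
    reps_low: int = 6
    frame_rate_hz: float = 500.0
    trial_len: int = 500
    onset_frame: int = 250
    rest_noise_sd: float = 0.3  # stationary SD of the AR(1) jitter, degrees
    noise_ar1: float = 0.9
    rest_angle_sd: float = 2.0  # per-trial rest-angle spread, degrees
    prestim_whisk_prob: float = 0.32
    untracked_prob: float = 0.036
    low_power_scale: float = 0.4
    low_power_latency_shift_ms: float = 30.0
    rhythm_ramp_ms: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.onset_frame < self.trial_len:
            raise ValueError("onset_frame must fall inside the trial")
        for name in ("prestim_whisk_prob", "untracked_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if not 0.0 <= self.noise_ar1 < 1.0:
            raise ValueError("noise_ar1 must lie in [0, 1)")
        if self.rest_noise_sd < 0 or self.rest_angle_sd < 0:
            raise ValueError("noise SDs must be non-negative")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.frame_rate_hz

    @property
    def reps_per_site(self) -> int:
        return self.reps_high + self.reps_low


def default_region_archetypes() -> dict[str, ResponseArchetype]:
    """Full-strength archetypes for the three response regions.

    Amplitudes and latencies sit near the empirically reported region values
    so pipeline-level runs produce qualitatively realistic maps; they are
    generator configuration, not measurements.
    """
    return {
        "wS1": ResponseArchetype(
            label="wS1",
            sustained_amp_contra=-15.0,
            sustained_amp_ipsi=15.0,
            rise_tau_ms=15.0,
            rhythm_amp_contra=2.0,
            rhythm_amp_ipsi=10.0,
            latency_mean_ms=34.0,
            latency_sd_ms=6.0,
            bilateral_phase="anti_phase",
        ),
        "wM1_wM2": ResponseArchetype(
            label="wM1_wM2",
            sustained_amp_contra=17.0,
            sustained_amp_ipsi=18.0,
            rise_tau_ms=25.0,
            rhythm_amp_contra=8.0,
            rhythm_amp_ipsi=8.0,
            latency_mean_ms=47.0,
            latency_sd_ms=7.0,
            bilateral_phase="in_phase",
        ),
        "PtA": ResponseArchetype(
            label="PtA",
            sustained_amp_contra=12.0,
            sustained_amp_ipsi=14.0,
            rise_tau_ms=25.0,
            rhythm_amp_contra=13.0,
            rhythm_amp_ipsi=12.0,
            latency_mean_ms=46.0,
            latency_sd_ms=8.0,
            bilateral_phase="in_phase",
        ),
    }


def default_layout(
    grid: StimGrid | None = None,
    *,
    kernel_sigma_mm: float = 0.6,
    label_threshold: float = 0.1,
    rhythm_floor_deg: float = 1.0,
    background_latency_ms: float = 45.0,
) -> dict[tuple[int, int], ResponseArchetype]:
    """Map every grid site to a blended :class:`ResponseArchetype`.

    Each region contributes with a Gaussian spatial kernel centered on the
    grid site nearest its nominal stereotaxic center. A site is labeled by
    its dominant region when that kernel weight reaches ``label_threshold``,
    otherwise ``"silent"``. Sites in the wS1 block couple the two whiskers in
    anti-phase; all other sites are in-phase, with at least
    ``rhythm_floor_deg`` of shared rhythmic drive.
    """
    grid = grid or StimGrid()
    regions = default_region_archetypes()
    centers = {
        label: grid.site_coord(*grid.nearest_site(*REGION_CENTERS_MM[label]))
        for label in regions
    }
    two_sig2 = 2.0 * kernel_sigma_mm**2
    w0 = 0.05  # background weight anchoring latency/tau defaults

    layout: dict[tuple[int, int], ResponseArchetype] = {}
    for row, col in grid.sites():
        ml, ap = grid.site_coord(row, col)
        w = {
            label: math.exp(
                -((ml - cx) ** 2 + (ap - cy) ** 2) / two_sig2
            )
            for label, (cx, cy) in centers.items()
        }
        dominant = max(w, key=w.get)
        label = dominant if w[dominant] >= label_threshold else "silent"

        sus_c = sum(w[r] * regions[r].sustained_amp_contra for r in regions)
        sus_i = sum(w[r] * regions[r].sustained_amp_ipsi for r in regions)

        if label == "wS1":
            phase = "anti_phase"
            rhy_c = w["wS1"] * regions["wS1"].rhythm_amp_contra
            rhy_i = w["wS1"] * regions["wS1"].rhythm_amp_ipsi
        else:
            phase = "in_phase"
            rhy_c = max(
                w["wM1_wM2"] * regions["wM1_wM2"].rhythm_amp_contra
                + w["PtA"] * regions["PtA"].rhythm_amp_contra,
                rhythm_floor_deg,
            )
            rhy_i = max(
                w["wM1_wM2"] * regions["wM1_wM2"].rhythm_amp_ipsi
                + w["PtA"] * regions["PtA"].rhythm_amp_ipsi,
                rhythm_floor_deg,
            )

        total = sum(w.values()) + w0
        latency = (
            sum(w[r] * regions[r].latency_mean_ms for r in regions)
            + w0 * background_latency_ms
        ) / total
        latency_sd = (
            sum(w[r] * regions[r].latency_sd_ms for r in regions) + w0 * 7.0
        ) / total
        tau = (
            sum(w[r] * regions[r].rise_tau_ms for r in regions) + w0 * 25.0
        ) / total

        layout[(row, col)] = ResponseArchetype(
            label=label,
            sustained_amp_contra=sus_c,
            sustained_amp_ipsi=sus_i,
            rise_tau_ms=tau,
            rhythm_amp_contra=rhy_c,
            rhythm_amp_ipsi=rhy_i,
            latency_mean_ms=latency,
            latency_sd_ms=latency_sd,
            bilateral_phase=phase,
        )
    return layout


def layout_blocks(
    layout: dict[tuple[int, int], ResponseArchetype],
) -> dict[str, list[tuple[int, int]]]:
    """Group layout sites by archetype label (the injected region blocks)."""
    blocks: dict[str, list[tuple[int, int]]] = {}
    for site, arch in layout.items():
        blocks.setdefault(arch.label, []).append(site)
    return blocks


def _ar1_noise(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    """Stationary AR(1) noise with stationary SD ``sd`` (50-sample burn-in)."""
    if sd == 0.0:
        return np.zeros(n)
    burn = 50
    innov = rng.standard_normal(n + burn) * sd * math.sqrt(1.0 - phi**2)
    x = lfilter([1.0], [1.0, -phi], innov)
    return x[burn:]


def simulate_trace(
    archetype: ResponseArchetype,
    side: str,
    power: str = "high",
    rng: np.random.Generator | int | None = None,
    config: GeneratorConfig | None = None,
    *,
    rhythm_freq_hz: float | None = None,
    rhythm_phase: float | None = None,
    latency_ms: float | None = None,
    rest_angle_deg: float = 0.0,
) -> AngleTrace:
    """Simulate one whisker's angle trace for one trial.

    ``latency_ms`` (if given) is the base evoked latency; the low-power
    latency increment is applied on top of it inside this function, and low
    power also scales both evoked amplitudes by ``config.low_power_scale``.
    Identical ``rng`` seed and arguments give a bit-identical trace.
    """
    if side not in ("contra", "ipsi"):
        raise ValueError(f"side must be 'contra' or 'ipsi', got {side!r}")
    if power not in ("high", "low"):
        raise ValueError(f"unknown power level {power!r}")
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(rng)

    a_sust = (
        archetype.sustained_amp_contra
        if side == "contra"
        else archetype.sustained_amp_ipsi
    )
    a_rhy = (
        archetype.rhythm_amp_contra if side == "contra" else archetype.rhythm_amp_ipsi
    )

    if latency_ms is None:
        latency_ms = max(
            0.0, rng.normal(archetype.latency_mean_ms, archetype.latency_sd_ms)
        )
    if rhythm_freq_hz is None:
        rhythm_freq_hz = rng.uniform(*archetype.rhythm_freq_range_hz)
    if rhythm_phase is None:
        rhythm_phase = rng.uniform(0.0, 2.0 * math.pi)

    scale = 1.0
    if power == "low":
        scale = cfg.low_power_scale
        latency_ms = latency_ms + cfg.low_power_latency_shift_ms

    if not all(
        math.isfinite(v) for v in (latency_ms, rhythm_freq_hz, rhythm_phase)
    ):
        raise ValueError("trace parameters must be finite")

    n = cfg.trial_len
    noise = _ar1_noise(rng, n, cfg.rest_noise_sd, cfg.noise_ar1)

    # End-of-frame clock: frame i -> (i - onset + 1) * dt ms after onset.
    t_ms = (np.arange(n) - cfg.onset_frame + 1) * cfg.dt_ms
    e = t_ms - latency_ms
    active = e > 0.0
    rise = np.where(active, 1.0 - np.exp(-np.clip(e, 0.0, None) / archetype.rise_tau_ms), 0.0)
    sustained = scale * a_sust * rise

    phase = rhythm_phase + (
        math.pi if side == "contra" and archetype.bilateral_phase == "anti_phase" else 0.0
    )
    ramp = np.clip(e / cfg.rhythm_ramp_ms, 0.0, 1.0)
    rhythm = np.where(
        active,
        scale * a_rhy * ramp * np.sin(2.0 * math.pi * rhythm_freq_hz * e / 1000.0 + phase),
        0.0,
    )

    samples = rest_angle_deg + noise + sustained + rhythm
    return AngleTrace(samples, frame_rate_hz=cfg.frame_rate_hz, onset_frame=cfg.onset_frame)


def _trial_seed(
    config: GeneratorConfig, mouse_idx: int, row: int, col: int, rep: int, power: str
) -> np.random.SeedSequence:
    p = 0 if power == "high" else 1
    return np.random.SeedSequence(
        entropy=(int(config.seed) & 0x7FFFFFFF, mouse_idx, row, col, rep, p)
    )


def simulate_trial(
    archetype: ResponseArchetype,
    config: GeneratorConfig,
    mouse_idx: int,
    row: int,
    col: int,
    rep: int,
    power: str,
) -> Trial:
    """Simulate one bilateral trial with a reproducible per-trial stream."""
    ss = _trial_seed(config, mouse_idx, row, col, rep, power)
    r_meta, r_left, r_right = (np.random.default_rng(s) for s in ss.spawn(3))

    mouse_id = f"m{mouse_idx + 1}"
    session_id = f"s{rep // 6 + 1}" if power == "high" else f"s{config.reps_high // 6 + 1}"
    coord = config.grid.site_coord(row, col)
    n = config.trial_len

    if r_meta.random() < config.untracked_prob:
        nan = np.full(n, np.nan)
        return Trial(
            mouse_id, session_id, rep, (row, col), coord, power,
            AngleTrace(nan.copy(), config.frame_rate_hz, config.onset_frame),
            AngleTrace(nan.copy(), config.frame_rate_hz, config.onset_frame),
        )

    # Shared per-trial draws: latency, rhythm frequency/phase couple the two
    # whiskers according to the archetype's bilateral_phase.
    latency = max(0.0, r_meta.normal(archetype.latency_mean_ms, archetype.latency_sd_ms))
    freq = r_meta.uniform(*archetype.rhythm_freq_range_hz)
    phase = r_meta.uniform(0.0, 2.0 * math.pi)
    rest_left = r_meta.normal(0.0, config.rest_angle_sd)
    rest_right = r_meta.normal(0.0, config.rest_angle_sd)
    whisking = r_meta.random() < config.prestim_whisk_prob
    if whisking:
        w_amp = r_meta.uniform(2.0, 4.0)
        w_freq = r_meta.uniform(8.0, 12.0)
        w_phase = r_meta.uniform(0.0, 2.0 * math.pi)

    shared = dict(rhythm_freq_hz=freq, rhythm_phase=phase, latency_ms=latency)
    left = simulate_trace(
        archetype, "ipsi", power, r_left, config, rest_angle_deg=rest_left, **shared
    )
    right = simulate_trace(
        archetype, "contra", power, r_right, config, rest_angle_deg=rest_right, **shared
    )

    if whisking:
        pre = np.arange(config.onset_frame)
        t_pre = pre * config.dt_ms
        wave = w_amp * np.sin(2.0 * math.pi * w_freq * t_pre / 1000.0 + w_phase)
        left.samples[pre] += wave
        right.samples[pre] += wave

    return Trial(
        mouse_id, session_id, rep, (row, col), coord, power, left, right,
        extras={"prestim_whisking": whisking},
    )


def simulate_dataset(
    config: GeneratorConfig | None = None,
    layout: dict[tuple[int, int], ResponseArchetype] | None = None,
) -> list[Trial]:
    """Simulate the full mapping dataset: every mouse, site, rep and power."""
    config = config or GeneratorConfig()
    layout = layout if layout is not None else default_layout(config.grid)
    missing = [s for s in config.grid.sites() if s not in layout]
    if missing:
        raise KeyError(f"layout is missing {len(missing)} grid site(s): {missing[:5]}")

    trials: list[Trial] = []
    for mouse_idx in range(config.n_mice):
        for row, col in config.grid.sites():
            arch = layout[(row, col)]
            for power, reps in (("high", config.reps_high), ("low", config.reps_low)):
                for rep in range(reps):
                    trials.append(
                        simulate_trial(arch, config, mouse_idx, row, col, rep, power)
                    )
    return trials


def simulate_intrinsic_stack(
    blob_center_mm: tuple[float, float] = (3.1, -1.4),
    blob_amp: float = -0.01,
    noise_sd: float = 0.0,
    rng_seed: int | None = 0,
    *,
    blob_sigma_mm: float = 0.5,
    shape: tuple[int, int] = (96, 96),
    mm_per_px: float = 0.06,
    bregma_px: tuple[int, int] = (48, 12),
    n_baseline: int = 40,
    n_stim: int = 40,
    n_post: int = 20,
    baseline_reflectance: float = 1.0,
):
    """Simulate a 10-Hz intrinsic optical imaging trial stack.

    The evoked intrinsic signal is a *decrease* in reflectance (``blob_amp``
    must be <= 0) with a Gaussian spatial profile centered at
    ``blob_center_mm`` (Bregma-aligned), present during the stimulation
    epoch only. Deterministic per seed.
    """
    from .sensory import ImageStack  # local import to avoid a cycle

    if blob_amp > 0:
        raise ValueError("blob_amp must be <= 0 (intrinsic signal is a reflectance decrease)")
    rng = np.random.default_rng(rng_seed)

    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    ml = (cols - bregma_px[1]) * mm_per_px
    ap = (bregma_px[0] - rows) * mm_per_px
    g = np.exp(
        -((ml - blob_center_mm[0]) ** 2 + (ap - blob_center_mm[1]) ** 2)
        / (2.0 * blob_sigma_mm**2)
    )

    n_frames = n_baseline + n_stim + n_post
    frames = np.full((n_frames, *shape), baseline_reflectance, dtype=float)
    stim = slice(n_baseline, n_baseline + n_stim)
    frames[stim] = baseline_reflectance * (1.0 + blob_amp * g)
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, frames.shape)

    return ImageStack(
        frames=frames,
        n_baseline=n_baseline,
        n_stim=n_stim,
        n_post=n_post,
        frame_rate_hz=10.0,
        mm_per_px=mm_per_px,
        bregma_px=bregma_px,
    )
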