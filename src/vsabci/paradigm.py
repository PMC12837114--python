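"""Synthetic Hex-o-Spell oddball session generator.

Simulates the stimulation paradigm of a 6-target hexagonal visual oddball
BCI: blocks of pseudorandom target intensifications (100 ms flash, 200 ms
onset-to-onset spacing with uniform +/-50 ms jitter, 10-15 intensifications
per target), one block per cued target per visuospatial-attention (VSA)
condition (overt / covert / free), 18 blocks in total.

The EEG model is a component-sum event-related potential (ERP) generator:
each stimulus evokes a set of named components (P1, N1, P3 by default), each
the outer product of a spatial topography and a Gaussian temporal kernel.
Attention-modulated components (the P3) appear only on target stimuli, with
condition-dependent amplitude scaling and trial-to-trial latency jitter;
visual components scale with the proximity of gaze to the flashed stimulus,
which makes early ERPs gaze-dependent (large under overt fixation, attenuated
under central fixation). Background activity is spatially correlated AR(1)
colored noise. Binocular gaze traces follow the per-condition fixation
strategy with per-eye dropout.

All randomness flows from a single master seed through per-block child
seeds, so a session is byte-identical across runs and individual blocks are
reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from vsabci.errors import DomainError

#: Approximate 2-D scalp coordinates (unit head radius; x right, y anterior)
#: for the 18-electrode 10-20 montage used by the simulator. Only relative
#: distances matter (topography and noise-covariance kernels).
ELECTRODE_POSITIONS: dict[str, tuple[float, float]] = {
    "Fz": (0.00, 0.40), "F3": (-0.30, 0.42), "F4": (0.30, 0.42),
    "F7": (-0.65, 0.35), "F8": (0.65, 0.35),
    "Cz": (0.00, 0.00), "C3": (-0.40, 0.00), "C4": (0.40, 0.00),
    "Pz": (0.00, -0.40), "P3": (-0.30, -0.42), "P4": (0.30, -0.42),
    "P7": (-0.65, -0.35), "P8": (0.65, -0.35),
    "Oz": (0.00, -0.80), "O1": (-0.25, -0.78), "O2": (0.25, -0.78),
    "TP9": (-0.85, -0.10), "TP10": (0.85, -0.10),
    # EOG electrodes sit near the eyes, well anterior of the scalp ring.
    "EOGh": (-0.55, 0.95), "EOGv": (0.15, 1.00),
}

DEFAULT_EEG_CHANNELS: tuple[str, ...] = (
    "Fz", "F3", "F4", "F7", "F8", "Cz", "C3", "C4", "Pz", "P3", "P4",
    "P7", "P8", "Oz", "O1", "O2", "TP9", "TP10",
)
DEFAULT_EOG_CHANNELS: tuple[str, ...] = ("EOGh", "EOGv")

CONDITIONS: tuple[str, ...] = ("overt", "covert", "free")


@dataclass(frozen=True)
class ParadigmConfig:
    """Geometry and timing of the hexagonal oddball stimulation paradigm.

    Defaults follow the experimental protocol: six circular targets of
    4.15 deg visual angle on a hexagon of radius 12.28 deg, intensified to
    5.50 deg for 100 ms, with a nominal 200 ms onset-to-onset interval
    jittered uniformly by +/-50 ms, and 10-15 intensifications per target
    per block.
    """

    n_targets: int = 6
    hex_radius_deg: float = 12.28
    target_diameter_deg: float = 4.15
    intensified_diameter_deg: float = 5.50
    flash_duration_ms: float = 100.0
    isi_nominal_ms: float = 200.0
    isi_jitter_ms: float = 50.0
    reps_min: int = 10
    reps_max: int = 15
    conditions: tuple[str, ...] = CONDITIONS
    sfreq: float = 1000.0
    eeg_channels: tuple[str, ...] = DEFAULT_EEG_CHANNELS
    eog_channels: tuple[str, ...] = DEFAULT_EOG_CHANNELS
    block_gap_s: float = 2.0
    gaze_rate_hz: float = 60.0

    def __post_init__(self) -> None:
        if self.reps_min > self.reps_max:
            raise DomainError(f"reps_min={self.reps_min} > reps_max={self.reps_max}")
        if self.reps_min < 1:
            raise DomainError("reps_min must be >= 1")
        if self.flash_duration_ms >= self.isi_nominal_ms - self.isi_jitter_ms:
            raise DomainError(
                "flash_duration must be shorter than the minimum onset-to-onset gap "
                f"({self.isi_nominal_ms - self.isi_jitter_ms:g} ms)"
            )
        for name, v in (
            ("hex_radius_deg", self.hex_radius_deg),
            ("target_diameter_deg", self.target_diameter_deg),
            ("intensified_diameter_deg", self.intensified_diameter_deg),
        ):
            if v <= 0:
                raise DomainError(f"{name} must be positive, got {v}")
        if self.isi_jitter_ms < 0:
            raise DomainError("isi_jitter_ms must be >= 0")
        unknown = [c for c in self.conditions if c not in CONDITIONS]
        if unknown:
            raise DomainError(f"unknown conditions: {unknown}")

    @property
    def channels(self) -> tuple[str, ...]:
        return self.eeg_channels + self.eog_channels

    @property
    def target_positions(self) -> np.ndarray:
        """(n_targets, 2) screen coordinates (degrees, origin at center).

        Vertices of a regular hexagon, target 0 at the top, proceeding
        clockwise.
        """
        k = np.arange(self.n_targets)
        ang = np.pi / 2 - 2 * np.pi * k / self.n_targets
        return self.hex_radius_deg * np.column_stack([np.cos(ang), np.sin(ang)])


@dataclass(frozen=True)
class ErpComponentSpec:
    """One named ERP component: topography (x) temporal kernel.

    The temporal kernel is a Gaussian bump of standard deviation
    ``kernel_width_ms`` centered at ``latency_mean_ms`` plus a per-trial
    latency shift drawn from N(0, jitter). ``modulation`` controls when the
    component is present:

    - ``attention``: target stimuli only; amplitude and latency jitter are
      taken from the active :class:`ConditionProfile` (the P3 contrast).
    - ``visual``: every stimulus, scaled by ``exp(-gaze_offset / visual_decay_deg)``
      where gaze_offset is the angular distance from fixation to the flashed
      stimulus (early gaze-dependent components).
    - ``unmodulated``: every stimulus, no scaling.
    """

    name: str
    topography: Mapping[str, float]
    kernel_width_ms: float
    latency_mean_ms: float
    amplitude_uv: float
    latency_jitter_sd_ms: float = 0.0
    modulation: str = "unmodulated"
    visual_decay_deg: float = 6.0

    def __post_init__(self) -> None:
        if self.modulation not in ("attention", "visual", "unmodulated"):
            raise DomainError(f"unknown modulation {self.modulation!r}")
        if self.kernel_width_ms <= 0:
            raise DomainError("kernel_width_ms must be positive")
        if self.latency_jitter_sd_ms < 0:
            raise DomainError("latency_jitter_sd_ms must be >= 0")
        if not any(w != 0 for w in self.topography.values()):
            raise DomainError(f"component {self.name!r} has an all-zero topography")

    def topography_vector(self, channels: Sequence[str]) -> np.ndarray:
        return np.array([self.topography.get(ch, 0.0) for ch in channels])


@dataclass(frozen=True)
class ConditionProfile:
    """Per-VSA-condition behavior: P3 statistics and gaze strategy."""

    condition: str
    p3_amplitude_scale: float = 1.0
    p3_jitter_sd_ms: float = 20.0
    gaze_strategy: str = "fixate_target"  # fixate_target | fixate_center | mixture
    p_overt: float = 0.7  # mixture only: per-block probability of target fixation
    gaze_noise_sd_deg: float = 1.0
    dropout_prob_per_eye: float = 0.05

    def __post_init__(self) -> None:
        if self.gaze_strategy not in ("fixate_target", "fixate_center", "mixture"):
            raise DomainError(f"unknown gaze strategy {self.gaze_strategy!r}")
        if not 0.0 <= self.dropout_prob_per_eye <= 1.0:
            raise DomainError("dropout_prob_per_eye must be in [0, 1]")
        if not 0.0 <= self.p_overt <= 1.0:
            raise DomainError("p_overt must be in [0, 1]")


@dataclass(frozen=True)
class NoiseSpec:
    """Colored background-noise model.

    Spatially correlated (distance-decay covariance) temporally AR(1)
    Gaussian noise, scaled to a per-channel RMS in microvolts. Optional
    eye-blink artifacts (Poisson events on the vertical EOG with frontal
    leakage) are off by default.
    """

    rms_uv: float = 2.5
    ar_coeff: float = 0.97
    spatial_decay: float = 0.6
    blink_rate_hz: float = 0.0
    blink_amp_uv: float = 150.0
    blink_width_ms: float = 60.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ar_coeff < 1.0:
            raise DomainError("ar_coeff must be in [0, 1)")
        if self.rms_uv < 0:
            raise DomainError("rms_uv must be >= 0")


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered intensification schedule of one stimulation block."""

    onsets_ms: np.ndarray
    stimulus_targets: np.ndarray
    block_id: int
    cued_target: int
    condition: str

    def __post_init__(self) -> None:
        if len(self.onsets_ms) != len(self.stimulus_targets):
            raise DomainError("onsets and stimulus ids differ in length")
        if np.any(np.diff(self.onsets_ms) <= 0):
            raise DomainError("onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.onsets_ms)


@dataclass
class SimulatedSession:
    """A complete simulated recording with ground truth.

    Attributes
    ----------
    eeg : (n_channels, n_samples) float array, microvolts.
    events : one row per intensification with columns
        onset_ms, block_id, condition, cued_target, stimulus_target, is_target.
    gaze : binocular trace with columns t_ms, lx, ly, rx, ry, l_valid, r_valid.
    blocks : per-block metadata (block_id, condition, cued_target,
        t_start_ms, t_end_ms, gaze_strategy).
    ground_truth : per-event latent state (true P3 latency shift, effective
        component amplitudes, gaze offset of the flashed stimulus).
    """

    eeg: np.ndarray
    sfreq: float
    ch_names: list[str]
    ch_types: list[str]
    events: pd.DataFrame
    gaze: pd.DataFrame
    blocks: pd.DataFrame
    ground_truth: pd.DataFrame
    seed: int
    config: ParadigmConfig = field(default_factory=ParadigmConfig)

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sfreq


def _gaussian_topography(
    center: tuple[float, float], sigma: float, channels: Sequence[str] = DEFAULT_EEG_CHANNELS,
) -> dict[str, float]:
    """Smooth scalp topography: Gaussian in electrode space, peak weight 1."""
    pos = np.array([ELECTRODE_POSITIONS[ch] for ch in channels])
    d2 = np.sum((pos - np.asarray(center)) ** 2, axis=1)
    w = np.exp(-d2 / (2 * sigma**2))
    w /= w.max()
    return {ch: float(v) for ch, v in zip(channels, w)}


def default_erp_model() -> list[ErpComponentSpec]:
    """P1 / N1 / P3 component set.

    P1 and N1 are occipital/occipito-temporal visual components that scale
    with gaze proximity to the flashed stimulus; the P3 is a centro-parietal
    attention component present on target stimuli only, whose amplitude and
    latency jitter come from the condition profile.
    """
    return [
        ErpComponentSpec(
            name="P1",
            topography=_gaussian_topography((0.0, -0.80), 0.40),
            kernel_width_ms=18.0,
            latency_mean_ms=110.0,
            amplitude_uv=3.0,
            latency_jitter_sd_ms=5.0,
            modulation="visual",
        ),
        ErpComponentSpec(
            name="N1",
            topography=_gaussian_topography((0.0, -0.65), 0.50),
            kernel_width_ms=25.0,
            latency_mean_ms=175.0,
            amplitude_uv=-4.0,
            latency_jitter_sd_ms=5.0,
            modulation="visual",
        ),
        ErpComponentSpec(
            name="P3",
            topography=_gaussian_topography((0.0, -0.30), 0.55),
            kernel_width_ms=60.0,
            latency_mean_ms=380.0,
            amplitude_uv=6.0,
            modulation="attention",
        ),
    ]


def default_condition_profiles() -> dict[str, ConditionProfile]:
    """Default VSA condition set.

    Overt fixation on the cued target yields the full-amplitude, low-jitter
    P3; covert attention with central fixation attenuates the P3 and roughly
    triples its latency jitter; free viewing is a per-block mixture in which
    users mostly (p = 0.7) fall back on target fixation.
    """
    return {
        "overt": ConditionProfile(
            condition="overt", p3_amplitude_scale=1.0, p3_jitter_sd_ms=20.0,
            gaze_strategy="fixate_target",
        ),
        "covert": ConditionProfile(
            condition="covert", p3_amplitude_scale=0.7, p3_jitter_sd_ms=60.0,
            gaze_strategy="fixate_center",
        ),
        "free": ConditionProfile(
            condition="free", p3_amplitude_scale=0.9, p3_jitter_sd_ms=35.0,
            gaze_strategy="mixture", p_overt=0.7,
        ),
    }


def build_block_schedule(
    cfg: ParadigmConfig,
    cued_target: int,
    condition: str,
    rng: np.random.Generator,
    block_id: int = 0,
    t_start_ms: float = 0.0,
) -> StimulusSchedule:
    """Draw one block's pseudorandom intensification schedule.

    Per-target counts are uniform on [reps_min, reps_max]. The order is
    round-structured: every round is a permutation of the targets that still
    have intensifications left, so the first ``reps_min`` rounds each contain
    all six targets exactly once. A target never opens a round it just
    closed, except in tail rounds where a single remaining target makes the
    repetition unavoidable. Onset-to-onset gaps are
    ``isi_nominal_ms`` + U(-isi_jitter_ms, +isi_jitter_ms).
    """
    if not 0 <= cued_target < cfg.n_targets:
        raise DomainError(
            f"cued_target must be in 0..{cfg.n_targets - 1}, got {cued_target}"
        )
    counts = rng.integers(cfg.reps_min, cfg.reps_max + 1, size=cfg.n_targets)
    order: list[int] = []
    for r in range(int(counts.max())):
        active = np.flatnonzero(counts > r)
        perm = rng.permutation(active)
        if order and len(perm) >= 2 and perm[0] == order[-1]:
            j = int(rng.integers(1, len(perm)))
            perm[0], perm[j] = perm[j], perm[0]
        order.extend(int(t) for t in perm)

    gaps = cfg.isi_nominal_ms + rng.uniform(
        -cfg.isi_jitter_ms, cfg.isi_jitter_ms, size=len(order) - 1
    )
    onsets = t_start_ms + np.concatenate([[0.0], np.cumsum(gaps)])
    return StimulusSchedule(
        onsets_ms=onsets,
        stimulus_targets=np.asarray(order, dtype=int),
        block_id=block_id,
        cued_target=cued_target,
        condition=condition,
    )


def _effective_components(
    erp: Sequence[ErpComponentSpec],
    profile: ConditionProfile,
    is_target: bool,
    gaze_offset_deg: float,
) -> list[tuple[ErpComponentSpec, float, float]]:
    """Resolve (component, effective amplitude, jitter SD) for one stimulus."""
    out = []
    for comp in erp:
        if comp.modulation == "attention":
            if not is_target:
                continue
            amp = comp.amplitude_uv * profile.p3_amplitude_scale
            jitter = profile.p3_jitter_sd_ms
        elif comp.modulation == "visual":
            amp = comp.amplitude_uv * math.exp(-gaze_offset_deg / comp.visual_decay_deg)
            jitter = comp.latency_jitter_sd_ms
        else:
            amp = comp.amplitude_uv
            jitter = comp.latency_jitter_sd_ms
        out.append((comp, amp, jitter))
    return out


def synth_epoch_signal(
    erp: Sequence[ErpComponentSpec],
    profile: ConditionProfile,
    is_target: bool,
    gaze_offset_deg: float,
    rng: np.random.Generator,
    channels: Sequence[str] = DEFAULT_EEG_CHANNELS,
    sfreq: float = 1000.0,
    tmin_ms: float = -200.0,
    tmax_ms: float = 1000.0,
) -> tuple[np.ndarray, float]:
    """Noise-free single-stimulus waveform and the drawn P3 latency shift.

    Returns ``(waveform, true_shift_ms)`` where waveform is
    (n_channels, n_samples) over [tmin_ms, tmax_ms) and true_shift_ms is the
    latency shift applied to the attention component (0 when absent).
    """
    if gaze_offset_deg < 0:
        raise DomainError("gaze_offset_deg must be >= 0")
    t = np.arange(tmin_ms, tmax_ms, 1000.0 / sfreq)
    wave = np.zeros((len(channels), len(t)))
    true_shift = 0.0
    for comp, amp, jitter_sd in _effective_components(
        erp, profile, is_target, gaze_offset_deg
    ):
        shift = float(rng.normal(0.0, jitter_sd)) if jitter_sd > 0 else 0.0
        if comp.modulation == "attention":
            true_shift = shift
        kernel = amp * np.exp(
            -((t - (comp.latency_mean_ms + shift)) ** 2) / (2 * comp.kernel_width_ms**2)
        )
        wave += np.outer(comp.topography_vector(channels), kernel)
    return wave, true_shift


def simulate_gaze(
    cfg: ParadigmConfig,
    profile: ConditionProfile,
    cued_target: int,
    t_start_ms: float,
    t_end_ms: float,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, str]:
    """Binocular gaze trace for one block.

    Fixation point follows the profile's strategy (``mixture`` draws a
    per-block Bernoulli(p_overt) choice between target and center fixation).
    Each eye gets an independent small horizontal vergence offset, Gaussian
    positional noise, and i.i.d. per-sample dropout clearing its validity
    flag (dropped samples are NaN). Returns the trace and the strategy
    actually used ("fixate_target" or "fixate_center").
    """
    strategy = profile.gaze_strategy
    if strategy == "mixture":
        strategy = "fixate_target" if rng.random() < profile.p_overt else "fixate_center"
    fix = (
        cfg.target_positions[cued_target]
        if strategy == "fixate_target"
        else np.zeros(2)
    )
    t = np.arange(t_start_ms, t_end_ms, 1000.0 / cfg.gaze_rate_hz)
    n = len(t)
    cols = {"t_ms": t}
    for eye, vergence in (("l", -0.3), ("r", 0.3)):
        xy = fix + rng.normal(0.0, profile.gaze_noise_sd_deg, size=(n, 2))
        xy[:, 0] += vergence
        valid = rng.random(n) >= profile.dropout_prob_per_eye
        xy[~valid] = np.nan
        cols[f"{eye}x"], cols[f"{eye}y"] = xy[:, 0], xy[:, 1]
        cols[f"{eye}_valid"] = valid
    return pd.DataFrame(cols), strategy


def _colored_noise(
    n_ch: int,
    n_samples: int,
    positions: np.ndarray,
    spec: NoiseSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Spatially correlated AR(1) Gaussian noise, per-channel RMS = rms_uv."""
    if spec.rms_uv == 0:
        return np.zeros((n_ch, n_samples))
    white = rng.standard_normal((n_ch, n_samples))
    ar = lfilter([1.0], [1.0, -spec.ar_coeff], white, axis=1)
    ar *= math.sqrt(1.0 - spec.ar_coeff**2)  # stationary unit variance
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=2)
    k = np.exp(-d / spec.spatial_decay) + 1e-9 * np.eye(n_ch)
    mix = np.linalg.cholesky(k)
    # renormalize rows so every channel keeps unit marginal variance
    mix /= np.linalg.norm(mix, axis=1, keepdims=True)
    return spec.rms_uv * (mix @ ar)


def _add_blinks(
    eeg: np.ndarray,
    ch_names: Sequence[str],
    sfreq: float,
    spec: NoiseSpec,
    rng: np.random.Generator,
) -> None:
    """Poisson eye blinks: large EOGv deflection with frontal leakage."""
    n = eeg.shape[1]
    n_blinks = rng.poisson(spec.blink_rate_hz * n / sfreq)
    if n_blinks == 0:
        return
    centers = rng.uniform(0, n / sfreq, size=n_blinks)
    width_s = spec.blink_width_ms / 1000.0
    t = np.arange(n) / sfreq
    # leakage decays with distance from the eyes (anterior y)
    leak = np.array(
        [
            max(0.0, ELECTRODE_POSITIONS.get(ch, (0, -1))[1]) * 0.5
            for ch in ch_names
        ]
    )
    for i, ch in enumerate(ch_names):
        if ch == "EOGv":
            leak[i] = 1.0
        elif ch == "EOGh":
            leak[i] = 0.3
    for c in centers:
        kern = spec.blink_amp_uv * np.exp(-((t - c) ** 2) / (2 * width_s**2))
        eeg += np.outer(leak, kern)


def simulate_session(
    cfg: ParadigmConfig | None = None,
    erp: Sequence[ErpComponentSpec] | None = None,
    profiles: Mapping[str, ConditionProfile] | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    conditions: Sequence[str] | None = None,
) -> SimulatedSession:
    """Simulate a full recording session.

    One block per (condition, cued target) pair, presented in randomized
    order with ``block_gap_s`` pauses. Event waveforms are superposed on
    spatially correlated colored noise; gaze is generated per block from the
    condition's strategy; every latent draw (P3 shift, effective component
    amplitudes, gaze strategy) is recorded in ``ground_truth``.

    ``conditions`` restricts the session to a subset of ``cfg.conditions``
    (e.g. a covert-only session of 6 blocks) without changing any block-level
    statistics.
    """
    cfg = cfg or ParadigmConfig()
    erp = list(erp) if erp is not None else default_erp_model()
    profiles = dict(profiles) if profiles is not None else default_condition_profiles()
    noise = noise or NoiseSpec()
    conditions = tuple(conditions) if conditions is not None else cfg.conditions
    missing = [c for c in conditions if c not in profiles]
    if missing:
        raise DomainError(f"no ConditionProfile for conditions: {missing}")

    ss = np.random.SeedSequence(seed)
    rng_order, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))

    block_keys = [(c, t) for c in conditions for t in range(cfg.n_targets)]
    order = rng_order.permutation(len(block_keys))
    block_keys = [block_keys[i] for i in order]
    block_seeds = ss.spawn(len(block_keys))

    channels = list(cfg.channels)
    ch_types = ["eeg"] * len(cfg.eeg_channels) + ["eog"] * len(cfg.eog_channels)
    positions = np.array([ELECTRODE_POSITIONS[ch] for ch in channels])
    n_eeg = len(cfg.eeg_channels)

    lead_in_ms = 1000.0
    tail_ms = 1500.0
    epoch_lo, epoch_hi = -200.0, 1000.0  # synthesis span per event
    t_kernel = np.arange(epoch_lo, epoch_hi, 1000.0 / cfg.sfreq)
    klen = len(t_kernel)

    # -- schedules first, to size the recording -------------------------------
    schedules: list[StimulusSchedule] = []
    block_rows = []
    gaze_frames = []
    cursor = lead_in_ms
    block_rngs = []
    for bid, ((cond, tgt), bs) in enumerate(zip(block_keys, block_seeds)):
        rng_sched, rng_sig, rng_gaze = (np.random.default_rng(s) for s in bs.spawn(3))
        block_rngs.append(rng_sig)
        sched = build_block_schedule(cfg, tgt, cond, rng_sched, block_id=bid, t_start_ms=cursor)
        schedules.append(sched)
        t_end = sched.onsets_ms[-1] + cfg.isi_nominal_ms
        gaze_df, strategy = simulate_gaze(
            cfg, profiles[cond], tgt, cursor, t_end, rng_gaze
        )
        gaze_frames.append(gaze_df)
        block_rows.append(
            dict(
                block_id=bid, condition=cond, cued_target=tgt,
                t_start_ms=cursor, t_end_ms=t_end, gaze_strategy=strategy,
            )
        )
        cursor = t_end + cfg.block_gap_s * 1000.0

    n_samples = int(round((cursor + tail_ms) * cfg.sfreq / 1000.0))
    eeg = _colored_noise(len(channels), n_samples, positions, noise, rng_noise)
    if noise.blink_rate_hz > 0:
        _add_blinks(eeg, channels, cfg.sfreq, noise, rng_noise)

    # -- superpose event responses -------------------------------------------
    event_rows = []
    gt_rows = []
    tpos = cfg.target_positions
    eid = 0
    for sched, row, rng_sig in zip(schedules, block_rows, block_rngs):
        profile = profiles[row["condition"]]
        fix = (
            tpos[row["cued_target"]]
            if row["gaze_strategy"] == "fixate_target"
            else np.zeros(2)
        )
        for onset, stim in zip(sched.onsets_ms, sched.stimulus_targets):
            is_target = bool(stim == row["cued_target"])
            gaze_off = float(np.linalg.norm(tpos[stim] - fix))
            wave, shift = synth_epoch_signal(
                erp, profile, is_target, gaze_off, rng_sig,
                channels=cfg.eeg_channels, sfreq=cfg.sfreq,
                tmin_ms=epoch_lo, tmax_ms=epoch_hi,
            )
            start = int(round((onset + epoch_lo) * cfg.sfreq / 1000.0))
            stop = start + klen
            if start < 0 or stop > n_samples:  # cannot occur by construction
                raise RuntimeError("event waveform exceeds recording bounds")
            eeg[:n_eeg, start:stop] += wave
            p3_amp = next(
                (
                    a
                    for c, a, _ in _effective_components(erp, profile, is_target, gaze_off)
                    if c.modulation == "attention"
                ),
                0.0,
            )
            event_rows.append(
                dict(
                    onset_ms=float(onset), block_id=row["block_id"],
                    condition=row["condition"], cued_target=row["cued_target"],
                    stimulus_target=int(stim), is_target=is_target,
                )
            )
            gt_rows.append(
                dict(
                    event_id=eid, block_id=row["block_id"],
                    condition=row["condition"], is_target=is_target,
                    true_shift_ms=shift, p3_amplitude_uv=p3_amp,
                    gaze_offset_deg=gaze_off, gaze_strategy=row["gaze_strategy"],
                )
            )
            eid += 1

    return SimulatedSession(
        eeg=eeg,
        sfreq=cfg.sfreq,
        ch_names=channels,
        ch_types=ch_types,
        events=pd.DataFrame(event_rows),
        gaze=pd.concat(gaze_frames, ignore_index=True),
        blocks=pd.DataFrame(block_rows),
        ground_truth=pd.DataFrame(gt_rows),
        seed=seed,
        config=cfg,
    )


def covert_profile_pair(jitter_sd_ms: float) -> dict[str, ConditionProfile]:
    """Covert-only profile set with a chosen P3 latency-jitter SD.

    Convenience for jitter-contrast experiments: identical to the default
    covert profile except for the jitter SD, so sessions at different jitter
    levels are otherwise matched.
    """
    base = default_condition_profiles()["covert"]
    return {"covert": replace(base, p3_jitter_sd_ms=jitter_sd_ms)}
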