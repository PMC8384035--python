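"""Synthetic gait trial generator.

Produces multi-rate recordings of treadmill walking with the structure an
sEMG-driven motion decoder relies on:

* a quasi-periodic four-phase gait schedule — initial contact (IC), flat foot
  (FF), heel off (HO), toe off / swing (TO);
* per-muscle activation envelopes built from raised-cosine bursts whose timing
  is phase-locked to the schedule;
* raw sEMG = envelope x band-limited zero-mean noise carrier;
* a joint-angle trace driven by the same burst kernels *delayed* by the
  electromechanical delay (EMD), so muscle activity genuinely leads motion;
* two foot-switch (FSR) pressure channels consistent with the phase schedule;
* an optional "exoskeleton" condition that perturbs burst gains, burst timing
  and phase durations, emulating assistance-induced distribution shift.

Everything is reproducible bit-exactly from ``SimConfig.seed``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as _sig

#: Gait phase names in schedule order. Integer codes are indices into this tuple.
PHASES: tuple[str, ...] = ("IC", "FF", "HO", "TO")

IC, FF, HO, TO = range(4)

#: The nine lower-limb muscles conventionally recorded in treadmill gait studies.
MUSCLES_9: tuple[str, ...] = ("RF", "VM", "VL", "TA", "SL", "ST", "BF", "GM", "GL")

# Default per-muscle, per-phase burst gains (rows: MUSCLES_9, cols: IC FF HO TO).
# Chosen so every phase has at least one strongly dominant muscle and channels
# have distinct phase signatures; loosely follows typical activation timing
# (quadriceps at contact, plantarflexors in stance/push-off, TA in swing).
_DEFAULT_GAINS = np.array(
    [
        [1.00, 0.45, 0.10, 0.15],  # RF
        [1.00, 0.30, 0.10, 0.20],  # VM
        [0.95, 0.50, 0.20, 0.25],  # VL
        [0.80, 0.10, 0.10, 1.00],  # TA
        [0.10, 0.90, 1.00, 0.10],  # SL
        [0.70, 0.15, 0.10, 1.00],  # ST
        [0.90, 0.75, 0.70, 0.65],  # BF
        [0.10, 0.60, 1.00, 0.10],  # GM
        [0.40, 0.75, 1.00, 0.15],  # GL
    ]
)

# Weights mixing muscle kernels into the joint-angle drive signal: dorsiflexors
# positive, plantarflexors negative, thigh muscles mildly positive.
_DEFAULT_ANGLE_WEIGHTS = np.array([0.3, 0.2, 0.2, 1.0, -0.9, 0.3, 0.1, -0.8, -0.8])


@dataclass
class ConditionShift:
    """Perturbation defining an altered recording condition (e.g. exoskeleton).

    Parameters
    ----------
    gain_mult : mapping of muscle name to multiplicative burst-gain factor.
    burst_delay_ms : additive shift of every burst centre, in milliseconds.
    phase_duration_factors : mapping of phase name to duration scale factor.
        The scaled phase's share of the cycle changes by exactly this factor;
        the remaining phases are renormalised so the cycle length is unchanged.
    """

    gain_mult: Mapping[str, float] = field(default_factory=dict)
    burst_delay_ms: float = 0.0
    phase_duration_factors: Mapping[str, float] = field(default_factory=dict)


def default_exo_shift() -> ConditionShift:
    """Default exoskeleton shift: +30% gain on the plantarflexors (SL, GM, GL),
    a 20% shorter initial-contact phase, and a 15 ms burst delay."""
    return ConditionShift(
        gain_mult={"SL": 1.3, "GM": 1.3, "GL": 1.3},
        burst_delay_ms=15.0,
        phase_duration_factors={"IC": 0.8},
    )


@dataclass
class SimConfig:
    """Parameters of the synthetic gait generator.

    Defaults emulate level treadmill walking at a ~1.1 s stride with nine
    recorded muscles, sEMG at 1111.11 Hz, foot switches at 500 Hz and a joint
    angle trace at 100 Hz, with a 40 ms electromechanical lead of the muscle
    envelopes over the angle.
    """

    duration_s: float = 60.0
    cycle_mean_s: float = 1.1
    cycle_jitter_cv: float = 0.05
    phase_fractions: tuple[float, float, float, float] = (0.10, 0.35, 0.30, 0.25)
    n_muscles: int = 9
    muscle_names: tuple[str, ...] | None = None
    burst_centers: np.ndarray | None = None  # (n_muscles, 4) fraction-of-cycle
    burst_gains: np.ndarray | None = None  # (n_muscles, 4) amplitudes >= 0
    burst_width_frac: float = 0.18
    emd_ms: float = 40.0
    noise_band_hz: tuple[float, float] = (20.0, 450.0)
    fs_emg: float = 1111.11
    fs_fsr: float = 500.0
    fs_angle: float = 100.0
    angle_range_deg: tuple[float, float] = (-20.0, 15.0)
    angle_noise_deg: float = 0.3
    angle_weights: np.ndarray | None = None
    fsr_noise: float = 0.05
    seed: int = 0
    condition_shift: ConditionShift | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.cycle_mean_s <= 0:
            raise ValueError("cycle_mean_s must be positive")
        for name in ("fs_emg", "fs_fsr", "fs_angle"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        fr = np.asarray(self.phase_fractions, dtype=float)
        if fr.shape != (4,) or np.any(fr <= 0):
            raise ValueError("phase_fractions must be 4 positive numbers")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("phase_fractions must sum to 1")
        if self.muscle_names is None:
            if self.n_muscles == 9:
                self.muscle_names = MUSCLES_9
            else:
                self.muscle_names = tuple(f"M{i + 1}" for i in range(self.n_muscles))
        if len(self.muscle_names) != self.n_muscles:
            raise ValueError("muscle_names length must equal n_muscles")
        if self.burst_gains is None:
            if self.n_muscles == 9:
                self.burst_gains = _DEFAULT_GAINS.copy()
            else:
                # round-robin one dominant phase per muscle
                g = np.full((self.n_muscles, 4), 0.15)
                for m in range(self.n_muscles):
                    g[m, m % 4] = 1.0
                self.burst_gains = g
        self.burst_gains = np.asarray(self.burst_gains, dtype=float)
        if self.burst_gains.shape != (self.n_muscles, 4):
            raise ValueError("burst_gains must have shape (n_muscles, 4)")
        if np.any(self.burst_gains < 0):
            raise ValueError("burst_gains must be non-negative")
        if self.burst_centers is None:
            # default: burst at the midpoint of each phase
            cum = np.concatenate([[0.0], np.cumsum(fr)])
            mids = (cum[:-1] + cum[1:]) / 2.0
            self.burst_centers = np.tile(mids, (self.n_muscles, 1))
        self.burst_centers = np.asarray(self.burst_centers, dtype=float)
        if self.burst_centers.shape != (self.n_muscles, 4):
            raise ValueError("burst_centers must have shape (n_muscles, 4)")
        if self.angle_weights is None:
            if self.n_muscles == 9:
                self.angle_weights = _DEFAULT_ANGLE_WEIGHTS.copy()
            else:
                w = np.ones(self.n_muscles)
                w[1::2] = -1.0
                self.angle_weights = w
        self.angle_weights = np.asarray(self.angle_weights, dtype=float)

    def digest(self) -> str:
        """Short stable hash of the configuration (for trial provenance)."""
        h = hashlib.sha256(repr(self).encode()).hexdigest()
        return h[:12]


@dataclass
class PhaseLabels:
    """Per-sample gait-phase labels on one clock.

    ``labels`` holds integer codes indexing :data:`PHASES`; ``cycle_starts``
    are sample indices of TO -> IC transitions (the start of each gait cycle).
    """

    labels: np.ndarray
    fs: float
    cycle_starts: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.cycle_starts = np.asarray(self.cycle_starts, dtype=np.int64)

    @property
    def names(self) -> list[str]:
        return [PHASES[k] for k in self.labels]

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class Trial:
    """One synthetic recording session with multi-rate streams."""

    emg: np.ndarray  # (n_muscles, n_emg) raw sEMG
    fsr_heel: np.ndarray  # (n_fsr,)
    fsr_toe: np.ndarray  # (n_fsr,)
    angle: np.ndarray  # (n_angle,) degrees
    phase_truth: PhaseLabels  # on the FSR clock
    channel_names: tuple[str, ...]
    fs_emg: float
    fs_fsr: float
    fs_angle: float
    condition: str = "noExo"
    meta: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return self.emg.shape[1] / self.fs_emg


def _n_samples(duration_s: float, fs: float) -> int:
    # floor convention: matches truncation semantics of acquisition hardware
    return int(np.floor(duration_s * fs + 1e-9))


def _phase_fractions_for(config: SimConfig) -> np.ndarray:
    """Per-cycle phase fractions, applying any condition-shift duration scaling."""
    fr = np.asarray(config.phase_fractions, dtype=float).copy()
    shift = config.condition_shift
    if shift is None or not shift.phase_duration_factors:
        return fr
    scaled = np.zeros(4, dtype=bool)
    for name, factor in shift.phase_duration_factors.items():
        p = PHASES.index(name)
        fr[p] = config.phase_fractions[p] * factor
        scaled[p] = True
    # renormalise the unscaled phases so the cycle length is preserved and the
    # scaled phases keep their exact factor
    rest = ~scaled
    target = 1.0 - fr[scaled].sum()
    if target <= 0:
        raise ValueError("phase_duration_factors leave no room for other phases")
    fr[rest] *= target / fr[rest].sum()
    return fr


def _schedule(config: SimConfig, rng: np.random.Generator):
    """Draw the cycle schedule.

    Returns (cycle_starts_s, cycle_durations_s, boundaries_s, boundary_phases)
    covering [ -pad, duration + pad ] so that edge bursts and the EMD shift
    have support beyond the recorded interval.
    """
    fr = _phase_fractions_for(config)
    pad = 2.0 * config.cycle_mean_s + 2.0 * config.emd_ms / 1000.0
    total = config.duration_s + 2 * pad
    durs = []
    acc = 0.0
    while acc < total:
        d = config.cycle_mean_s * (1.0 + config.cycle_jitter_cv * rng.standard_normal())
        d = max(d, 0.4 * config.cycle_mean_s)
        durs.append(d)
        acc += d
    durs = np.asarray(durs)
    starts = np.concatenate([[0.0], np.cumsum(durs)[:-1]]) - pad
    # phase boundaries inside each cycle
    edges = np.cumsum(fr)[:-1]  # 3 interior boundaries
    bounds = [starts[0]]
    phases = []
    for s, d in zip(starts, durs):
        inner = s + edges * d
        bounds.extend(list(inner) + [s + d])
        phases.extend([IC, FF, HO, TO])
    return starts, durs, np.asarray(bounds), np.asarray(phases, dtype=np.int8), fr


def _phase_at(times: np.ndarray, bounds: np.ndarray, phases: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(bounds, times, side="right") - 1
    idx = np.clip(idx, 0, len(phases) - 1)
    return phases[idx]


def _kernels(config: SimConfig, starts, durs, times: np.ndarray) -> np.ndarray:
    """Per-muscle burst kernel k_m(t) evaluated at `times` (shape n_m x len(times)).

    Bursts are raised cosines: gain * cos^2(pi * (t - c) / w) on |t - c| <= w/2,
    with width w = burst_width_frac * cycle duration. The area of one burst is
    exactly gain * w / 2, which makes per-phase activation areas analytically
    checkable.
    """
    shift = config.condition_shift
    delay_s = (shift.burst_delay_ms / 1000.0) if shift is not None else 0.0
    gains = config.burst_gains.copy()
    if shift is not None and shift.gain_mult:
        for name, mult in shift.gain_mult.items():
            try:
                m = config.muscle_names.index(name)
            except ValueError:
                continue
            gains[m, :] *= mult
    out = np.zeros((config.n_muscles, len(times)))
    for s, d in zip(starts, durs):
        w = config.burst_width_frac * d
        for p in range(4):
            centers = s + config.burst_centers[:, p] * d + delay_s
            # evaluate only near the widest possible support
            lo = np.searchsorted(times, centers.min() - w / 2)
            hi = np.searchsorted(times, centers.max() + w / 2)
            if hi <= lo:
                continue
            tt = times[lo:hi]
            u = (tt[None, :] - centers[:, None]) / w
            mask = np.abs(u) <= 0.5
            burst = np.where(mask, np.cos(np.pi * u) ** 2, 0.0)
            out[:, lo:hi] += gains[:, p][:, None] * burst
    return out


def _bandlimited_noise(n: int, fs: float, band: tuple[float, float], rng) -> np.ndarray:
    """Zero-mean unit-variance noise band-limited to `band` Hz."""
    white = rng.standard_normal(n + 400)
    hi = min(band[1], 0.99 * fs / 2)
    sos = _sig.butter(4, [band[0], hi], btype="bandpass", fs=fs, output="sos")
    x = _sig.sosfilt(sos, white)[400:]  # drop filter warm-up
    return (x - x.mean()) / x.std()


def generate_trial(config: SimConfig) -> Trial:
    """Generate one synthetic trial. Deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    starts, durs, bounds, bphases, fr = _schedule(config, rng)

    n_emg = _n_samples(config.duration_s, config.fs_emg)
    n_fsr = _n_samples(config.duration_s, config.fs_fsr)
    n_ang = _n_samples(config.duration_s, config.fs_angle)
    t_emg = np.arange(n_emg) / config.fs_emg
    t_fsr = np.arange(n_fsr) / config.fs_fsr
    t_ang = np.arange(n_ang) / config.fs_angle

    emd_s = config.emd_ms / 1000.0

    # envelopes lead the angle drive by exactly emd_s
    env = _kernels(config, starts, durs, t_emg + emd_s)
    emg = np.empty_like(env)
    for m in range(config.n_muscles):
        carrier = _bandlimited_noise(n_emg, config.fs_emg, config.noise_band_hz, rng)
        emg[m] = env[m] * carrier

    # angle: affine readout of the weighted (undelayed) kernel mixture
    drive = config.angle_weights @ _kernels(config, starts, durs, t_ang)
    lo, hi = drive.min(), drive.max()
    a0, a1 = config.angle_range_deg
    if hi - lo < 1e-12:
        angle = np.full(n_ang, (a0 + a1) / 2.0)
    else:
        angle = a0 + (a1 - a0) * (drive - lo) / (hi - lo)
    angle = angle + config.angle_noise_deg * rng.standard_normal(n_ang)

    # foot switches: heel loaded in IC+FF, forefoot loaded in FF+HO
    phase_fsr = _phase_at(t_fsr, bounds, bphases)
    heel = np.isin(phase_fsr, (IC, FF)).astype(float)
    toe = np.isin(phase_fsr, (FF, HO)).astype(float)
    heel = heel + config.fsr_noise * rng.standard_normal(n_fsr)
    toe = toe + config.fsr_noise * rng.standard_normal(n_fsr)

    cyc = np.flatnonzero((phase_fsr[1:] == IC) & (phase_fsr[:-1] == TO)) + 1
    truth = PhaseLabels(labels=phase_fsr, fs=config.fs_fsr, cycle_starts=cyc)

    condition = "noExo" if config.condition_shift is None else "exo"
    meta = {
        "seed": int(config.seed),
        "config_digest": config.digest(),
        "phase_fractions": tuple(float(x) for x in fr),
        "emd_ms": float(config.emd_ms),
    }
    return Trial(
        emg=emg,
        fsr_heel=heel,
        fsr_toe=toe,
        angle=angle,
        phase_truth=truth,
        channel_names=tuple(config.muscle_names),
        fs_emg=config.fs_emg,
        fs_fsr=config.fs_fsr,
        fs_angle=config.fs_angle,
        condition=condition,
        meta=meta,
    )


def weighted_envelope(trial_config: SimConfig) -> np.ndarray:
    """Noise-free weighted envelope mixture on the sEMG clock (for diagnostics).

    Equals the angle drive signal advanced by ``emd_ms``; its cross-correlation
    with the generated angle trace peaks at a lag of the electromechanical
    delay, which is how the simulated EMD structure can be verified.
    """
    rng = np.random.default_rng(trial_config.seed)
    starts, durs, *_ = _schedule(trial_config, rng)
    n_emg = _n_samples(trial_config.duration_s, trial_config.fs_emg)
    t_emg = np.arange(n_emg) / trial_config.fs_emg
    emd_s = trial_config.emd_ms / 1000.0
    k = _kernels(trial_config, starts, durs, t_emg + emd_s)
    return trial_config.angle_weights @ k


def label_phases_from_fsr(
    heel: np.ndarray,
    toe: np.ndarray,
    threshold: float = 0.5,
    fs: float = 500.0,
    min_run_ms: float = 20.0,
) -> PhaseLabels:
    """Derive gait-phase labels from heel and forefoot pressure traces.

    A channel is "on" where it exceeds ``threshold`` x its own maximum. The
    contact pattern maps to phases as: heel only -> IC, both -> FF, toe only
    -> HO, neither -> TO. Spurious runs shorter than ``min_run_ms`` are merged
    into their preceding run. Cycle boundaries are TO -> IC transitions.
    """
    heel = np.asarray(heel, dtype=float)
    toe = np.asarray(toe, dtype=float)
    if heel.shape != toe.shape or heel.ndim != 1:
        raise ValueError("heel and toe must be equal-length 1-D traces")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    h_on = heel > threshold * heel.max() if heel.max() > 0 else np.zeros(len(heel), bool)
    t_on = toe > threshold * toe.max() if toe.max() > 0 else np.zeros(len(toe), bool)
    if not h_on.any() and not t_on.any():
        raise ValueError("no contacts detected")

    labels = np.full(len(heel), TO, dtype=np.int8)
    labels[h_on & ~t_on] = IC
    labels[h_on & t_on] = FF
    labels[~h_on & t_on] = HO

    min_run = max(int(round(min_run_ms * fs / 1000.0)), 1)
    labels = _merge_short_runs(labels, min_run)

    cyc = np.flatnonzero((labels[1:] == IC) & (labels[:-1] == TO)) + 1
    return PhaseLabels(labels=labels, fs=fs, cycle_starts=cyc)


def _merge_short_runs(labels: np.ndarray, min_run: int) -> np.ndarray:
    """Merge runs shorter than min_run samples into the preceding run."""
    labels = labels.copy()
    for _ in range(8):  # merging can create new short runs; a few passes settle
        change = np.flatnonzero(np.diff(labels)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(labels)]])
        short = np.flatnonzero((ends - starts) < min_run)
        if len(short) == 0 or len(starts) == 1:
            break
        for i in short:
            if i == 0:
                labels[starts[0] : ends[0]] = labels[ends[0]] if ends[0] < len(labels) else labels[0]
            else:
                labels[starts[i] : ends[i]] = labels[starts[i] - 1]
    return labels


def make_condition_pair(
    config: SimConfig, shift: ConditionShift | None = None
) -> tuple[Trial, Trial]:
    """Generate a (noExo, exo) trial pair from the same generator family.

    The two trials share the muscle set, burst layout and joint-profile family;
    the exo trial applies ``shift`` (default :func:`default_exo_shift`) and uses
    an independent noise realisation.
    """
    if shift is None:
        shift = default_exo_shift()
    cfg_a = replace(config, condition_shift=None)
    cfg_b = replace(config, condition_shift=shift, seed=config.seed + 10007)
    return generate_trial(cfg_a), generate_trial(cfg_b)
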