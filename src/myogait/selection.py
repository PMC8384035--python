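"""Per-phase muscle effects and activation-driven muscle subset selection.

For each muscle the activation a(t) is integrated over every phase segment of
every complete gait cycle, giving per-phase areas A_i (activation-seconds)
averaged across cycles. Normalising each muscle's areas by that muscle's own
maximum yields the unitless effect E_i in [0, 1], whose row maximum is exactly
1 by construction.

Selection discards redundant muscles: a muscle whose activation level is
similar across most of the cycle carries little phase-discriminative
information. Formally, muscle m is discarded when at least three of its
phase-effects have a within-``delta`` partner in the same row, i.e. there are
>= 3 phases p for which some other phase q satisfies |E[m,p] - E[m,q]| <=
delta. After discarding, any phase left without a retained muscle of effect at
least ``min_phase_cover`` gets back the discarded muscle strongest in that
phase, so every phase keeps a dedicated, strongly activated muscle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import IC, PHASES, TO, MUSCLES_9, PhaseLabels

#: Reference per-phase activation effects for the nine lower-limb muscles
#: during level treadmill walking (rows follow MUSCLES_9, columns IC/FF/HO/TO).
#: Used as the worked example for the selection rule: applying
#: :func:`select_muscles` with the default threshold retains RF, TA, ST, GM, GL.
REFERENCE_NINE_MUSCLE_EFFECTS = np.array(
    [
        [1.00, 0.49, 0.25, 0.29],  # RF
        [1.00, 0.35, 0.27, 0.33],  # VM
        [1.00, 0.54, 0.56, 0.53],  # VL
        [0.81, 0.18, 0.21, 1.00],  # TA
        [0.21, 0.94, 1.00, 0.21],  # SL
        [0.74, 0.24, 0.23, 1.00],  # ST
        [1.00, 0.88, 0.96, 0.87],  # BF
        [0.16, 0.61, 1.00, 0.16],  # GM
        [0.44, 0.78, 1.00, 0.18],  # GL
    ]
)


@dataclass
class EffectMatrix:
    """Per-muscle, per-phase activation areas and normalized effects."""

    muscles: tuple[str, ...]
    areas: np.ndarray  # (n_muscles, 4), activation-seconds
    effects: np.ndarray  # (n_muscles, 4), row max == 1
    phases: tuple[str, ...] = PHASES
    n_cycles_averaged: int = 0


@dataclass
class SelectionReport:
    """Outcome of the selection rule with per-muscle explanations."""

    retained: list[str]
    discarded: list[str]
    readded: list[str]
    reasons: dict[str, str] = field(default_factory=dict)
    delta: float = 0.15
    min_phase_cover: float = 0.6


def phase_areas(
    a: np.ndarray, labels: PhaseLabels | np.ndarray, fs: float | None = None
) -> tuple[np.ndarray, int]:
    """Average per-phase area of one activation trace over complete cycles.

    ``labels`` must be on the same clock as ``a`` (pass a plain label array
    plus ``fs``, or a :class:`PhaseLabels`). Each complete cycle (between
    successive TO->IC transitions) contributes the trapezoidal integral of a(t)
    over each phase segment; areas are averaged across cycles.

    Returns (areas[4], n_cycles).
    """
    a = np.asarray(a, dtype=float)
    if isinstance(labels, PhaseLabels):
        lab = labels.labels
        fs = labels.fs
    else:
        lab = np.asarray(labels)
        if fs is None:
            raise ValueError("fs is required when labels is a plain array")
    if len(a) != len(lab):
        raise ValueError("activation and labels must share one clock")
    starts = np.flatnonzero((lab[1:] == IC) & (lab[:-1] == TO)) + 1
    if len(starts) < 2:
        raise ValueError("need at least one complete gait cycle")
    dt = 1.0 / fs
    acc = np.zeros(4)
    n_cycles = len(starts) - 1
    for c0, c1 in zip(starts[:-1], starts[1:]):
        seg_lab = lab[c0:c1]
        seg_a = a[c0:c1]
        change = np.flatnonzero(np.diff(seg_lab)) + 1
        run_starts = np.concatenate([[0], change])
        run_ends = np.concatenate([change, [len(seg_lab)]])
        for rs, re in zip(run_starts, run_ends):
            p = int(seg_lab[rs])
            if re - rs >= 2:
                acc[p] += np.trapezoid(seg_a[rs:re], dx=dt)
    return acc / n_cycles, n_cycles


def effect_matrix(
    areas: np.ndarray, muscles: tuple[str, ...] | list[str], n_cycles: int = 0
) -> EffectMatrix:
    """Normalise per-muscle areas by each muscle's own maximum (E = A / max A)."""
    areas = np.atleast_2d(np.asarray(areas, dtype=float))
    if areas.shape[1] != 4:
        raise ValueError("areas must have 4 phase columns")
    if np.any(areas < 0):
        raise ValueError("areas must be non-negative")
    if len(muscles) != areas.shape[0]:
        raise ValueError("muscle names must match area rows")
    row_max = areas.max(axis=1)
    zero = np.flatnonzero(row_max == 0)
    if len(zero):
        raise ValueError(f"muscle '{muscles[zero[0]]}' has zero activation in every phase")
    effects = areas / row_max[:, None]
    return EffectMatrix(
        muscles=tuple(muscles), areas=areas, effects=effects,
        n_cycles_averaged=n_cycles,
    )


def _partnered_phase_count(row: np.ndarray, delta: float) -> int:
    """Number of phases whose effect has a within-delta partner in the same row."""
    diff = np.abs(row[:, None] - row[None, :])
    np.fill_diagonal(diff, np.inf)
    return int(np.sum(diff.min(axis=1) <= delta))


def select_muscles(
    E: EffectMatrix | np.ndarray,
    delta: float = 0.15,
    min_phase_cover: float = 0.6,
    muscles: tuple[str, ...] | None = None,
) -> SelectionReport:
    """Apply the redundancy discard rule and the phase-coverage repair.

    Discards muscle m when >= 3 of its phase-effects have a within-``delta``
    partner in the same row (its activation profile is nearly flat across most
    of the cycle). If a phase then has no retained muscle with effect >=
    ``min_phase_cover``, the discarded muscle strongest in that phase is
    re-added. Ties break by input order.
    """
    if isinstance(E, EffectMatrix):
        eff = E.effects
        names = E.muscles
    else:
        eff = np.atleast_2d(np.asarray(E, dtype=float))
        names = tuple(muscles) if muscles is not None else tuple(
            f"M{i + 1}" for i in range(eff.shape[0])
        )
    if not (0.0 < delta < 1.0):
        raise ValueError("delta must be in (0, 1)")
    n = eff.shape[0]
    retained: list[int] = []
    discarded: list[int] = []
    reasons: dict[str, str] = {}
    for m in range(n):
        cnt = _partnered_phase_count(eff[m], delta)
        if cnt >= 3:
            discarded.append(m)
            reasons[names[m]] = (
                f"discarded: {cnt} phases with a within-{delta:g} partner"
            )
        else:
            retained.append(m)
            reasons[names[m]] = (
                f"retained: only {cnt} phases with a within-{delta:g} partner"
            )
    readded: list[int] = []
    current = set(retained)
    for p in range(4):
        best = max((eff[m, p] for m in current), default=-np.inf)
        if best < min_phase_cover and discarded:
            cand = max(
                (m for m in discarded if m not in current),
                key=lambda m: eff[m, p],
                default=None,
            )
            if cand is not None:
                current.add(cand)
                readded.append(cand)
                reasons[names[cand]] += (
                    f"; re-added for phase {PHASES[p]} coverage"
                )
    final = sorted(current)
    if not final:
        raise ValueError("no muscles retained even after coverage repair")
    return SelectionReport(
        retained=[names[m] for m in final],
        discarded=[names[m] for m in discarded if m not in readded],
        readded=[names[m] for m in readded],
        reasons=reasons,
        delta=delta,
        min_phase_cover=min_phase_cover,
    )


def effects_from_trial(trial, params=None, channels=None) -> EffectMatrix:
    """Convenience: raw trial -> activation traces -> effect matrix."""
    from .activation import ActivationParams, activation_trace
    from .io import align

    aligned = align(trial)
    if params is None:
        params = ActivationParams(fs=aligned.fs_emg)
    names = list(channels) if channels is not None else list(aligned.channel_names)
    rows = []
    n_cycles = 0
    for name in names:
        ch = aligned.channel_names.index(name)
        tr = activation_trace(aligned.emg[ch], params)
        areas, n_cycles = phase_areas(tr.a, aligned.phase, fs=aligned.fs_emg)
        rows.append(areas)
    return effect_matrix(np.vstack(rows), tuple(names), n_cycles=n_cycles)
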