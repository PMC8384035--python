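"""Per-phase areas, effect normalisation, and the muscle subset rule."""

import itertools

import numpy as np
import pytest

from myogait.activation import ActivationParams, activation_trace
from myogait.io import align
from myogait.selection import (
    REFERENCE_NINE_MUSCLE_EFFECTS,
    effect_matrix,
    phase_areas,
    select_muscles,
)
from myogait.simulate import MUSCLES_9, PhaseLabels


def _one_cycle_labels(durations_s, fs=1000.0, n_cycles=2):
    lab = []
    for _ in range(n_cycles):
        for p, d in enumerate(durations_s):
            lab.extend([p] * int(round(d * fs)))
    return PhaseLabels(labels=np.array(lab), fs=fs, cycle_starts=[])


class TestPhaseAreas:
    def test_unit_activation_gives_phase_durations(self):
        # complete cycles lie between successive TO->IC transitions, so
        # 4 repeats yield 3 interior transitions = 2 measurable cycles
        durations = (0.1, 0.35, 0.30, 0.25)
        labels = _one_cycle_labels(durations, fs=1000.0, n_cycles=4)
        a = np.ones(len(labels))
        areas, n_cycles = phase_areas(a, labels)
        assert n_cycles == 2
        assert np.allclose(areas, durations, atol=3e-3)

    def test_zero_activation_zero_areas(self):
        labels = _one_cycle_labels((0.1, 0.35, 0.30, 0.25), n_cycles=3)
        areas, _ = phase_areas(np.zeros(len(labels)), labels)
        assert np.all(areas == 0)

    def test_no_complete_cycle_raises(self):
        labels = PhaseLabels(labels=np.zeros(100, dtype=np.int8), fs=1000.0, cycle_starts=[])
        with pytest.raises(ValueError, match="complete gait cycle"):
            phase_areas(np.ones(100), labels)

    def test_single_burst_area_matches_closed_form(self):
        """A raised-cosine burst of gain g and width w has area exactly g*w/2."""
        from myogait.simulate import SimConfig, generate_trial

        gains = np.zeros((2, 4))
        gains[0, 1] = 0.8  # single FF burst on muscle 1
        gains[1, 0] = 0.5  # keep the other channel non-silent
        cfg = SimConfig(
            duration_s=30, seed=13, n_muscles=2, burst_gains=gains,
            cycle_jitter_cv=0.0, angle_noise_deg=0.0,
        )
        trial = generate_trial(cfg)
        aligned = align(trial)
        # integrate the noise-free envelope itself (the oracle path)
        from myogait.simulate import _kernels, _n_samples, _schedule

        rng = np.random.default_rng(cfg.seed)
        starts, durs, *_ = _schedule(cfg, rng)
        t = np.arange(_n_samples(cfg.duration_s, cfg.fs_emg)) / cfg.fs_emg
        env = _kernels(cfg, starts, durs, t + cfg.emd_ms / 1000.0)[0]
        areas, _ = phase_areas(env, aligned.phase, fs=cfg.fs_emg)
        w = cfg.burst_width_frac * cfg.cycle_mean_s
        expected = 0.8 * w / 2.0
        assert areas[1] == pytest.approx(expected, rel=0.01)


class TestEffectMatrix:
    def test_row_normalisation(self):
        E = effect_matrix(np.array([[2.0, 1.0, 1.0, 1.0]]), ("M1",))
        assert np.allclose(E.effects, [[1.0, 0.5, 0.5, 0.5]])

    def test_row_max_is_exactly_one(self):
        rng = np.random.default_rng(3)
        areas = rng.random((6, 4)) + 0.01
        E = effect_matrix(areas, tuple(f"M{i}" for i in range(6)))
        assert np.allclose(E.effects.max(axis=1), 1.0, atol=1e-12)

    def test_reference_table_rows_are_self_normalised(self):
        assert np.allclose(REFERENCE_NINE_MUSCLE_EFFECTS.max(axis=1), 1.0)

    def test_phase_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        areas = rng.random((3, 4)) + 0.1
        perm = np.array([2, 0, 3, 1])
        E1 = effect_matrix(areas, ("A", "B", "C"))
        E2 = effect_matrix(areas[:, perm], ("A", "B", "C"))
        assert np.allclose(E1.effects[:, perm], E2.effects)

    def test_all_zero_row_names_the_muscle(self):
        areas = np.array([[1.0, 1, 1, 1], [0.0, 0, 0, 0]])
        with pytest.raises(ValueError, match="'DEAD'"):
            effect_matrix(areas, ("OK", "DEAD"))


class TestSelectMuscles:
    def test_reference_table_retains_published_subset(self):
        rep = select_muscles(REFERENCE_NINE_MUSCLE_EFFECTS, delta=0.15, muscles=MUSCLES_9)
        assert rep.retained == ["RF", "TA", "ST", "GM", "GL"]
        assert set(rep.discarded) == {"VM", "VL", "SL", "BF"}

    def test_subset_stable_across_delta_interval(self):
        # interval interior only: 0.06 and 0.19 sit exactly on row-gap
        # boundaries of the reference table, where float representation of
        # e.g. |0.94 - 1.00| decides the comparison
        for delta in np.arange(0.065, 0.186, 0.01):
            rep = select_muscles(REFERENCE_NINE_MUSCLE_EFFECTS, delta=float(delta), muscles=MUSCLES_9)
            assert rep.retained == ["RF", "TA", "ST", "GM", "GL"], f"delta={delta}"

    def test_matches_brute_force_rule_oracle(self):
        """The vectorised partner-count rule equals a literal enumeration."""
        rng = np.random.default_rng(8)
        for _ in range(50):
            eff = rng.random((5, 4))
            eff = eff / eff.max(axis=1, keepdims=True)
            rep = select_muscles(eff, delta=0.15, min_phase_cover=0.0)
            expected = []
            for m in range(5):
                count = 0
                for p in range(4):
                    if any(
                        q != p and abs(eff[m, p] - eff[m, q]) <= 0.15
                        for q in range(4)
                    ):
                        count += 1
                if count < 3:
                    expected.append(f"M{m + 1}")
            assert rep.retained == expected or (not expected and rep.retained)

    def test_identity_effects_all_recovered_by_coverage(self):
        eff = np.eye(4)
        rep = select_muscles(eff, delta=0.15)
        # each muscle is discarded (three mutually-similar zeros), then
        # re-added as the unique per-phase cover
        assert len(rep.retained) == 4
        assert set(rep.readded) == set(rep.retained)

    def test_total_redundancy_collapses_to_minimal_cover(self):
        eff = np.ones((5, 4))
        rep = select_muscles(eff, delta=0.15)
        assert len(rep.retained) <= 4
        assert rep.retained == ["M1"]  # input-order tie-break, covers all phases

    def test_permutation_consistency(self):
        eff = REFERENCE_NINE_MUSCLE_EFFECTS
        perm = np.array([4, 2, 0, 8, 6, 1, 3, 5, 7])
        names = tuple(MUSCLES_9[i] for i in perm)
        rep = select_muscles(eff[perm], delta=0.15, muscles=names)
        assert set(rep.retained) == {"RF", "TA", "ST", "GM", "GL"}

    def test_bad_delta_rejected(self):
        with pytest.raises(ValueError):
            select_muscles(REFERENCE_NINE_MUSCLE_EFFECTS, delta=1.5, muscles=MUSCLES_9)


def test_simulated_trial_effects_reflect_burst_gains(short_trial):
    """Muscles dominantly bursting in one phase get their top effect there."""
    aligned = align(short_trial)
    params = ActivationParams(fs=short_trial.fs_emg)
    for name, dominant in [("TA", "TO"), ("GM", "HO")]:
        ch = short_trial.channel_names.index(name)
        tr = activation_trace(short_trial.emg[ch], params)
        areas, _ = phase_areas(tr.a, aligned.phase, fs=short_trial.fs_emg)
        E = effect_matrix(areas[None, :], (name,))
        from myogait.simulate import PHASES

        assert PHASES[int(E.effects[0].argmax())] == dominant
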