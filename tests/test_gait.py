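"""Stance detection, duty factors, relative phases and gait labelling."""

import math

import numpy as np
import pytest

from tegotae.gait import (GaitDiagram, InsufficientDataError,
                          classify_gait, clean_diagram, convergence_time,
                          detect_stance, duty_factors, estimate_period,
                          relative_phases, touchdown_times, GaitLabel)
from tegotae.legs import LEGS, Leg, mirror

from conftest import synth_diagram

QUAD = (Leg.L1, Leg.R1, Leg.L3, Leg.R3)


class TestDetectStance:
    def test_constant_force_single_leg(self):
        forces = np.zeros((100, 6))
        forces[:, Leg.L1.index] = 8.0
        d = detect_stance(forces, 0.01)
        assert d.stance[:, Leg.L1.index].all()
        assert not d.stance[:, 1:].any() or not d.stance[:, [l.index for l in LEGS if l != Leg.L1]].any()

    def test_fraction_rule_matches_published_instance(self):
        """10% of a 15 N peak reproduces the 1.5 N threshold."""
        forces = np.zeros((50, 6))
        forces[:, 0] = 15.0
        d = detect_stance(forces, 0.01, ("fraction", 0.10))
        assert d.threshold == pytest.approx(1.5)

    def test_square_wave_duty(self):
        t = np.arange(1000)
        forces = np.zeros((1000, 6))
        forces[:, 2] = np.where((t % 100) < 40, 8.0, 0.0)
        d = detect_stance(forces, 0.01)
        assert d.stance[:, 2].mean() == pytest.approx(0.40)

    def test_absolute_mode(self):
        forces = np.full((10, 6), 2.0)
        assert detect_stance(forces, 0.01, ("absolute", 1.5)).stance.all()
        assert not detect_stance(forces, 0.01, ("absolute", 3.0)).stance.any()

    def test_all_zero_series_warns_and_returns_all_swing(self):
        with pytest.warns(UserWarning):
            d = detect_stance(np.zeros((10, 6)), 0.01)
        assert not d.stance.any()

    def test_thresholding_idempotent_on_binary_signal(self):
        rng = np.random.default_rng(2)
        raster = (rng.random((200, 6)) < 0.5).astype(float)
        d = detect_stance(raster * 8.0, 0.01)
        np.testing.assert_array_equal(d.stance, raster.astype(np.uint8))


class TestDutyFactors:
    def test_half_cycle_oscillation(self):
        d = synth_diagram({leg: 0.0 for leg in LEGS}, duty=0.5)
        table = duty_factors(d, window_periods=6, period=2.0)
        np.testing.assert_allclose(table.per_leg, 0.5, atol=0.01)

    def test_all_stance_is_one(self):
        d = GaitDiagram(np.ones((1000, 6)), 0.01, 1.0)
        table = duty_factors(d, window_periods=6, period=1.0)
        np.testing.assert_allclose(table.per_leg, 1.0)

    def test_square_wave_duty_value(self):
        d = synth_diagram({leg: 0.0 for leg in LEGS}, duty=0.4)
        table = duty_factors(d, window_periods=6, period=2.0)
        np.testing.assert_allclose(table.per_leg, 0.4, atol=0.01)

    def test_insufficient_span_names_requirement(self):
        d = synth_diagram({leg: 0.0 for leg in LEGS}, duty=0.5, n_cycles=3)
        with pytest.raises(InsufficientDataError, match="required"):
            duty_factors(d, window_periods=6, period=2.0)

    def test_bounds_and_swing_complement(self):
        rng = np.random.default_rng(8)
        raster = (rng.random((1200, 6)) < 0.6).astype(np.uint8)
        d = GaitDiagram(raster, 0.01, 1.0)
        table = duty_factors(d, window_periods=6, period=1.0)
        assert np.all(table.per_leg >= 0) and np.all(table.per_leg <= 1)
        swing = 1.0 - d.window(d.duration - 6.0, d.duration).stance.mean(axis=0)
        np.testing.assert_allclose(table.per_leg, 1.0 - swing)


class TestRelativePhases:
    def test_simultaneous_touchdowns(self):
        d = synth_diagram({Leg.L1: 0.0, Leg.R1: 0.0}, duty=0.5, legs=(Leg.L1, Leg.R1))
        ph = relative_phases(touchdown_times(d))
        assert ph[Leg.L1.index, Leg.R1.index] == pytest.approx(0.0, abs=0.05)

    def test_anti_phase_square_waves(self):
        d = synth_diagram({Leg.L1: 0.0, Leg.R1: 0.5}, duty=0.5, legs=(Leg.L1, Leg.R1))
        ph = relative_phases(touchdown_times(d))
        assert ph[Leg.L1.index, Leg.R1.index] == pytest.approx(math.pi, abs=0.05)

    def test_metachronal_thirds(self):
        d = synth_diagram({Leg.L3: 0.0, Leg.L2: 1 / 3, Leg.L1: 2 / 3}, duty=0.5,
                          legs=(Leg.L1, Leg.L2, Leg.L3))
        ph = relative_phases(touchdown_times(d))
        assert ph[Leg.L3.index, Leg.L2.index] == pytest.approx(2 * math.pi / 3, abs=0.05)
        assert ph[Leg.L2.index, Leg.L1.index] == pytest.approx(2 * math.pi / 3, abs=0.05)

    def test_too_few_events_is_nan(self):
        d = synth_diagram({Leg.L1: 0.0}, duty=0.5, n_cycles=8, legs=(Leg.L1,))
        ph = relative_phases(touchdown_times(d), period=2.0)
        assert np.isnan(ph[Leg.L1.index, Leg.L2.index])

    def test_period_estimate(self):
        d = synth_diagram({leg: 0.0 for leg in LEGS}, duty=0.5, period=2.0)
        assert estimate_period(touchdown_times(d)) == pytest.approx(2.0, rel=0.02)


def _tetrapod_offsets(jitter=0.0):
    # diagonal pairs (L3,R2), (L2,R1), (L1,R3) stepping a third of a cycle apart,
    # ipsilateral touchdown order hind -> middle -> fore on both sides
    base = {Leg.L3: 0.0, Leg.L2: 1 / 3, Leg.L1: 2 / 3,
            Leg.R2: 0.0, Leg.R1: 1 / 3, Leg.R3: 2 / 3}
    return {leg: (v + jitter * ((leg.index % 3) - 1)) % 1.0 for leg, v in base.items()}


def _tripod_offsets(jitter=0.0):
    base = {Leg.L1: 0.0, Leg.R2: 0.0, Leg.L3: 0.0,
            Leg.R1: 0.5, Leg.L2: 0.5, Leg.R3: 0.5}
    return {leg: (v + jitter * ((leg.index % 3) - 1)) % 1.0 for leg, v in base.items()}


class TestClassifier:
    @pytest.mark.parametrize("delta", [math.pi / 6, math.pi / 4])
    @pytest.mark.parametrize("duty", [0.5, 0.65])
    @pytest.mark.parametrize("jitter", [0.0, 0.03])
    def test_tripod_round_trip(self, delta, duty, jitter):
        d = synth_diagram(_tripod_offsets(jitter), duty=duty)
        assert classify_gait(d, delta=delta).label == "tripod"

    def test_tripod_from_synthetic_phase_set(self):
        # phases (L1..L3, R1..R3) = (0, pi, 0, pi, 0, pi): triads alternate
        offsets = {leg: (0.5 if leg in (Leg.L2, Leg.R1, Leg.R3) else 0.0)
                   for leg in LEGS}
        assert classify_gait(synth_diagram(offsets, duty=0.5)).label == "tripod"

    @pytest.mark.parametrize("delta", [math.pi / 6, math.pi / 4])
    @pytest.mark.parametrize("duty", [0.55, 0.7])
    @pytest.mark.parametrize("jitter", [0.0, 0.03])
    def test_tetrapod_round_trip(self, delta, duty, jitter):
        d = synth_diagram(_tetrapod_offsets(jitter), duty=duty)
        assert classify_gait(d, delta=delta).label == "tetrapod"

    @pytest.mark.parametrize("delta", [math.pi / 6, math.pi / 4])
    @pytest.mark.parametrize("duty", [0.78, 0.85])
    def test_wave_round_trip(self, delta, duty):
        d = synth_diagram(_tetrapod_offsets(), duty=duty)
        assert classify_gait(d, delta=delta).label == "wave"

    @pytest.mark.parametrize("delta", [math.pi / 6, math.pi / 4])
    @pytest.mark.parametrize("duty", [0.5, 0.6])
    def test_trot_round_trip(self, delta, duty):
        d = synth_diagram({Leg.L1: 0.0, Leg.R3: 0.0, Leg.R1: 0.5, Leg.L3: 0.5},
                          duty=duty, legs=QUAD)
        label = classify_gait(d, delta=delta)
        assert label.label == "trot_ls_walk"
        assert label.sub_label == "trot"

    @pytest.mark.parametrize("delta", [math.pi / 6, math.pi / 4])
    def test_ls_walk_round_trip(self, delta):
        # staggered touchdown order L1, R3, R1, L3 at quarter-cycle lags
        d = synth_diagram({Leg.L1: 0.0, Leg.R3: 0.25, Leg.R1: 0.5, Leg.L3: 0.75},
                          duty=0.6, legs=QUAD)
        label = classify_gait(d, delta=delta)
        assert label.label == "trot_ls_walk"
        assert label.sub_label == "ls_walk"

    def test_one_sided_metachronal_is_other(self):
        # left legs step back-to-front, right legs front-to-back: the failure
        # pattern of the ablated controller, not an insect gait
        offsets = {Leg.L3: 0.0, Leg.L2: 1 / 3, Leg.L1: 2 / 3,
                   Leg.R1: 0.0, Leg.R2: 1 / 3, Leg.R3: 2 / 3}
        assert classify_gait(synth_diagram(offsets, duty=0.5)).label == "other"

    @pytest.mark.parametrize("builder, expected", [
        (lambda: synth_diagram(_tripod_offsets(), duty=0.5), "tripod"),
        (lambda: synth_diagram(_tetrapod_offsets(), duty=0.65), "tetrapod"),
        (lambda: synth_diagram({Leg.L1: 0.0, Leg.R3: 0.0, Leg.R1: 0.5,
                                Leg.L3: 0.5}, duty=0.55, legs=QUAD),
         "trot_ls_walk"),
    ])
    def test_mirror_invariance(self, builder, expected):
        d = builder()
        mirrored = GaitDiagram(mirror(d.stance), d.sample_dt, d.threshold, d.t0)
        assert classify_gait(d).label == expected
        assert classify_gait(mirrored).label == expected

    def test_chatter_cleaning_removes_spurious_events(self):
        d = synth_diagram({Leg.L1: 0.0, Leg.R1: 0.5}, duty=0.5,
                          legs=(Leg.L1, Leg.R1))
        noisy = d.stance.copy()
        noisy[37:39, Leg.L1.index] = 0   # force dip inside stance
        noisy[120:122, Leg.R1.index] = 1  # spike inside swing
        noisy_d = GaitDiagram(noisy, d.sample_dt, d.threshold)
        cleaned = clean_diagram(noisy_d, 0.3)
        np.testing.assert_array_equal(cleaned.stance, d.stance)


class TestConvergenceTime:
    def _labels(self, names):
        return [GaitLabel(n) for n in names]

    def test_stable_from_start(self):
        starts = [0.0, 2.0, 4.0, 6.0]
        labels = self._labels(["tetrapod"] * 4)
        assert convergence_time(starts, labels) == 0.0

    def test_single_flip(self):
        starts = [0.0, 2.0, 4.0, 6.0]
        labels = self._labels(["other", "other", "tetrapod", "tetrapod"])
        assert convergence_time(starts, labels) == 4.0

    def test_never_stable_is_non_convergent(self):
        starts = [0.0, 2.0, 4.0, 6.0]
        labels = self._labels(["other", "tetrapod", "other", "tetrapod"])
        assert convergence_time(starts, labels) == math.inf
        labels = self._labels(["tetrapod", "other", "tetrapod", "other"])
        assert convergence_time(starts, labels) == math.inf
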