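"""Bias bookkeeping, the well-tempered height rule, FES estimation."""

import math

import numpy as np
import pytest

from sumdkit.constants import KB
from sumdkit.dynamics import DynamicsConfig, State
from sumdkit.metadynamics import (
    BiasState,
    Hill,
    MetadConfig,
    bias_potential,
    closed_state_fraction,
    coordinate_cv,
    estimate_fes,
    next_hill_height,
    polar_angle_cv,
    read_hills,
    run_metadynamics,
    write_hills,
)


def make_bias(hills=(), cvs=None, gamma=6.0, temperature=298.0):
    cvs = cvs or (coordinate_cv(0),)
    bias = BiasState(cvs, gamma, temperature)
    for h in hills:
        bias.add_hill(h)
    return bias


class TestBiasPotential:
    def test_no_hills_is_zero(self):
        assert bias_potential(make_bias(), [0.0]) == 0.0

    def test_single_hill_center_value(self):
        bias = make_bias([Hill((2.0,), (0.3,), 0.25, 0.5)])
        assert bias_potential(bias, [2.0]) == pytest.approx(0.25)

    def test_matches_term_by_term_summation(self, rng):
        """20 random hills at a random probe: independent closed-form sum."""
        hills = [
            Hill(
                (rng.uniform(-5, 5), rng.uniform(-math.pi, math.pi)),
                (rng.uniform(0.1, 1.0), rng.uniform(0.1, 1.0)),
                rng.uniform(0.05, 0.5),
                float(i),
            )
            for i in range(20)
        ]
        cvs = (coordinate_cv(0), polar_angle_cv())
        bias = make_bias(hills, cvs=cvs)
        probe = np.array([1.3, 2.9])
        expected = 0.0
        for h in hills:
            d0 = probe[0] - h.center[0]
            d1 = (probe[1] - h.center[1] + math.pi) % (2 * math.pi) - math.pi
            expected += h.height * math.exp(
                -(d0**2) / (2 * h.widths[0] ** 2) - (d1**2) / (2 * h.widths[1] ** 2)
            )
        assert bias_potential(bias, probe) == pytest.approx(expected, rel=1e-12)

    def test_periodic_wrapping_of_angle_cv(self):
        bias = make_bias(
            [Hill((math.pi - 0.05,), (0.3,), 0.2, 0.0)], cvs=(polar_angle_cv(),)
        )
        near = bias_potential(bias, [-math.pi + 0.05])  # 0.1 rad away via wrap
        far = bias_potential(bias, [0.0])
        assert near > far

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bias_potential(make_bias(), [0.0, 1.0])


class TestNextHillHeight:
    CONFIG = MetadConfig(cvs=(coordinate_cv(0),), sigmas=(0.04,))

    def test_initial_height_at_zero_bias(self):
        assert next_hill_height(make_bias(), [0.0], self.CONFIG) == pytest.approx(0.3)

    def test_unit_exponent_gives_w0_over_e(self):
        """V = kB (gamma-1) T at the hill point -> height w0 / e."""
        gamma, temp = 6.0, 298.0
        target_v = KB * (gamma - 1) * temp
        bias = make_bias([Hill((0.0,), (1.0,), target_v, 0.0)])
        h = next_hill_height(bias, [0.0], self.CONFIG)
        assert h == pytest.approx(0.3 / math.e, rel=1e-12)

    def test_huge_bias_factor_recovers_standard_metadynamics(self):
        config = MetadConfig(cvs=(coordinate_cv(0),), sigmas=(0.04,), bias_factor=1e9)
        bias = make_bias([Hill((0.0,), (1.0,), 5.0, 0.0)], gamma=1e9)
        assert next_hill_height(bias, [0.0], config) == pytest.approx(0.3, abs=1e-6)


class TestRunMetadynamics:
    def metad_config(self, duration, **kw):
        return MetadConfig(
            cvs=(coordinate_cv(0),),
            sigmas=(0.25,),
            stride=0.5,
            duration=duration,
            **kw,
        )

    def test_duration_below_stride_deposits_nothing(self, double_well_1d, rng):
        dyn = DynamicsConfig(dt=0.01, temperature=298.0)
        start = State(position=np.array([-1.5]), velocity=np.zeros(1))
        bias, seg = run_metadynamics(
            double_well_1d, start, dyn, self.metad_config(0.4), rng
        )
        assert bias.hills == []

    def test_hill_count_is_floor_duration_over_stride(self, double_well_1d, rng):
        dyn = DynamicsConfig(dt=0.01, temperature=298.0)
        start = State(position=np.array([-1.5]), velocity=np.zeros(1))
        for duration in (10.0, 10.3, 49.9):
            bias, _ = run_metadynamics(
                double_well_1d, start, dyn, self.metad_config(duration),
                np.random.default_rng(1),
            )
            assert len(bias.hills) == math.floor(duration / 0.5)

    def test_fixed_seed_identical_hill_sequence(self, double_well_1d):
        dyn = DynamicsConfig(dt=0.01, temperature=298.0)
        start = State(position=np.array([-1.5]), velocity=np.zeros(1))
        runs = [
            run_metadynamics(
                double_well_1d, start, dyn, self.metad_config(20.0),
                np.random.default_rng(4),
            )[0]
            for _ in range(2)
        ]
        assert [h.center for h in runs[0].hills] == [h.center for h in runs[1].hills]
        assert [h.height for h in runs[0].hills] == [h.height for h in runs[1].hills]

    def test_hill_heights_damp_in_revisited_region(self, harmonic_1d):
        """Single well: heights decay as the well is repeatedly revisited."""
        dyn = DynamicsConfig(dt=0.01, temperature=298.0)
        start = State(position=np.array([0.0]), velocity=np.zeros(1))
        bias, _ = run_metadynamics(
            harmonic_1d, start, dyn, self.metad_config(150.0),
            np.random.default_rng(2),
        )
        h = np.array([hill.height for hill in bias.hills])
        assert h[0] == pytest.approx(0.3)
        # late hills in the (repeatedly visited) well are much smaller
        assert h[-20:].mean() < 0.5 * h[:20].mean()

    def test_grid_and_analytic_bias_agree(self, double_well_1d):
        """Both evaluation modes produce the same trajectory and hills."""
        dyn = DynamicsConfig(dt=0.01, temperature=298.0)
        start = State(position=np.array([-1.5]), velocity=np.zeros(1))
        kw = dict(bias_factor=6.0, temperature=298.0)
        b_a, s_a = run_metadynamics(
            double_well_1d, start, dyn,
            self.metad_config(30.0, bias_eval="analytic", **kw),
            np.random.default_rng(6),
        )
        b_g, s_g = run_metadynamics(
            double_well_1d, start, dyn,
            self.metad_config(30.0, bias_eval="grid", grid_bounds=((-9.0, 9.0),),
                              grid_points=8192, **kw),
            np.random.default_rng(6),
        )
        assert len(b_a.hills) == len(b_g.hills)
        np.testing.assert_allclose(
            [h.center[0] for h in b_a.hills],
            [h.center[0] for h in b_g.hills],
            atol=0.05,
        )

    def test_biased_run_crosses_barrier_unbiased_does_not(self, double_well_1d):
        """Paired budget: metadynamics >= 5 crossings where plain MD has none.

        The wells are deepened so the central barrier is ~6.7 kcal/mol
        (~11 kT at 298 K): thermally inaccessible on this budget, but
        routinely crossed once the bias fills the starting well.  A
        light particle keeps the post-fill diffusion across the barrier
        region fast.
        """
        from sumdkit.toy_system import Confinement, GaussianWell, ToySystem

        deep = ToySystem(
            dims=1,
            wells=[GaussianWell((-1.5,), 8.0, 0.7), GaussianWell((1.5,), 8.0, 0.7)],
            barriers=[],
            orthosteric_center=(-1.5,),
            ligand_mass=3.0,
            confinement=Confinement(half_length=4.0, spring_constant=10.0),
        )
        dyn = DynamicsConfig(dt=0.01, temperature=298.0, sample_stride=10)
        start = State(position=np.array([-1.5]), velocity=np.zeros(1))

        def crossings(seg_cv):
            side = np.sign(seg_cv)
            return int(np.sum(np.diff(side[side != 0]) != 0))

        from sumdkit.sumd import run_unbiased

        biased_crossings = []
        unbiased_crossings = []
        for seed in range(20):
            rng_b = np.random.default_rng(100 + seed)
            bias, seg = run_metadynamics(
                deep, start, dyn, self.metad_config(400.0, w0=0.5), rng_b
            )
            biased_crossings.append(crossings(seg.cv_values.ravel()))
            rng_u = np.random.default_rng(100 + seed)
            plain = run_unbiased(deep, start, 400.0, dyn, rng_u)
            unbiased_crossings.append(crossings(plain.positions[:, 0]))
        assert sum(unbiased_crossings) == 0
        assert np.median(biased_crossings) >= 5


class TestEstimateFes:
    def test_single_hill_scaled_inverted_gaussian(self):
        """F = -(gamma/(gamma-1)) V: prefactor 1.2 at gamma = 6."""
        bias = make_bias([Hill((0.0,), (0.5,), 1.0, 0.0)], gamma=6.0)
        fes = estimate_fes(bias, bounds=[(-3.0, 3.0)], n_points=601, time_average=0)
        # minimum of -1.2*V is at the hill center; after shift F(center)=0
        center_idx = np.argmin(np.abs(fes.grid))
        assert fes.values[center_idx] == pytest.approx(0.0, abs=1e-12)
        # far away V ~ 0, so F -> 1.2 * height
        assert fes.values[0] == pytest.approx(1.2 * 1.0, rel=1e-4)

    def test_empty_bias_rejected(self):
        with pytest.raises(ValueError):
            estimate_fes(make_bias())

    def test_linearity_in_accumulated_bias(self, rng):
        """V of concatenated hill sets adds; F scales linearly before shift."""
        hills_a = [Hill((float(rng.uniform(-2, 2)),), (0.4,), 0.2, float(i)) for i in range(5)]
        hills_b = [Hill((float(rng.uniform(-2, 2)),), (0.4,), 0.3, float(5 + i)) for i in range(5)]
        both = make_bias(hills_a + hills_b)
        a = make_bias(hills_a)
        b = make_bias(hills_b)
        for probe in (-1.0, 0.0, 1.7):
            assert bias_potential(both, [probe]) == pytest.approx(
                bias_potential(a, [probe]) + bias_potential(b, [probe]), rel=1e-12
            )


class TestClosedStateFraction:
    def test_all_below_threshold(self):
        frac, _ = closed_state_fraction([3.0, 4.0, 2.5], 5.0)
        assert frac == 1.0

    def test_none_below_threshold(self):
        frac, _ = closed_state_fraction([7.0, 8.0], 5.0)
        assert frac == 0.0

    def test_half_below(self):
        series = [4.0] * 50 + [6.0] * 50
        frac, _ = closed_state_fraction(series, 5.0)
        assert frac == 0.5

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            closed_state_fraction([], 5.0)


class TestHillsFile:
    def test_roundtrip(self, tmp_path, rng):
        hills = [
            Hill((float(rng.uniform(-3, 3)),), (0.25,), float(rng.uniform(0.05, 0.3)), float(i) * 0.5)
            for i in range(10)
        ]
        bias = make_bias(hills)
        path = tmp_path / "HILLS"
        write_hills(bias, path)
        loaded = read_hills(path, (coordinate_cv(0),))
        assert len(loaded.hills) == 10
        np.testing.assert_allclose(
            [h.center[0] for h in loaded.hills], [h.center[0] for h in hills], atol=1e-8
        )
        assert loaded.bias_factor == pytest.approx(6.0)

    def test_malformed_file_rejected(self, tmp_path):
        p = tmp_path / "HILLS"
        p.write_text("no header\n1 2 3\n")
        with pytest.raises(ValueError):
            read_hills(p, (coordinate_cv(0),))
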