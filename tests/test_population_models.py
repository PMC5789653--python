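"""Cohort simulation under the equilibrium-point and set-point models."""

import numpy as np
import pytest

from eqpoint.correlation_analysis import correlation
from eqpoint.errors import InputError
from eqpoint.feedback_core import EffectorCurve, SensorCurve
from eqpoint.population_models import (
    PopulationSpec,
    sample_population,
    simulate_cohort,
    simulate_equilibrium_cohort,
    simulate_setpoint_cohort,
)


def spec_for(system, **kwargs):
    defaults = dict(n=100, seed=0, model="equilibrium")
    defaults.update(kwargs)
    return PopulationSpec.for_system(system, **defaults)


class TestSpecValidation:
    def test_mode_cv_consistency_enforced(self):
        with pytest.raises(InputError):
            spec_for("calcium_pth", variation_mode="effector_dominant", alpha_cv=0.1)
        with pytest.raises(InputError):
            spec_for("calcium_pth", variation_mode="sensor_dominant", gain_cv=0.2)

    def test_cv_bounds(self):
        with pytest.raises(InputError):
            spec_for("calcium_pth", gain_cv=1.0)
        with pytest.raises(InputError):
            spec_for("calcium_pth", n=1)

    def test_spec_dict_round_trip(self):
        spec = spec_for("glucose_insulin", n=50, seed=3, model="setpoint")
        clone = PopulationSpec.from_dict(spec.to_dict())
        assert clone == spec


class TestSamplePopulation:
    def test_zero_cv_gives_identical_copies(self):
        spec = spec_for("calcium_pth", n=5, p0_cv=0.0, gain_cv=0.0, k_cv=0.0)
        individuals = sample_population(spec)
        assert len(individuals) == 5
        for ind in individuals:
            assert ind.system.sensor == spec.system.sensor
            assert ind.system.effector == spec.system.effector

    def test_lognormal_draw_mean_matches_moment_formula(self):
        # median = template, so mean = template * exp(sigma^2/2); for CV 0.2
        # that is within 2% of the template, and the n=1000 sample mean lands
        # within 5% of the template gain.
        spec = spec_for("calcium_pth", n=1000, seed=42, gain_cv=0.2)
        gains = np.array([i.system.effector.gain for i in sample_population(spec)])
        template = spec.system.effector.gain
        assert abs(gains.mean() - template) / template < 0.05
        sigma = np.sqrt(np.log1p(0.2**2))
        assert abs(gains.mean() - template * np.exp(sigma**2 / 2)) / template < 0.03

    def test_same_seed_bitwise_identical(self):
        a = sample_population(spec_for("glucose_insulin", n=200, seed=9))
        b = sample_population(spec_for("glucose_insulin", n=200, seed=9))
        for ia, ib in zip(a, b):
            assert ia.system.effector == ib.system.effector
            assert ia.system.sensor == ib.system.sensor

    def test_draws_independent_across_parameters(self):
        spec = spec_for("calcium_pth", n=2000, seed=5, p0_cv=0.2, gain_cv=0.2, k_cv=0.2)
        frame = simulate_equilibrium_cohort(spec).parameters
        corr = frame[["p0", "gain", "k"]].corr().to_numpy()
        off_diag = corr[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off_diag) < 0.1)


class TestEquilibriumCohort:
    def test_effector_dominant_points_lie_on_shared_sensor_curve(self):
        spec = spec_for("calcium_pth", n=200, seed=1)
        sample = simulate_equilibrium_cohort(spec)
        expected_h = spec.system.sensor(sample.p)
        np.testing.assert_allclose(sample.h, expected_h, rtol=1e-9)

    @pytest.mark.parametrize(
        "system,rho", [("calcium_pth", -1.0), ("glucose_insulin", 1.0)]
    )
    def test_effector_dominant_spearman_is_exact(self, system, rho):
        spec = spec_for(system, n=1000, seed=2)
        sample = simulate_equilibrium_cohort(spec)
        r, _ = correlation(sample, method="spearman")
        assert r == rho

    def test_mixed_mode_small_sensor_variation_keeps_sensor_sign(self):
        spec = spec_for(
            "calcium_pth",
            n=2000,
            seed=7,
            variation_mode="mixed",
            alpha_cv=0.05,
            beta_cv=0.05,
            p0_cv=0.3,
            gain_cv=0.3,
            k_cv=0.3,
        )
        r, _ = correlation(simulate_equilibrium_cohort(spec), method="pearson")
        assert r < 0

    def test_pairs_satisfy_both_curve_equations(self):
        spec = spec_for("glucose_insulin", n=100, seed=3)
        sample = simulate_equilibrium_cohort(spec)
        for i in range(len(sample)):
            row = sample.parameters.iloc[i]
            sensor = SensorCurve(
                direction=spec.system.sensor.direction,
                alpha=row["alpha"],
                beta=row["beta"],
            )
            effector = EffectorCurve(
                direction=spec.system.effector.direction,
                p0=row["p0"],
                gain=row["gain"],
                k=row["k"],
            )
            assert sensor(sample.p[i]) == pytest.approx(sample.h[i], rel=1e-9)
            assert effector(sample.h[i]) == pytest.approx(sample.p[i], abs=1e-8)

    def test_model_mismatch_rejected(self):
        spec = spec_for("calcium_pth", model="setpoint")
        with pytest.raises(InputError):
            simulate_equilibrium_cohort(spec)


class TestSetpointCohort:
    def test_shared_inverse_curve_when_effector_fixed(self):
        # all individuals share one effector: H is a strictly monotone
        # function of the drawn target, so Spearman is exactly +1/-1
        spec = spec_for(
            "calcium_pth",
            n=1000,
            seed=4,
            model="setpoint",
            p0_cv=0.0,
            gain_cv=0.0,
            k_cv=0.0,
        )
        sample = simulate_setpoint_cohort(spec)
        r, _ = correlation(sample, method="spearman")
        assert r == 1.0  # stimulatory effector

    @pytest.mark.parametrize(
        "system,positive", [("calcium_pth", True), ("glucose_insulin", False)]
    )
    def test_pearson_sign_follows_effector_direction(self, system, positive):
        spec = spec_for(system, n=10000, seed=6, model="setpoint")
        r, _ = correlation(simulate_setpoint_cohort(spec), method="pearson")
        assert (r > 0) is positive

    def test_targets_attained_exactly_through_effector_inverse(self):
        spec = spec_for("glucose_insulin", n=300, seed=8, model="setpoint")
        sample = simulate_setpoint_cohort(spec)
        for i in range(0, len(sample), 17):
            row = sample.parameters.iloc[i]
            effector = EffectorCurve(
                direction=spec.system.effector.direction,
                p0=row["p0"],
                gain=row["gain"],
                k=row["k"],
            )
            assert effector(sample.h[i]) == pytest.approx(sample.p[i], abs=1e-9)
            lo = row["p0"] + spec.eps * row["gain"]
            hi = row["p0"] + (1 - spec.eps) * row["gain"]
            assert lo <= sample.p[i] <= hi

    def test_targets_independent_of_effector_draws(self):
        spec = spec_for("calcium_pth", n=5000, seed=10, model="setpoint",
                        setpoint_cv=0.05)
        sample = simulate_setpoint_cohort(spec)
        gain = sample.parameters["gain"].to_numpy()
        r = np.corrcoef(sample.p, gain)[0, 1]
        # truncation induces only a weak residual dependence
        assert abs(r) < 0.1

    def test_determinism(self):
        a = simulate_setpoint_cohort(spec_for("ft4_tsh", n=500, seed=12, model="setpoint"))
        b = simulate_setpoint_cohort(spec_for("ft4_tsh", n=500, seed=12, model="setpoint"))
        np.testing.assert_array_equal(a.p, b.p)
        np.testing.assert_array_equal(a.h, b.h)


class TestCohortSample:
    def test_export_schema(self, tmp_path):
        spec = spec_for("calcium_pth", n=20, seed=0)
        sample = simulate_cohort(spec)
        out = tmp_path / "cohort.csv"
        sample.to_csv(out)
        import pandas as pd

        frame = pd.read_csv(out)
        assert list(frame.columns) == ["id", "P", "H", "model", "seed"]
        assert len(frame) == 20
        assert (frame["model"] == "equilibrium").all()
        assert (frame["seed"] == 0).all()

    def test_all_values_finite_positive(self):
        for model in ("equilibrium", "setpoint"):
            sample = simulate_cohort(spec_for("glucose_insulin", n=200, seed=1, model=model))
            assert np.all(np.isfinite(sample.p)) and np.all(sample.p > 0)
            assert np.all(np.isfinite(sample.h)) and np.all(sample.h > 0)


class TestContinuityTowardEffectorDominant:
    def test_mixed_mode_converges_as_sensor_cv_shrinks(self):
        # mean Pearson over replicates approaches the effector-dominant
        # value monotonically as sensor variation vanishes
        def mean_r(sensor_cv, reps=30, n=400):
            rs = []
            for seed in range(reps):
                kwargs = dict(n=n, seed=seed, model="equilibrium")
                if sensor_cv == 0.0:
                    spec = spec_for("calcium_pth", **kwargs)
                else:
                    spec = spec_for(
                        "calcium_pth",
                        variation_mode="mixed",
                        alpha_cv=sensor_cv,
                        beta_cv=sensor_cv,
                        **kwargs,
                    )
                rs.append(correlation(simulate_equilibrium_cohort(spec), "pearson")[0])
            return float(np.mean(rs))

        reference = mean_r(0.0)
        gaps = [abs(mean_r(cv) - reference) for cv in (0.2, 0.1, 0.05, 0.02)]
        assert all(g1 > g2 for g1, g2 in zip(gaps, gaps[1:]))
        assert gaps[-1] < 0.1
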