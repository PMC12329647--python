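"""Closed-form layer: thresholds, equilibria, boundary curves, wave speeds."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drivewave import (
    DriveParams,
    Model,
    Outcome,
    Regime,
    coexistence_frequency,
    fitness_thresholds,
    linear_wave_speed,
    predicted_outcome,
    regime_and_equilibria,
    regime_boundary_r,
)
from drivewave.analytics import equilibrium_residual

from conftest import make_demo


class TestFitnessThresholds:
    def test_reference_parameters(self):
        s1, s2g = fitness_thresholds(DriveParams(s=0.5, c=0.85, h=0.9))
        assert s1 == pytest.approx(0.85 / 0.865, abs=1e-12)
        assert s2g == pytest.approx(0.85 / 1.665, abs=1e-12)

    def test_thresholds_coincide_at_additive_dominance(self, rng):
        for c in rng.uniform(0.01, 0.99, size=20):
            s1, s2g = fitness_thresholds(DriveParams(s=0.5, c=c, h=0.5))
            assert s1 == pytest.approx(s2g, rel=1e-12)
            assert s1 == pytest.approx(2 * c / (1 + c), rel=1e-12)

    def test_ordering_follows_dominance(self):
        s1, s2g = fitness_thresholds(DriveParams(s=0.5, c=0.6, h=0.3))
        assert s1 < s2g
        s1, s2g = fitness_thresholds(DriveParams(s=0.5, c=0.6, h=0.8))
        assert s1 > s2g

    def test_no_conversion_no_advantage(self):
        assert fitness_thresholds(DriveParams(s=0.5, c=0.0, h=0.7)) == (0.0, 0.0)

    def test_sentinels(self):
        assert fitness_thresholds(DriveParams(s=0.5, c=0.85, h=0.0))[1] == math.inf
        assert fitness_thresholds(DriveParams(s=0.5, c=1.0, h=0.7))[0] == math.inf


class TestCoexistenceFrequency:
    def test_reference_value_and_residual(self):
        drive = DriveParams(s=0.95, c=0.85, h=0.3)
        p = coexistence_frequency(drive)
        assert p == pytest.approx(0.8493, abs=1e-4)
        s, c, h = drive.s, drive.c, drive.h
        residual = (2 * h - 1) * s * p + (1 - s * h) * (1 + c) - 1
        assert abs(residual) < 1e-12

    def test_limits_of_the_band(self):
        c, h = 0.85, 0.3
        s1, s2g = fitness_thresholds(DriveParams(s=0.5, c=c, h=h))
        p_lo = coexistence_frequency(DriveParams(s=s1 + 1e-9, c=c, h=h))
        assert p_lo == pytest.approx(1.0, abs=1e-6)
        # near s2g the root vanishes; approach from inside the band
        p_hi = coexistence_frequency(DriveParams(s=min(s2g, 1.0) - 1e-9, c=c, h=h))
        assert 0.0 < p_hi < 1.0

    def test_outside_band_rejected(self):
        with pytest.raises(ValueError, match="band"):
            coexistence_frequency(DriveParams(s=0.2, c=0.85, h=0.3))
        with pytest.raises(ValueError):
            coexistence_frequency(DriveParams(s=0.7, c=0.85, h=0.5))


class TestPredictedOutcome:
    @pytest.mark.parametrize(
        "s,h,regime,expected",
        [
            (0.3, 0.9, "finite_large", Outcome.DRIVE_INVASION),
            (0.99, 0.9, "zero", Outcome.GENE_DRIVE_CLEARANCE),
            (0.95, 0.3, "finite_large", Outcome.COEXISTENCE),
            (0.7, 0.9, "finite_large", Outcome.BISTABLE_FREQUENCY),
            (0.99, 0.9, "finite_large", Outcome.WILD_TYPE_INVASION),
            (0.3, 0.9, "zero", Outcome.DRIVE_INVASION),
            (0.7, 0.9, "zero", Outcome.GENE_DRIVE_CLEARANCE),
        ],
    )
    def test_table_cells(self, s, h, regime, expected):
        assert predicted_outcome(DriveParams(s=s, c=0.85, h=h), regime).outcome == expected

    def test_bistability_requires_dominance(self):
        # an initial-condition-dependent outcome only exists for h > 1/2
        for s in np.linspace(0.05, 0.99, 30):
            for h in (0.1, 0.3, 0.49):
                out = predicted_outcome(DriveParams(s=s, c=0.85, h=h), "finite_large")
                assert out.outcome != Outcome.BISTABLE_FREQUENCY
            for h in (0.51, 0.8, 1.0):
                out = predicted_outcome(DriveParams(s=s, c=0.85, h=h), "finite_large")
                assert out.outcome != Outcome.COEXISTENCE


class TestRegimeAndEquilibria:
    @pytest.mark.parametrize(
        "model,r,a,F,regime,n_plus,n_tau",
        [
            ("BN", 2.0, None, 0.7, Regime.PERSISTENCE, 1 - 0.3 / 1.4, None),
            ("DN", 2.0, None, 0.7, Regime.PERSISTENCE, 0.55, None),
            ("BA", 2.0, -0.5, 0.7, Regime.PERSISTENCE, 0.84010, None),
            ("DA", 10.0, 0.2, 0.9, Regime.BISTABILITY, 0.82361, 0.37639),
            ("DA", 1.0, 0.2, 0.9, Regime.ERADICATION, None, None),
            ("BN", 0.3, None, 0.7, Regime.ERADICATION, None, None),
        ],
    )
    def test_table_cells(self, model, r, a, F, regime, n_plus, n_tau):
        report = regime_and_equilibria(make_demo(model, r=r, a=a), F)
        assert report.regime == regime
        if n_plus is None:
            assert report.n_plus is None
        else:
            assert report.n_plus == pytest.approx(n_plus, abs=1e-4)
        if n_tau is None:
            assert report.n_tau is None
        else:
            assert report.n_tau == pytest.approx(n_tau, abs=1e-4)

    def test_neutral_wake_returns_to_carrying_capacity(self):
        for model in Model:
            report = regime_and_equilibria(make_demo(model, r=2.0, a=0.5), 1.0)
            assert report.regime == Regime.PERSISTENCE
            assert report.n_plus == 1.0

    def test_equilibria_satisfy_fixed_point_equation(self, rng):
        """Every returned density solves F B(n) = D(n) of its model (demography oracle)."""
        checked = 0
        for _ in range(300):
            model = str(rng.choice(["BN", "BA", "DN", "DA"]))
            demo = make_demo(model, r=float(rng.uniform(0.05, 20)),
                             a=float(rng.uniform(-1, 1)))
            F = float(rng.uniform(0.05, 1.0))
            report = regime_and_equilibria(demo, F)
            for n in (report.n_plus, report.n_tau):
                if n is not None and n > 0:
                    assert abs(equilibrium_residual(demo, F, n)) < 1e-10
                    checked += 1
        assert checked > 100

    def test_weak_allee_at_minus_one_matches_no_allee_partition(self, rng):
        """a = -1 collapses BA to the BN regime partition and DA to DN (no bistable band)."""
        for _ in range(200):
            r = float(rng.uniform(0.05, 20))
            F = float(rng.uniform(0.05, 0.999))
            for allee, plain in (("BA", "BN"), ("DA", "DN")):
                rep_a = regime_and_equilibria(make_demo(allee, r=r, a=-1.0), F)
                rep_p = regime_and_equilibria(make_demo(plain, r=r), F)
                assert rep_a.regime == rep_p.regime
                assert rep_a.regime != Regime.BISTABILITY

    def test_eradication_region_grows_with_allee_threshold(self):
        r_grid = np.linspace(0.1, 15, 25)
        F_grid = np.linspace(0.1, 0.95, 25)
        for model in ("BA", "DA"):
            prev = None
            for a in (-1.0, -0.5, 0.0, 0.5):
                region = {
                    (r, F)
                    for r in r_grid
                    for F in F_grid
                    if regime_and_equilibria(make_demo(model, r=r, a=a), F).regime
                    == Regime.ERADICATION
                }
                if prev is not None:
                    assert prev <= region
                prev = region

    def test_final_density_ordering_between_families(self, rng):
        """Deaths-regulated wakes are sparser: n+(DN) < n+(BN), n+(DA) < n+(BA)."""
        found = 0
        for _ in range(300):
            r = float(rng.uniform(0.1, 20))
            F = float(rng.uniform(0.05, 0.999))
            a = float(rng.uniform(-1, 1))
            for births, deaths in (("BN", "DN"), ("BA", "DA")):
                rb = regime_and_equilibria(make_demo(births, r=r, a=a), F)
                rd = regime_and_equilibria(make_demo(deaths, r=r, a=a), F)
                if rb.n_plus is not None and rd.n_plus is not None:
                    assert rd.n_plus < rb.n_plus
                    found += 1
        assert found > 50

    def test_final_density_non_increasing_in_allee_threshold(self):
        for model in ("BA", "DA"):
            for r, F in ((5.0, 0.8), (10.0, 0.9), (2.0, 0.95)):
                n_prev = None
                for a in (-1.0, -0.6, -0.2, 0.2, 0.6):
                    rep = regime_and_equilibria(make_demo(model, r=r, a=a), F)
                    if rep.n_plus is None:
                        n_prev = None
                        continue
                    if n_prev is not None:
                        assert rep.n_plus <= n_prev + 1e-12
                    n_prev = rep.n_plus

    def test_strong_allee_never_persists(self, rng):
        for _ in range(200):
            demo = make_demo(str(rng.choice(["BA", "DA"])), r=float(rng.uniform(0.05, 50)),
                             a=float(rng.uniform(1e-3, 1)))
            rep = regime_and_equilibria(demo, float(rng.uniform(0.05, 0.999)))
            assert rep.regime != Regime.PERSISTENCE

    def test_invalid_fitness_rejected(self):
        with pytest.raises(ValueError):
            regime_and_equilibria(make_demo("BN", r=1.0), 0.0)
        with pytest.raises(ValueError):
            regime_and_equilibria(make_demo("BN", r=1.0), 1.2)


class TestBoundaryCurves:
    s_grid = np.linspace(0.01, 0.9, 30)

    def test_ba_at_minus_one_reduces_to_no_allee_condition(self):
        r = regime_boundary_r("BA", -1.0, self.s_grid, "lower")
        np.testing.assert_allclose(r, self.s_grid / (1 - self.s_grid), rtol=1e-12)

    def test_ba_lower_boundary_value(self):
        r = regime_boundary_r("BA", 0.0, np.array([0.2]), "lower")
        assert r[0] == pytest.approx(1.0)

    def test_da_eradication_at_all_growth_rates(self):
        # ((1-a)/2)^2 = 0.16 < s = 0.3: eradication regardless of r in model DA
        r = regime_boundary_r("DA", 0.2, np.array([0.3]), "lower")
        assert np.isinf(r[0])
        # while BA keeps a finite boundary at the same parameters
        r_ba = regime_boundary_r("BA", 0.2, np.array([0.3]), "lower")
        assert np.isfinite(r_ba[0])

    def test_upper_boundary_absent_for_strong_allee(self):
        for model in ("BA", "DA"):
            r = regime_boundary_r(model, 0.5, self.s_grid, "upper")
            assert np.all(np.isinf(r))

    def test_monotone_in_allee_threshold(self):
        for model in ("BA", "DA"):
            for bnd in ("lower", "upper"):
                prev = None
                for a in (-1.0, -0.5, 0.0, 0.5):
                    cur = regime_boundary_r(model, a, self.s_grid, bnd)
                    if prev is not None:
                        assert np.all(cur >= prev - 1e-12)
                    prev = cur

    def test_boundary_consistent_with_regime_classifier(self):
        """Crossing the lower boundary in r flips eradication to not-eradication."""
        for model in ("BA", "DA"):
            for a in (-0.5, 0.0, 0.3):
                for s in (0.05, 0.1, 0.2):
                    r_b = regime_boundary_r(model, a, np.array([s]), "lower")[0]
                    if not np.isfinite(r_b):
                        continue
                    below = regime_and_equilibria(make_demo(model, r=r_b * 0.95, a=a), 1 - s)
                    above = regime_and_equilibria(make_demo(model, r=r_b * 1.05, a=a), 1 - s)
                    assert below.regime == Regime.ERADICATION
                    assert above.regime != Regime.ERADICATION

    def test_no_allee_models_rejected(self):
        with pytest.raises(ValueError):
            regime_boundary_r("BN", -0.5, self.s_grid, "lower")


class TestLinearWaveSpeed:
    def test_threshold_of_existence(self):
        # (1-sh)(1+c) = 1 exactly at s = s2g
        c, h = 0.85, 0.9
        s2g = c / (h * (1 + c))
        drive = DriveParams(s=s2g, c=c, h=h)
        assert linear_wave_speed("births_regulated", None, drive) is None

    def test_reference_values(self):
        drive = DriveParams(s=0.2, c=0.85, h=0.3)
        vB = linear_wave_speed("births_regulated", None, drive)
        assert vB == pytest.approx(2 * math.sqrt(0.739), abs=1e-12)
        vD = linear_wave_speed("deaths_regulated", make_demo("DN", r=3.0), drive)
        assert vD == pytest.approx(2 * vB, rel=1e-12)  # sqrt(1+r) = 2 at r = 3

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(s=st.floats(0.0, 0.27), r=st.floats(0.0, 20.0), a=st.floats(-1.0, 1.0))
    def test_speed_independent_of_allee_threshold(self, s, r, a):
        drive = DriveParams(s=s, c=0.85, h=0.9)
        vBA = linear_wave_speed("births_regulated", make_demo("BA", r=r, a=a), drive)
        vBN = linear_wave_speed("births_regulated", make_demo("BN", r=r), drive)
        assert vBA == vBN
        vDA = linear_wave_speed("deaths_regulated", make_demo("DA", r=r, a=a), drive)
        vDN = linear_wave_speed("deaths_regulated", make_demo("DN", r=r), drive)
        assert vDA == vDN
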