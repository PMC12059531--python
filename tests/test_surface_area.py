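"""Allometric and QSM surface area, height models, Monte Carlo plot totals."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stemflux import (DEFAULT_HEIGHT_CORRECTION, DEFAULT_SITE_HEIGHT_MODEL,
                      Cylinder, HeightModel, QSMTree, ScaledHeightModel,
                      SurfaceAreaEstimate, allometric_surface_area,
                      estimate_all_methods, fit_height_model,
                      height_correction_coefficient, monte_carlo_plot_sa,
                      qsm_surface_area)


def random_tree(rng, n_cyl=50, tag="t") -> QSMTree:
    """A random valid cylinder chain with side branches."""
    cyls = [Cylinder(0, None, 0, float(rng.uniform(0.05, 0.5)),
                     float(rng.uniform(0.5, 2.0)), 0.0)]
    for i in range(1, n_cyl):
        parent = int(rng.integers(0, i))
        cyls.append(Cylinder(i, parent, int(rng.integers(0, 3)),
                             float(rng.uniform(0.004, 0.4)),
                             float(rng.uniform(0.2, 2.0)),
                             float(rng.uniform(0.0, 40.0))))
    return QSMTree(tag=tag, cylinders=cyls, sa_sd=0.0)


class TestAllometry:
    @pytest.mark.parametrize("dbh, correction, expected", [
        (10.0, 1.0, 6.166),       # X=1, exponent 0.790
        (50.0, 1.0, 106.7),       # X=log10(50)
        (10.0, 1.669, 10.29),     # height-corrected
    ])
    def test_polynomial_values(self, dbh, correction, expected):
        assert allometric_surface_area(dbh, correction) == pytest.approx(
            expected, rel=1e-3)

    def test_strictly_increasing_up_to_turnover(self):
        # the cubic in log10(DBH) rises up to DBH ~152 cm and declines
        # beyond: an extrapolation artefact of the fitted polynomial
        dbh = np.linspace(10.0, 150.0, 1401)
        sa = allometric_surface_area(dbh)
        assert np.all(np.diff(sa) > 0)
        assert allometric_surface_area(210.0) < allometric_surface_area(152.0)

    def test_nonpositive_dbh_rejected(self):
        with pytest.raises(ValueError):
            allometric_surface_area(0.0)

    def test_vectorized_matches_scalar(self):
        dbh = np.array([12.0, 57.0, 180.0])
        sa = allometric_surface_area(dbh)
        assert sa == pytest.approx([allometric_surface_area(d) for d in dbh])


class TestHeightModel:
    def test_noiseless_recovery_of_site_coefficients(self):
        dbh = np.linspace(10.0, 210.0, 120)
        height = 14.779 * np.log(dbh) - 24.546
        model = fit_height_model(dbh, height, log_base="natural")
        assert model.slope == pytest.approx(14.779, abs=1e-9)
        assert model.intercept == pytest.approx(-24.546, abs=1e-9)
        assert model.r2 == pytest.approx(1.0)

    def test_noisy_recovery_within_sampling_error(self, rng):
        dbh = rng.uniform(10.0, 210.0, 200)
        height = 14.779 * np.log(dbh) - 24.546 + rng.normal(0.0, 2.0, 200)
        model = fit_height_model(dbh, height)
        assert abs(model.slope - 14.779) < 0.5

    def test_two_points_define_exact_line(self):
        model = fit_height_model([10.0, 100.0], [10.0, 40.0])
        assert model.r2 == pytest.approx(1.0)

    def test_degenerate_census_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_height_model([50.0, 50.0, 50.0], [30.0, 31.0, 32.0])

    def test_log_base_is_explicit(self):
        natural = HeightModel(14.779, -24.546, log_base="natural")
        base10 = HeightModel(14.779, -24.546, log_base="base10")
        assert natural.predict(50.0) != base10.predict(50.0)
        # site model yields the observed 27-65 m canopy for large stems
        assert 25.0 < natural.predict(42.6) < natural.predict(105.5) < 70.0


class TestCorrectionCoefficient:
    def test_identical_models_give_one(self):
        dbh = np.linspace(10.0, 210.0, 50)
        site = DEFAULT_SITE_HEIGHT_MODEL
        assert height_correction_coefficient(dbh, site, site) == pytest.approx(1.0)

    def test_constant_ratio_reference(self):
        dbh = np.linspace(10.0, 210.0, 50)
        site = DEFAULT_SITE_HEIGHT_MODEL
        ref = ScaledHeightModel(site, 1.669)
        assert height_correction_coefficient(dbh, site, ref) == pytest.approx(
            1.669, rel=1e-12)

    def test_varying_ratio_matches_explicit_loop(self, rng):
        dbh = rng.uniform(10.0, 210.0, 80)
        site = DEFAULT_SITE_HEIGHT_MODEL

        class LinearRatioRef:
            def predict(self, d):
                d = np.asarray(d, dtype=float)
                ratio = 1.5 + 0.3 * (d - 10.0) / 200.0
                return ratio * site.predict(d)

        coeff = height_correction_coefficient(dbh, site, LinearRatioRef())
        expected = np.mean([LinearRatioRef().predict(d) / site.predict(d)
                            for d in dbh])
        assert coeff == pytest.approx(float(expected), rel=1e-12)

    def test_nonpositive_prediction_rejected(self):
        bad_site = HeightModel(1.0, -100.0)  # negative heights everywhere
        with pytest.raises(ValueError, match="non-positive"):
            height_correction_coefficient([50.0], bad_site, bad_site)


class TestQSMSurfaceArea:
    def test_single_cylinder_lateral_area(self):
        tree = QSMTree("t", [Cylinder(0, None, 0, 0.1, 2.0, 0.0)])
        assert qsm_surface_area(tree) == pytest.approx(2 * math.pi * 0.1 * 2.0)

    def test_truncation_threshold_semantics(self):
        tree = QSMTree("t", [Cylinder(0, None, 0, 0.1, 2.0, 0.0),
                             Cylinder(1, 0, 1, 0.009, 1.0, 1.0)])  # 1.8 cm diam
        big = 2 * math.pi * 0.1 * 2.0
        small = 2 * math.pi * 0.009 * 1.0
        assert qsm_surface_area(tree, 0.0) == pytest.approx(big + small)
        assert qsm_surface_area(tree, 0.02) == pytest.approx(big)
        # a cylinder of exactly 2 cm diameter is kept
        tree2 = QSMTree("t", [Cylinder(0, None, 0, 0.01, 1.0, 0.0)])
        assert qsm_surface_area(tree2, 0.02) > 0

    def test_matches_bruteforce_sum(self, rng):
        tree = random_tree(rng)
        expected = sum(2 * math.pi * c.radius_m * c.length_m
                       for c in tree.cylinders)
        assert qsm_surface_area(tree) == pytest.approx(expected, rel=1e-12)

    @given(trunc=st.floats(0.0, 0.5), seed=st.integers(0, 100))
    def test_monotone_in_truncation(self, trunc, seed):
        tree = random_tree(np.random.default_rng(seed), n_cyl=20)
        assert qsm_surface_area(tree, trunc) <= qsm_surface_area(tree, 0.0)

    def test_empty_tree_rejected(self):
        with pytest.raises(ValueError):
            qsm_surface_area(QSMTree("t", []))

    def test_invalid_topology_rejected(self):
        with pytest.raises(ValueError, match="root"):
            QSMTree("t", [Cylinder(0, None, 0, 0.1, 1.0, 0.0),
                          Cylinder(1, None, 0, 0.1, 1.0, 1.0)])


class TestMonteCarlo:
    def test_zero_sd_is_exact_sum(self):
        res = monte_carlo_plot_sa(sa=[10.0, 20.0, 30.0], sd=[0.0, 0.0, 0.0],
                                  n_draws=100, seed=0)
        assert res.mean == pytest.approx(60.0)
        assert res.se == 0.0

    def test_two_unit_sd_trees_give_sqrt2(self):
        res = monte_carlo_plot_sa(sa=[50.0, 50.0], sd=[1.0, 1.0],
                                  n_draws=10_000, seed=1)
        assert res.se == pytest.approx(math.sqrt(2.0), rel=0.05)

    def test_same_seed_is_bit_identical(self):
        a = monte_carlo_plot_sa(sa=[10.0, 20.0], sd=[2.0, 3.0], seed=42)
        b = monte_carlo_plot_sa(sa=[10.0, 20.0], sd=[2.0, 3.0], seed=42)
        assert a.mean == b.mean and a.se == b.se

    def test_converges_to_analytic_quadrature(self, rng):
        sd = rng.uniform(0.5, 3.0, 30)
        sa = rng.uniform(20.0, 200.0, 30)
        res = monte_carlo_plot_sa(sa=sa, sd=sd, n_draws=100_000, seed=7)
        assert res.se == pytest.approx(math.sqrt(float(np.sum(sd ** 2))),
                                       rel=0.02)

    def test_accepts_estimate_objects_and_counts_clipping(self):
        ests = [SurfaceAreaEstimate("a", "TLS_t0", 1.0, 5.0)]  # sd >> sa
        res = monte_carlo_plot_sa(ests, n_draws=2000, seed=3)
        assert res.n_truncated > 0


class TestAllMethodsTable:
    def test_height_corrected_ratio_exact_per_tree_and_total(self, rng):
        census = pd.DataFrame({"tag": ["a", "b"], "dbh_cm": [30.0, 80.0],
                               "height_m": [25.0, 45.0], "species": "x",
                               "buttressed": [False, False]})
        trees = [random_tree(rng, 10, "a"), random_tree(rng, 10, "b")]
        table = estimate_all_methods(census, trees)
        wide = table.pivot(index="tree_tag", columns="method", values="sa_m2")
        ratio = wide["SA_ha"] / wide["SA_a"]
        assert np.allclose(ratio, DEFAULT_HEIGHT_CORRECTION)
        assert wide["SA_ha"].sum() / wide["SA_a"].sum() == pytest.approx(
            DEFAULT_HEIGHT_CORRECTION, rel=1e-12)
        assert (wide["TLS_t2"] <= wide["TLS_t0"]).all()
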