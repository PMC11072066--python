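"""Distributions, Trigen fitting, PSA, CEAC, tornado regression."""

import numpy as np
import pytest
from scipy import stats

from voctree import (
    ArmResult,
    TriangularSpec,
    TrigenInfeasibleError,
    TrigenSpec,
    WTPThreshold,
    ceac,
    make_owsa_range,
    run_psa,
    tornado_regression,
    triangular_sample,
    trigen_to_triangular,
)
from voctree.uncertainty import (
    InvalidSampleError,
    PSARejectionError,
    PSASampleSet,
    one_way_sensitivity,
)

WTP = WTPThreshold(547_500.0)


def _scipy_triang(tri: TriangularSpec):
    c = (tri.mode - tri.minimum) / (tri.maximum - tri.minimum)
    return stats.triang(c, loc=tri.minimum, scale=tri.maximum - tri.minimum)


class TestOwsaRange:
    @pytest.mark.parametrize(
        "point, expected", [(6678.0, (5676, 6678, 7680)), (96.0, (82, 96, 110))]
    )
    def test_published_unit_cost_bounds(self, point, expected):
        assert make_owsa_range(point, 0.15).rounded_bounds() == expected

    def test_bounds_symmetric_about_mode(self, rng):
        for _ in range(50):
            x = float(rng.uniform(1, 1e6))
            f = float(rng.uniform(0.01, 0.99))
            spec = make_owsa_range(x, f)
            assert spec.maximum - spec.mode == pytest.approx(spec.mode - spec.minimum, rel=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError):
            make_owsa_range(-1.0, 0.15)
        with pytest.raises(ValueError):
            make_owsa_range(10.0, 1.5)


class TestTriangular:
    def test_ppf_endpoints_and_symmetric_median(self):
        spec = TriangularSpec(0.0, 1.0, 2.0)
        assert spec.ppf(0.0) == 0.0
        assert spec.ppf(1.0) == 2.0
        assert spec.ppf(0.5) == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_spec_returns_constant(self, rng):
        spec = TriangularSpec(3.0, 3.0, 3.0)
        assert np.all(triangular_sample(spec, rng, size=10) == 3.0)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            TriangularSpec(1.0, 0.5, 2.0)

    def test_sample_mean_matches_closed_form(self, rng):
        a, m, b = 2.0, 5.0, 11.0
        spec = TriangularSpec(a, m, b)
        n = 100_000
        draws = triangular_sample(spec, rng, size=n)
        var = (a * a + m * m + b * b - a * m - a * b - m * b) / 18.0
        se = np.sqrt(var / n)
        assert abs(draws.mean() - (a + m + b) / 3.0) < 3 * se

    def test_ks_distance_against_analytic_cdf(self, rng):
        spec = TriangularSpec(0.1, 0.4, 0.9)
        draws = triangular_sample(spec, rng, size=100_000)
        stat = stats.kstest(draws, _scipy_triang(spec).cdf).statistic
        assert stat < 1.63 / np.sqrt(draws.size)  # 1% critical value

    def test_cdf_ppf_inverse(self, rng):
        spec = TriangularSpec(-2.0, 0.5, 3.0)
        u = rng.uniform(size=1000)
        assert np.allclose(spec.cdf(spec.ppf(u)), u, atol=1e-12)


class TestTrigen:
    def test_extreme_percentiles_pin_support_to_anchors(self):
        tri = trigen_to_triangular(TrigenSpec(0.2, 0.5, 0.9, 0.0, 100.0))
        assert (tri.minimum, tri.maximum) == (0.2, 0.9)

    def test_symmetric_spec_widens_support_beyond_anchors(self):
        tri = trigen_to_triangular(TrigenSpec(0.4, 0.5, 0.6, 5.0, 95.0))
        assert tri.minimum < 0.4 and tri.maximum > 0.6
        # independent CDF oracle
        sp = _scipy_triang(tri)
        assert sp.cdf(0.4) == pytest.approx(0.05, abs=1e-9)
        assert sp.cdf(0.6) == pytest.approx(0.95, abs=1e-9)

    def test_fit_against_grid_inversion_oracle(self):
        # brute-force grid inversion of the triangular CDF, step 1e-6:
        # given each fitted endpoint, the opposite endpoint found by grid
        # search on the scipy CDF must agree with the package's solution
        spec = TrigenSpec(0.4, 0.5, 0.6, 5.0, 95.0)
        tri = trigen_to_triangular(spec)
        grid = np.arange(0.3, 0.4, 1e-6)
        cdf_at_lower = np.array(
            [
                _scipy_triang(TriangularSpec(a, 0.5, tri.maximum)).cdf(0.4)
                for a in grid[::1000]
            ]
        )
        best = grid[::1000][np.argmin(np.abs(cdf_at_lower - 0.05))]
        assert abs(best - tri.minimum) < 1e-3

    def test_published_success_row_percentile_round_trip(self, rng):
        # 5 mg/kg success row: anchors 0.3888 / 0.6401 at the 5th/95th
        spec = TrigenSpec(0.3888, 0.5152, 0.6401, 5.0, 95.0)
        tri = trigen_to_triangular(spec)
        draws = triangular_sample(tri, rng, size=100_000)
        lo, hi = np.percentile(draws, [5, 95])
        tol_lo = 4 * np.sqrt(0.05 * 0.95 / draws.size) / tri.pdf(0.3888)
        tol_hi = 4 * np.sqrt(0.05 * 0.95 / draws.size) / tri.pdf(0.6401)
        assert abs(lo - 0.3888) < tol_lo
        assert abs(hi - 0.6401) < tol_hi

    def test_round_trip_identity_on_random_specs(self, rng):
        for _ in range(200):
            a = float(rng.uniform(-5, 5))
            b = a + float(rng.uniform(0.1, 10))
            # keep the mode inside the 5-95 percentile band, else the
            # percentile-anchored form cannot represent the distribution
            m = a + float(rng.uniform(0.06, 0.94)) * (b - a)
            tri = TriangularSpec(a, m, b)
            lo, hi = tri.ppf(0.05), tri.ppf(0.95)
            fitted = trigen_to_triangular(TrigenSpec(lo, m, hi, 5.0, 95.0))
            assert fitted.minimum == pytest.approx(a, abs=1e-7)
            assert fitted.maximum == pytest.approx(b, abs=1e-7)

    def test_infeasible_anchors(self):
        with pytest.raises(TrigenInfeasibleError):
            trigen_to_triangular(TrigenSpec(0.5, 0.5, 0.5, 5.0, 95.0))

    def test_invalid_percentiles(self):
        with pytest.raises(ValueError):
            TrigenSpec(0.1, 0.2, 0.3, 95.0, 5.0)


class _LinearModel:
    """Two-arm stand-in whose comparator cost is linear in two parameters."""

    def __init__(self, base=None):
        self.base = base or {"x1": 0.3, "x2": 0.6}
        self.default_comparisons = [("b", "a")]

    def evaluate(self, values=None):
        v = {**self.base, **(values or {})}
        for p in v.values():
            if not (0.0 <= p <= 1.0):
                raise InvalidSampleError("out of range")
        cost = 1000.0 * v["x1"] + 500.0 * v["x2"]
        return [
            ArmResult("a", 100.0, 0.5),
            ArmResult("b", cost, 0.8),
        ]


class TestRunPSA:
    def test_point_masses_reproduce_base_case(self):
        model = _LinearModel()
        specs = {k: TriangularSpec(v, v, v) for k, v in model.base.items()}
        s = run_psa(model, specs, n=1, seed=0, wtp=WTP)
        base = model.evaluate({})
        assert s.delta_cost[0, 0] == base[1].expected_cost - base[0].expected_cost
        assert s.delta_effect[0, 0] == pytest.approx(0.3)

    def test_same_seed_is_bit_identical(self):
        model = _LinearModel()
        specs = {
            "x1": TriangularSpec(0.1, 0.3, 0.5),
            "x2": TrigenSpec(0.4, 0.6, 0.8, 5.0, 95.0),
        }
        s1 = run_psa(model, specs, n=200, seed=42, wtp=WTP)
        s2 = run_psa(model, specs, n=200, seed=42, wtp=WTP)
        assert np.array_equal(s1.input_matrix, s2.input_matrix)
        assert np.array_equal(s1.nmb, s2.nmb)

    def test_out_of_range_samples_are_rejected_and_counted(self):
        model = _LinearModel()
        # a range spilling slightly below zero: some draws rejected
        specs = {
            "x1": TriangularSpec(-0.05, 0.3, 0.5),
            "x2": TriangularSpec(0.4, 0.6, 0.8),
        }
        s = run_psa(model, specs, n=500, seed=1, wtp=WTP, max_reject_frac=0.5)
        assert s.n_rejected > 0
        assert np.all(s.input_matrix >= 0.0)

    def test_rejection_cap_aborts_with_diagnostic(self):
        model = _LinearModel()
        specs = {"x1": TriangularSpec(-1.0, -0.5, -0.1)}  # never valid
        with pytest.raises(PSARejectionError):
            run_psa(model, specs, n=50, seed=1, wtp=WTP)

    def test_unknown_parameter_slot_is_an_error(self, model):
        with pytest.raises(ValueError, match="no model slot"):
            model.evaluate({"nonsense.p_success": 0.5})


def _handmade_samples(dc, de, wtp=WTP):
    dc = np.asarray(dc, float).reshape(-1, 1)
    de = np.asarray(de, float).reshape(-1, 1)
    return PSASampleSet(
        seed=0,
        n_iterations=len(dc),
        wtp=wtp,
        parameter_names=["p"],
        comparison_labels=["b vs a"],
        input_matrix=np.zeros((len(dc), 1)),
        delta_cost=dc,
        delta_effect=de,
        nmb=wtp.value * de - dc,
    )


class TestCEAC:
    def test_all_dominant_curve_is_one(self):
        s = _handmade_samples([-10, -20, -5], [0.1, 0.2, 0.3])
        pts = ceac(s, [0, 1e5, 1e6])
        assert all(p.probability_cost_effective == 1.0 for p in pts)
        assert all(p.probability_dominant == 1.0 for p in pts)

    def test_hand_count_half(self):
        # NMB signs (+, +, -, -) at the threshold
        lam = WTP.value
        s = _handmade_samples([1.0, 2.0, 3.0, 4.0], [2 / lam, 3 / lam, 2 / lam, 3 / lam])
        # nmb = lam*de - dc = (1, 1, -1, -1)
        [pt] = ceac(s, [lam])
        assert pt.probability_cost_effective == 0.5

    def test_lambda_zero_counts_cost_savings(self):
        s = _handmade_samples([-1.0, 2.0, -3.0, 4.0], [0.1, 0.1, 0.1, 0.1])
        [pt] = ceac(s, [0.0])
        assert pt.probability_cost_effective == 0.5

    def test_monotone_when_all_effect_gains(self, rng):
        n = 500
        s = _handmade_samples(rng.normal(0, 1e5, n), rng.uniform(0.01, 0.5, n))
        grid = np.linspace(0, 2e6, 50)
        probs = [p.probability_cost_effective for p in ceac(s, grid)]
        assert all(b >= a for a, b in zip(probs, probs[1:]))

    def test_dominant_bounded_by_cost_effective(self, rng):
        n = 500
        s = _handmade_samples(rng.normal(0, 1e5, n), rng.normal(0.1, 0.2, n))
        for p in ceac(s, np.linspace(0, 2e6, 20)):
            assert p.probability_dominant <= p.probability_cost_effective

    def test_empty_grid_is_an_error(self):
        s = _handmade_samples([1.0, -1.0], [0.1, 0.1])
        with pytest.raises(ValueError):
            ceac(s, [])


def _regression_samples(X, y, names=None):
    n, p = X.shape
    names = names or [f"x{i}" for i in range(p)]
    return PSASampleSet(
        seed=0,
        n_iterations=n,
        wtp=WTP,
        parameter_names=list(names),
        comparison_labels=["b vs a"],
        input_matrix=X,
        delta_cost=np.zeros((n, 1)),
        delta_effect=np.zeros((n, 1)),
        nmb=y.reshape(-1, 1),
    )


class TestTornado:
    def test_identity_regression(self, rng):
        X = rng.normal(size=(500, 3))
        s = _regression_samples(X, X[:, 1].copy())
        rep = tornado_regression(s, "nmb")
        coefs = {e.parameter: e.standardized_coefficient for e in rep.entries}
        assert coefs["x1"] == pytest.approx(1.0, abs=1e-6)
        assert abs(coefs["x0"]) < 1e-6 and abs(coefs["x2"]) < 1e-6
        assert rep.entries[0].parameter == "x1" and rep.entries[0].rank == 1

    def test_row_permutation_leaves_coefficients_unchanged(self, rng):
        X = rng.normal(size=(300, 2))
        y = 2.0 * X[:, 0] + X[:, 1] + rng.normal(0, 0.1, 300)
        s1 = _regression_samples(X, y)
        perm = rng.permutation(300)
        s2 = _regression_samples(X[perm], y[perm])
        c1 = [e.standardized_coefficient for e in tornado_regression(s1, "nmb").entries]
        c2 = [e.standardized_coefficient for e in tornado_regression(s2, "nmb").entries]
        assert np.allclose(c1, c2, atol=1e-10)

    def test_ranking_invariant_to_affine_input_rescaling(self, rng):
        X = rng.normal(size=(400, 3))
        y = 3.0 * X[:, 0] - 2.0 * X[:, 1] + 0.5 * X[:, 2] + rng.normal(0, 0.1, 400)
        base = tornado_regression(_regression_samples(X, y), "nmb")
        X2 = X.copy()
        X2[:, 1] = -7.0 * X2[:, 1] + 100.0  # affine rescale one column
        rescaled = tornado_regression(_regression_samples(X2, y), "nmb")
        assert [e.parameter for e in base.entries] == [e.parameter for e in rescaled.entries]
        assert abs(rescaled.entries[1].standardized_coefficient) == pytest.approx(
            abs(base.entries[1].standardized_coefficient), abs=1e-9
        )

    def test_constant_column_dropped_with_warning(self, rng):
        X = rng.normal(size=(200, 2))
        X[:, 1] = 5.0
        y = X[:, 0].copy()
        with pytest.warns(UserWarning, match="dropped"):
            rep = tornado_regression(_regression_samples(X, y), "nmb")
        assert rep.dropped == ["x1"]
        assert [e.parameter for e in rep.entries] == ["x0"]

    def test_collinear_column_dropped_with_warning(self, rng):
        X = rng.normal(size=(200, 3))
        X[:, 2] = 2.0 * X[:, 0]
        y = X[:, 0] + rng.normal(0, 0.1, 200)
        with pytest.warns(UserWarning, match="dropped"):
            rep = tornado_regression(_regression_samples(X, y), "nmb")
        assert "x2" in rep.dropped

    def test_needs_more_rows_than_parameters(self, rng):
        X = rng.normal(size=(3, 4))
        with pytest.raises(ValueError):
            tornado_regression(_regression_samples(X, X[:, 0].copy()), "nmb")


class TestOneWaySA:
    def test_single_parameter_summary(self):
        model = _LinearModel()
        table = one_way_sensitivity(
            model, {"x1": TriangularSpec(0.2, 0.3, 0.4)}, n=100, seed=0, wtp=WTP
        )
        assert list(table["parameter"].unique()) == ["x1"]
        row = table.iloc[0]
        assert row["quantity"] == "icer"
        assert row["p2.5"] <= row["mean"] <= row["p97.5"]
        assert row["n"] == 100
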