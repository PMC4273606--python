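"""Co-transduction model: analytic distribution, simulation, inference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rgbtrace as rt
from rgbtrace.model import CLASS_PATTERNS, LABELLED_CLASSES


def enumeration_oracle(p_r, p_g, p_b):
    """Independent oracle: enumerate the 8 presence patterns directly."""
    probs = {}
    total = 0.0
    for r in (False, True):
        for g in (False, True):
            for b in (False, True):
                pr = (p_r if r else 1 - p_r) * (p_g if g else 1 - p_g) \
                    * (p_b if b else 1 - p_b)
                if r or g or b:
                    probs[rt.class_of_pattern(r, g, b)] = pr
                    total += pr
    return {k: v / total for k, v in probs.items()}


class TestTransductionProbability:
    def test_limits(self):
        assert rt.transduction_probability(0.0) == 0.0
        assert rt.transduction_probability(50.0) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            rt.transduction_probability(-0.1)

    def test_matches_poisson_zero_class(self):
        # fraction of nonzero draws among 1e6 Poisson(1) samples
        rng = np.random.default_rng(0)
        frac = np.mean(rng.poisson(1.0, 10**6) > 0)
        se = np.sqrt(frac * (1 - frac) / 10**6)
        assert abs(rt.transduction_probability(1.0) - frac) < 3 * se

    def test_strictly_increasing(self):
        mois = np.linspace(0, 5, 200)
        p = rt.transduction_probability(mois)
        assert np.all(np.diff(p) > 0)

    def test_round_trip_with_inverse(self):
        for p in (0.0, 0.1, 0.5, 0.9):
            assert rt.transduction_probability(
                rt.moi_from_probability(p)) == pytest.approx(p)


class TestExpectedClassDistribution:
    def test_saturated_rate_gives_all_triple(self):
        f = rt.expected_class_distribution(1.0, 1.0, 1.0)
        assert f["RGB"] == pytest.approx(1.0)
        assert sum(f.values()) == pytest.approx(1.0)

    def test_vanishing_rate_gives_all_single(self):
        f = rt.expected_class_distribution(1e-4, 1e-4, 1e-4)
        assert f["R"] + f["G"] + f["B"] > 0.999

    def test_half_rate_matches_enumeration(self):
        # at p=1/2 all 8 patterns are equiprobable; conditioning leaves 1/7
        f = rt.expected_class_distribution(0.5, 0.5, 0.5)
        oracle = enumeration_oracle(0.5, 0.5, 0.5)
        for cls in LABELLED_CLASSES:
            assert f[cls] == pytest.approx(oracle[cls])
            assert f[cls] == pytest.approx(1 / 7)

    def test_unequal_rates_closed_form(self):
        p_r, p_g, p_b = 0.2, 0.5, 0.7
        f = rt.expected_class_distribution(p_r, p_g, p_b)
        denom = 1 - (1 - p_r) * (1 - p_g) * (1 - p_b)
        assert f["R"] == pytest.approx(p_r * (1 - p_g) * (1 - p_b) / denom)
        assert f["GB"] == pytest.approx((1 - p_r) * p_g * p_b / denom)
        assert f["RGB"] == pytest.approx(p_r * p_g * p_b / denom)

    def test_all_zero_is_undefined(self):
        with pytest.raises(ValueError):
            rt.expected_class_distribution(0.0, 0.0, 0.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rt.expected_class_distribution(1.2, 0.5, 0.5)

    @settings(derandomize=True, max_examples=50)
    @given(st.tuples(*[st.floats(0.001, 1.0)] * 3))
    def test_sums_to_one(self, p):
        f = rt.expected_class_distribution(*p)
        assert sum(f.values()) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.tuples(*[st.floats(0.001, 1.0)] * 3))
    def test_permutation_equivariance(self, p):
        f = rt.expected_class_distribution(*p)
        g = rt.expected_class_distribution(p[1], p[0], p[2])  # swap R and G
        assert g["G"] == pytest.approx(f["R"])
        assert g["R"] == pytest.approx(f["G"])
        assert g["GB"] == pytest.approx(f["RB"])
        assert g["RB"] == pytest.approx(f["GB"])
        assert g["RGB"] == pytest.approx(f["RGB"])

    def test_triple_fraction_monotone_in_each_rate(self):
        grid = np.linspace(0.05, 1.0, 20)
        base = (0.3, 0.6, 0.2)
        for axis in range(3):
            vals = []
            for v in grid:
                p = list(base)
                p[axis] = v
                vals.append(rt.expected_class_distribution(*p)["RGB"])
            assert np.all(np.diff(vals) >= -1e-12)


class TestSimulation:
    def test_zero_moi_all_unlabelled(self):
        d = rt.simulate_class_counts(rt.VectorSet(0, 0, 0), 100, rng=1)
        assert d.counts["unlabelled"] == 100
        assert not d.has_labelled
        with pytest.raises(ValueError):
            _ = d.fractions

    def test_high_moi_essentially_all_triple(self):
        # P(missing any vector) = 1-(1-e^-10)^3 ~ 1.4e-4 per cell
        d = rt.simulate_class_counts(rt.VectorSet(10, 10, 10), 1000, rng=2)
        assert d.counts["RGB"] >= 995

    def test_fractions_converge_to_analytic(self):
        vs = rt.VectorSet.from_probabilities(0.5, 0.5, 0.5)
        d = rt.simulate_class_counts(vs, 100_000, rng=3)
        grouped = d.grouped_fractions()
        n = d.labelled_total
        for key, expect in (("single", 3 / 7), ("double", 3 / 7),
                            ("triple", 1 / 7)):
            se = np.sqrt(expect * (1 - expect) / n)
            assert abs(grouped[key] - expect) < 3 * se

    def test_reproducible_given_seed(self):
        vs = rt.VectorSet(1, 2, 3)
        a = rt.simulate_class_counts(vs, 1000, rng=11)
        b = rt.simulate_class_counts(vs, 1000, rng=11)
        assert a.counts == b.counts

    def test_requires_positive_n(self):
        with pytest.raises(ValueError):
            rt.simulate_class_counts(rt.VectorSet(1, 1, 1), 0, rng=0)


class TestFit:
    def test_exact_expected_counts_recover_rate(self):
        # at p=0.5 the 7 labelled classes are uniform: 1000 cells each
        d = rt.ClassDistribution({c: 1000 for c in LABELLED_CLASSES})
        fit = rt.fit_transduction_rate(d, mode="equal")
        assert fit.estimate == pytest.approx(0.5, abs=1e-6)
        assert fit.ci[0] < 0.5 < fit.ci[1]
        assert not fit.at_boundary

    def test_all_triple_hits_upper_boundary(self):
        d = rt.ClassDistribution({"RGB": 50})
        fit = rt.fit_transduction_rate(d, mode="equal")
        assert fit.estimate == 1.0
        assert fit.at_boundary
        assert fit.ci[1] == 1.0

    def test_per_vector_recovers_unequal_rates(self):
        truth = (0.2, 0.5, 0.7)
        f = rt.expected_class_distribution(*truth)
        counts = {c: int(round(f[c] * 10**6)) for c in LABELLED_CLASSES}
        fit = rt.fit_transduction_rate(rt.ClassDistribution(counts),
                                       mode="per-vector")
        for est, tru in zip(fit.estimate, truth):
            assert est == pytest.approx(tru, abs=5e-3)
        for (lo, hi), tru in zip(fit.ci, truth):
            assert lo < tru < hi

    def test_per_vector_degenerate_counts_flagged_not_crashed(self):
        fit = rt.fit_transduction_rate(rt.ClassDistribution({"R": 40}),
                                       mode="per-vector")
        assert fit.at_boundary
        assert fit.estimate[0] == pytest.approx(1.0)

    def test_simulation_consistency_short(self):
        vs = rt.VectorSet.from_probabilities(0.3, 0.3, 0.3)
        rng = np.random.default_rng(7)
        estimates = []
        for _ in range(30):
            d = rt.simulate_class_counts(vs, 500, rng=rng)
            estimates.append(rt.fit_transduction_rate(d).estimate)
        assert abs(np.median(estimates) - 0.3) < 0.03

    def test_needs_labelled_cells(self):
        with pytest.raises(ValueError):
            rt.fit_transduction_rate(rt.ClassDistribution({"unlabelled": 5}))

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            rt.fit_transduction_rate(
                rt.ClassDistribution({"R": 1}), mode="bogus")


class TestGoodnessOfFit:
    def test_perfect_agreement(self):
        f = rt.expected_class_distribution(0.5, 0.5, 0.5)
        counts = {c: 100 for c in LABELLED_CLASSES}
        res = rt.goodness_of_fit(rt.ClassDistribution(counts), f)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_evaluated_statistic(self):
        # all N observations in class R against a uniform expectation
        N = 700
        uniform = {c: 1 / 7 for c in LABELLED_CLASSES}
        expected_count = N / 7
        oracle = ((N - expected_count) ** 2 / expected_count
                  + 6 * expected_count)
        res = rt.goodness_of_fit(rt.ClassDistribution({"R": N}), uniform)
        assert res.statistic == pytest.approx(oracle)
        assert res.p_value < 1e-10

    def test_zero_expected_with_observations_is_infinite(self):
        exp = {c: 0.0 for c in LABELLED_CLASSES}
        exp["RGB"] = 1.0
        res = rt.goodness_of_fit(rt.ClassDistribution({"R": 3, "RGB": 4}), exp)
        assert np.isinf(res.statistic)
        assert res.p_value == 0.0

    def test_monte_carlo_p_value_close_to_asymptotic(self):
        f = rt.expected_class_distribution(0.4, 0.4, 0.4)
        d = rt.simulate_class_counts(
            rt.VectorSet.from_probabilities(0.4, 0.4, 0.4), 2000, rng=5)
        asym = rt.goodness_of_fit(d, f)
        mc = rt.goodness_of_fit(d, f, n_monte_carlo=4000, rng=6)
        assert mc.method == "monte-carlo"
        assert abs(mc.p_value - asym.p_value) < 0.05

    def test_p_values_uniform_under_null(self):
        # correct null: simulated counts tested against their own generator
        from scipy import stats
        p = 0.5
        f = rt.expected_class_distribution(p, p, p)
        vs = rt.VectorSet.from_probabilities(p, p, p)
        rng = np.random.default_rng(9)
        pvals = [rt.goodness_of_fit(
            rt.simulate_class_counts(vs, 2000, rng=rng), f).p_value
            for _ in range(500)]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestTitre:
    def test_matches_published_scale(self):
        # 5e4 cells, 0.0001 ul = 1e-7 ml, 0.3% positive -> 1.5e9 TU/ml
        res = rt.titre_from_dilution(5e4, 1e-7, 0.003)
        assert res["tu_per_ml"].iloc[0] == pytest.approx(1.5e9)
        assert not res["outside_linear_range"].iloc[0]

    def test_zero_fraction_zero_titre(self):
        assert rt.titre_from_dilution(5e4, 1e-7, 0.0)["tu_per_ml"].iloc[0] == 0

    def test_poisson_correction_ratio(self):
        raw = rt.titre_from_dilution(1e4, 1e-3, 0.1)["tu_per_ml"].iloc[0]
        cor = rt.titre_from_dilution(1e4, 1e-3, 0.1,
                                     poisson_correct=True)["tu_per_ml"].iloc[0]
        assert cor / raw == pytest.approx(-np.log(0.9) / 0.1)

    def test_saturated_well_rejected_with_correction(self):
        with pytest.raises(ValueError):
            rt.titre_from_dilution(1e4, 1e-3, 1.0, poisson_correct=True)

    def test_nonlinear_wells_flagged(self):
        res = rt.titre_from_dilution(1e4, 1e-3, [0.1, 0.5])
        assert list(res["outside_linear_range"]) == [False, True]


class TestClassDistributionType:
    def test_counts_and_fractions_consistent(self):
        d = rt.ClassDistribution({"R": 2, "G": 1, "RGB": 1, "unlabelled": 4})
        assert d.labelled_total == 4
        assert d.total == 8
        f = d.fractions
        assert sum(f.values()) == pytest.approx(1.0)
        assert f["R"] == pytest.approx(0.5)

    def test_negative_and_unknown_rejected(self):
        with pytest.raises(ValueError):
            rt.ClassDistribution({"R": -1})
        with pytest.raises(ValueError):
            rt.ClassDistribution({"magenta": 1})

    def test_frame_round_trip(self):
        d = rt.ClassDistribution({"R": 3, "GB": 2, "unlabelled": 7})
        assert rt.ClassDistribution.from_frame(d.to_frame()).counts == d.counts


def test_class_curves_table_shape_and_limits():
    curves = rt.class_curves(np.linspace(0.01, 1.0, 10))
    assert list(curves.columns) == ["p", "single", "double", "triple"]
    assert curves.iloc[-1]["triple"] == pytest.approx(1.0)
    row_sums = curves[["single", "double", "triple"]].sum(axis=1)
    assert np.allclose(row_sums, 1.0)


def test_vector_set_validation_and_scaling():
    with pytest.raises(ValueError):
        rt.VectorSet(-1, 0, 0)
    with pytest.raises(ValueError):
        rt.VectorSet(1, 1, 1, expr_r=0)
    vs = rt.VectorSet(0.2, 0.4, 0.8, mix_ratio=(1, 2, 4))
    assert np.allclose(vs.scaled(2.0).mois, [0.4, 0.8, 1.6])
    with pytest.raises(ValueError):
        rt.VectorSet(1, 1, 1, mix_ratio=(1, 0, 1))
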