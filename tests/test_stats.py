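"""The meta-analysis battery against independent statistical oracles."""

import math

import numpy as np
import pytest
from scipy import optimize, stats as sps

from pepitrial.epitopes import Vaccine, scan_peptides
from pepitrial.stats import (
    DataPair,
    auc_sweep,
    chi2_nminus1,
    group_location_test,
    mean_epitope_count,
    pairwise_match_summary,
    pearson_with_p,
    per_position_binder_frequency,
    perpendicular_fit,
    roc_for_threshold,
)
from pepitrial.synthetic import (
    BindingModel,
    PopulationModel,
    default_locus_catalogs,
    sample_antigens,
    sample_binding_table,
    sample_population,
)
from pepitrial.trial import RatePoint


def _pairs_from_rates(measured, predicted, n_m=50, n_p=100):
    return [
        DataPair(
            f"t{i}",
            RatePoint(round(m * n_m), n_m),
            RatePoint(round(p * n_p), n_p),
        )
        for i, (m, p) in enumerate(zip(measured, predicted))
    ]


class TestPearson:
    def test_perfect_linearity(self):
        xs = [0.1, 0.2, 0.3, 0.4, 0.5]
        res = pearson_with_p(xs, [2 * x + 1 for x in xs])
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_example(self):
        # closed form on ranks: r = 0.8, t = 0.8 * sqrt(3 / 0.36), df = 3
        res = pearson_with_p([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.r == pytest.approx(0.8)
        t = 0.8 * math.sqrt(3 / 0.36)
        assert res.p == pytest.approx(2 * sps.t.sf(t, df=3))
        assert res.df == 3

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.random(12)
            y = 0.5 * x + rng.normal(scale=0.2, size=12)
            res = pearson_with_p(x, y)
            ref = sps.pearsonr(x, y)
            assert res.r == pytest.approx(ref.statistic, abs=1e-12)
            assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_p([1, 2], [3, 4])
        with pytest.raises(ValueError):
            pearson_with_p([1, 1, 1], [1, 2, 3])

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        x, y = rng.random(10), rng.random(10)
        base = pearson_with_p(x, y)
        scaled = pearson_with_p(3 * x - 1, y)
        flipped = pearson_with_p(-2 * x, y)
        assert scaled.r == pytest.approx(base.r)
        assert flipped.r == pytest.approx(-base.r)


class TestPerpendicularFit:
    def test_exact_diagonal(self):
        xs = [0.0, 0.5, 1.0, 1.5]
        fit = perpendicular_fit(xs, xs)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_axis_swap_reciprocal_slope(self):
        rng = np.random.default_rng(3)
        x = rng.random(25)
        y = 0.4 * x + rng.normal(scale=0.05, size=25)
        fwd = perpendicular_fit(x, y)
        rev = perpendicular_fit(y, x)
        assert rev.slope == pytest.approx(1.0 / fwd.slope)

    def test_closed_form_matches_numeric_minimizer(self):
        """Slope agrees with a direct numeric minimization of summed squared
        perpendicular distances over the line angle."""
        rng = np.random.default_rng(4)
        x = rng.random(20)
        y = 0.7 * x + rng.normal(scale=0.1, size=20)
        fit = perpendicular_fit(x, y)

        def perp_ss(theta):
            # line through the centroid at angle theta; distance to normal
            nx, ny = -math.sin(theta), math.cos(theta)
            xc, yc = x - x.mean(), y - y.mean()
            return float(((xc * nx + yc * ny) ** 2).sum())

        res = optimize.minimize_scalar(
            perp_ss, bounds=(-math.pi / 2 + 1e-6, math.pi / 2 - 1e-6),
            method="bounded",
        )
        assert fit.slope == pytest.approx(math.tan(res.x), abs=1e-5)
        assert fit.perp_rss == pytest.approx(res.fun, rel=1e-8)

    def test_vertical_cloud_flagged_not_overflowed(self):
        fit = perpendicular_fit([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])
        assert fit.vertical
        assert fit.intercept == pytest.approx(1.0)  # x-location

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            perpendicular_fit([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])

    def test_bootstrap_bands_are_seeded_and_ordered(self):
        rng = np.random.default_rng(5)
        x = rng.random(30)
        y = x + rng.normal(scale=0.1, size=30)
        kwargs = dict(band_x=[0.2, 0.8], n_boot=200, seed=9)
        a = perpendicular_fit(x, y, **kwargs)
        b = perpendicular_fit(x, y, **kwargs)
        assert a.confidence_halfwidth == b.confidence_halfwidth
        for conf, pred in zip(a.confidence_halfwidth, a.prediction_halfwidth):
            assert 0 < conf < pred  # prediction bands include residual scatter


def _pearson_chi2_2x2(a, b, c, d):
    """Textbook Pearson chi-squared for a 2x2 table, written out in expecteds."""
    n = a + b + c + d
    stat = 0.0
    rows, cols = (a + b, c + d), (a + c, b + d)
    obs = ((a, b), (c, d))
    for i in range(2):
        for j in range(2):
            e = rows[i] * cols[j] / n
            stat += (obs[i][j] - e) ** 2 / e
    return stat


class TestChi2NMinus1:
    def test_identical_rates_perfect_match(self):
        res = chi2_nminus1(RatePoint(30, 50), RatePoint(30, 50))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_contingency_oracle(self):
        # 28/40 vs 180/433: Pearson chi2 scaled by (N-1)/N = 472/473
        res = chi2_nminus1(RatePoint(28, 40), RatePoint(180, 433))
        expected = _pearson_chi2_2x2(28, 12, 180, 253) * 472 / 473
        assert res.statistic == pytest.approx(expected, rel=1e-12)
        assert res.p_value == pytest.approx(sps.chi2.sf(expected, df=1), rel=1e-12)

    def test_symmetric_in_arguments(self):
        a, b = RatePoint(7, 20), RatePoint(15, 31)
        assert chi2_nminus1(a, b).statistic == pytest.approx(
            chi2_nminus1(b, a).statistic
        )

    def test_zero_margin_convention(self):
        assert chi2_nminus1(RatePoint(0, 10), RatePoint(0, 25)).p_value == 1.0
        assert chi2_nminus1(RatePoint(10, 10), RatePoint(25, 25)).p_value == 1.0

    def test_random_tables_against_textbook_formula(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            n1, n2 = int(rng.integers(5, 80)), int(rng.integers(5, 500))
            k1, k2 = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n2 + 1))
            res = chi2_nminus1(RatePoint(k1, n1), RatePoint(k2, n2))
            col1, col2 = k1 + k2, (n1 - k1) + (n2 - k2)
            if col1 == 0 or col2 == 0:
                assert res.p_value == 1.0
                continue
            n = n1 + n2
            expected = _pearson_chi2_2x2(k1, n1 - k1, k2, n2 - k2) * (n - 1) / n
            assert res.statistic == pytest.approx(expected, rel=1e-9)


class TestMatchSummary:
    def test_identical_pairs_match_everywhere(self):
        pairs = [
            DataPair(f"t{i}", RatePoint(10, 20), RatePoint(25, 50))
            for i in range(5)
        ]
        assert pairwise_match_summary(pairs, "p_gt_0.05") == 1.0
        assert pairwise_match_summary(pairs, "within_10pct") == 1.0

    def test_ten_point_boundary_is_inclusive(self):
        pairs = [DataPair("t", RatePoint(30, 100), RatePoint(40, 100))]
        assert pairwise_match_summary(pairs, "within_10pct") == 1.0
        pairs = [DataPair("t", RatePoint(30, 100), RatePoint(41, 100))]
        assert pairwise_match_summary(pairs, "within_10pct") == 0.0

    def test_fraction_equals_direct_enumeration(self):
        rng = np.random.default_rng(7)
        pairs = []
        for i in range(59):
            n_m, n_p = int(rng.integers(10, 60)), 433
            pairs.append(
                DataPair(
                    f"t{i}",
                    RatePoint(int(rng.integers(0, n_m + 1)), n_m),
                    RatePoint(int(rng.integers(0, n_p + 1)), n_p),
                )
            )
        expected = (
            sum(
                1
                for p in pairs
                if chi2_nminus1(p.measured, p.predicted).p_value > 0.05
            )
            / 59
        )
        assert pairwise_match_summary(pairs, "p_gt_0.05") == pytest.approx(expected)


class TestRoc:
    def test_perfectly_separated_scores(self):
        measured = [0.9, 0.8, 0.85, 0.2, 0.3, 0.1]
        predicted = [0.7, 0.75, 0.9, 0.2, 0.25, 0.1]
        roc = roc_for_threshold(_pairs_from_rates(measured, predicted), 50.0)
        assert roc.auc == pytest.approx(1.0)
        assert roc.points[0] == (0.0, 0.0)
        assert roc.points[-1] == (1.0, 1.0)

    def test_constant_scores_give_chance_auc(self):
        measured = [0.9, 0.8, 0.2, 0.3]
        predicted = [0.5, 0.5, 0.5, 0.5]
        roc = roc_for_threshold(_pairs_from_rates(measured, predicted), 50.0)
        assert roc.auc == pytest.approx(0.5)

    def test_single_class_degenerate(self):
        roc = roc_for_threshold(
            _pairs_from_rates([0.9, 0.8, 0.7], [0.1, 0.2, 0.3]), 50.0
        )
        assert roc.degenerate and roc.auc is None

    def test_counts_define_the_curve(self):
        measured = [0.9, 0.6, 0.4, 0.2]
        predicted = [0.8, 0.5, 0.6, 0.1]
        roc = roc_for_threshold(_pairs_from_rates(measured, predicted), 50.0)
        for (tp, fp, tn, fn), (x, y) in zip(roc.counts, roc.points[1:]):
            assert x == pytest.approx(fp / (fp + tn))
            assert y == pytest.approx(tp / (tp + fn))

    def test_auc_equals_rank_sum_statistic(self):
        """Trapezoid AUC with tie grouping equals U/(n_pos*n_neg)."""
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = 30
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            pairs = [
                DataPair(
                    f"t{i}",
                    RatePoint(int(labels[i]), 1),
                    RatePoint(round(scores[i] * 100), 100),
                )
                for i in range(n)
            ]
            roc = roc_for_threshold(pairs, 50.0)
            pos, neg = scores[labels], scores[~labels]
            u = sps.mannwhitneyu(pos, neg, alternative="two-sided").statistic
            assert roc.auc == pytest.approx(u / (pos.size * neg.size), abs=1e-12)

    def test_complement_symmetry_without_ties(self):
        rng = np.random.default_rng(9)
        measured = rng.random(12)
        predicted = rng.permutation(measured)
        pairs = _pairs_from_rates(measured, predicted, n_m=1000, n_p=1000)
        flipped = [
            DataPair(
                p.label,
                p.measured,
                RatePoint(
                    p.predicted.denominator - p.predicted.numerator,
                    p.predicted.denominator,
                ),
            )
            for p in pairs
        ]
        a = roc_for_threshold(pairs, 50.0).auc
        b = roc_for_threshold(flipped, 50.0).auc
        assert a + b == pytest.approx(1.0)


class TestAucSweep:
    def test_perfect_predictions_sweep_at_one(self):
        rates = [0.15, 0.25, 0.35, 0.45, 0.55, 0.65, 0.75, 0.85, 0.95]
        pairs = _pairs_from_rates(rates, rates, n_m=100, n_p=100)
        sweep = auc_sweep(pairs)
        assert sweep  # non-degenerate thresholds exist
        assert all(v == pytest.approx(1.0) for v in sweep.values())

    def test_sweep_equals_per_threshold_calls(self):
        rng = np.random.default_rng(10)
        pairs = _pairs_from_rates(rng.random(20), rng.random(20))
        sweep = auc_sweep(pairs, range(30, 81, 10))
        for t, auc in sweep.items():
            assert auc == roc_for_threshold(pairs, t).auc

    def test_uninformative_scores_concentrate_near_half(self):
        rng = np.random.default_rng(11)
        aucs = []
        for _ in range(30):
            measured = rng.random(40)
            predicted = rng.random(40)  # independent of the labels
            aucs.extend(
                auc_sweep(_pairs_from_rates(measured, predicted)).values()
            )
        assert abs(np.mean(aucs) - 0.5) < 0.05


class TestGroupLocation:
    def test_identical_groups_p_one(self):
        assert group_location_test([1.0, 1.0], [1.0, 1.0], kind="rank") == 1.0
        assert group_location_test([2.0, 2.0], [2.0, 2.0], kind="mean") == 1.0

    def test_large_shift_is_significant(self):
        rng = np.random.default_rng(12)
        a = rng.random(20)
        b = a + 10.0
        assert group_location_test(a, b, kind="rank") < 1e-3
        assert group_location_test(a, b, kind="mean") < 1e-3

    def test_rank_p_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            a = np.round(rng.random(15), 1)
            b = np.round(rng.random(18), 1)
            if np.ptp(np.concatenate([a, b])) == 0:
                continue
            ours = group_location_test(a, b, kind="rank")
            ref = sps.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic",
                use_continuity=False,
            ).pvalue
            assert ours == pytest.approx(ref, rel=1e-9)

    def test_mean_kind_is_welch(self):
        rng = np.random.default_rng(14)
        a, b = rng.random(10), rng.random(14) * 3
        assert group_location_test(a, b, kind="mean") == pytest.approx(
            sps.ttest_ind(a, b, equal_var=False).pvalue
        )


@pytest.fixture(scope="module")
def binder_landscape():
    population = sample_population(
        PopulationModel(default_locus_catalogs(), 10, seed=30)
    )
    antigen = sample_antigens(1, (60, 60), seed=31)[0]
    alleles = sorted(population.distinct_alleles)
    peptides = [w.peptide for w in scan_peptides(antigen)]
    table = sample_binding_table(
        alleles,
        peptides,
        BindingModel(base_binder_rate=0.1, promiscuity_boost=3.0, seed=32),
    )
    return population, antigen, table


class TestRepresentativenessOps:
    def test_per_position_brute_force(self, binder_landscape):
        population, antigen, table = binder_landscape
        vec = per_position_binder_frequency(population, antigen, 2, table)
        assert vec.size == len(antigen) - 8
        seq = antigen.sequence
        for i in range(vec.size):
            pep = seq[i : i + 9]
            count = 0
            for s in population:
                n = sum(
                    1
                    for a in s.genotype.distinct_alleles
                    if (pep, a) in table.records
                    and table.records[(pep, a)].percentile_rank <= 2.0
                )
                if n >= 2:
                    count += 1
            assert vec[i] == pytest.approx(count / len(population))

    def test_elementwise_monotone_in_threshold(self, binder_landscape):
        population, antigen, table = binder_landscape
        v1 = per_position_binder_frequency(population, antigen, 1, table)
        v4 = per_position_binder_frequency(population, antigen, 4, table)
        assert (v4 <= v1 + 1e-12).all()

    def test_mean_count_equals_frequency_column_sum(self, binder_landscape):
        population, antigen, table = binder_landscape
        for n in (1, 2, 3):
            mean = mean_epitope_count(population, antigen, n, table)
            vec = per_position_binder_frequency(population, antigen, n, table)
            assert mean == pytest.approx(vec.sum(), rel=1e-12)

    def test_empty_table_zero_mean(self, binder_landscape):
        population, antigen, _ = binder_landscape
        from pepitrial.epitopes import BindingTable

        assert mean_epitope_count(population, antigen, 1, BindingTable()) == 0.0
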