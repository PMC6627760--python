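"""Cohort statistics: binomial tests, BH correction, enrichment helpers."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from mirsomatic.stats import (
    bh_adjust,
    binom_two_tailed,
    chromosome_regression,
    clinical_association,
    continuous_binom_two_tailed,
    expression_vs_mutation,
    frequency_correlation,
    hotspot_scan,
    overlap_enrichment,
    subregion_density_table,
)


def _pmf(n, p0):
    return [math.comb(n, j) * p0**j * (1 - p0) ** (n - j) for j in range(n + 1)]


def oracle_two_tailed(k, n, p0, method):
    """Full-enumeration binomial two-tailed p (independent of scipy)."""
    pmf = _pmf(n, p0)
    if method == "double":
        lower = sum(pmf[: k + 1])
        upper = sum(pmf[k:])
        return min(1.0, 2.0 * min(lower, upper))
    cutoff = pmf[k] * (1 + 1e-7)
    return min(1.0, sum(q for q in pmf if q <= cutoff))


class TestBinomTwoTailed:
    @pytest.mark.parametrize("method", ["double", "minlike"])
    def test_enumeration_oracle(self, method):
        rng = np.random.default_rng(0)
        for _ in range(150):
            n = int(rng.integers(1, 51))
            k = int(rng.integers(0, n + 1))
            p0 = float(rng.uniform(0.01, 0.99))
            assert binom_two_tailed(k, n, p0, method) == pytest.approx(
                oracle_two_tailed(k, n, p0, method), abs=1e-12
            )

    def test_closed_form_all_failures(self):
        # k=0, n=10, p0=0.5: double tail = 2 * 0.5^10
        assert binom_two_tailed(0, 10, 0.5) == pytest.approx(
            2 * 0.5**10, abs=1e-15
        )

    def test_k_equals_n_near_certain_rate(self):
        assert binom_two_tailed(20, 20, 1 - 1e-9) == pytest.approx(1.0, abs=1e-6)

    def test_invalid_p0(self):
        with pytest.raises(ValueError):
            binom_two_tailed(1, 10, 0.0)

    def test_continuous_matches_discrete_at_integers(self):
        for k, n, p0 in [(3, 20, 0.05), (7, 545, 6e-4), (0, 10, 0.5)]:
            assert continuous_binom_two_tailed(k, n, p0) == pytest.approx(
                binom_two_tailed(k, n, p0, "double"), rel=1e-9
            )

    def test_continuous_monotone_in_fractional_k(self):
        # deeper into the upper tail -> smaller p
        p_lo = continuous_binom_two_tailed(7.0, 545, 6e-4)
        p_hi = continuous_binom_two_tailed(9.5, 560, 6e-4)
        assert p_hi < p_lo


class TestBhAdjust:
    def test_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_identical_values_unchanged(self):
        assert bh_adjust([0.2] * 7) == pytest.approx([0.2] * 7)

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=100)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_reference_step_up_implementation(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = rng.uniform(size=m)
            _, ref, _, _ = multipletests(p, method="fdr_bh")
            assert bh_adjust(p) == pytest.approx(ref, abs=1e-12)


class TestDensityTable:
    def test_fold_change_is_density_ratio(self):
        counts = {"flank5": 10, "flank3": 10, "loop": 10, "passenger": 10,
                  "guide": 40, "seed": 12}
        lengths = {"flank5": 1000, "flank3": 1000, "loop": 1000,
                   "passenger": 1000, "guide": 1000, "seed": 300}
        df = subregion_density_table(counts, lengths).set_index("label")
        total_density = 80 / 5000 * 1e6
        assert df.loc["guide", "fold_change"] == pytest.approx(
            (40 / 1000 * 1e6) / total_density
        )
        assert df.loc["total", "fold_change"] == pytest.approx(1.0)
        assert df.loc["duplex", "n_mutations"] == 50

    def test_expectation_gives_fold_one_p_near_one(self):
        counts = {lbl: 20 for lbl in
                  ("flank5", "flank3", "loop", "passenger", "guide")}
        lengths = {lbl: 5000 for lbl in
                   ("flank5", "flank3", "loop", "passenger", "guide")}
        df = subregion_density_table(counts, lengths).set_index("label")
        assert df.loc["loop", "fold_change"] == pytest.approx(1.0)
        assert df.loc["loop", "p_value"] > 0.5

    def test_zero_length_label_rejected(self):
        with pytest.raises(ValueError):
            subregion_density_table({"flank5": 1}, {"flank5": 0})


class TestHotspotScan:
    def test_symmetric_null_no_gene_stands_out(self):
        counts = {f"g{i}": 3 for i in range(10)}
        lengths = {f"g{i}": 100 for i in range(10)}
        df = hotspot_scan(counts, lengths)
        assert df.p_nominal.nunique() == 1
        assert (df.p_bh >= df.p_nominal - 1e-15).all()

    def test_planted_hotspot_attains_minimum_bh(self):
        rng = np.random.default_rng(1)
        lengths = {f"g{i}": int(rng.integers(80, 140)) for i in range(500)}
        larr = np.array([lengths[f"g{i}"] for i in range(500)], dtype=float)
        base = rng.multinomial(900, larr / larr.sum())
        counts = {f"g{i}": int(base[i]) for i in range(500)}
        counts["g7"] += 100  # ~10x the background mean for that gene
        df = hotspot_scan(counts, lengths)
        assert df.iloc[0].gene_id == "g7"
        assert df.iloc[0].p_bh == df.p_bh.min()

    def test_unit_weights_reproduce_nominal(self):
        counts = {f"g{i}": int(c) for i, c in enumerate([5, 1, 0, 2, 3])}
        lengths = {f"g{i}": 100 + 10 * i for i in range(5)}
        weighted = {g: float(c) for g, c in counts.items()}
        df = hotspot_scan(counts, lengths, weighted_counts=weighted)
        assert df.p_weighted_nominal.values == pytest.approx(
            df.p_nominal.values, rel=1e-9
        )

    def test_zero_count_genes_belong_to_family(self):
        counts = {"g0": 8}
        lengths = {f"g{i}": 100 for i in range(20)}
        df = hotspot_scan(counts, lengths)
        assert len(df) == 20
        assert df.n.iloc[0] == 8


class TestOverlapEnrichment:
    def test_cohort_overlap_arithmetic(self):
        expected, fold, z, p = overlap_enrichment(350, 353, 181, 1642)
        assert expected == pytest.approx(350 * 353 / 1642, rel=1e-12)
        assert expected == pytest.approx(75.24, abs=0.005)
        assert fold == pytest.approx(181 / expected, rel=1e-12)
        assert fold == pytest.approx(2.41, abs=0.005)
        assert z > 10 and p < 1e-40

    def test_observed_equals_expected(self):
        expected, fold, z, p = overlap_enrichment(40, 50, 20, 100)
        assert (fold, z, p) == (pytest.approx(1.0), pytest.approx(0.0),
                                pytest.approx(1.0))

    def test_normal_approximation_tracks_exact_hypergeometric(self):
        # moderate deviation: the normal tail must approximate the exact
        # two-sided hypergeometric enumeration
        n_a, n_b, universe = 30, 40, 200
        rv = sps.hypergeom(universe, n_a, n_b)
        for obs in (9, 10, 11):
            _, _, _, p_norm = overlap_enrichment(n_a, n_b, obs, universe)
            # mid-p exact two-sided tail (the continuity-free counterpart
            # of the uncorrected normal approximation)
            upper = rv.sf(obs) + 0.5 * rv.pmf(obs)
            lower = rv.cdf(obs - 1) + 0.5 * rv.pmf(obs)
            p_exact = min(1.0, 2 * min(upper, lower))
            assert p_norm == pytest.approx(p_exact, abs=0.06)

    def test_zero_universe_rejected(self):
        with pytest.raises(ValueError):
            overlap_enrichment(1, 1, 1, 0)


class TestRegression:
    def test_perfect_line(self):
        x = np.arange(1, 11, dtype=float)
        res = chromosome_regression(x, 2 * x)
        assert res.r2 == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)

    def test_fixture_matches_pearson_squared(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(10, 100, size=10)
        y = 1.5 * x + rng.normal(0, 10, size=10)
        res = chromosome_regression(x, y)
        # independent algebraic formula for r^2
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        r2 = sxy**2 / (np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert res.r2 == pytest.approx(r2, rel=1e-12)
        assert (res.band_lower <= res.fitted + 1e-12).all()
        assert (res.band_upper >= res.fitted - 1e-12).all()

    def test_permuted_response_r2_near_zero_on_average(self):
        rng = np.random.default_rng(8)
        x = np.arange(1, 21, dtype=float)
        y = 3 * x
        r2s = []
        for _ in range(50):
            r2s.append(chromosome_regression(x, rng.permutation(y)).r2)
        assert np.mean(r2s) < 0.15

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            chromosome_regression([5, 5, 5], [1, 2, 3])


class TestAssociations:
    def test_fisher_perfect_separation(self):
        # enumeration over 2x2 tables with margins (5,5)/(5,5): the two
        # extreme tables have probability 1/C(10,5) = 1/252 each
        mutated = [True] * 5 + [False] * 5
        cats = ["III-IV"] * 5 + ["I-II"] * 5
        odds, p = clinical_association(mutated, cats)
        assert p == pytest.approx(2 / 252, rel=1e-9)

    def test_independence_p_one(self):
        mutated = [True] * 5 + [False] * 5 + [True] * 5 + [False] * 5
        cats = ["a"] * 10 + ["b"] * 10
        odds, p = clinical_association(mutated, cats)
        assert p == pytest.approx(1.0)
        assert odds == pytest.approx(1.0)

    def test_empty_margin_reported_undefined(self):
        odds, p = clinical_association([False] * 6, ["a"] * 3 + ["b"] * 3)
        assert p == 1.0 and math.isnan(odds)

    def test_swapping_categories_inverts_odds_preserves_p(self):
        mutated = [True, True, True, False, False, True, False, False, False]
        cats = ["a", "a", "b", "a", "b", "a", "b", "b", "a"]
        o1, p1 = clinical_association(mutated, cats)
        flipped = ["b" if c == "a" else "a" for c in cats]
        o2, p2 = clinical_association(mutated, flipped)
        assert p1 == pytest.approx(p2)
        assert o1 == pytest.approx(1 / o2)


class TestExpression:
    def test_all_mutated_below_median(self):
        expr = {f"s{i}": float(i) for i in range(10)}
        assert expression_vs_mutation(expr, ["s0", "s1", "s2"]) == 1.0

    def test_empty_mutated_set_missing(self):
        expr = {f"s{i}": float(i) for i in range(4)}
        assert expression_vs_mutation(expr, []) is None

    def test_random_assignment_expectation_half(self):
        rng = np.random.default_rng(9)
        fracs = []
        for _ in range(200):
            expr = {f"s{i}": float(v)
                    for i, v in enumerate(rng.normal(size=40))}
            picked = list(rng.choice([f"s{i}" for i in range(40)], size=5,
                                     replace=False))
            fracs.append(expression_vs_mutation(expr, picked))
        assert np.mean(fracs) == pytest.approx(0.5, abs=0.06)


class TestFrequencyCorrelation:
    def test_identical_vectors(self):
        r2, p = frequency_correlation([1, 2, 3, 4.0], [1, 2, 3, 4.0])
        assert r2 == pytest.approx(1.0)

    def test_sign_free(self):
        a = [1, 2, 3, 4, 5.0]
        r2_pos, _ = frequency_correlation(a, [2, 4, 6, 8, 10.0])
        r2_neg, _ = frequency_correlation(a, [10, 8, 6, 4, 2.0])
        assert r2_pos == pytest.approx(r2_neg)

    def test_fixture_matches_algebraic_pearson(self):
        rng = np.random.default_rng(12)
        a = rng.uniform(size=15)
        b = a * 0.7 + rng.normal(0, 0.1, size=15)
        r2, _ = frequency_correlation(a, b)
        cov = np.mean((a - a.mean()) * (b - b.mean()))
        r = cov / (a.std() * b.std())
        assert r2 == pytest.approx(r**2, rel=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            frequency_correlation([1, 2], [1, 2, 3])
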