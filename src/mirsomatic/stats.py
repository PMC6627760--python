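"""Cohort-level mutation statistics.

The central model is a length-aware binomial null: conditional on the total
number of mutations observed in the cohort, each mutation falls into a gene
(or subregion) with probability equal to that region's share of the total
analyzed sequence.  Per-gene enrichment is scored with a two-tailed binomial
test; a weighted variant of the test substitutes fractional mutation scores
into the continuous binomial tail (regularized incomplete beta).  Families
of per-gene tests are corrected with the Benjamini-Hochberg step-up
procedure.

Densities are reported in mutations per megabase of cohort-aggregate
sequence (subregion length x number of samples).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps

DISJOINT_LABELS = ("flank5", "flank3", "loop", "passenger", "guide")


# ---------------------------------------------------------------------------
# binomial machinery
# ---------------------------------------------------------------------------


def binom_two_tailed(k: int, n: int, p0: float, method: str = "double") -> float:
    """Two-tailed binomial p-value for k successes out of n at null rate p0.

    ``method="double"`` doubles the smaller of the two one-sided tails
    (capped at 1); ``method="minlike"`` sums P(X = j) over all outcomes no
    more likely than the observed one.
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    if method == "double":
        lower = sps.binom.cdf(k, n, p0)
        upper = sps.binom.sf(k - 1, n, p0)
        return float(min(1.0, 2.0 * min(lower, upper)))
    if method == "minlike":
        pmf = sps.binom.pmf(np.arange(n + 1), n, p0)
        cutoff = pmf[k] * (1 + 1e-7)  # tolerate roundoff on ties
        return float(min(1.0, pmf[pmf <= cutoff].sum()))
    raise ValueError(f"unknown method {method!r}")


def _double_tail_vec(k: np.ndarray, n: float, p0: np.ndarray) -> np.ndarray:
    lower = sps.binom.cdf(k, n, p0)
    upper = sps.binom.sf(k - 1, n, p0)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def continuous_binom_two_tailed(k: float, n: float, p0: float) -> float:
    """Two-tailed binomial test extended to fractional counts.

    Uses the identity P(X >= k) = I_{p0}(k, n - k + 1) (regularized
    incomplete beta), which is exact at integer k and interpolates smoothly
    between integers, so weighted mutation scores such as 9.5 can be tested
    within the same framework.  Two-tailed by doubling the smaller tail.
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    if k < 0 or k > n:
        raise ValueError("k must satisfy 0 <= k <= n")
    upper = 1.0 if k <= 0 else float(special.betainc(k, n - k + 1, p0))
    lower = 1.0 if k >= n else 1.0 - float(special.betainc(k + 1, n - k, p0))
    return min(1.0, 2.0 * min(lower, upper))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(adjusted, 1.0)
    return out


# ---------------------------------------------------------------------------
# subregion densities (Table-1-style)
# ---------------------------------------------------------------------------


@dataclass
class DensityResult:
    label: str
    n_mutations: int
    length_bp: int
    density: float  # mut/Mbp
    fold_change: float
    p_value: float | None


def subregion_density_table(
    counts: dict[str, int],
    lengths: dict[str, int],
    method: str = "double",
) -> pd.DataFrame:
    """Mutation density, fold change and binomial p per precursor subregion.

    ``counts``/``lengths`` are keyed by the five disjoint labels plus
    ``seed``; the total is their sum over the disjoint labels (the seed is a
    subset of guide and is not added again).  An explicit ``total`` entry in
    both dicts overrides the sum -- used when cohort-wide totals deduplicate
    variants that fall in two overlapping genes and so undercount the naive
    per-label sum.  Fold change is the label density over the total density;
    the p-value is a two-tailed binomial test of the label count against the
    label's length share.  A pooled ``duplex`` row (guide + passenger) is
    appended.
    """
    for label in DISJOINT_LABELS:
        if lengths.get(label, 0) <= 0:
            raise ValueError(f"zero or missing length for label {label!r}")
    total_count = counts.get(
        "total", sum(counts.get(label, 0) for label in DISJOINT_LABELS)
    )
    total_length = lengths.get(
        "total", sum(lengths[label] for label in DISJOINT_LABELS)
    )

    work = [(label, counts.get(label, 0), lengths[label])
            for label in DISJOINT_LABELS]
    if "seed" in lengths and lengths["seed"] > 0:
        work.append(("seed", counts.get("seed", 0), lengths["seed"]))
    work.append(
        ("duplex",
         counts.get("guide", 0) + counts.get("passenger", 0),
         lengths["guide"] + lengths["passenger"])
    )
    work.append(("total", total_count, total_length))

    total_density = total_count / total_length * 1e6
    rows = []
    for label, k, length in work:
        density = k / length * 1e6
        fold = density / total_density if total_density > 0 else float("nan")
        if label == "total":
            p = None
        else:
            p = binom_two_tailed(k, total_count, length / total_length, method)
        rows.append(
            {
                "label": label,
                "n_mutations": k,
                "length_bp": length,
                "density": density,
                "fold_change": fold,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# hotspot scan
# ---------------------------------------------------------------------------


@dataclass
class HotspotResult:
    gene_id: str
    k: int
    weighted_k: float
    n: int
    weighted_n: float
    p0: float
    p_nominal: float
    p_bh: float
    p_weighted_nominal: float | None
    p_weighted_bh: float | None


def hotspot_scan(
    counts: dict[str, int],
    lengths: dict[str, int],
    cohort_total: int | None = None,
    weighted_counts: dict[str, float] | None = None,
    method: str = "double",
) -> pd.DataFrame:
    """Per-gene overmutation test against the length-proportional null.

    ``counts`` maps gene -> observed mutation count (genes with zero counts
    must be included for a correct family); ``lengths`` maps gene -> analyzed
    region length in bp.  Each gene is tested with a two-tailed binomial:
    k = gene count, n = cohort total, p0 = gene length / total length.  When
    ``weighted_counts`` is given, a parallel test runs on the continuous
    binomial tail with (weighted_k, weighted_n).  Both p-value families are
    BH-adjusted across all analyzed genes.
    """
    genes = [g for g in lengths if lengths[g] > 0]
    dropped = set(lengths) - set(genes)
    if dropped:
        import logging

        logging.getLogger(__name__).warning(
            "excluding %d zero-length genes from hotspot scan", len(dropped)
        )
    genes.sort()
    length_arr = np.array([lengths[g] for g in genes], dtype=float)
    k_arr = np.array([counts.get(g, 0) for g in genes], dtype=float)
    total_length = length_arr.sum()
    n = int(cohort_total) if cohort_total is not None else int(k_arr.sum())
    p0_arr = length_arr / total_length

    if method == "double":
        p_nom = _double_tail_vec(k_arr, n, p0_arr)
    else:
        p_nom = np.array(
            [binom_two_tailed(int(k), n, p0, method) for k, p0 in zip(k_arr, p0_arr)]
        )
    p_bh = bh_adjust(p_nom)

    if weighted_counts is not None:
        wk_arr = np.array([weighted_counts.get(g, 0.0) for g in genes], dtype=float)
        wn = float(wk_arr.sum())
        p_wnom = np.array(
            [continuous_binom_two_tailed(wk, wn, p0)
             for wk, p0 in zip(wk_arr, p0_arr)]
        )
        p_wbh = bh_adjust(p_wnom)
    else:
        wk_arr = k_arr
        wn = float(n)
        p_wnom = np.full(len(genes), np.nan)
        p_wbh = np.full(len(genes), np.nan)

    df = pd.DataFrame(
        {
            "gene_id": genes,
            "k": k_arr.astype(int),
            "weighted_k": wk_arr,
            "n": n,
            "weighted_n": wn,
            "p0": p0_arr,
            "p_nominal": p_nom,
            "p_bh": p_bh,
            "p_weighted_nominal": p_wnom,
            "p_weighted_bh": p_wbh,
        }
    )
    return df.sort_values(["p_nominal", "gene_id"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# enrichment / association helpers
# ---------------------------------------------------------------------------


def overlap_enrichment(
    n_a: int, n_b: int, observed_overlap: int, universe: int
) -> tuple[float, float, float, float]:
    """Overlap of two gene sets vs the hypergeometric expectation.

    Returns (expected, fold, z, p) where z and the two-tailed p come from
    the normal approximation to the hypergeometric distribution of the
    overlap of two sets of sizes ``n_a`` and ``n_b`` drawn from ``universe``.
    """
    if universe <= 0:
        raise ValueError("universe must be positive")
    if observed_overlap > min(n_a, n_b) or min(n_a, n_b) > universe:
        raise ValueError("overlap/set sizes inconsistent with universe")
    expected = n_a * n_b / universe
    fold = observed_overlap / expected if expected > 0 else float("nan")
    var = (
        n_a * n_b * (universe - n_a) * (universe - n_b)
        / (universe**2 * (universe - 1))
    ) if universe > 1 else 0.0
    if var <= 0:
        return expected, fold, 0.0, 1.0
    z = (observed_overlap - expected) / np.sqrt(var)
    p = float(2 * sps.norm.sf(abs(z)))
    return expected, fold, float(z), p


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p_value: float
    x: np.ndarray
    fitted: np.ndarray
    band_lower: np.ndarray
    band_upper: np.ndarray


def chromosome_regression(genes_per_chrom, variants_per_chrom) -> RegressionResult:
    """OLS fit of per-chromosome variant counts on gene counts.

    Returns slope, r^2, the two-sided p-value for the slope, and a pointwise
    95% confidence band over the observed x range for plotting.
    """
    x = np.asarray(genes_per_chrom, dtype=float)
    y = np.asarray(variants_per_chrom, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 chromosomes")
    if np.ptp(x) == 0:
        raise ValueError("gene counts are constant across chromosomes")
    fit = sps.linregress(x, y)
    n = x.size
    fitted = fit.intercept + fit.slope * x
    resid = y - fitted
    s2 = (resid**2).sum() / (n - 2)
    sxx = ((x - x.mean()) ** 2).sum()
    se_mean = np.sqrt(s2 * (1 / n + (x - x.mean()) ** 2 / sxx))
    tcrit = sps.t.ppf(0.975, n - 2)
    order = np.argsort(x)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        x=x[order],
        fitted=fitted[order],
        band_lower=(fitted - tcrit * se_mean)[order],
        band_upper=(fitted + tcrit * se_mean)[order],
    )


def clinical_association(mutated_flags, category_labels) -> tuple[float, float]:
    """Fisher exact association between gene mutation and a binary category.

    Returns (odds_ratio, two-tailed p).  With an empty margin the test is
    undefined: p = 1 and odds ratio NaN.
    """
    mutated = np.asarray(mutated_flags, dtype=bool)
    cats = np.asarray(category_labels)
    if mutated.size != cats.size:
        raise ValueError("length mismatch")
    levels = sorted(pd.unique(cats).tolist())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 category levels, got {levels}")
    table = np.array(
        [
            [int(np.sum(mutated & (cats == lev))) for lev in levels],
            [int(np.sum(~mutated & (cats == lev))) for lev in levels],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan"), 1.0
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def expression_vs_mutation(
    expression_by_sample: dict[str, float] | pd.Series,
    mutated_samples,
) -> float | None:
    """Fraction of mutated samples whose expression is below the cohort median.

    The median is taken over all samples with expression values.  Mutated
    samples lacking expression are excluded (logged); returns None when no
    mutated sample has expression data.
    """
    series = pd.Series(expression_by_sample, dtype=float)
    if series.size < 2:
        raise ValueError("need expression for at least 2 samples")
    median = series.median()
    mutated = [s for s in mutated_samples if s in series.index]
    missing = set(mutated_samples) - set(mutated)
    if missing:
        import logging

        logging.getLogger(__name__).info(
            "%d mutated samples lack expression data", len(missing)
        )
    if not mutated:
        return None
    below = sum(series[s] < median for s in mutated)
    return below / len(mutated)


def frequency_correlation(per_gene_frequencies, reference_frequencies
                          ) -> tuple[float, float]:
    """Pearson r^2 and two-sided p between paired per-gene frequencies."""
    a = np.asarray(per_gene_frequencies, dtype=float)
    b = np.asarray(reference_frequencies, dtype=float)
    if a.size != b.size:
        raise ValueError("length mismatch")
    r, p = sps.pearsonr(a, b)
    return float(r**2), float(p)


# ---------------------------------------------------------------------------
# count aggregation from mapped variants
# ---------------------------------------------------------------------------


def subregion_substitution_counts(variants) -> dict[str, int]:
    """Substitution counts per subregion label (complex mutations excluded).

    Each substitution contributes to exactly one of the five disjoint labels
    and additionally to ``seed`` when applicable.
    """
    counts = {label: 0 for label in DISJOINT_LABELS + ("seed",)}
    for v in variants:
        if v.variant_class != "substitution":
            continue
        for label in DISJOINT_LABELS:
            if label in v.subregion_labels:
                counts[label] += 1
                break
        if "seed" in v.subregion_labels:
            counts["seed"] += 1
    return counts


def per_gene_burden(variants) -> tuple[dict[str, int], dict[str, float]]:
    """Per-gene mutation counts and weighted scores (complex counts as one)."""
    counts: dict[str, int] = {}
    weighted: dict[str, float] = {}
    for v in variants:
        counts[v.gene_id] = counts.get(v.gene_id, 0) + 1
        weighted[v.gene_id] = weighted.get(v.gene_id, 0.0) + v.weight
    return counts, weighted
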