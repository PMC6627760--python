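# Methods

## Gene-region model

The unit of analysis is the extended miRNA gene region: the
pre-miRNA-coding sequence plus `flank_len = 25` nt upstream and downstream.
Coordinates are 1-based and strand-aware (precursor sense); extended
positions ≤ 0 address the 5′ flank (0 is 1 nt upstream) and positions > L
the 3′ flank, which is also how HGVS `n.` names are formed (`n.1-18A>G`,
`n.77+26C>T`).

Precursor boundaries are reconstructed from the mature-arm coordinates: the
loader trims each stem-loop record to the outer bounds of its mature arms,
so position 1 is the first nucleotide of the 5p miRNA and position L the
last of the 3p miRNA. When only one arm is annotated, the counterpart is
first predicted inside the stem-loop by the duplex-geometry rule
(5p [a, b] → 3p [L+3−b, L+3−a], the image of the pairing i + j = L + 1
shifted 2 nt so both strands carry 2-nt 3′ overhangs), clamped to the
stem-loop, and the trim then uses both arms. Predicted arms shorter than
10 nt after clamping abort the gene (degenerate hairpin). This convention
was chosen over keeping raw stem-loop coordinates because it makes the
guide/passenger/loop intervals an exact partition of [1, L] — the property
the length accounting below depends on — and matches how published
precursor-relative variant names (e.g. a variant at the penultimate
precursor position sitting "next to the DROSHA cleavage site") behave. For
annotations whose arms do not touch the precursor ends, the residual basal
positions are absorbed into the adjacent arm's subregion so the partition
still holds.

Arm dominance uses the mature read counts: ≥90 % of reads from one arm
makes that arm's mature interval the guide (the other is passenger);
otherwise the precursor is balanced and **both** arms are counted as guide
with an empty passenger set. The balanced rule follows from the aggregate
subregion lengths it implies (mean guide length above one mature length,
mean passenger below one), which is the only assignment consistent with the
per-subregion density accounting we reproduce. Precursors with no reads at
all are classed balanced with a warning rather than dropped. The seed is
positions 2–8 of each guide mature. Cleavage windows are ±2 nt (default,
configurable) around the DROSHA scissile positions {1, L} and the DICER
duplex/loop boundaries; no folding is performed, so these windows are a
sequence-coordinate proxy for the structurally defined sites.

Biogenesis-enhancer motifs are located by sequence only: basal UG within
17 nt upstream of position 1, CNNC within the 25-nt 3′ flank, UGUG inside
the apical loop. The windows follow the conventions of the biogenesis
literature and are module constants.

## Density accounting

Cohort-aggregate subregion length = (sum of interval lengths over genes) ×
(number of samples), in bp; densities are mutations per Mbp of that
denominator. The five disjoint labels (flank5, flank3, loop, passenger,
guide) sum exactly to the extended-region total; the seed is reported but
not added (it is a guide subset). `subregion_density_table` accepts an
explicit `total` entry overriding the per-label sum, because cohort-wide
totals deduplicate variants that fall in two overlapping genes and can
therefore be slightly below the naive sum.

## Filtering model

Calls are read per caller with pysam from four configurable VCF dialects
(allele depths in `AD`/`RD`, somatic score `SSC` in INFO or FORMAT, base
quality `BQ` per allele). Only PASS records enter; multi-allelic records
are split. Duplicate files of one patient/caller sum their reads; across
callers, depths are pooled as the per-field **maximum** — the callers
re-observe the same sequencing reads, so summing would double-count
evidence — while SSC/BQ stay per caller. Indel representations are
normalized (shared suffix then prefix trimming) before deduplication.

The four quality criteria are applied with strict thresholds (alt reads
≥ 2; frequency ratio ≥ 5 computed on alt/(alt+ref) frequencies, the
criterion that removes germline contaminants whose tumor and normal
frequencies match; SSC > 30; BQ > 20). Criterion (i) applies only when the
normal sample shows zero alternative reads, (ii) otherwise; (iii)/(iv)
bind only when a caller of the corresponding family supports the variant
and are satisfied by the best supporting caller of that family. All
violated criteria are recorded, so filtering is idempotent and auditable.

## Weighting and the weighted test

Mutation weights: seed 2×, guide 1.5×, cleavage-site or motif-affecting
1.5×, other 1×, combined by **maximum** (a seed mutation inside a motif
scores 2, not 3.5) — additive semantics would allow per-gene weighted
scores above 2× the count, which the per-gene score structure rules out.
Complex mutations (≥2 alterations, one gene, one sample) count once with
the union of their labels; they are excluded from the substitution-only
density and motif analyses but included in per-gene burden.

The nominal hotspot test is the two-tailed binomial with k = gene count,
n = cohort total, p₀ = gene length / total length. Two-tail method
`double` (2 × smaller tail, capped at 1) is the default; `minlike`
(summing all outcomes no more likely than k) is available — the choice
matters in the tails of small-n tests, and the default mirrors the common
desk-calculator convention. The weighted test substitutes (k_w, n_w) into
P(X ≥ k) = I_{p₀}(k, n−k+1), the regularized-incomplete-beta extension of
the binomial survival function, which is exact at integers (verified in
tests) and interpolates smoothly for fractional scores. BH correction runs
over **all** analyzed genes (zero-count genes included); the family is the
set of genes with defined length, configurable in principle via the run
config's family policy.

## Synthetic cohorts

The generator emulates the study conditions end to end. Defaults are the
full-scale cohort: 1642 genes over 23 chromosomes and both strands, mature
arms 20–24 nt, loops 10–25 nt, arm-profile mixture 0.4/0.4/0.2
(5p/3p/balanced, realized exactly), 15 % of genes annotated with a single
arm, 569 + 497 samples in two cancer labels, background 5.2×10⁻⁶
substitutions per bp per sample (≈545 mutations per cancer at full scale),
and ~300× depth at called sites. Stem-loops carry 4-nt/2-nt basal stubs so
that single-arm counterpart prediction is exact before trimming, and the
second half of each stem-loop is the reverse complement of the first, so
the arms are duplex-compatible.

Somatic substitutions arrive per gene as Poisson(background × multiplier ×
extended length), uniform in position — the same uniform, length-only null
the hotspot test assumes; no trinucleotide-context bias is modeled.
Planted categories (seed, cleavage-window, motif-destroying,
motif-creating) are placed by direct search in the correct subregions.
Germline contaminants are emitted with matched tumor/normal allele
frequencies (0.35–0.6) so criterion (ii) must remove them; configurable
fractions of background calls violate each quality criterion (with the
relevant caller family forced to detect them so the criterion binds).
Callers detect each variant independently with configurable sensitivity
(default 1.0, so truth bookkeeping is exact); caller files are VCF v4.2 in
the four dialects. Identical config + seed gives byte-identical files.

What the simulation does **not** model: indels and multi-nucleotide
variants (the variant machinery supports them; the generator emits
substitutions only), read-level errors, mapping artifacts, copy-number
state, context-dependent mutation signatures, and caller-specific
systematic biases. Passing the end-to-end tests therefore shows the
pipeline's bookkeeping, filtering and statistics are correct under the
stated generative model, not that caller idiosyncrasies on real TCGA data
are handled.

## Numerical and design choices

- Binomial tails come from scipy (`binom.cdf/sf`, `special.betainc`); the
  BH step-up is implemented directly (and checked against the statsmodels
  reference in tests). Ties in `minlike` use a 1+10⁻⁷ relative cushion on
  the observed likelihood.
- The mutated-gene-set overlap between two cancers uses the hypergeometric
  mean/variance with a normal z (no continuity correction); tests compare
  it against the exact mid-p enumeration.
- Per-chromosome regression is ordinary least squares with a pointwise 95 %
  t confidence band.
- Sizes used in the statistical studies: the null-calibration study runs
  500 genes × 200 replicates at 200 expected mutations per gene. The
  discrete double-tail binomial is conservative at small expected counts
  (attained type-I ≈ 0.02 at 1–2 expected mutations per gene), so the
  calibration check is run in the near-continuous regime where the attained
  rate approaches the nominal 0.05; this regime choice is a property of the
  statistic, documented here deliberately. The power study plants 7
  mutations on one of 1642 genes against a 545-mutation background
  (100 replicates). Test and demo cohorts use 25–120 genes and 5–70
  samples with proportionally raised background rates, keeping the same
  generative model at tractable size.
- All tabular outputs are sorted on stable keys, so re-running any stage on
  unchanged inputs is byte-identical.

## Known limitations

- Cleavage windows and biogenesis-motif windows are sequence-coordinate
  conventions, not structure-derived; an optional dot-bracket override for
  the duplex pairing is a design hook, not implemented.
- Arm labels fall back to a midpoint rule when mature names carry no
  -5p/-3p suffix; unusual annotations (two matures on one arm) keep the
  first of each label with a warning.
- The frequency-ratio filter interprets "5× higher frequency" on allele
  frequencies, not raw counts; with very unequal tumor/normal depths the
  two readings differ.
- Expression association and clinical association helpers are exact but
  deliberately simple (median split; 2×2 Fisher); no multivariate
  adjustment.
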