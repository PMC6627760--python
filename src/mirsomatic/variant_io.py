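"""Per-caller somatic VCF parsing, cross-caller merging, and quality filters.

Somatic calls come as one VCF per patient per caller in the dialects of four
callers (MuSE, MuTect2, VarScan2, SomaticSniper).  Only PASS records are
kept.  Duplicate files of the same patient/caller are combined by summing
read counts; calls are then unified across callers so that a variant seen by
several algorithms appears once, and the harmonized calls are screened with
four quality criteria:

(i)   >= 2 alternative-allele reads in the tumor (when the normal shows no
      alternative reads);
(ii)  tumor alternative-allele frequency >= 5x the normal frequency (when
      the normal does show alternative reads);
(iii) somatic score SSC > 30, for VarScan2/SomaticSniper-supported calls;
(iv)  tumor alt-read base quality BQ > 20, for MuSE/MuTect2-supported calls.

Criteria (iii) and (iv) bind only when a caller of the respective family
supports the variant, and are satisfied if at least one supporting caller of
that family meets the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

CALLERS = ("MuSE", "MuTect2", "VarScan2", "SomaticSniper")
SSC_FAMILY = frozenset({"VarScan2", "SomaticSniper"})
BQ_FAMILY = frozenset({"MuSE", "MuTect2"})


@dataclass(frozen=True)
class CallerDialect:
    """Where a caller's VCF keeps allele depths and quality scores.

    ``ad_style`` is "allelic" (FORMAT/AD lists per-allele depths, reference
    first) or "varscan" (FORMAT/RD reference depth plus scalar FORMAT/AD
    alternative depth).  SSC may live in INFO or per-sample FORMAT; BQ is a
    per-allele FORMAT field.
    """

    ad_style: str = "allelic"
    ssc_source: str | None = None  # None | "info" | "format"
    bq_source: str | None = None  # None | "format"


DEFAULT_DIALECTS: dict[str, CallerDialect] = {
    "MuSE": CallerDialect(ad_style="allelic", bq_source="format"),
    "MuTect2": CallerDialect(ad_style="allelic", bq_source="format"),
    "VarScan2": CallerDialect(ad_style="varscan", ssc_source="info"),
    "SomaticSniper": CallerDialect(ad_style="allelic", ssc_source="format"),
}


@dataclass
class SomaticCall:
    patient_id: str
    caller: str
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    filter_status: str
    tumor_ref_reads: int
    tumor_alt_reads: int
    normal_ref_reads: int
    normal_alt_reads: int
    ssc: float | None = None
    bq_alt: float | None = None

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        for attr in ("tumor_ref_reads", "tumor_alt_reads",
                     "normal_ref_reads", "normal_alt_reads"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be non-negative")


@dataclass
class MergedVariant:
    """A per-patient somatic call unified across callers."""

    patient_id: str
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    supporting_callers: set[str]
    tumor_ref_reads: int
    tumor_alt_reads: int
    normal_ref_reads: int
    normal_alt_reads: int
    ssc_by_caller: dict[str, float] = field(default_factory=dict)
    bq_by_caller: dict[str, float] = field(default_factory=dict)
    pass_filters: bool = False
    fail_reasons: list[str] = field(default_factory=list)

    @property
    def key(self) -> tuple:
        return (self.patient_id, self.chromosome, self.position,
                self.ref_allele, self.alt_allele)

    @property
    def is_indel(self) -> bool:
        return len(self.ref_allele) != len(self.alt_allele)

    def tumor_af(self) -> float:
        depth = self.tumor_ref_reads + self.tumor_alt_reads
        return self.tumor_alt_reads / depth if depth else 0.0

    def normal_af(self) -> float:
        depth = self.normal_ref_reads + self.normal_alt_reads
        return self.normal_alt_reads / depth if depth else 0.0


@dataclass(frozen=True)
class FilterThresholds:
    min_tumor_alt_reads: int = 2
    min_freq_ratio: float = 5.0
    min_ssc: float = 30.0  # strict: SSC must exceed this
    min_bq: float = 20.0  # strict: BQ must exceed this


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def _scalar(value):
    if isinstance(value, tuple):
        return value[0] if value else None
    return value


def parse_caller_file(
    path: str,
    caller: str,
    patient_id: str,
    dialect: CallerDialect | None = None,
    tumor_sample: str = "TUMOR",
    normal_sample: str = "NORMAL",
) -> list[SomaticCall]:
    """Extract PASS somatic calls from one caller VCF.

    Multi-allelic records are split into one call per alternative allele.
    Records whose depth fields cannot be read are skipped with a warning;
    a missing tumor or normal sample column is a hard error.
    """
    if dialect is None:
        dialect = DEFAULT_DIALECTS.get(caller, CallerDialect())
    calls: list[SomaticCall] = []
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        if tumor_sample not in samples or normal_sample not in samples:
            raise ValueError(
                f"{path}: expected samples {tumor_sample!r} and {normal_sample!r}, "
                f"found {samples}"
            )
        for rec in vcf:
            filters = list(rec.filter.keys()) or ["."]
            if filters != ["PASS"]:
                continue
            if not rec.alts:
                continue
            for alt_index, alt in enumerate(rec.alts):
                try:
                    calls.append(
                        _build_call(rec, alt_index, alt, caller, patient_id,
                                    dialect, tumor_sample, normal_sample)
                    )
                except (KeyError, TypeError, ValueError) as exc:
                    logger.warning(
                        "%s: skipping record %s:%s (%s)",
                        path, rec.chrom, rec.pos, exc,
                    )
    return calls


def _depths(sample, alt_index: int, dialect: CallerDialect) -> tuple[int, int]:
    if dialect.ad_style == "varscan":
        ref_reads = _scalar(sample["RD"])
        alt_reads = _scalar(sample["AD"])
    else:
        ad = sample["AD"]
        ref_reads = ad[0]
        alt_reads = ad[alt_index + 1]
    if ref_reads is None or alt_reads is None:
        raise ValueError("missing allele depths")
    return int(ref_reads), int(alt_reads)


def _build_call(rec, alt_index, alt, caller, patient_id, dialect,
                tumor_sample, normal_sample) -> SomaticCall:
    tumor = rec.samples[tumor_sample]
    normal = rec.samples[normal_sample]
    t_ref, t_alt = _depths(tumor, alt_index, dialect)
    n_ref, n_alt = _depths(normal, alt_index, dialect)

    ssc = None
    if dialect.ssc_source == "info":
        ssc = _scalar(rec.info.get("SSC"))
    elif dialect.ssc_source == "format":
        ssc = _scalar(tumor.get("SSC"))
    bq = None
    if dialect.bq_source == "format":
        raw = tumor.get("BQ")
        if isinstance(raw, tuple):
            # per-allele (reference first) or alt-only, depending on length
            bq = raw[alt_index + 1] if len(raw) > len(rec.alts) else raw[alt_index]
        else:
            bq = raw
    return SomaticCall(
        patient_id=patient_id,
        caller=caller,
        chromosome=rec.chrom,
        position=rec.pos,
        ref_allele=rec.ref,
        alt_allele=alt,
        filter_status="PASS",
        tumor_ref_reads=t_ref,
        tumor_alt_reads=t_alt,
        normal_ref_reads=n_ref,
        normal_alt_reads=n_alt,
        ssc=float(ssc) if ssc is not None else None,
        bq_alt=float(bq) if bq is not None else None,
    )


# ---------------------------------------------------------------------------
# normalization and merging
# ---------------------------------------------------------------------------


def normalize_alleles(position: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Minimal variant representation: trim shared suffix, then prefix.

    Collapses the different padded representations callers use for the same
    indel so that cross-caller deduplication works on a canonical key.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        position += 1
    return position, ref, alt


def combine_duplicate_files(calls: list[SomaticCall]) -> list[SomaticCall]:
    """Merge calls from multiple files of one patient/caller, summing reads.

    Identical (chrom, pos, ref, alt) records are collapsed; read counts are
    summed, quality scores take the maximum observed.
    """
    merged: dict[tuple, SomaticCall] = {}
    for call in calls:
        key = (call.patient_id, call.caller, call.chromosome, call.position,
               call.ref_allele, call.alt_allele)
        if key not in merged:
            merged[key] = replace(call)
        else:
            kept = merged[key]
            kept.tumor_ref_reads += call.tumor_ref_reads
            kept.tumor_alt_reads += call.tumor_alt_reads
            kept.normal_ref_reads += call.normal_ref_reads
            kept.normal_alt_reads += call.normal_alt_reads
            if call.ssc is not None:
                kept.ssc = call.ssc if kept.ssc is None else max(kept.ssc, call.ssc)
            if call.bq_alt is not None:
                kept.bq_alt = (call.bq_alt if kept.bq_alt is None
                               else max(kept.bq_alt, call.bq_alt))
    return sorted(
        merged.values(),
        key=lambda c: (c.patient_id, c.caller, c.chromosome, c.position,
                       c.ref_allele, c.alt_allele),
    )


def merge_across_callers(calls: list[SomaticCall]) -> list[MergedVariant]:
    """Unify one patient's calls across callers.

    Alleles are normalized first so that differing indel representations
    collapse.  Because the callers observe the same sequencing reads, depth
    evidence is pooled as the per-field maximum across callers (not summed);
    SSC/BQ are kept per caller for family-specific filtering.
    """
    merged: dict[tuple, MergedVariant] = {}
    for call in calls:
        pos, ref, alt = normalize_alleles(call.position, call.ref_allele,
                                          call.alt_allele)
        key = (call.patient_id, call.chromosome, pos, ref, alt)
        if key not in merged:
            merged[key] = MergedVariant(
                patient_id=call.patient_id,
                chromosome=call.chromosome,
                position=pos,
                ref_allele=ref,
                alt_allele=alt,
                supporting_callers=set(),
                tumor_ref_reads=0,
                tumor_alt_reads=0,
                normal_ref_reads=0,
                normal_alt_reads=0,
            )
        mv = merged[key]
        mv.supporting_callers.add(call.caller)
        mv.tumor_ref_reads = max(mv.tumor_ref_reads, call.tumor_ref_reads)
        mv.tumor_alt_reads = max(mv.tumor_alt_reads, call.tumor_alt_reads)
        mv.normal_ref_reads = max(mv.normal_ref_reads, call.normal_ref_reads)
        mv.normal_alt_reads = max(mv.normal_alt_reads, call.normal_alt_reads)
        if call.ssc is not None:
            prev = mv.ssc_by_caller.get(call.caller)
            mv.ssc_by_caller[call.caller] = (call.ssc if prev is None
                                             else max(prev, call.ssc))
        if call.bq_alt is not None:
            prev = mv.bq_by_caller.get(call.caller)
            mv.bq_by_caller[call.caller] = (call.bq_alt if prev is None
                                            else max(prev, call.bq_alt))
    return sorted(
        merged.values(),
        key=lambda v: (v.patient_id, v.chromosome, v.position, v.ref_allele,
                       v.alt_allele),
    )


# ---------------------------------------------------------------------------
# quality filters
# ---------------------------------------------------------------------------


def apply_quality_filters(
    variant: MergedVariant, thresholds: FilterThresholds | None = None
) -> MergedVariant:
    """Screen one merged variant; returns a copy with the verdict filled in.

    Every violated criterion is recorded in ``fail_reasons``; the variant
    passes iff no reason accumulates.  Applying the filters twice leaves the
    verdict unchanged.
    """
    if thresholds is None:
        thresholds = FilterThresholds()
    t = thresholds
    reasons: list[str] = []

    tumor_depth = variant.tumor_ref_reads + variant.tumor_alt_reads
    if tumor_depth == 0:
        reasons.append("no_tumor_coverage")
    elif variant.normal_alt_reads == 0:
        if variant.tumor_alt_reads < t.min_tumor_alt_reads:
            reasons.append("min_alt_reads")
    else:
        normal_af = variant.normal_af()
        if variant.tumor_af() < t.min_freq_ratio * normal_af:
            reasons.append("freq_ratio")

    ssc_callers = variant.supporting_callers & SSC_FAMILY
    if ssc_callers:
        values = [variant.ssc_by_caller[c] for c in ssc_callers
                  if variant.ssc_by_caller.get(c) is not None]
        if not values or max(values) <= t.min_ssc:
            reasons.append("ssc")

    bq_callers = variant.supporting_callers & BQ_FAMILY
    if bq_callers:
        values = [variant.bq_by_caller[c] for c in bq_callers
                  if variant.bq_by_caller.get(c) is not None]
        if not values or max(values) <= t.min_bq:
            reasons.append("bq")

    out = replace(variant, fail_reasons=reasons, pass_filters=not reasons)
    return out


# ---------------------------------------------------------------------------
# cohort-level driver
# ---------------------------------------------------------------------------


def load_manifest(path: str) -> pd.DataFrame:
    """Read a (patient_id, caller, path) manifest.

    Relative VCF paths are resolved against the manifest's directory.
    """
    import os

    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"patient_id", "caller", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest lacks columns: {sorted(missing)}")
    base = os.path.dirname(os.path.abspath(path))
    df["path"] = [
        p if os.path.isabs(p) else os.path.join(base, p) for p in df["path"]
    ]
    return df


def process_patient(
    files: list[tuple[str, str]],
    patient_id: str,
    thresholds: FilterThresholds | None = None,
    dialects: dict[str, CallerDialect] | None = None,
) -> list[MergedVariant]:
    """Parse -> combine duplicates -> merge callers -> filter for one patient.

    ``files`` is a list of (caller, path) pairs; a caller may appear several
    times (duplicate TCGA-style files).
    """
    per_caller: dict[str, list[SomaticCall]] = {}
    for caller, path in files:
        dialect = (dialects or DEFAULT_DIALECTS).get(caller)
        per_caller.setdefault(caller, []).extend(
            parse_caller_file(path, caller, patient_id, dialect=dialect)
        )
    calls: list[SomaticCall] = []
    for caller_calls in per_caller.values():
        calls.extend(combine_duplicate_files(caller_calls))
    merged = merge_across_callers(calls)
    return [apply_quality_filters(v, thresholds) for v in merged]


def process_manifest(
    manifest: str | pd.DataFrame,
    thresholds: FilterThresholds | None = None,
    dialects: dict[str, CallerDialect] | None = None,
) -> dict[str, list[MergedVariant]]:
    """Run the merge/filter stage for every patient in a manifest."""
    df = load_manifest(manifest) if isinstance(manifest, str) else manifest
    out: dict[str, list[MergedVariant]] = {}
    for patient_id, group in df.groupby("patient_id", sort=True):
        files = list(zip(group["caller"], group["path"]))
        out[str(patient_id)] = process_patient(
            files, str(patient_id), thresholds=thresholds, dialects=dialects
        )
    return out


def merged_variants_table(variants: list[MergedVariant]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": v.patient_id,
            "chrom": v.chromosome,
            "pos": v.position,
            "ref": v.ref_allele,
            "alt": v.alt_allele,
            "callers": ",".join(sorted(v.supporting_callers)),
            "tumor_ref": v.tumor_ref_reads,
            "tumor_alt": v.tumor_alt_reads,
            "normal_ref": v.normal_ref_reads,
            "normal_alt": v.normal_alt_reads,
            "pass": v.pass_filters,
            "fail_reasons": ",".join(v.fail_reasons),
        }
        for v in variants
    ]
    return pd.DataFrame(
        rows,
        columns=["patient_id", "chrom", "pos", "ref", "alt", "callers",
                 "tumor_ref", "tumor_alt", "normal_ref", "normal_alt",
                 "pass", "fail_reasons"],
    )
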