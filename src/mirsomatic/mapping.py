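"""Mapping of filtered somatic calls onto miRNA gene regions.

Assigns each merged variant to every extended gene region it overlaps,
converts alleles to precursor sense for minus-strand genes, names variants
in HGVS-style ``n.`` notation relative to the precursor (flank positions use
the ``n.1-k`` / ``n.L+k`` offset forms), labels the affected subregions,
collapses multiple alterations of one gene in one sample into a single
complex mutation, and scores each variant with the weighting scheme used in
the weighted hotspot analysis (2x seed, 1.5x guide strand, 1.5x functional
motif or DROSHA/DICER cleavage site, 1x otherwise; combined by maximum).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .annotation import MirnaGeneRegion, genomic_to_precursor, revcomp
from .variant_io import MergedVariant

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Weights:
    seed: float = 2.0
    guide: float = 1.5
    motif_or_cleavage: float = 1.5
    other: float = 1.0


@dataclass
class MirnaVariant:
    merged: MergedVariant
    gene_id: str
    precursor_position: int  # extended coordinate; <=0 flank5, >L flank3
    hgvs: str
    subregion_labels: set[str]
    variant_class: str  # substitution | indel | complex
    ref_allele: str = ""  # precursor sense
    alt_allele: str = ""
    weight: float = 1.0
    component_hgvs: list[str] = field(default_factory=list)  # for complex

    @property
    def patient_id(self) -> str:
        return self.merged.patient_id


# ---------------------------------------------------------------------------
# HGVS-style naming
# ---------------------------------------------------------------------------


def format_position(ext_pos: int, L: int) -> str:
    """Extended precursor coordinate -> HGVS position string.

    Body positions print as-is; 5'-flank positions (<= 0) as ``1-k`` where k
    is the distance upstream of position 1; 3'-flank positions (> L) as
    ``L+k``.  Position 0 is never emitted: it is offset form ``1-1``.
    """
    if ext_pos <= 0:
        return f"1-{1 - ext_pos}"
    if ext_pos > L:
        return f"{L}+{ext_pos - L}"
    return str(ext_pos)


def hgvs_name(L: int, ext_pos: int, ref: str, alt: str) -> str:
    """HGVS ``n.`` name for a variant at an extended precursor coordinate.

    Substitutions use ``n.<pos><ref>><alt>``; pure deletions/insertions use
    del/ins syntax, anything else delins.  Alleles are given in precursor
    sense.
    """
    if len(ref) == 1 and len(alt) == 1:
        return f"n.{format_position(ext_pos, L)}{ref}>{alt}"
    if len(alt) == 1 and ref.startswith(alt):
        # deletion of ref[1:], anchored at ext_pos
        start, end = ext_pos + 1, ext_pos + len(ref) - 1
        p1, p2 = format_position(start, L), format_position(end, L)
        span = p1 if start == end else f"{p1}_{p2}"
        return f"n.{span}del{ref[1:]}"
    if len(ref) == 1 and alt.startswith(ref):
        p1 = format_position(ext_pos, L)
        p2 = format_position(ext_pos + 1, L)
        return f"n.{p1}_{p2}ins{alt[1:]}"
    start, end = ext_pos, ext_pos + len(ref) - 1
    p1, p2 = format_position(start, L), format_position(end, L)
    span = p1 if start == end else f"{p1}_{p2}"
    return f"n.{span}delins{alt}"


_POS = r"(?:(?P<body>\d+)(?:(?P<sign>[+-])(?P<off>\d+))?)"
_SUB_RE = re.compile(rf"^n\.{_POS}(?P<ref>[ACGTU])>(?P<alt>[ACGTU])$")
_DEL_RE = re.compile(r"^n\.(?P<p1>[\d+-]+?)(?:_(?P<p2>[\d+-]+?))?del(?P<seq>[ACGTU]+)$")
_INS_RE = re.compile(r"^n\.(?P<p1>[\d+-]+?)_(?P<p2>[\d+-]+?)ins(?P<seq>[ACGTU]+)$")


def _parse_position(text: str) -> int:
    m = re.match(r"^(\d+)([+-])(\d+)$", text)
    if m:
        base, sign, off = int(m.group(1)), m.group(2), int(m.group(3))
        return base + off if sign == "+" else base - off
    return int(text)


def parse_hgvs(name: str) -> tuple[int, str, str]:
    """Parse an HGVS ``n.`` name back to (extended position, ref, alt).

    Inverse of :func:`hgvs_name` for substitutions, deletions and
    insertions (deletions return the anchored padded alleles).
    """
    m = _SUB_RE.match(name)
    if m:
        pos = int(m.group("body"))
        if m.group("sign") == "-":
            pos -= int(m.group("off"))
        elif m.group("sign") == "+":
            pos += int(m.group("off"))
        return pos, m.group("ref"), m.group("alt")
    m = _INS_RE.match(name)
    if m:
        pos = _parse_position(m.group("p1"))
        return pos, "N", "N" + m.group("seq")
    m = _DEL_RE.match(name)
    if m:
        pos = _parse_position(m.group("p1")) - 1
        return pos, "N" + m.group("seq"), "N"
    raise ValueError(f"unparseable HGVS name: {name!r}")


# ---------------------------------------------------------------------------
# region index and mapping
# ---------------------------------------------------------------------------


class GeneRegionIndex:
    """Interval index of extended gene regions keyed by chromosome."""

    def __init__(self, regions: list[MirnaGeneRegion]):
        self.regions = {r.gene_id: r for r in regions}
        self._trees: dict[str, IntervalTree] = {}
        for r in regions:
            lo, hi = r.extended_genomic_span
            tree = self._trees.setdefault(r.precursor.chromosome, IntervalTree())
            tree[lo : hi + 1] = r.gene_id

    def overlapping(self, chrom: str, start: int, end: int | None = None
                    ) -> list[MirnaGeneRegion]:
        end = start if end is None else end
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = sorted({iv.data for iv in tree.overlap(start, end + 1)})
        return [self.regions[g] for g in hits]


def map_variant(
    variant: MergedVariant, index: GeneRegionIndex
) -> list[MirnaVariant]:
    """Assign a merged variant to every gene region it overlaps.

    Returns one record per overlapped gene (usually 0 or 1); a variant in
    two overlapping genes yields two records.  For minus-strand genes the
    alleles are reverse-complemented so ref/alt read in precursor sense, and
    the position reported is the 5'-most affected precursor coordinate.
    """
    ref = variant.ref_allele
    span_end = variant.position + len(ref) - 1
    regions = index.overlapping(variant.chromosome, variant.position, span_end)
    if len(regions) > 1:
        logger.info(
            "variant %s:%d overlaps %d genes", variant.chromosome,
            variant.position, len(regions),
        )
    out = []
    for region in regions:
        pre = region.precursor
        if pre.strand == "+":
            pos = genomic_to_precursor(variant.position, pre)
            r, a = ref, variant.alt_allele
        else:
            pos = genomic_to_precursor(span_end, pre)
            r, a = revcomp(ref), revcomp(variant.alt_allele)
        variant_class = "indel" if variant.is_indel else "substitution"
        labels = _labels_for_span(region, pos, pos + len(r) - 1)
        name = hgvs_name(region.length, pos, r, a)
        out.append(
            MirnaVariant(
                merged=variant,
                gene_id=region.gene_id,
                precursor_position=pos,
                hgvs=name,
                subregion_labels=labels,
                variant_class=variant_class,
                ref_allele=r,
                alt_allele=a,
            )
        )
    return out


def _labels_for_span(region: MirnaGeneRegion, start: int, end: int) -> set[str]:
    labels: set[str] = set()
    for p in range(start, end + 1):
        labels |= region.labels_at(p)
    return labels


# ---------------------------------------------------------------------------
# complex-mutation collapsing and weighting
# ---------------------------------------------------------------------------


def classify_variant_type(
    variants: list[MirnaVariant],
) -> list[MirnaVariant]:
    """Collapse same-gene same-sample multiplets into complex mutations.

    Input is the full list of mapped variants; any (patient, gene) group
    holding two or more alterations is replaced by a single record of class
    ``complex`` whose subregion labels are the union of its components and
    whose name joins the component names.
    """
    groups: dict[tuple[str, str], list[MirnaVariant]] = {}
    for v in variants:
        groups.setdefault((v.patient_id, v.gene_id), []).append(v)
    out: list[MirnaVariant] = []
    for (_, _), members in sorted(groups.items()):
        if len(members) == 1:
            out.append(members[0])
            continue
        members = sorted(members, key=lambda v: v.precursor_position)
        first = members[0]
        labels: set[str] = set()
        for m in members:
            labels |= m.subregion_labels
        out.append(
            MirnaVariant(
                merged=first.merged,
                gene_id=first.gene_id,
                precursor_position=first.precursor_position,
                hgvs=";".join(m.hgvs for m in members),
                subregion_labels=labels,
                variant_class="complex",
                component_hgvs=[m.hgvs for m in members],
            )
        )
    out.sort(key=lambda v: (v.gene_id, v.patient_id, v.precursor_position))
    return out


def assign_weight(
    variant: MirnaVariant,
    has_motif_event: bool = False,
    weights: Weights | None = None,
) -> float:
    """Weight of a mutation for the weighted hotspot score.

    Maximum of the applicable factors: seed mutations 2x; guide-strand
    mutations 1.5x; mutations hitting a DROSHA/DICER cleavage window or
    affecting a functional motif 1.5x; all others 1x.
    """
    w = weights or Weights()
    labels = variant.subregion_labels
    candidates = [w.other]
    if "seed" in labels:
        candidates.append(w.seed)
    if "guide" in labels:
        candidates.append(w.guide)
    if "cleavage_site" in labels or has_motif_event:
        candidates.append(w.motif_or_cleavage)
    return max(candidates)


def variants_table(variants: list[MirnaVariant]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": v.gene_id,
            "patient_id": v.patient_id,
            "chrom": v.merged.chromosome,
            "genomic_pos": v.merged.position,
            "precursor_pos": v.precursor_position,
            "hgvs": v.hgvs,
            "labels": ",".join(sorted(v.subregion_labels)),
            "class": v.variant_class,
            "weight": v.weight,
        }
        for v in variants
    ]
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "patient_id", "chrom", "genomic_pos",
                 "precursor_pos", "hgvs", "labels", "class", "weight"],
    )
    return df.sort_values(["gene_id", "patient_id", "precursor_pos"]).reset_index(
        drop=True
    )


def gene_sample_matrix(variants: list[MirnaVariant]) -> pd.DataFrame:
    """Per-gene-per-sample mutation count matrix (genes x samples)."""
    df = variants_table(variants)
    if df.empty:
        return pd.DataFrame()
    return (
        df.groupby(["gene_id", "patient_id"]).size().unstack(fill_value=0).sort_index()
    )
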