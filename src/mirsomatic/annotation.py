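"""miRNA gene-region model.

Builds the extended analysis unit of the pipeline -- the pre-miRNA-coding
sequence plus 25-nt flanks -- from a miRBase-style GFF3 annotation
(``miRNA_primary_transcript`` stem-loops with ``miRNA`` mature records linked
by ``Derives_from``) and a per-arm read-count table.

Coordinate conventions
----------------------
Precursor-relative positions are 1-based and inclusive, read 5'->3' in the
sense of the precursor RNA (so they are strand-aware).  Extended-region
positions cover the flanks as well: positions <= 0 address the 5' flank
(position 0 is 1 nt upstream of the precursor), positions > L address the
3' flank, where L is the precursor length.

By default the precursor is reconstructed from the outer mature-miRNA
coordinates: the stem-loop record is trimmed so that position 1 is the first
nucleotide of the 5' arm and position L the last nucleotide of the 3' arm
(predicting the missing arm from the 2-nt 3'-overhang duplex geometry when
only one arm is annotated).  Under this convention the mature arms and the
apical loop exactly partition [1, L].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

logger = logging.getLogger(__name__)

FLANK_LEN = 25
DOMINANCE_THRESHOLD = 0.90
SEED_OFFSET = (2, 8)  # mature positions forming the seed
OVERHANG = 2  # 3' overhang of the DICER duplex, nt
MIN_ARM_LEN = 10  # shorter predicted arms indicate a degenerate hairpin

Interval = tuple[int, int]

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAATGCAA")


def revcomp(seq: str) -> str:
    """Reverse complement (DNA alphabet; U treated as T)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MatureArm:
    """A mature miRNA arm in precursor-relative coordinates."""

    arm_label: str  # "5p" | "3p"
    start: int
    end: int
    read_count: int = 0
    is_annotated: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.start < self.end):
            raise ValueError(f"invalid arm interval [{self.start}, {self.end}]")
        if self.arm_label not in ("5p", "3p"):
            raise ValueError(f"arm_label must be 5p or 3p, got {self.arm_label!r}")
        if self.read_count < 0:
            raise ValueError("read_count must be non-negative")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class PrecursorAnnotation:
    """A stem-loop record with its mature arms.

    ``sequence``, when present, is the extended-region sequence (flank5 +
    precursor + flank3) in precursor sense, or the bare precursor sequence;
    which one is inferred from its length.
    """

    gene_id: str
    chromosome: str
    strand: str
    genomic_start: int
    genomic_end: int
    arms: list[MatureArm]
    confidence: set[str] = field(default_factory=set)
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.genomic_start > self.genomic_end:
            raise ValueError("genomic_start > genomic_end")
        if not self.arms:
            raise ValueError("precursor needs at least one mature arm")
        for arm in self.arms:
            if arm.end > self.length:
                raise ValueError(
                    f"{self.gene_id}: arm [{arm.start},{arm.end}] outside precursor "
                    f"of length {self.length}"
                )

    @property
    def length(self) -> int:
        return self.genomic_end - self.genomic_start + 1

    def arm(self, label: str) -> MatureArm | None:
        for a in self.arms:
            if a.arm_label == label:
                return a
        return None

    # -- sequence access -------------------------------------------------

    def extended_sequence(self, flank_len: int = FLANK_LEN) -> str | None:
        """Extended-region sequence, or None when unavailable.

        Returns None as well when only a bare precursor sequence is stored
        but flanks are requested.
        """
        if self.sequence is None:
            return None
        if len(self.sequence) == self.length + 2 * flank_len:
            return self.sequence
        return None

    def precursor_sequence(self, flank_len: int = FLANK_LEN) -> str | None:
        if self.sequence is None:
            return None
        if len(self.sequence) == self.length:
            return self.sequence
        if len(self.sequence) == self.length + 2 * flank_len:
            return self.sequence[flank_len : flank_len + self.length]
        return None


@dataclass
class MirnaGeneRegion:
    """Extended miRNA gene region partitioned into functional subregions.

    Subregion intervals are in extended coordinates: ``flank5`` is
    ``[1 - flank_len, 0]``, ``flank3`` is ``[L + 1, L + flank_len]`` and the
    body labels (guide/passenger/loop/seed) lie within ``[1, L]``.  Guide,
    passenger and loop partition ``[1, L]``; the seed (mature positions 2-8
    of each guide arm) is a subset of guide.
    """

    precursor: PrecursorAnnotation
    arm_class: str  # 5p_dominant | 3p_dominant | balanced
    subregions: dict[str, list[Interval]]
    cleavage_windows: list[tuple[str, Interval]]
    biogenesis_motif_sites: list[tuple[str, Interval]]
    flank_len: int = FLANK_LEN

    @property
    def gene_id(self) -> str:
        return self.precursor.gene_id

    @property
    def length(self) -> int:
        return self.precursor.length

    @property
    def extended_genomic_span(self) -> Interval:
        p = self.precursor
        return (p.genomic_start - self.flank_len, p.genomic_end + self.flank_len)

    def labels_at(self, position: int) -> set[str]:
        """Subregion labels covering an extended-coordinate position."""
        hit = set()
        for label, ivs in self.subregions.items():
            if any(s <= position <= e for s, e in ivs):
                hit.add(label)
        for _, (s, e) in self.cleavage_windows:
            if s <= position <= e:
                hit.add("cleavage_site")
        return hit

    def subregion_length(self, label: str) -> int:
        return sum(e - s + 1 for s, e in self.subregions.get(label, []))


# ---------------------------------------------------------------------------
# coordinate helpers
# ---------------------------------------------------------------------------


def genomic_to_precursor(pos: int, precursor: PrecursorAnnotation) -> int:
    """Genomic position -> precursor-relative (extended) coordinate."""
    if precursor.strand == "+":
        rel = pos - precursor.genomic_start + 1
    else:
        rel = precursor.genomic_end - pos + 1
    return rel


def precursor_to_genomic(rel: int, precursor: PrecursorAnnotation) -> int:
    if precursor.strand == "+":
        return precursor.genomic_start + rel - 1
    return precursor.genomic_end - rel + 1


def ext_to_seq_index(pos: int, flank_len: int = FLANK_LEN) -> int:
    """Extended-coordinate position -> 0-based index in the extended sequence."""
    return pos + flank_len - 1


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def _read_mirbase_gff3(path: str) -> tuple[list[dict], list[dict]]:
    """Read stem-loop and mature features from a miRBase-dialect GFF3."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )

    def as_dict(f) -> dict:
        rec = {
            "chrom": f.seqid,
            "type": f.featuretype,
            "start": f.start,
            "end": f.end,
            "strand": f.strand,
        }
        for key, values in f.attributes.items():
            if values:
                rec[key] = values[0]
        return rec

    stemloops = [as_dict(f) for f in db.features_of_type("miRNA_primary_transcript")]
    matures = [as_dict(f) for f in db.features_of_type("miRNA")]
    return stemloops, matures


def load_readcounts(path: str) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = list(df.columns)
    return dict(zip(df[cols[0]].astype(str), df[cols[1]].astype(int)))


def load_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def _arm_label_for(rel_start: int, rel_end: int, L: int, name: str | None) -> str:
    if name:
        low = name.lower()
        if low.endswith("-5p") or "-5p" in low:
            return "5p"
        if low.endswith("-3p") or "-3p" in low:
            return "3p"
    mid = (rel_start + rel_end) / 2
    return "5p" if mid <= (L + 1) / 2 else "3p"


def load_annotation(
    gff3_path: str,
    readcount_table_path: str | None = None,
    fasta_path: str | None = None,
    trim_to_mature: bool = True,
    flank_len: int = FLANK_LEN,
) -> list[PrecursorAnnotation]:
    """Load precursor annotations from a miRBase-style GFF3.

    Mature records are converted to precursor-relative coordinates respecting
    strand; read counts are joined by mature ID (missing counts default to 0).
    With ``trim_to_mature`` (default) the precursor boundaries are moved to
    the outer mature coordinates, matching the convention in which mature
    arms flank the apical loop with no basal residue.

    Mature records falling outside their stem-loop are rejected with a
    warning; stem-loops left without any mature record are skipped.
    """
    stemloops, matures = _read_mirbase_gff3(gff3_path)
    counts = load_readcounts(readcount_table_path) if readcount_table_path else {}
    seqs = load_fasta(fasta_path) if fasta_path else {}

    by_parent: dict[str, list[dict]] = {}
    for m in matures:
        parent = m.get("Derives_from")
        if parent:
            by_parent.setdefault(parent, []).append(m)

    out: list[PrecursorAnnotation] = []
    for sl in stemloops:
        sl_id = sl.get("ID") or sl.get("Name")
        children = by_parent.get(sl_id, [])
        kept = []
        for m in children:
            if m["start"] < sl["start"] or m["end"] > sl["end"] or m["strand"] != sl["strand"]:
                logger.warning(
                    "mature %s outside stem-loop %s; record rejected",
                    m.get("ID") or m.get("Name"), sl_id,
                )
                continue
            kept.append(m)
        if not kept:
            logger.warning("stem-loop %s has no usable mature record; skipped", sl_id)
            continue

        sl_len = sl["end"] - sl["start"] + 1
        # mature coordinates relative to the stem-loop, precursor sense
        arms = []
        for m in kept:
            if sl["strand"] == "+":
                rs, re_ = m["start"] - sl["start"] + 1, m["end"] - sl["start"] + 1
            else:
                rs, re_ = sl["end"] - m["end"] + 1, sl["end"] - m["start"] + 1
            label = _arm_label_for(rs, re_, sl_len, m.get("Name") or m.get("ID"))
            mid = m.get("ID") or m.get("Name") or ""
            arms.append(
                MatureArm(
                    arm_label=label,
                    start=rs,
                    end=re_,
                    read_count=int(counts.get(mid, 0)),
                    is_annotated=True,
                )
            )
        arms.sort(key=lambda a: a.start)
        if len({a.arm_label for a in arms}) != len(arms):
            logger.warning("stem-loop %s: duplicate arm labels; keeping first of each", sl_id)
            seen: set[str] = set()
            arms = [a for a in arms if not (a.arm_label in seen or seen.add(a.arm_label))]

        if len(arms) == 1 and trim_to_mature:
            # reconstruct the missing precursor end from the overhang rule
            try:
                arms.append(predict_counterpart_arm(sl_len, arms[0]))
                arms.sort(key=lambda a: a.start)
            except ValueError as exc:
                logger.warning("stem-loop %s: %s; kept untrimmed", sl_id, exc)

        if trim_to_mature and len(arms) == 2:
            rel_lo = min(a.start for a in arms)
            rel_hi = max(a.end for a in arms)
        else:
            rel_lo, rel_hi = 1, sl_len
        trim_front, trim_back = rel_lo - 1, sl_len - rel_hi
        arms = [replace(a, start=a.start - trim_front, end=a.end - trim_front)
                for a in arms]
        if sl["strand"] == "+":
            g_start, g_end = sl["start"] + trim_front, sl["end"] - trim_back
        else:
            g_start, g_end = sl["start"] + trim_back, sl["end"] - trim_front

        seq = seqs.get(sl_id) or seqs.get(sl.get("Name", ""))
        if seq is not None:
            # stored sequence is precursor sense over the *untrimmed* record,
            # possibly with flank_len of context on each side
            if len(seq) == sl_len:
                seq = seq[trim_front : sl_len - trim_back]
            elif len(seq) == sl_len + 2 * flank_len:
                # keep flank_len context around the trimmed precursor
                seq = seq[trim_front : len(seq) - trim_back]
            else:
                logger.warning("sequence length mismatch for %s; sequence dropped", sl_id)
                seq = None

        confidence = set()
        conf_attr = sl.get("confidence", "")
        for flag in conf_attr.split(","):
            flag = flag.strip()
            if flag:
                confidence.add(flag)

        out.append(
            PrecursorAnnotation(
                gene_id=sl_id,
                chromosome=sl["chrom"],
                strand=sl["strand"],
                genomic_start=g_start,
                genomic_end=g_end,
                arms=arms,
                confidence=confidence,
                sequence=seq,
            )
        )
    return out


# ---------------------------------------------------------------------------
# arm prediction and classification
# ---------------------------------------------------------------------------


def predict_counterpart_arm(precursor_length: int, known_arm: MatureArm) -> MatureArm:
    """Predict the missing arm from 2-nt 3'-overhang duplex geometry.

    On a perfect hairpin with base pairing i + j = L + 1, a duplex whose
    strands each carry a 2-nt 3' overhang maps a 5p arm [a, b] onto the 3p
    arm [L + 3 - b, L + 3 - a] (and symmetrically back); the predicted
    interval is clamped to [1, L].
    """
    L = precursor_length
    a, b = known_arm.start, known_arm.end
    start, end = L + 1 + OVERHANG - b, L + 1 + OVERHANG - a
    start, end = max(1, start), min(L, end)
    if end - start + 1 < MIN_ARM_LEN:
        raise ValueError(
            f"predicted counterpart arm [{start},{end}] shorter than {MIN_ARM_LEN} nt "
            "after clamping: degenerate hairpin"
        )
    label = "3p" if known_arm.arm_label == "5p" else "5p"
    return MatureArm(arm_label=label, start=start, end=end, read_count=0, is_annotated=False)


def classify_arm_dominance(reads_5p: int, reads_3p: int) -> str:
    """Classify a precursor by the fraction of mature reads from the 5' arm.

    >=90% of reads from the 5' arm -> 5p_dominant; <=10% -> 3p_dominant;
    otherwise balanced.  Precursors with no reads at all are treated as
    balanced (with a warning) rather than dropped.
    """
    if reads_5p < 0 or reads_3p < 0:
        raise ValueError("read counts must be non-negative")
    total = reads_5p + reads_3p
    if total == 0:
        logger.warning("no arm reads; classifying as balanced")
        return "balanced"
    if reads_5p / total >= DOMINANCE_THRESHOLD:
        return "5p_dominant"
    if reads_3p / total >= DOMINANCE_THRESHOLD:
        return "3p_dominant"
    return "balanced"


# ---------------------------------------------------------------------------
# region construction
# ---------------------------------------------------------------------------


def _seed_interval(arm: MatureArm) -> Interval:
    lo, hi = SEED_OFFSET
    return (arm.start + lo - 1, arm.start + hi - 1)


def build_gene_region(
    precursor: PrecursorAnnotation,
    flank_len: int = FLANK_LEN,
    cleavage_halfwidth: int = 2,
) -> MirnaGeneRegion:
    """Partition the extended gene region into functional subregions.

    Guide strand = mature arm(s) of the dominant arm; for balanced
    precursors both arms are guide and the passenger set is empty.  The
    apical loop is the interval strictly between the two arms.  Any basal
    residue between a precursor end and its arm (absent when the precursor
    was reconstructed from mature coordinates) is absorbed into the adjacent
    arm's subregion so that guide/passenger/loop always partition [1, L].

    Cleavage windows are centered on the DROSHA scissile positions (1 and L)
    and the DICER duplex/loop boundaries, +/- ``cleavage_halfwidth`` nt.
    """
    L = precursor.length
    arm5 = precursor.arm("5p")
    arm3 = precursor.arm("3p")
    if arm5 is None and arm3 is None:
        raise ValueError(f"{precursor.gene_id}: no arms")
    if arm5 is None:
        arm5 = predict_counterpart_arm(L, arm3)
    if arm3 is None:
        arm3 = predict_counterpart_arm(L, arm5)
    if arm5.end >= arm3.start:
        raise ValueError(
            f"{precursor.gene_id}: overlapping arm intervals "
            f"[{arm5.start},{arm5.end}] / [{arm3.start},{arm3.end}]"
        )

    arm_class = classify_arm_dominance(arm5.read_count, arm3.read_count)

    # arm subregions extended outward to the precursor ends
    region5: Interval = (1, arm5.end)
    region3: Interval = (arm3.start, L)
    loop: Interval = (arm5.end + 1, arm3.start - 1)

    if arm_class == "5p_dominant":
        guide, passenger = [region5], [region3]
        seeds = [_seed_interval(arm5)]
    elif arm_class == "3p_dominant":
        guide, passenger = [region3], [region5]
        seeds = [_seed_interval(arm3)]
    else:  # balanced: both arms act as guide
        guide, passenger = [region5, region3], []
        seeds = [_seed_interval(arm5), _seed_interval(arm3)]

    subregions: dict[str, list[Interval]] = {
        "flank5": [(1 - flank_len, 0)],
        "flank3": [(L + 1, L + flank_len)],
        "guide": guide,
        "passenger": passenger,
        "loop": [loop] if loop[0] <= loop[1] else [],
        "seed": seeds,
    }

    w = cleavage_halfwidth
    cleavage_windows = [
        ("drosha5", (1 - w, 1 + w)),
        ("drosha3", (L - w, L + w)),
        ("dicer5", (arm5.end - w, arm5.end + w)),
        ("dicer3", (arm3.start - w, arm3.start + w)),
    ]

    region = MirnaGeneRegion(
        precursor=precursor,
        arm_class=arm_class,
        subregions=subregions,
        cleavage_windows=cleavage_windows,
        biogenesis_motif_sites=[],
        flank_len=flank_len,
    )
    region.biogenesis_motif_sites = _find_biogenesis_sites(region)
    return region


#: biogenesis-enhancer motifs and the extended-coordinate windows scanned,
#: expressed relative to precursor ends: basal UG within 17 nt upstream of
#: position 1, CNNC within the 25-nt 3' flank, UGUG in the apical loop.
BASAL_UG_WINDOW = 17


def _find_biogenesis_sites(region: MirnaGeneRegion) -> list[tuple[str, Interval]]:
    from .motifs import iupac_scan

    seq = region.precursor.extended_sequence(region.flank_len)
    if seq is None:
        return []
    L = region.length
    fl = region.flank_len
    windows = {
        "UG": (1 - BASAL_UG_WINDOW, 0),
        "CNNC": (L + 1, L + fl),
    }
    loop_ivs = region.subregions.get("loop", [])
    sites: list[tuple[str, Interval]] = []
    for motif, (ws, we) in windows.items():
        lo, hi = ext_to_seq_index(ws, fl), ext_to_seq_index(we, fl) + 1
        lo = max(lo, 0)
        for off in iupac_scan(seq[lo:hi], motif):
            start = ws + (lo - ext_to_seq_index(ws, fl)) + off
            sites.append((motif, (start, start + len(motif) - 1)))
    for ls, le in loop_ivs:
        lo, hi = ext_to_seq_index(ls, fl), ext_to_seq_index(le, fl) + 1
        for off in iupac_scan(seq[lo:hi], "UGUG"):
            start = ls + off
            sites.append(("UGUG", (start, start + 3)))
    return sites


# ---------------------------------------------------------------------------
# length accounting
# ---------------------------------------------------------------------------

DISJOINT_LABELS = ("flank5", "flank3", "loop", "passenger", "guide")


def region_length_accounting(
    regions: list[MirnaGeneRegion], n_samples: int
) -> dict[str, int]:
    """Cohort-aggregate subregion lengths in bp.

    For each label, total length = sum of interval lengths over all genes x
    number of samples (the denominator of mut/Mbp densities).  ``total`` is
    the sum over the five disjoint labels; the seed is reported too but not
    added to the total, being a subset of guide.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    out = {label: 0 for label in DISJOINT_LABELS + ("seed",)}
    for region in regions:
        for label in out:
            out[label] += region.subregion_length(label)
    out = {label: bp * n_samples for label, bp in out.items()}
    out["total"] = sum(out[label] for label in DISJOINT_LABELS)
    return out


def regions_table(regions: list[MirnaGeneRegion]) -> pd.DataFrame:
    """Gene-region summary table (one row per gene)."""
    rows = []
    for r in regions:
        row = {
            "gene_id": r.gene_id,
            "chrom": r.precursor.chromosome,
            "strand": r.precursor.strand,
            "length": r.length,
            "arm_class": r.arm_class,
        }
        for label in DISJOINT_LABELS + ("seed",):
            row[label] = ";".join(f"{s}..{e}" for s, e in r.subregions.get(label, []))
        rows.append(row)
    return pd.DataFrame(rows).sort_values("gene_id").reset_index(drop=True)
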