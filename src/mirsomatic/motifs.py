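"""RNA-binding-protein motif scanning and mutation impact calls.

Scans precursor sequences against a catalogue of IUPAC sequence motifs bound
by proteins that regulate miRNA biogenesis, and reports motifs lost or
gained at a variant position when comparing wild-type and mutant sequences.
Motifs annotated as loop-restricted are searched only within the apical-loop
subregion; all others over the whole pre-miRNA.  Searches run 5'->3' and
overlapping matches are reported individually.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass
from typing import TYPE_CHECKING

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .annotation import MirnaGeneRegion
    from .mapping import MirnaVariant

IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U", "T": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class MotifSpec:
    protein: str
    pattern: str  # IUPAC, RNA alphabet
    loop_restricted: bool

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty motif pattern")
        bad = set(self.pattern.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC characters in pattern: {sorted(bad)}")


@dataclass(frozen=True)
class MotifEvent:
    gene_id: str
    protein: str
    pattern: str
    match_start: int  # extended precursor coordinate of the match
    direction: str  # "lost" | "gained"
    causal_variant: str  # HGVS name


def load_catalogue(path=None) -> list[MotifSpec]:
    """Load the motif catalogue TSV (protein, pattern, loop_restricted)."""
    if path is None:
        path = importlib.resources.files("mirsomatic.data") / "motif_catalogue.tsv"
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        MotifSpec(r.protein, to_rna(str(r.pattern)), bool(r.loop_restricted))
        for r in df.itertuples()
    ]


def _pattern_regex(pattern: str) -> re.Pattern:
    # lookahead form so overlapping matches are all reported
    body = "".join(
        c if len(IUPAC[c]) == 1 else "[" + IUPAC[c] + "]" for c in to_rna(pattern)
    )
    return re.compile(f"(?=({body}))")


def iupac_scan(sequence: str, pattern: str) -> list[int]:
    """All (possibly overlapping) match offsets of an IUPAC pattern, 0-based.

    Case- and T/U-insensitive in both arguments.
    """
    return [m.start() for m in _pattern_regex(pattern).finditer(to_rna(sequence))]


def scan_motifs(
    sequence: str, spec: MotifSpec, search_interval: tuple[int, int] | None = None
) -> list[int]:
    """Match positions (1-based within ``sequence``) fully inside the interval.

    ``search_interval`` is 1-based inclusive over ``sequence``; None scans the
    whole sequence.  The loop interval should be supplied for loop-restricted
    specs.
    """
    if search_interval is None:
        lo, hi = 1, len(sequence)
    else:
        lo, hi = search_interval
    lo = max(lo, 1)
    hi = min(hi, len(sequence))
    if hi - lo + 1 < len(spec.pattern):
        return []
    window = sequence[lo - 1 : hi]
    return [lo + off for off in iupac_scan(window, spec.pattern)]


def _matches_in_precursor(
    seq: str, spec: MotifSpec, loop: tuple[int, int] | None
) -> set[int]:
    """Match start positions (precursor 1-based) for a spec on a precursor."""
    if spec.loop_restricted:
        if loop is None:
            return set()
        return set(scan_motifs(seq, spec, loop))
    return set(scan_motifs(seq, spec, (1, len(seq))))


def motif_events(
    wt_sequence: str,
    variant: "MirnaVariant",
    region: "MirnaGeneRegion",
    catalogue: list[MotifSpec] | None = None,
) -> list[MotifEvent]:
    """Motifs lost or gained at a substitution's locus.

    ``wt_sequence`` is the bare precursor sequence (positions 1..L).  Only
    substitutions inside the precursor are analyzed; flank variants return no
    events.  A motif counts as lost when a wild-type match overlapping the
    variant position has no mutant match at the same locus, and vice versa
    for gained; each (protein, locus) yields one event, so a single variant
    may emit several.
    """
    if catalogue is None:
        catalogue = load_catalogue()
    pos = variant.precursor_position
    L = region.length
    if variant.variant_class != "substitution" or not 1 <= pos <= L:
        return []
    seq = to_rna(wt_sequence)
    alt = to_rna(variant.alt_allele)  # precursor sense
    mut = seq[: pos - 1] + alt + seq[pos:]

    loop_ivs = region.subregions.get("loop", [])
    loop = loop_ivs[0] if loop_ivs else None

    events = []
    for spec in catalogue:
        wt_hits = _matches_in_precursor(seq, spec, loop)
        mut_hits = _matches_in_precursor(mut, spec, loop)
        span = len(spec.pattern) - 1
        for start in sorted(wt_hits - mut_hits):
            if start <= pos <= start + span:
                events.append(
                    MotifEvent(region.gene_id, spec.protein, spec.pattern,
                               start, "lost", variant.hgvs)
                )
        for start in sorted(mut_hits - wt_hits):
            if start <= pos <= start + span:
                events.append(
                    MotifEvent(region.gene_id, spec.protein, spec.pattern,
                               start, "gained", variant.hgvs)
                )
    return events


#: biogenesis-enhancer motifs with their extended-coordinate search windows
#: (basal UG upstream of position 1, UGUG in the loop, CNNC in the 3' flank)
BIOGENESIS_MOTIFS = ("UG", "UGUG", "CNNC")


def biogenesis_motif_events(
    extended_sequence: str,
    variant: "MirnaVariant",
    region: "MirnaGeneRegion",
) -> list[MotifEvent]:
    """Lost/gained events for the basal UG, loop UGUG and flanking CNNC motifs.

    Unlike protein-motif scanning, the variant may sit anywhere in the
    extended region (the UG and CNNC windows live in the flanks).
    """
    from .annotation import BASAL_UG_WINDOW, ext_to_seq_index

    if variant.variant_class != "substitution":
        return []
    fl = region.flank_len
    L = region.length
    pos = variant.precursor_position
    idx = ext_to_seq_index(pos, fl)
    seq = to_rna(extended_sequence)
    if not 0 <= idx < len(seq):
        return []
    alt = to_rna(variant.alt_allele)  # precursor sense
    mut = seq[:idx] + alt + seq[idx + 1 :]

    loop_ivs = region.subregions.get("loop", [])
    windows = [("UG", (1 - BASAL_UG_WINDOW, 0)), ("CNNC", (L + 1, L + fl))]
    if loop_ivs:
        windows.append(("UGUG", loop_ivs[0]))

    events = []
    for motif, (ws, we) in windows:
        lo = max(ext_to_seq_index(ws, fl), 0)
        hi = min(ext_to_seq_index(we, fl) + 1, len(seq))
        span = len(motif) - 1
        wt_hits = {lo + off for off in iupac_scan(seq[lo:hi], motif)}
        mut_hits = {lo + off for off in iupac_scan(mut[lo:hi], motif)}
        for start_idx in sorted(wt_hits ^ mut_hits):
            if not start_idx <= idx <= start_idx + span:
                continue
            direction = "lost" if start_idx in wt_hits else "gained"
            start_ext = start_idx - fl + 1
            events.append(
                MotifEvent(region.gene_id, motif, motif, start_ext, direction,
                           variant.hgvs)
            )
    return events


def events_table(events: list[MotifEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": e.gene_id,
                "protein": e.protein,
                "pattern": e.pattern,
                "match_start": e.match_start,
                "direction": e.direction,
                "causal_variant": e.causal_variant,
            }
            for e in events
        ],
        columns=["gene_id", "protein", "pattern", "match_start", "direction",
                 "causal_variant"],
    )
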