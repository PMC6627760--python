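"""End-to-end orchestration: annotation -> filtering -> mapping -> statistics.

Chains the pipeline stages on file inputs, keeps per-stage record accounting
(calls read, PASS, filter failures by reason, mapped, complex-merged), and
produces the standard outputs: merged-variant and per-variant tables, motif
event tables, per-cancer subregion density tables, the hotspot scan, and a
run-summary dictionary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation as ann
from . import mapping as mp
from . import motifs as mo
from . import stats as st
from .variant_io import FilterThresholds, MergedVariant, process_manifest

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Tunable constants of a pipeline run (defaults = standard analysis)."""

    flank_len: int = ann.FLANK_LEN
    cleavage_halfwidth: int = 2
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    weights: mp.Weights = field(default_factory=mp.Weights)
    dominance_threshold: float = ann.DOMINANCE_THRESHOLD
    bh_family: str = "all_genes"  # family size policy for BH correction
    seed: int = 0

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "thresholds" in raw:
            raw["thresholds"] = FilterThresholds(**raw["thresholds"])
        if "weights" in raw:
            raw["weights"] = mp.Weights(**raw["weights"])
        return cls(**raw)


@dataclass
class PipelineResult:
    regions: list[ann.MirnaGeneRegion]
    merged: list[MergedVariant]
    variants: list[mp.MirnaVariant]  # after complex collapsing, weighted
    motif_events: list[mo.MotifEvent]
    density_tables: dict[str, pd.DataFrame]  # per cancer label
    hotspots: dict[str, pd.DataFrame]
    summary: dict
    accounting: dict[str, int]


def build_regions(
    gff3: str,
    readcounts: str | None = None,
    fasta: str | None = None,
    config: RunConfig | None = None,
) -> list[ann.MirnaGeneRegion]:
    cfg = config or RunConfig()
    precursors = ann.load_annotation(
        gff3, readcounts, fasta, flank_len=cfg.flank_len
    )
    return [
        ann.build_gene_region(
            p, flank_len=cfg.flank_len, cleavage_halfwidth=cfg.cleavage_halfwidth
        )
        for p in precursors
    ]


def filter_and_map(
    regions: list[ann.MirnaGeneRegion],
    manifest: str | pd.DataFrame,
    config: RunConfig | None = None,
) -> tuple[list[MergedVariant], list[mp.MirnaVariant], dict[str, int]]:
    """Merge/filter caller files and map passing variants onto gene regions.

    Returns (all merged variants with verdicts, mapped variants before
    complex collapsing, accounting counters).
    """
    cfg = config or RunConfig()
    per_patient = process_manifest(manifest, thresholds=cfg.thresholds)
    merged = [v for calls in per_patient.values() for v in calls]
    passed = [v for v in merged if v.pass_filters]

    index = mp.GeneRegionIndex(regions)
    mapped: list[mp.MirnaVariant] = []
    for v in passed:
        mapped.extend(mp.map_variant(v, index))

    accounting = {
        "merged_variants": len(merged),
        "pass_filters": len(passed),
        "failed_filters": len(merged) - len(passed),
        "mapped_variants": len(mapped),
    }
    reasons: dict[str, int] = {}
    for v in merged:
        for r in v.fail_reasons:
            reasons[f"failed_{r}"] = reasons.get(f"failed_{r}", 0) + 1
    accounting.update(dict(sorted(reasons.items())))
    for key, value in accounting.items():
        logger.info("accounting: %s = %d", key, value)
    return merged, mapped, accounting


def annotate_motifs(
    mapped: list[mp.MirnaVariant],
    regions: list[ann.MirnaGeneRegion],
    catalogue: list[mo.MotifSpec] | None = None,
) -> tuple[list[mo.MotifEvent], set[tuple[str, str, str]]]:
    """Motif gain/loss events for mapped substitutions.

    Returns the event list and the set of (patient, gene, hgvs) records that
    affect at least one motif (protein motif or biogenesis-enhancer motif),
    used by the weighting scheme.
    """
    if catalogue is None:
        catalogue = mo.load_catalogue()
    by_id = {r.gene_id: r for r in regions}
    events: list[mo.MotifEvent] = []
    flagged: set[tuple[str, str, str]] = set()
    for v in mapped:
        if v.variant_class != "substitution":
            continue
        region = by_id[v.gene_id]
        pre_seq = region.precursor.precursor_sequence(region.flank_len)
        ext_seq = region.precursor.extended_sequence(region.flank_len)
        evs: list[mo.MotifEvent] = []
        if pre_seq:
            evs.extend(mo.motif_events(pre_seq, v, region, catalogue))
        if ext_seq:
            evs.extend(mo.biogenesis_motif_events(ext_seq, v, region))
        if evs:
            flagged.add((v.patient_id, v.gene_id, v.hgvs))
        events.extend(evs)
    return events, flagged


def collapse_and_weigh(
    mapped: list[mp.MirnaVariant],
    flagged: set[tuple[str, str, str]],
    config: RunConfig | None = None,
) -> list[mp.MirnaVariant]:
    cfg = config or RunConfig()
    collapsed = mp.classify_variant_type(mapped)
    for v in collapsed:
        names = v.component_hgvs or [v.hgvs]
        has_motif = any((v.patient_id, v.gene_id, n) in flagged for n in names)
        v.weight = mp.assign_weight(v, has_motif, cfg.weights)
    return collapsed


def cohort_statistics(
    regions: list[ann.MirnaGeneRegion],
    variants: list[mp.MirnaVariant],
    cancer_by_patient: dict[str, str],
    n_samples_by_cancer: dict[str, int],
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame], dict]:
    """Per-cancer density tables, hotspot scans and a run summary."""
    density_tables: dict[str, pd.DataFrame] = {}
    hotspot_tables: dict[str, pd.DataFrame] = {}
    gene_ext_lengths = {
        r.gene_id: r.length + 2 * r.flank_len for r in regions
    }

    summary: dict = {"cancers": {}}
    for cancer in sorted(n_samples_by_cancer):
        n_samples = n_samples_by_cancer[cancer]
        subset = [
            v for v in variants
            if cancer_by_patient.get(v.patient_id) == cancer
        ]
        lengths = ann.region_length_accounting(regions, n_samples)
        counts = st.subregion_substitution_counts(subset)
        density_tables[cancer] = st.subregion_density_table(counts, lengths)

        gene_counts, gene_weighted = st.per_gene_burden(subset)
        hotspot_tables[cancer] = st.hotspot_scan(
            gene_counts, gene_ext_lengths, weighted_counts=gene_weighted
        )

        by_class = {"substitution": 0, "indel": 0, "complex": 0}
        for v in subset:
            by_class[v.variant_class] = by_class.get(v.variant_class, 0) + 1
        mutated_samples = {v.patient_id for v in subset}
        chrom_counts: dict[str, int] = {}
        for v in subset:
            c = v.merged.chromosome
            chrom_counts[c] = chrom_counts.get(c, 0) + 1
        summary["cancers"][cancer] = {
            "n_samples": n_samples,
            "n_variants": len(subset),
            "n_mutated_genes": len({v.gene_id for v in subset}),
            "variant_classes": by_class,
            "frac_samples_mutated": len(mutated_samples) / n_samples
            if n_samples else 0.0,
            "per_chromosome_variants": dict(sorted(chrom_counts.items())),
        }

    genes_per_chrom: dict[str, int] = {}
    for r in regions:
        c = r.precursor.chromosome
        genes_per_chrom[c] = genes_per_chrom.get(c, 0) + 1
    summary["n_genes"] = len(regions)
    summary["genes_per_chromosome"] = dict(sorted(genes_per_chrom.items()))
    return density_tables, hotspot_tables, summary


def run_all(
    gff3: str,
    readcounts: str | None,
    fasta: str | None,
    manifest: str,
    metadata: str | None = None,
    outdir: str | None = None,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Full pipeline over file inputs; writes tables under ``outdir``."""
    cfg = config or RunConfig()
    regions = build_regions(gff3, readcounts, fasta, cfg)
    merged, mapped, accounting = filter_and_map(regions, manifest, cfg)
    events, flagged = annotate_motifs(mapped, regions)
    variants = collapse_and_weigh(mapped, flagged, cfg)
    accounting["complex_merged"] = sum(
        1 for v in variants if v.variant_class == "complex"
    )
    accounting["final_variants"] = len(variants)

    if metadata is not None:
        meta = pd.read_csv(metadata, sep="\t")
        cancer_by_patient = dict(
            zip(meta["patient_id"].astype(str), meta["cancer_type"].astype(str))
        )
        n_by_cancer = meta.groupby("cancer_type")["patient_id"].nunique().to_dict()
    else:
        patients = sorted({v.patient_id for v in merged})
        cancer_by_patient = {p: "ALL" for p in patients}
        n_by_cancer = {"ALL": len(patients)}

    density, hotspots, summary = cohort_statistics(
        regions, variants, cancer_by_patient, n_by_cancer
    )
    summary["accounting"] = accounting

    if outdir is not None:
        write_outputs(outdir, regions, merged, variants, events, density,
                      hotspots, summary)
    return PipelineResult(
        regions=regions,
        merged=merged,
        variants=variants,
        motif_events=events,
        density_tables=density,
        hotspots=hotspots,
        summary=summary,
        accounting=accounting,
    )


def write_outputs(outdir, regions, merged, variants, events, density,
                  hotspots, summary) -> None:
    from .variant_io import merged_variants_table

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ann.regions_table(regions).to_csv(out / "regions.tsv", sep="\t", index=False)
    merged_variants_table(
        sorted(merged, key=lambda v: v.key)
    ).to_csv(out / "merged_variants.tsv", sep="\t", index=False)
    mp.variants_table(variants).to_csv(out / "variants.tsv", sep="\t", index=False)
    mo.events_table(events).sort_values(
        ["gene_id", "match_start", "protein"]
    ).to_csv(out / "motif_events.tsv", sep="\t", index=False)
    for cancer, table in density.items():
        table.to_csv(out / f"density_{cancer}.tsv", sep="\t", index=False)
    for cancer, table in hotspots.items():
        table.to_csv(out / f"hotspots_{cancer}.tsv", sep="\t", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)


def comutation_matrix(
    variants: list[mp.MirnaVariant], metadata: pd.DataFrame
) -> pd.DataFrame:
    """Samples x genes mutation matrix with clinical annotation columns.

    One row per sample carrying at least one variant; clinical columns
    (cancer type, stage, gender, smoking) precede the per-gene 0/1 flags.
    """
    meta = metadata.set_index("patient_id")
    genes = sorted({v.gene_id for v in variants})
    flags: dict[str, dict[str, int]] = {}
    for v in variants:
        flags.setdefault(v.patient_id, {g: 0 for g in genes})[v.gene_id] = 1
    rows = []
    for patient in sorted(flags):
        row = {"patient_id": patient}
        if patient in meta.index:
            for col in ("cancer_type", "stage", "gender", "smoking_pack_years"):
                if col in meta.columns:
                    row[col] = meta.loc[patient, col]
        row.update(flags[patient])
        rows.append(row)
    return pd.DataFrame(rows)
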