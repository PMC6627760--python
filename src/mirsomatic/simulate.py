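"""Synthetic miRNA-gene cohorts with known ground truth.

Generates every input the pipeline consumes -- miRBase-style GFF3 annotation,
hairpin FASTA, arm read counts, four somatic caller VCFs per patient, sample
metadata and miRNA expression -- together with a truth table tracing every
emitted record, so each pipeline stage can be validated without external
data.

The generative model: hairpin genes with 20-24-nt mature arms and a
10-25-nt apical loop are placed on multiple chromosomes and both strands;
arm read profiles realize a configured 5p-dominant/3p-dominant/balanced
mixture.  Somatic substitutions arrive per gene as a Poisson process with
rate = background rate x gene multiplier x extended-region length, uniform
in position; configured hotspot genes carry rate multipliers and specific
event categories (seed, motif-destroying, motif-creating, cleavage-site
variants) can be planted.  Germline contaminants are emitted with matched
tumor/normal allele frequencies so the downstream frequency-ratio filter
must remove them; fractions of background calls can be made to violate each
quality criterion.  Callers detect each true variant independently with
per-caller sensitivity and write caller-dialect VCFs.

Identical config and seed give byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotation import (
    FLANK_LEN,
    MatureArm,
    MirnaGeneRegion,
    PrecursorAnnotation,
    build_gene_region,
    ext_to_seq_index,
    precursor_to_genomic,
)
from .motifs import IUPAC, MotifSpec, load_catalogue, to_rna
from .variant_io import CALLERS

BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

DEFAULT_CHROMS = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX",)


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the cohort the pipeline is designed around: 1642 miRNA
    genes, 569 + 497 tumor/normal pairs in two cancer types, a background of
    ~5 x 10^-6 somatic substitutions per bp per sample over the extended
    gene regions (~545 mutations per cancer at full scale) and ~300x
    sequencing depth at the called sites.
    """

    seed: int = 0
    n_genes: int = 1642
    chromosomes: tuple[str, ...] = DEFAULT_CHROMS
    arm_len_range: tuple[int, int] = (20, 24)
    loop_len_range: tuple[int, int] = (10, 25)
    arm_profile_fractions: tuple[float, float, float] = (0.4, 0.4, 0.2)
    single_arm_fraction: float = 0.15
    n_samples: dict[str, int] = field(
        default_factory=lambda: {"LUAD": 569, "LUSC": 497}
    )
    background_rate: float = 5.2e-6  # mutations per bp per sample
    hotspots: list[tuple[int, float]] = field(default_factory=list)
    planted: dict[str, int] = field(
        default_factory=lambda: {"seed": 0, "motif_lost": 0,
                                 "motif_gained": 0, "cleavage": 0}
    )
    germline_per_sample: float = 0.0  # expected contaminant calls per sample
    violate_fractions: dict[str, float] = field(
        default_factory=lambda: {"min_alt_reads": 0.0, "freq_ratio": 0.0,
                                 "ssc": 0.0, "bq": 0.0, "non_pass": 0.0}
    )
    caller_sensitivity: dict[str, float] = field(
        default_factory=lambda: {"MuSE": 1.0, "MuTect2": 1.0,
                                 "VarScan2": 1.0, "SomaticSniper": 1.0}
    )
    mean_depth: int = 300
    expression_mutation_effect: float = 0.0  # log-scale decrease when mutated

    def __post_init__(self) -> None:
        if abs(sum(self.arm_profile_fractions) - 1.0) > 1e-9:
            raise ValueError("arm_profile_fractions must sum to 1")
        if self.background_rate < 0 or self.germline_per_sample < 0:
            raise ValueError("rates must be non-negative")

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(dataclasses.asdict(self)), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("chromosomes", "arm_len_range", "loop_len_range",
                    "arm_profile_fractions"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "hotspots" in raw:
            raw["hotspots"] = [tuple(h) for h in raw["hotspots"]]
        return cls(**raw)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


@dataclass
class SimGene:
    gene_id: str
    chrom: str
    strand: str
    sl_start: int  # genomic, untrimmed stem-loop
    sl_end: int
    arm_len: int
    loop_len: int
    arm_class: str
    single_arm: str | None  # which arm is annotated alone, if any
    reads_5p: int
    reads_3p: int
    ext_seq: str  # stem-loop + flanks, precursor sense
    multiplier: float = 1.0
    precursor: PrecursorAnnotation | None = None
    region: MirnaGeneRegion | None = None

    @property
    def sl_len(self) -> int:
        return self.sl_end - self.sl_start + 1


def _make_classes(cfg: SimulationConfig, rng) -> list[str]:
    f5, f3, _ = cfg.arm_profile_fractions
    n5 = round(cfg.n_genes * f5)
    n3 = round(cfg.n_genes * f3)
    classes = (["5p_dominant"] * n5 + ["3p_dominant"] * n3
               + ["balanced"] * (cfg.n_genes - n5 - n3))
    rng.shuffle(classes)
    return classes


def generate_genes(cfg: SimulationConfig) -> list[SimGene]:
    """Build the gene models (deterministic for a given config)."""
    rng = np.random.default_rng(cfg.seed)
    classes = _make_classes(cfg, rng)
    n_single = round(cfg.n_genes * cfg.single_arm_fraction)
    chrom_weights = 1.0 / np.arange(1, len(cfg.chromosomes) + 1)
    chrom_weights /= chrom_weights.sum()
    cursors = {c: 10_000 for c in cfg.chromosomes}

    genes: list[SimGene] = []
    single_assigned = 0
    for i in range(cfg.n_genes):
        arm_len = int(rng.integers(cfg.arm_len_range[0], cfg.arm_len_range[1] + 1))
        loop_len = int(rng.integers(cfg.loop_len_range[0], cfg.loop_len_range[1] + 1))
        sl_len = 2 * arm_len + loop_len + 6
        arm_class = classes[i]

        # read profile realizing the class exactly (total 1000 reads)
        if arm_class == "5p_dominant":
            r5 = int(rng.integers(900, 1001))
            r3 = 1000 - r5
        elif arm_class == "3p_dominant":
            r3 = int(rng.integers(900, 1001))
            r5 = 1000 - r3
        else:
            r5 = int(rng.integers(110, 891))
            r3 = 1000 - r5

        single_arm = None
        if single_assigned < n_single and arm_class != "balanced":
            single_arm = "5p" if arm_class == "5p_dominant" else "3p"
            single_assigned += 1
            if single_arm == "5p":
                r3 = 0
            else:
                r5 = 0

        chrom = str(rng.choice(cfg.chromosomes, p=chrom_weights))
        strand = "+" if rng.random() < 0.5 else "-"
        start = cursors[chrom] + int(rng.integers(500, 5000))
        cursors[chrom] = start + sl_len

        seq = _hairpin_sequence(rng, sl_len, FLANK_LEN)
        genes.append(
            SimGene(
                gene_id=f"mir-{i + 1:04d}",
                chrom=chrom,
                strand=strand,
                sl_start=start,
                sl_end=start + sl_len - 1,
                arm_len=arm_len,
                loop_len=loop_len,
                arm_class=arm_class,
                single_arm=single_arm,
                reads_5p=r5,
                reads_3p=r3,
                ext_seq=seq,
            )
        )
    for idx, mult in cfg.hotspots:
        genes[idx].multiplier = float(mult)
    _attach_models(genes)
    return genes


def _hairpin_sequence(rng, sl_len: int, flank: int) -> str:
    """Random extended sequence with hairpin pairing i + j = sl_len + 1.

    Pairing is enforced over the second half of the stem-loop, making the
    arm regions reverse-complement compatible (a perfect hairpin whose
    DICER duplex carries 2-nt 3' overhangs under the arm geometry used
    here).  Flanks are unconstrained.
    """
    seq = list(rng.choice(list(BASES), size=sl_len + 2 * flank))
    for j in range(sl_len // 2 + 1, sl_len + 1):
        partner = sl_len + 1 - j
        seq[flank + j - 1] = _COMP[seq[flank + partner - 1]]
    return "".join(seq)


def _attach_models(genes: list[SimGene]) -> None:
    """Derive the trimmed precursor and region model for each gene.

    Stem-loop geometry: 5p arm at stem-loop positions [5, 4 + arm_len], 3p
    arm the overhang-rule image [sl_len + 3 - b, sl_len - 2]; trimming to the
    outer arm bounds leaves a precursor of length 2 x arm_len + loop_len
    whose arms touch its ends.
    """
    for g in genes:
        trim_front, trim_back = 4, 2
        L = g.sl_len - trim_front - trim_back
        if g.strand == "+":
            g_start, g_end = g.sl_start + trim_front, g.sl_end - trim_back
        else:
            g_start, g_end = g.sl_start + trim_back, g.sl_end - trim_front
        arms = [
            MatureArm("5p", 1, g.arm_len, g.reads_5p,
                      is_annotated=g.single_arm in (None, "5p")),
            MatureArm("3p", g.arm_len + g.loop_len + 1, L, g.reads_3p,
                      is_annotated=g.single_arm in (None, "3p")),
        ]
        seq = g.ext_seq[trim_front : len(g.ext_seq) - trim_back]
        g.precursor = PrecursorAnnotation(
            gene_id=g.gene_id,
            chromosome=g.chrom,
            strand=g.strand,
            genomic_start=g_start,
            genomic_end=g_end,
            arms=arms,
            sequence=seq,
        )
        g.region = build_gene_region(g.precursor)


# ---------------------------------------------------------------------------
# annotation files
# ---------------------------------------------------------------------------


def simulate_annotation(cfg: SimulationConfig, outdir: str) -> dict[str, str]:
    """Write GFF3 + FASTA + read-count TSV for a simulated gene set."""
    genes = generate_genes(cfg)
    return write_annotation(genes, outdir)


def write_annotation(genes: list[SimGene], outdir: str) -> dict[str, str]:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    gff_path = out / "annotation.gff3"
    fasta_path = out / "hairpins.fa"
    counts_path = out / "readcounts.tsv"

    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda x: (x.chrom, x.sl_start)):
        lines.append(
            "\t".join(
                [g.chrom, "sim", "miRNA_primary_transcript", str(g.sl_start),
                 str(g.sl_end), ".", g.strand, ".",
                 f"ID={g.gene_id};Name={g.gene_id}"]
            )
        )
        for label, rel in _annotated_arms_sl(g):
            rs, re_ = rel
            if g.strand == "+":
                ms, me = g.sl_start + rs - 1, g.sl_start + re_ - 1
            else:
                ms, me = g.sl_end - re_ + 1, g.sl_end - rs + 1
            lines.append(
                "\t".join(
                    [g.chrom, "sim", "miRNA", str(ms), str(me), ".", g.strand,
                     ".",
                     f"ID={g.gene_id}-{label};Name={g.gene_id}-{label};"
                     f"Derives_from={g.gene_id}"]
                )
            )
    gff_path.write_text("\n".join(lines) + "\n")

    with open(fasta_path, "w") as fh:
        for g in sorted(genes, key=lambda x: x.gene_id):
            fh.write(f">{g.gene_id}\n{g.ext_seq}\n")

    rows = []
    for g in sorted(genes, key=lambda x: x.gene_id):
        for label, _ in _annotated_arms_sl(g):
            reads = g.reads_5p if label == "5p" else g.reads_3p
            rows.append(f"{g.gene_id}-{label}\t{reads}")
    counts_path.write_text("mature_id\tread_count\n" + "\n".join(rows) + "\n")

    return {"gff3": str(gff_path), "fasta": str(fasta_path),
            "readcounts": str(counts_path)}


def _annotated_arms_sl(g: SimGene) -> list[tuple[str, tuple[int, int]]]:
    """Annotated arms in stem-loop coordinates (5p at [5, 4+arm_len])."""
    b = 4 + g.arm_len
    arms = {
        "5p": (5, b),
        "3p": (g.sl_len + 3 - b, g.sl_len - 2),
    }
    if g.single_arm:
        return [(g.single_arm, arms[g.single_arm])]
    return [("5p", arms["5p"]), ("3p", arms["3p"])]


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class TruthVariant:
    patient_id: str
    cancer: str
    gene_id: str
    chrom: str
    genomic_pos: int
    ref_genomic: str
    alt_genomic: str
    ext_pos: int  # extended precursor coordinate (trimmed model)
    subregion: str
    in_seed: bool
    in_cleavage: bool
    category: str  # background | seed | motif_lost | motif_gained | cleavage | germline
    is_germline: bool
    violation: str  # "" when the record is clean
    detected_by: tuple[str, ...]
    expected_pass: bool
    # sampled evidence shared by all callers observing the same reads
    tumor_ref: int = 0
    tumor_alt: int = 0
    normal_ref: int = 0
    normal_alt: int = 0
    ssc: float = 0.0
    bq: float = 0.0
    filter_status: str = "PASS"


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    genes: list[SimGene]
    truth: list[TruthVariant]
    files: dict[str, str]

    @property
    def regions(self) -> list[MirnaGeneRegion]:
        return [g.region for g in self.genes]

    def truth_frame(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(t) for t in self.truth]
        df = pd.DataFrame(rows)
        if not df.empty:
            df["detected_by"] = df["detected_by"].map(",".join)
        return df


def simulate_cohort(cfg: SimulationConfig, outdir: str) -> SimulatedCohort:
    """Generate annotation + caller VCFs + metadata + truth for a cohort."""
    rng = np.random.default_rng(cfg.seed)
    genes = generate_genes(cfg)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    files = write_annotation(genes, outdir)
    cfg.to_yaml(str(out / "config.yaml"))
    files["config"] = str(out / "config.yaml")

    patients = [
        (f"{cancer}-{i + 1:04d}", cancer)
        for cancer in sorted(cfg.n_samples)
        for i in range(cfg.n_samples[cancer])
    ]

    truth: list[TruthVariant] = []
    occupied: set[tuple[str, str, int, str]] = set()
    ext_lens = np.array([g.region.length + 2 * FLANK_LEN for g in genes])
    lams = cfg.background_rate * ext_lens * np.array(
        [g.multiplier for g in genes]
    )

    for patient_id, cancer in patients:
        n_per_gene = rng.poisson(lams)
        for gi in np.nonzero(n_per_gene)[0]:
            for _ in range(int(n_per_gene[gi])):
                tv = _place_background_variant(
                    rng, genes[int(gi)], patient_id, cancer, occupied, cfg
                )
                if tv is not None:
                    truth.append(tv)
        n_germ = rng.poisson(cfg.germline_per_sample)
        for _ in range(int(n_germ)):
            gi = int(rng.integers(len(genes)))
            tv = _place_germline_variant(
                rng, genes[gi], patient_id, cancer, occupied, cfg
            )
            if tv is not None:
                truth.append(tv)

    truth.extend(_place_planted_variants(rng, genes, patients, occupied, cfg))
    truth.sort(key=lambda t: (t.patient_id, t.chrom, t.genomic_pos,
                              t.alt_genomic))

    files.update(_write_vcfs(truth, patients, genes, out))
    files["metadata"] = _write_metadata(rng, patients, out)
    files["expression"] = _write_expression(rng, genes, patients, truth, cfg, out)

    tf = out / "truth_variants.tsv"
    cohort = SimulatedCohort(config=cfg, genes=genes, truth=truth, files=files)
    cohort.truth_frame().to_csv(tf, sep="\t", index=False)
    files["truth_variants"] = str(tf)
    gf = out / "truth_genes.tsv"
    pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "length": g.region.length,
                "ext_length": g.region.length + 2 * FLANK_LEN,
                "arm_class": g.arm_class,
                "single_arm": g.single_arm or "",
                "multiplier": g.multiplier,
            }
            for g in genes
        ]
    ).to_csv(gf, sep="\t", index=False)
    files["truth_genes"] = str(gf)
    return cohort


# -- variant placement ------------------------------------------------------


def _primary_label(region: MirnaGeneRegion, pos: int) -> str:
    for label in ("flank5", "flank3", "loop", "passenger", "guide"):
        if any(s <= pos <= e for s, e in region.subregions.get(label, [])):
            return label
    return "unassigned"


def _genomic_alleles(g: SimGene, ext_pos: int, ref: str, alt: str
                     ) -> tuple[int, str, str]:
    pos = precursor_to_genomic(ext_pos, g.precursor)
    if g.strand == "-":
        return pos, _COMP[ref], _COMP[alt]
    return pos, ref, alt


def _trimmed_ext_seq(g: SimGene) -> str:
    return g.ext_seq[4 : len(g.ext_seq) - 2]


def _new_variant_site(rng, g: SimGene, occupied, patient_id: str,
                      ext_range: tuple[int, int] | None = None,
                      max_tries: int = 50):
    """Pick an unoccupied substitution site; returns (ext_pos, ref, alt)."""
    L = g.region.length
    lo, hi = ext_range if ext_range else (1 - FLANK_LEN, L + FLANK_LEN)
    seq = _trimmed_ext_seq(g)
    for _ in range(max_tries):
        ext_pos = int(rng.integers(lo, hi + 1))
        ref = seq[ext_to_seq_index(ext_pos, FLANK_LEN)]
        alt = str(rng.choice([b for b in BASES if b != ref]))
        gpos, gref, galt = _genomic_alleles(g, ext_pos, ref, alt)
        key = (patient_id, g.chrom, gpos, galt)
        if key not in occupied:
            occupied.add(key)
            return ext_pos, ref, alt, gpos, gref, galt
    return None


def _detection(rng, cfg: SimulationConfig, force: tuple[str, ...] = ()
               ) -> tuple[str, ...]:
    detected = [c for c in CALLERS
                if rng.random() < cfg.caller_sensitivity.get(c, 1.0)]
    for c in force:
        if c not in detected:
            detected.append(c)
    return tuple(sorted(detected))


def _clean_evidence(rng, cfg: SimulationConfig) -> dict:
    t_depth = max(30, int(rng.poisson(cfg.mean_depth)))
    n_depth = max(30, int(rng.poisson(cfg.mean_depth)))
    af = rng.uniform(0.15, 0.6)
    t_alt = max(2, int(rng.binomial(t_depth, af)))
    return {
        "tumor_ref": t_depth - t_alt,
        "tumor_alt": t_alt,
        "normal_ref": n_depth,
        "normal_alt": 0,
        "ssc": round(float(rng.uniform(35, 95)), 1),
        "bq": round(float(rng.uniform(25, 40)), 1),
    }


def _pick_violation(rng, cfg: SimulationConfig) -> str:
    u = rng.random()
    acc = 0.0
    for name in ("min_alt_reads", "freq_ratio", "ssc", "bq", "non_pass"):
        acc += cfg.violate_fractions.get(name, 0.0)
        if u < acc:
            return name
    return ""


def _apply_violation(rng, ev: dict, violation: str) -> tuple[dict, str, tuple]:
    """Returns (evidence, filter_status, forced callers)."""
    status, force = "PASS", ()
    if violation == "min_alt_reads":
        ev["tumor_ref"] += ev["tumor_alt"] - 1
        ev["tumor_alt"] = 1
    elif violation == "freq_ratio":
        t_af = ev["tumor_alt"] / (ev["tumor_alt"] + ev["tumor_ref"])
        n_depth = ev["normal_ref"] + ev["normal_alt"]
        n_alt = int(np.ceil(n_depth * t_af / 4))  # ratio <= 4 < 5
        ev["normal_alt"] = max(1, n_alt)
        ev["normal_ref"] = n_depth - ev["normal_alt"]
    elif violation == "ssc":
        ev["ssc"] = round(float(rng.uniform(5, 28)), 1)
        force = ("VarScan2",)
    elif violation == "bq":
        ev["bq"] = round(float(rng.uniform(5, 19)), 1)
        force = ("MuSE",)
    elif violation == "non_pass":
        status = "REJECT"
    return ev, status, force


def _make_truth(rng, cfg, g: SimGene, patient_id, cancer, site, category,
                is_germline=False, violation="") -> TruthVariant:
    ext_pos, ref, alt, gpos, gref, galt = site
    region = g.region
    if is_germline:
        n_depth = max(30, int(rng.poisson(cfg.mean_depth)))
        t_depth = max(30, int(rng.poisson(cfg.mean_depth)))
        af = rng.uniform(0.35, 0.6)
        t_alt = max(1, int(rng.binomial(t_depth, af)))
        n_alt = max(1, int(rng.binomial(n_depth, af)))
        ev = {
            "tumor_ref": t_depth - t_alt, "tumor_alt": t_alt,
            "normal_ref": n_depth - n_alt, "normal_alt": n_alt,
            "ssc": round(float(rng.uniform(35, 95)), 1),
            "bq": round(float(rng.uniform(25, 40)), 1),
        }
        status, force = "PASS", ()
    else:
        ev = _clean_evidence(rng, cfg)
        ev, status, force = _apply_violation(rng, ev, violation)
    detected = _detection(rng, cfg, force=force)
    labels = region.labels_at(ext_pos)
    expected_pass = (
        not is_germline and violation == "" and status == "PASS"
        and len(detected) > 0
    )
    return TruthVariant(
        patient_id=patient_id,
        cancer=cancer,
        gene_id=g.gene_id,
        chrom=g.chrom,
        genomic_pos=gpos,
        ref_genomic=gref,
        alt_genomic=galt,
        ext_pos=ext_pos,
        subregion=_primary_label(region, ext_pos),
        in_seed="seed" in labels,
        in_cleavage="cleavage_site" in labels,
        category=category,
        is_germline=is_germline,
        violation=violation,
        detected_by=detected,
        expected_pass=expected_pass,
        filter_status=status,
        **ev,
    )


def _place_background_variant(rng, g, patient_id, cancer, occupied, cfg):
    site = _new_variant_site(rng, g, occupied, patient_id)
    if site is None:
        return None
    violation = _pick_violation(rng, cfg)
    return _make_truth(rng, cfg, g, patient_id, cancer, site, "background",
                       violation=violation)


def _place_germline_variant(rng, g, patient_id, cancer, occupied, cfg):
    site = _new_variant_site(rng, g, occupied, patient_id)
    if site is None:
        return None
    return _make_truth(rng, cfg, g, patient_id, cancer, site, "germline",
                       is_germline=True)


def _place_planted_variants(rng, genes, patients, occupied, cfg):
    out = []
    catalogue = load_catalogue()
    for category, count in sorted(cfg.planted.items()):
        for _ in range(int(count)):
            tv = _plant_one(rng, genes, patients, occupied, cfg, category,
                            catalogue)
            if tv is not None:
                out.append(tv)
    return out


def _plant_one(rng, genes, patients, occupied, cfg, category, catalogue,
               max_tries: int = 200):
    for _ in range(max_tries):
        g = genes[int(rng.integers(len(genes)))]
        patient_id, cancer = patients[int(rng.integers(len(patients)))]
        site = _planted_site(rng, g, occupied, patient_id, category, catalogue)
        if site is not None:
            return _make_truth(rng, cfg, g, patient_id, cancer, site, category)
    return None


def _planted_site(rng, g, occupied, patient_id, category, catalogue):
    region = g.region
    if category == "seed":
        s, e = region.subregions["seed"][
            int(rng.integers(len(region.subregions["seed"])))
        ]
        return _new_variant_site(rng, g, occupied, patient_id, (s, e))
    if category == "cleavage":
        name, (s, e) = region.cleavage_windows[
            int(rng.integers(len(region.cleavage_windows)))
        ]
        L = region.length
        s, e = max(s, 1 - FLANK_LEN), min(e, L + FLANK_LEN)
        return _new_variant_site(rng, g, occupied, patient_id, (s, e))
    if category in ("motif_lost", "motif_gained"):
        return _motif_site(rng, g, occupied, patient_id, category, catalogue)
    raise ValueError(f"unknown planted category {category!r}")


def _motif_site(rng, g, occupied, patient_id, category, catalogue):
    from .motifs import scan_motifs

    region = g.region
    L = region.length
    pre_seq = _trimmed_ext_seq(g)[FLANK_LEN : FLANK_LEN + L]
    rna = to_rna(pre_seq)
    loop_ivs = region.subregions.get("loop", [])
    loop = loop_ivs[0] if loop_ivs else None

    candidates = []
    for spec in catalogue:
        interval = loop if spec.loop_restricted else (1, L)
        if interval is None:
            continue
        if category == "motif_lost":
            for start in scan_motifs(rna, spec, interval):
                for k, ch in enumerate(spec.pattern):
                    allowed = set(IUPAC[ch])
                    base = rna[start + k - 1]
                    breakers = [b for b in "ACGU" if b != base and b not in allowed]
                    if breakers:
                        candidates.append((start + k, base, breakers))
        else:  # motif_gained: windows one mismatch away from a match
            plen = len(spec.pattern)
            lo, hi = interval
            for start in range(lo, hi - plen + 2):
                window = rna[start - 1 : start + plen - 1]
                mism = [
                    (k, ch) for k, ch in enumerate(spec.pattern)
                    if window[k] not in IUPAC[ch]
                ]
                if len(mism) == 1:
                    k, ch = mism[0]
                    fixes = [b for b in IUPAC[ch] if b != window[k]]
                    if fixes:
                        candidates.append((start + k, window[k], fixes))
    if not candidates:
        return None
    pos, base, alts = candidates[int(rng.integers(len(candidates)))]
    ref = pre_seq[pos - 1]  # DNA base at that precursor position
    alt_rna = str(rng.choice(alts))
    alt = alt_rna.replace("U", "T")
    if alt == ref:
        return None
    gpos, gref, galt = _genomic_alleles(g, pos, ref, alt)
    key = (patient_id, g.chrom, gpos, galt)
    if key in occupied:
        return None
    occupied.add(key)
    return pos, ref, alt, gpos, gref, galt


# ---------------------------------------------------------------------------
# caller VCF emission
# ---------------------------------------------------------------------------

_VCF_DEFS = {
    "MuSE": (
        ['##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
         '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
         '##FORMAT=<ID=BQ,Number=R,Type=Float,Description="Average base quality">'],
        "GT:AD:BQ",
    ),
    "MuTect2": (
        ['##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
         '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
         '##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction">',
         '##FORMAT=<ID=BQ,Number=R,Type=Float,Description="Average base quality">'],
        "GT:AD:AF:BQ",
    ),
    "VarScan2": (
        ['##INFO=<ID=SSC,Number=1,Type=Float,Description="Somatic score">',
         '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
         '##FORMAT=<ID=RD,Number=1,Type=Integer,Description="Reference depth">',
         '##FORMAT=<ID=AD,Number=1,Type=Integer,Description="Alternate depth">',
         '##FORMAT=<ID=FREQ,Number=1,Type=String,Description="Allele frequency">'],
        "GT:RD:AD:FREQ",
    ),
    "SomaticSniper": (
        ['##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
         '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
         '##FORMAT=<ID=SSC,Number=1,Type=Float,Description="Somatic score">'],
        "GT:AD:SSC",
    ),
}


def _vcf_record(caller: str, t: TruthVariant) -> str:
    info = "."
    if caller == "VarScan2":
        info = f"SSC={t.ssc}"
    t_af = t.tumor_alt / max(1, t.tumor_alt + t.tumor_ref)
    n_af = t.normal_alt / max(1, t.normal_alt + t.normal_ref)
    if caller == "MuSE":
        tum = f"0/1:{t.tumor_ref},{t.tumor_alt}:{t.bq},{t.bq}"
        norm = f"0/0:{t.normal_ref},{t.normal_alt}:{t.bq},{t.bq}"
    elif caller == "MuTect2":
        tum = f"0/1:{t.tumor_ref},{t.tumor_alt}:{t_af:.4f}:{t.bq},{t.bq}"
        norm = f"0/0:{t.normal_ref},{t.normal_alt}:{n_af:.4f}:{t.bq},{t.bq}"
    elif caller == "VarScan2":
        tum = f"0/1:{t.tumor_ref}:{t.tumor_alt}:{t_af * 100:.2f}%"
        norm = f"0/0:{t.normal_ref}:{t.normal_alt}:{n_af * 100:.2f}%"
    else:  # SomaticSniper
        tum = f"0/1:{t.tumor_ref},{t.tumor_alt}:{t.ssc}"
        norm = f"0/0:{t.normal_ref},{t.normal_alt}:{t.ssc}"
    fmt = _VCF_DEFS[caller][1]
    return "\t".join(
        [t.chrom, str(t.genomic_pos), ".", t.ref_genomic, t.alt_genomic, ".",
         t.filter_status, info, fmt, tum, norm]
    )


def _write_vcfs(truth, patients, genes, out: Path) -> dict[str, str]:
    vcf_dir = out / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    chrom_max: dict[str, int] = {}
    for g in genes:
        chrom_max[g.chrom] = max(chrom_max.get(g.chrom, 0), g.sl_end + 1000)
    contigs = [f"##contig=<ID={c},length={n}>"
               for c, n in sorted(chrom_max.items())]

    by_patient: dict[str, list[TruthVariant]] = {p: [] for p, _ in patients}
    for t in truth:
        by_patient[t.patient_id].append(t)

    manifest_rows = []
    for patient_id, _ in patients:
        for caller in CALLERS:
            records = [
                t for t in by_patient[patient_id] if caller in t.detected_by
            ]
            path = vcf_dir / f"{patient_id}.{caller}.vcf"
            defs, _fmt = _VCF_DEFS[caller]
            header = (
                ["##fileformat=VCFv4.2",
                 '##FILTER=<ID=PASS,Description="Accepted">',
                 '##FILTER=<ID=REJECT,Description="Rejected">']
                + contigs + defs
                + ["#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
                   "\tTUMOR\tNORMAL"]
            )
            body = [_vcf_record(caller, t) for t in records]
            path.write_text("\n".join(header + body) + "\n")
            manifest_rows.append(
                f"{patient_id}\t{caller}\tvcf/{path.name}"
            )

    manifest = out / "manifest.tsv"
    manifest.write_text("patient_id\tcaller\tpath\n" + "\n".join(manifest_rows) + "\n")
    return {"vcf_dir": str(vcf_dir), "manifest": str(manifest)}


# ---------------------------------------------------------------------------
# metadata and expression
# ---------------------------------------------------------------------------


def _write_metadata(rng, patients, out: Path) -> str:
    rows = []
    for patient_id, cancer in patients:
        rows.append(
            {
                "patient_id": patient_id,
                "cancer_type": cancer,
                "stage": str(rng.choice(["I", "II", "III", "IV"],
                                        p=[0.35, 0.3, 0.25, 0.1])),
                "gender": str(rng.choice(["male", "female"])),
                "smoking_pack_years": int(rng.integers(0, 80)),
            }
        )
    path = out / "metadata.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return str(path)


def _write_expression(rng, genes, patients, truth, cfg, out: Path) -> str:
    """Log-normal expression per miRNA x sample.

    With a positive ``expression_mutation_effect`` e, mutated (gene, sample)
    pairs have their log-expression lowered by e, emulating mutations that
    reduce the miRNA level.
    """
    mutated = {(t.gene_id, t.patient_id) for t in truth if not t.is_germline}
    sample_ids = [p for p, _ in patients]
    gene_means = rng.normal(6.0, 1.5, size=len(genes))
    mat = rng.normal(
        gene_means[:, None], 0.8, size=(len(genes), len(sample_ids))
    )
    if cfg.expression_mutation_effect:
        for gi, g in enumerate(genes):
            for si, s in enumerate(sample_ids):
                if (g.gene_id, s) in mutated:
                    mat[gi, si] -= cfg.expression_mutation_effect
    df = pd.DataFrame(np.exp(mat),
                      index=[g.gene_id for g in genes], columns=sample_ids)
    df.index.name = "gene_id"
    path = out / "expression.tsv"
    df.round(3).to_csv(path, sep="\t")
    return str(path)


# ---------------------------------------------------------------------------
# lightweight count-level simulation (for statistical calibration studies)
# ---------------------------------------------------------------------------


def simulate_gene_counts(
    rng, lengths: np.ndarray, n_mutations: int,
    multipliers: np.ndarray | None = None,
) -> np.ndarray:
    """Multinomial per-gene mutation counts with probability ~ length x rate.

    Models the conditional distribution of the cohort's mutations across
    genes given the total, which is exactly the null (all multipliers 1) of
    the hotspot test.
    """
    lengths = np.asarray(lengths, dtype=float)
    w = lengths if multipliers is None else lengths * np.asarray(multipliers)
    return rng.multinomial(n_mutations, w / w.sum())
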