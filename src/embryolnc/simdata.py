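"""Synthetic stage-structured embryo transcriptome data with planted truth.

Generates (1) a gene annotation with planted cis-neighbor pairs, (2) an FPKM
expression matrix over a fixed developmental-stage design with planted flat,
stage-specific and co-expression-module genes, and (3) an assembly fixture
(two assembler outputs, a reference, coverage values and per-tool
coding-potential calls) for the transcript-filtering pipeline.

Noise is log-normal on the log10(FPKM+1) scale with per-cell zero inflation
(dropout). All draws flow from a single numpy Generator seeded by
``SimConfig.seed`` so identical configs give byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    CODING,
    LNCRNA,
    GeneRecord,
    TranscriptModel,
    write_expression,
    write_gene_gtf,
    write_sample_sheet,
    write_transcript_gtf,
)

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "PlantedPair",
    "AssemblyFixture",
    "simulate_annotation",
    "simulate_expression",
    "simulate_assembly_fixture",
    "simulate_all",
    "write_outputs",
]

#: the seven consecutive human pre-implantation stages of the emulated design
DEFAULT_STAGES = (
    "oocyte", "zygote", "2cell", "4cell", "8cell", "morula", "blastocyst",
)
#: cells per stage in the emulated 90-cell design
DEFAULT_CELLS_PER_STAGE = (3, 3, 6, 12, 20, 16, 30)

# expression-model constants (FPKM / log10 units)
FLAT_MEAN_LOG10_FPKM = 1.0      # flat genes: ~10 FPKM baseline, lognormal spread
FLAT_SD_LOG10_FPKM = 0.4
SPECIFIC_OFF_FPKM = 0.0         # stage-specific genes are silent off-stage
SPECIFIC_ON_FPKM = 100.0        # and strongly expressed in their stage
MODULE_BASE_FPKM = 0.5
MODULE_TRAJ_AMPLITUDE = 2.5     # log10 units, Gaussian bump over stage axis
PAIR_TRAJ_SD = 0.8              # log10 units, iid per-stage latent for pairs
PAIR_BASE_FPKM = 30.0           # baseline FPKM of planted neighbor-pair genes
DROPOUT_MIDPOINT_LOG = 1.0      # log10(FPKM+1) where dropout is half-maximal
DROPOUT_SHAPE = 0.3             # logistic steepness of the dropout decay
MIN_INTERGENIC_BP = 20_000      # keeps unplanted genes out of neighbor range


@dataclass
class SimConfig:
    """Parameters of the synthetic dataset."""

    n_chromosomes: int = 3
    chrom_length_bp: int = 60_000_000
    n_genes: int = 400
    frac_lncrna: float = 0.3
    stages: tuple[str, ...] = DEFAULT_STAGES
    cells_per_stage: tuple[int, ...] = DEFAULT_CELLS_PER_STAGE
    n_modules: int = 3
    module_size: int = 40
    n_specific_genes: int = 60
    #: fraction of stage-specific genes planted in lncRNAs (lncRNAs are
    #: more temporally specific than coding genes in early embryos)
    lnc_specific_bias: float = 0.5
    n_neighbor_pairs_divergent: int = 15
    n_neighbor_pairs_unidirectional: int = 15
    neighbor_gap_bp: int = 5_000
    neighbor_rho: float = 0.8
    lnc_expression_scale: float = 0.25
    noise_sd: float = 0.2
    dropout_rate: float = 0.1
    module_loading_low: float = 0.7
    module_loading_high: float = 1.3
    # assembly-fixture class sizes and call behaviour
    n_fixture_novel_lnc: int = 10
    n_fixture_coding_like: int = 5
    n_fixture_annotated: int = 8
    n_fixture_too_short: int = 6
    n_fixture_single_exon: int = 6
    fixture_call_agreement: float = 1.0
    good_coverage_range: tuple[float, float] = (10.0, 50.0)
    bad_coverage_range: tuple[float, float] = (0.2, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cells_per_stage) != len(self.stages):
            raise ValueError("cells_per_stage must match stages in length")
        if not (0.0 <= self.frac_lncrna <= 1.0):
            raise ValueError("frac_lncrna must lie in [0, 1]")
        if not (0.0 <= self.neighbor_rho <= 1.0):
            raise ValueError("neighbor_rho must lie in [0, 1]")
        if not (0 <= self.neighbor_gap_bp < 10_000):
            raise ValueError("neighbor_gap_bp must lie in [0, 10000)")
        for name in ("n_chromosomes", "n_genes", "n_modules", "module_size",
                     "n_specific_genes", "n_neighbor_pairs_divergent",
                     "n_neighbor_pairs_unidirectional"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        n_pair_genes = 2 * (self.n_neighbor_pairs_divergent
                            + self.n_neighbor_pairs_unidirectional)
        n_planted = (n_pair_genes + self.n_modules * self.module_size
                     + self.n_specific_genes)
        if n_planted > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small for {n_planted} planted genes")

    @property
    def n_cells(self) -> int:
        return int(sum(self.cells_per_stage))


@dataclass(frozen=True)
class PlantedPair:
    gene_a: str          # lncRNA member
    gene_b: str          # protein-coding member
    orientation: str     # divergent | unidirectional
    gap_bp: int
    rho: float


@dataclass
class SyntheticTruth:
    """Ground truth of the planted structure, keyed by emitted identifiers."""

    gene_archetype: dict[str, str]               # flat | stage_specific:<stage> | module:<k>
    planted_modules: dict[str, list[str]]
    planted_pairs: list[PlantedPair]
    assembly_labels: dict[str, dict[str, str]] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "gene_archetype": self.gene_archetype,
            "planted_modules": self.planted_modules,
            "planted_pairs": [asdict(p) for p in self.planted_pairs],
            "assembly_labels": self.assembly_labels,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class AssemblyFixture:
    set_a: list[TranscriptModel]
    set_b: list[TranscriptModel]
    reference: list[TranscriptModel]
    coverage: pd.DataFrame       # transcript_id, coverage, label, category
    calls: pd.DataFrame          # transcript_id, tool_1..tool_4


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def _make_exons(rng: np.random.Generator, start: int,
                n_exons: int) -> tuple[tuple[int, int], ...]:
    exon_lens = rng.integers(150, 1000, size=n_exons)
    intron_lens = rng.integers(500, 2500, size=max(n_exons - 1, 0))
    exons, pos = [], start
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + int(el)))
        pos = exons[-1][1] + (int(intron_lens[i]) if i < n_exons - 1 else 0)
    return tuple(exons)


def _make_gene(rng: np.random.Generator, gene_id: str, chrom: str, start: int,
               strand: str, biotype: str) -> GeneRecord:
    exons = _make_exons(rng, start, int(rng.integers(2, 5)))
    return GeneRecord(gene_id=gene_id, chrom=chrom, start=exons[0][0],
                      end=exons[-1][1], strand=strand, biotype=biotype,
                      exons=exons)


def simulate_annotation(
    config: SimConfig, rng: np.random.Generator | None = None,
) -> tuple[list[GeneRecord], SyntheticTruth]:
    """Place genes with >=20 kb spacing except for the planted neighbor pairs.

    Divergent pairs are head-to-head (left gene on '-', right gene on '+')
    with a gene-body gap of ``neighbor_gap_bp``; unidirectional pairs sit on
    the same strand at the same gap. Pair members are one lncRNA (upstream)
    and one coding gene.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n_pairs = config.n_neighbor_pairs_divergent + config.n_neighbor_pairs_unidirectional
    n_single = config.n_genes - 2 * n_pairs
    n_lnc_total = int(round(config.frac_lncrna * config.n_genes))
    n_lnc_single = max(n_lnc_total - n_pairs, 0)   # one lncRNA per pair

    # biotypes for non-pair genes, shuffled deterministically
    single_biotypes = np.array([LNCRNA] * n_lnc_single
                               + [CODING] * (n_single - n_lnc_single))
    rng.shuffle(single_biotypes)

    genes: list[GeneRecord] = []
    pairs: list[PlantedPair] = []
    cursors = {f"chr{i + 1}": 0 for i in range(config.n_chromosomes)}
    chrom_names = list(cursors)

    def place(span_cb, chrom_idx: int):
        chrom = chrom_names[chrom_idx % len(chrom_names)]
        gap = MIN_INTERGENIC_BP + int(rng.integers(0, 30_000))
        start = cursors[chrom] + gap
        end = span_cb(chrom, start)
        if end > config.chrom_length_bp:
            raise ValueError(
                f"chromosome {chrom} too short ({config.chrom_length_bp} bp) "
                f"for the requested gene count; increase chrom_length_bp")
        cursors[chrom] = end
        return chrom

    unit = 0
    gene_no = 0
    for k in range(n_pairs):
        orientation = ("divergent" if k < config.n_neighbor_pairs_divergent
                       else "unidirectional")
        ga_id = f"G{gene_no:05d}"
        gb_id = f"G{gene_no + 1:05d}"
        gene_no += 2

        def span(chrom: str, start: int, ga_id=ga_id, gb_id=gb_id,
                 orientation=orientation) -> int:
            if orientation == "divergent":
                sa, sb = "-", "+"
            else:
                sa = sb = "+"
            a = _make_gene(rng, ga_id, chrom, start, sa, LNCRNA)
            b = _make_gene(rng, gb_id, chrom, a.end + config.neighbor_gap_bp, sb, CODING)
            genes.extend([a, b])
            pairs.append(PlantedPair(ga_id, gb_id, orientation,
                                     config.neighbor_gap_bp, config.neighbor_rho))
            return b.end

        place(span, unit)
        unit += 1

    for i in range(n_single):
        gid = f"G{gene_no:05d}"
        gene_no += 1
        biotype = str(single_biotypes[i])
        strand = "+" if rng.random() < 0.5 else "-"

        def span(chrom: str, start: int, gid=gid, biotype=biotype,
                 strand=strand) -> int:
            g = _make_gene(rng, gid, chrom, start, strand, biotype)
            genes.append(g)
            return g.end

        place(span, unit)
        unit += 1

    # archetype assignment over non-pair genes
    pair_genes = {p.gene_a for p in pairs} | {p.gene_b for p in pairs}
    free = [g.gene_id for g in genes if g.gene_id not in pair_genes]
    rng.shuffle(free)
    archetype: dict[str, str] = {g.gene_id: "flat" for g in genes}
    modules: dict[str, list[str]] = {}
    at = 0
    for k in range(config.n_modules):
        members = sorted(free[at:at + config.module_size])
        at += config.module_size
        modules[f"M{k + 1}"] = members
        for gid in members:
            archetype[gid] = f"module:M{k + 1}"
    # stage-specific genes drawn preferentially from lncRNAs
    biotype_of = {g.gene_id: g.biotype for g in genes}
    remaining = free[at:]
    lnc_pool = [g for g in remaining if biotype_of[g] == LNCRNA]
    cod_pool = [g for g in remaining if biotype_of[g] == CODING]
    n_lnc_spec = min(int(round(config.lnc_specific_bias
                               * config.n_specific_genes)), len(lnc_pool))
    chosen = lnc_pool[:n_lnc_spec] + cod_pool[:config.n_specific_genes - n_lnc_spec]
    if len(chosen) < config.n_specific_genes:
        raise ValueError("not enough unplanted genes for n_specific_genes")
    for j, gid in enumerate(chosen):
        stage = config.stages[j % len(config.stages)]
        archetype[gid] = f"stage_specific:{stage}"

    truth = SyntheticTruth(gene_archetype=archetype, planted_modules=modules,
                           planted_pairs=pairs)
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes, truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _module_trajectories(config: SimConfig) -> dict[str, np.ndarray]:
    """Gaussian bumps (log10 units) peaking at stages spread across the axis."""
    n = len(config.stages)
    out = {}
    for k in range(config.n_modules):
        peak = (k * (n - 1)) / max(config.n_modules - 1, 1)
        s = np.arange(n, dtype=float)
        out[f"M{k + 1}"] = MODULE_TRAJ_AMPLITUDE * np.exp(-((s - peak) ** 2) / 2.0)
    return out


def sample_sheet_for(config: SimConfig) -> pd.DataFrame:
    rows = []
    for stage, n in zip(config.stages, config.cells_per_stage):
        for i in range(n):
            rows.append((f"{stage}_c{i + 1}", stage))
    return pd.DataFrame(rows, columns=["cell_id", "stage"])


def simulate_expression(
    annotation: list[GeneRecord],
    truth: SyntheticTruth,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (FPKM matrix genes x cells, sample sheet).

    Per-gene stage means are built on the log10(FPKM+1) scale from the gene's
    archetype; planted pair members share a per-stage latent trajectory with
    correlation ``neighbor_rho``; lncRNA mean FPKM is shrunk by
    ``lnc_expression_scale``; per-cell noise is N(0, noise_sd) on the log
    scale. Dropout is expression-dependent: a cell value is zeroed with
    probability dropout_rate * logistic((midpoint - mean_log)/shape), so
    weakly expressed genes drop out at up to ``dropout_rate`` while strongly
    expressed ones almost never do, as in deep full-length single-cell
    protocols.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    sheet = sample_sheet_for(config)
    n_stages = len(config.stages)
    stage_of_cell = np.array([config.stages.index(s) for s in sheet.stage])
    trajs = _module_trajectories(config)
    biotype = {g.gene_id: g.biotype for g in annotation}

    def log1p_fpkm(fpkm: float, gid: str) -> float:
        scale = config.lnc_expression_scale if biotype[gid] == LNCRNA else 1.0
        return float(np.log10(fpkm * scale + 1.0))

    # latent trajectories for planted pairs: truncated N(0, PAIR_TRAJ_SD)
    # per stage, bounded below so that (base + latent) stays positive and
    # pair members remain exactly affine in the shared factor at rho = 1
    pair_latent: dict[str, np.ndarray] = {}
    for p in truth.planted_pairs:
        shared = np.clip(rng.normal(0.0, PAIR_TRAJ_SD, size=n_stages),
                         -0.9, 3.0)
        indep = np.clip(rng.normal(0.0, PAIR_TRAJ_SD, size=n_stages),
                        -0.9, 3.0)
        pair_latent[p.gene_a] = shared
        pair_latent[p.gene_b] = (p.rho * shared
                                 + np.sqrt(max(1.0 - p.rho ** 2, 0.0)) * indep)

    mean_log = np.zeros((len(annotation), n_stages))
    gene_ids = [g.gene_id for g in annotation]
    for gi, gid in enumerate(gene_ids):
        arch = truth.gene_archetype[gid]
        if gid in pair_latent:
            # fixed strong baseline keeps base + latent positive, so the
            # log-scale profile is exactly affine in the latent factor
            base = log1p_fpkm(PAIR_BASE_FPKM, gid)
            mean_log[gi] = base + pair_latent[gid]
        elif arch == "flat":
            base = 10 ** rng.normal(FLAT_MEAN_LOG10_FPKM, FLAT_SD_LOG10_FPKM)
            mean_log[gi] = log1p_fpkm(base, gid)
        elif arch.startswith("stage_specific:"):
            stage = arch.split(":", 1)[1]
            s = config.stages.index(stage)
            mean_log[gi] = log1p_fpkm(SPECIFIC_OFF_FPKM, gid)
            mean_log[gi, s] = log1p_fpkm(SPECIFIC_ON_FPKM, gid)
        else:  # module:<k>
            mod = arch.split(":", 1)[1]
            loading = rng.uniform(config.module_loading_low,
                                  config.module_loading_high)
            mean_log[gi] = (log1p_fpkm(MODULE_BASE_FPKM, gid)
                            + loading * trajs[mod])

    cell_means = mean_log[:, stage_of_cell]
    noise = rng.normal(0.0, config.noise_sd, size=cell_means.shape) \
        if config.noise_sd > 0 else 0.0
    fpkm = np.maximum(10.0 ** (cell_means + noise) - 1.0, 0.0)
    if config.dropout_rate > 0:
        p_drop = config.dropout_rate / (
            1.0 + np.exp((cell_means - DROPOUT_MIDPOINT_LOG) / DROPOUT_SHAPE))
        fpkm[rng.random(fpkm.shape) < p_drop] = 0.0
    matrix = pd.DataFrame(fpkm, index=pd.Index(gene_ids, name="gene_id"),
                          columns=sheet.cell_id.tolist())
    return matrix, sheet


# ---------------------------------------------------------------------------
# Assembly fixture
# ---------------------------------------------------------------------------

def simulate_assembly_fixture(
    annotation: list[GeneRecord],
    config: SimConfig,
    truth: SyntheticTruth | None = None,
    rng: np.random.Generator | None = None,
) -> AssemblyFixture:
    """Emit two assembler outputs with planted transcript classes.

    Classes: ``annotated`` (exon-overlaps an annotated gene), ``too_short``
    (multi-exon, <=200 exonic bp), ``single_exon``, ``novel_lnc`` and
    ``coding_like`` (both novel multi-exon >200 bp; they differ only in the
    planted coding-potential calls). Novel transcripts appear in both sets
    with identical intron chains (set B terminal exons are extended by 50 bp
    to exercise terminal-end tolerance). Coverage values are drawn from the
    separated good/bad ranges; good/bad labels alternate within each
    coding/noncoding category so neither ROC is degenerate.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)

    # free space: beyond the last gene on chr1, well clear of annotation
    by_chrom_end = max((g.end for g in annotation if g.chrom == "chr1"), default=0)
    cursor = by_chrom_end + 100_000

    def novel_exons(n_exons: int, total_len: int) -> tuple[tuple[int, int], ...]:
        nonlocal cursor
        lens = np.full(n_exons, total_len // n_exons, dtype=int)
        lens[0] += total_len - int(lens.sum())
        exons, pos = [], cursor
        for i, el in enumerate(lens):
            exons.append((pos, pos + int(el)))
            pos = exons[-1][1] + 800
        cursor = exons[-1][1] + 50_000
        return tuple(exons)

    set_a: list[TranscriptModel] = []
    set_b: list[TranscriptModel] = []
    labels: dict[str, dict[str, str]] = {}
    tno = 0

    def add_both(exons, cls: str, strand: str = "+") -> str:
        nonlocal tno
        tid = f"T{tno:04d}"
        tno += 1
        set_a.append(TranscriptModel(tid, "chr1", strand, exons, source="assembler_A"))
        if len(exons) >= 2:
            bex = list(exons)
            bex[0] = (max(bex[0][0] - 50, 0), bex[0][1])
            bex[-1] = (bex[-1][0], bex[-1][1] + 50)
            exons_b = tuple(bex)
        else:
            exons_b = exons
        set_b.append(TranscriptModel(tid + "_b", "chr1", strand, exons_b,
                                     source="assembler_B"))
        labels[tid] = {"class": cls}
        return tid

    for _ in range(config.n_fixture_novel_lnc):
        add_both(novel_exons(int(rng.integers(2, 5)), int(rng.integers(400, 2000))),
                 "novel_lnc")
    for _ in range(config.n_fixture_coding_like):
        add_both(novel_exons(int(rng.integers(2, 5)), int(rng.integers(400, 2000))),
                 "coding_like")
    anno_chr1 = [g for g in annotation if g.chrom == "chr1"]
    for i in range(config.n_fixture_annotated):
        g = anno_chr1[i % len(anno_chr1)]
        add_both(g.exons, "annotated", g.strand)
    for _ in range(config.n_fixture_too_short):
        add_both(novel_exons(2, 160), "too_short")
    for _ in range(config.n_fixture_single_exon):
        # single-exon transfrags never match across assemblers
        tid = f"T{tno:04d}"
        tno += 1
        set_a.append(TranscriptModel(tid, "chr1", "+", novel_exons(1, 500),
                                     source="assembler_A"))
        labels[tid] = {"class": "single_exon"}

    # reference set = one transcript per annotated gene (for label_by_recovery)
    reference = [
        TranscriptModel(f"{g.gene_id}.t1", g.chrom, g.strand, g.exons,
                        source="reference", gene_id=g.gene_id)
        for g in annotation
    ]

    # coverage table with alternating good/bad labels within category
    biotype_of = {g.gene_id: g.biotype for g in annotation}
    rows = []
    per_category_count = {"coding": 0, "noncoding": 0}
    for t in set_a:
        cls = labels[t.transcript_id]["class"]
        if cls == "coding_like":
            category = "coding"
        elif cls == "annotated":
            g = anno_chr1[[a.exons for a in anno_chr1].index(t.exons)] \
                if t.exons in [a.exons for a in anno_chr1] else None
            category = ("coding" if g is not None and biotype_of[g.gene_id] == CODING
                        else "noncoding")
        else:
            category = "noncoding"
        good = per_category_count[category] % 2 == 0
        per_category_count[category] += 1
        lo, hi = (config.good_coverage_range if good else config.bad_coverage_range)
        rows.append((t.transcript_id, float(rng.uniform(lo, hi)),
                     "good" if good else "bad", category))
        labels[t.transcript_id]["quality"] = "good" if good else "bad"
    coverage = pd.DataFrame(rows, columns=["transcript_id", "coverage",
                                           "label", "category"])

    # per-tool coding-potential calls for the intersect survivors
    call_rows = []
    for t in set_a:
        cls = labels[t.transcript_id]["class"]
        if cls == "coding_like":
            n_coding = int(rng.integers(1, 5))
            calls = ["coding"] * n_coding + ["noncoding"] * (4 - n_coding)
            rng.shuffle(calls)
        else:
            calls = ["noncoding" if rng.random() < config.fixture_call_agreement
                     else "coding" for _ in range(4)]
            if cls == "novel_lnc" and config.fixture_call_agreement >= 1.0:
                calls = ["noncoding"] * 4
        call_rows.append([t.transcript_id] + calls)
    calls_df = pd.DataFrame(call_rows, columns=["transcript_id", "tool_1",
                                                "tool_2", "tool_3", "tool_4"])

    if truth is not None:
        truth.assembly_labels = labels
    return AssemblyFixture(set_a=set_a, set_b=set_b, reference=reference,
                           coverage=coverage, calls=calls_df)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def simulate_all(config: SimConfig):
    """Run the three generators off one generator instance."""
    rng = np.random.default_rng(config.seed)
    annotation, truth = simulate_annotation(config, rng)
    matrix, sheet = simulate_expression(annotation, truth, config, rng)
    fixture = simulate_assembly_fixture(annotation, config, truth, rng)
    return annotation, truth, matrix, sheet, fixture


def write_outputs(outdir: str | Path, config: SimConfig) -> dict[str, Path]:
    """Generate everything and write the plain-text artifact set."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation, truth, matrix, sheet, fixture = simulate_all(config)
    paths = {
        "annotation": outdir / "annotation.gtf",
        "expression": outdir / "expression.tsv",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.json",
        "assembly_a": outdir / "assembly_A.gtf",
        "assembly_b": outdir / "assembly_B.gtf",
        "reference": outdir / "reference.gtf",
        "coverage": outdir / "coverage.tsv",
        "calls": outdir / "coding_calls.tsv",
    }
    write_gene_gtf(annotation, paths["annotation"])
    write_expression(matrix, paths["expression"])
    write_sample_sheet(sheet, paths["samples"])
    paths["truth"].write_text(truth.to_json())
    write_transcript_gtf(fixture.set_a, paths["assembly_a"])
    write_transcript_gtf(fixture.set_b, paths["assembly_b"])
    write_transcript_gtf(fixture.reference, paths["reference"])
    fixture.coverage.to_csv(paths["coverage"], sep="\t", index=False,
                            float_format="%.6g")
    fixture.calls.to_csv(paths["calls"], sep="\t", index=False)
    return paths
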