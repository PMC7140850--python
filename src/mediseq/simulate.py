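"""Synthetic inputs for the pipeline: toy genome, annotation, reads,
ground truth, and proliferation-assay counts.

The simulator emulates a paired two-condition design (n_pairs control
samples vs n_pairs treated samples) of 80-bp single-end reads with
injected duplicates and deliberately non-uniform, spiky per-position
coverage. Spikiness is modeled as gamma-distributed per-position read
start intensities; the intensity profile is drawn once per gene and
shared by all samples, mimicking sequence-driven coverage bias that
reproduces across libraries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import Feature, FeatureModel

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

CONTROL_PREFIX = "Ctr"
TREATED_PREFIX = "ES"


@dataclass(frozen=True)
class SimConfig:
    """Knobs for the read-level simulation.

    Baseline expression values are target median-coverage units: a
    ``low_expr_frac`` slice of genes draws from ``low_expr_range``
    (around or below 5, the regime the fold-change regularizer damps);
    the rest draw from a log-normal around ``expr_median``.
    """

    seed: int = 0
    n_genes: int = 100
    n_pairs: int = 3
    read_length: int = 80
    frac_de: float = 0.1
    true_log2fc: float = 2.0
    frac_down: float = 0.5
    low_expr_frac: float = 0.1
    spikiness: float = 1.0
    dup_rate: float = 2.0
    # gene architecture
    n_exons: int = 2
    exon_length: int = 400
    intron_length: int = 50
    spacer_length: int = 60
    mirna_frac: float = 0.25
    mirna_length: int = 22
    genome_length: int | None = None
    # expression scale: heavy-tailed log-normal baselines (median
    # expr_median, log-sd expr_sigma) for the bulk of genes, uniform
    # low_expr_range for the low-expression slice. The unbounded tail
    # keeps the top of the pooled value distribution dominated by the
    # same genes in every sample, which quantile normalization needs.
    expr_median: float = 40.0
    expr_sigma: float = 1.0
    low_expr_range: tuple[float, float] = (2.0, 5.0)
    # optional floor for the log-normal bulk (baselines below it are
    # redrawn log-uniformly from [floor, 2*floor]); genes under ~10
    # median coverage have integer-quantized medians whose paired-test
    # p-values are discrete, so calibration studies set a floor. The
    # explicit low-expression slice is never floored.
    min_expression: float = 0.0
    # Up-regulated DE genes are planted with baselines inside this band;
    # down-regulated ones inside the band scaled by 2**|true_log2fc|.
    # Treated-column values then re-enter the region the down genes
    # vacate (and vice versa), preserving the globally balanced value
    # distribution that quantile normalization assumes; the floor also
    # keeps effects detectable at the simulated depth.
    de_expression_range: tuple[float, float] = (40.0, 100.0)
    # nuisance structure
    pair_sigma: float = 0.03
    sample_sigma: float = 0.015
    de_on_low_expr: bool = False
    junction_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must lie in [0, 1]")
        if self.read_length < 10:
            raise ValueError("read_length must be >= 10")
        if self.spikiness < 0:
            raise ValueError("spikiness must be >= 0")
        if self.dup_rate < 1:
            raise ValueError("dup_rate must be >= 1 (mean copies per unique read)")
        if self.exon_length < self.read_length:
            raise ValueError("exon_length must accommodate one full read")
        if self.mirna_frac > 0 and self.n_exons < 2:
            raise ValueError("intronic miRNAs require n_exons >= 2")
        if self.mirna_length >= self.intron_length:
            raise ValueError("mirna_length must fit inside an intron")

    @property
    def sample_names(self) -> list[str]:
        return [f"{CONTROL_PREFIX}{i + 1}" for i in range(self.n_pairs)] + [
            f"{TREATED_PREFIX}{i + 1}" for i in range(self.n_pairs)
        ]

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return [
            (f"{CONTROL_PREFIX}{i + 1}", f"{TREATED_PREFIX}{i + 1}")
            for i in range(self.n_pairs)
        ]

    @property
    def gene_span(self) -> int:
        return self.n_exons * self.exon_length + (self.n_exons - 1) * self.intron_length


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length, dtype=np.uint8)]).decode()


def simulate_genome(config: SimConfig) -> tuple[dict[str, str], FeatureModel]:
    """Build a single-contig random genome with evenly laid-out genes.

    Each gene has ``n_exons`` exons separated by introns; a ``mirna_frac``
    subset carries one miRNA nested inside its first intron. With a
    4-letter i.i.d. random sequence of ~1 Mb, every (read_length - 4)-mer
    is unique with overwhelming probability; multi-hit reads are in any
    case routed to the aligner's ``unplaced`` tally.
    """
    rng = np.random.default_rng(config.seed)
    span = config.gene_span
    needed = (
        config.n_genes * span + (config.n_genes + 1) * config.spacer_length
    )
    glen = config.genome_length if config.genome_length is not None else needed
    if glen < needed:
        raise ValueError(
            f"genome_length={glen} too small: {config.n_genes} genes of span "
            f"{span} plus spacers need at least {needed} nt"
        )
    contig = "chr1"
    sequence = _random_sequence(rng, glen)

    features: list[Feature] = []
    mirna_flags = rng.random(config.n_genes) < config.mirna_frac
    pos = config.spacer_length
    for gi in range(config.n_genes):
        gene_id = f"g{gi + 1:05d}"
        cursor = pos
        for ei in range(config.n_exons):
            features.append(
                Feature(
                    f"{gene_id}.exon{ei + 1}", gene_id, "exon", contig,
                    cursor, cursor + config.exon_length,
                )
            )
            cursor += config.exon_length
            if ei < config.n_exons - 1:
                features.append(
                    Feature(
                        f"{gene_id}.intron{ei + 1}", gene_id, "intron", contig,
                        cursor, cursor + config.intron_length,
                    )
                )
                if ei == 0 and mirna_flags[gi]:
                    off = (config.intron_length - config.mirna_length) // 2
                    features.append(
                        Feature(
                            f"mir-{gene_id}", f"mir-{gene_id}", "miRNA", contig,
                            cursor + off, cursor + off + config.mirna_length,
                        )
                    )
                cursor += config.intron_length
        pos = cursor + config.spacer_length

    model = FeatureModel(features, {contig: glen})
    return {contig: sequence}, model


@dataclass
class TruthTable:
    """Ground truth per exon-bearing gene, for recovery tests."""

    table: pd.DataFrame  # index gene_id; is_de, true_log2fc, baseline_expression

    def __post_init__(self) -> None:
        required = {"is_de", "true_log2fc", "baseline_expression"}
        if not required <= set(self.table.columns):
            raise ValueError(f"truth table needs columns {sorted(required)}")
        if self.table.index.duplicated().any():
            raise ValueError("duplicate gene_id in truth table")

    @property
    def de_genes(self) -> list[str]:
        return list(self.table.index[self.table["is_de"]])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "TruthTable":
        return cls(pd.read_csv(path, sep="\t", index_col="gene_id"))


def make_truth(annotation: FeatureModel, config: SimConfig) -> TruthTable:
    """Draw baselines and plant DE flags for every gene in the annotation.

    Exactly ``round(frac_de * n_genes)`` genes are flagged DE, a
    ``frac_down`` share of them down-regulated. Unless ``de_on_low_expr``
    is set, DE genes are drawn from genes with baseline inside
    ``de_expression_range``, so that planted effects are detectable at
    the simulated depth (not damped away by the fold-change regularizer)
    and do not escape the dynamic range spanned by the null genes.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    genes = list(annotation.gene_tracks(span="exon"))
    genes = [g for g in genes if not g.startswith("mir-")]
    n = len(genes)
    n_low = int(round(config.low_expr_frac * n))
    low_idx = rng.choice(n, size=n_low, replace=False)
    is_low = np.zeros(n, dtype=bool)
    is_low[low_idx] = True
    baseline = config.expr_median * np.exp(
        rng.normal(0.0, config.expr_sigma, size=n)
    )
    if config.min_expression > 0:
        under = baseline < config.min_expression
        lo_f = np.log(config.min_expression)
        baseline[under] = np.exp(
            rng.uniform(lo_f, lo_f + np.log(2.0), size=int(under.sum()))
        )
    baseline[is_low] = rng.uniform(*config.low_expr_range, size=n_low)

    de_lo, de_hi = config.de_expression_range
    scale = 2.0 ** abs(config.true_log2fc)
    n_de = int(round(config.frac_de * n))
    n_down = int(round(config.frac_down * n_de))
    n_up = n_de - n_down
    is_de = np.zeros(n, dtype=bool)
    l2fc = np.zeros(n)
    if config.de_on_low_expr:
        de_idx = rng.choice(n, size=n_de, replace=False)
        is_de[de_idx] = True
        sign = np.where(rng.random(n) < config.frac_down, -1.0, 1.0)
        l2fc = np.where(is_de, sign * abs(config.true_log2fc), 0.0)
    else:
        up_pool = np.flatnonzero(~is_low & (baseline >= de_lo) & (baseline <= de_hi))
        down_pool = np.flatnonzero(
            ~is_low & (baseline >= de_lo * scale) & (baseline <= de_hi * scale)
        )
        if n_up > up_pool.size or n_down > down_pool.size:
            raise ValueError(
                f"cannot plant {n_up} up / {n_down} down DE genes: eligible "
                f"pools hold {up_pool.size} / {down_pool.size}; enlarge "
                "n_genes, de_expression_range or expr_sigma"
            )
        up_idx = rng.choice(up_pool, size=n_up, replace=False)
        down_pool = np.setdiff1d(down_pool, up_idx, assume_unique=True)
        down_idx = rng.choice(down_pool, size=n_down, replace=False)
        is_de[up_idx] = True
        is_de[down_idx] = True
        l2fc[up_idx] = abs(config.true_log2fc)
        l2fc[down_idx] = -abs(config.true_log2fc)

    df = pd.DataFrame(
        {"is_de": is_de, "true_log2fc": l2fc, "baseline_expression": baseline},
        index=pd.Index(genes, name="gene_id"),
    )
    return TruthTable(df)


def _gene_start_weights(
    rng: np.random.Generator, exons: list[Feature], read_length: int, spikiness: float
) -> tuple[np.ndarray, np.ndarray]:
    """Valid genomic start positions within this gene's exons and their
    (unnormalized) spiky sampling weights, drawn once per gene."""
    starts = np.concatenate(
        [np.arange(e.start, e.end - read_length + 1) for e in exons]
    )
    if spikiness > 0:
        # mean-1 gamma: variance == spikiness
        weights = rng.gamma(1.0 / spikiness, spikiness, size=starts.size)
        weights += 1e-12
    else:
        weights = np.ones(starts.size)
    return starts, weights


def simulate_read_starts(
    genome: dict[str, str],
    annotation: FeatureModel,
    truth: TruthTable,
    config: SimConfig,
) -> tuple[dict[str, np.ndarray], dict[str, list[str]], str]:
    """Core of the read simulation: per-sample genomic start positions
    (duplicates expanded) plus any junction-read sequences.

    Returns (starts per sample, junction reads per sample, contig name).
    ``simulate_reads`` turns these into sequence lists; the pipeline can
    consume the positions directly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    tracks = annotation.gene_tracks(span="exon")
    genes = list(truth.table.index)
    missing = [g for g in genes if g not in tracks]
    if missing:
        raise ValueError(f"truth table genes missing from annotation: {missing[:3]}")

    samples = config.sample_names
    n_pairs = config.n_pairs
    pair_factor = np.exp(rng.normal(0.0, config.pair_sigma, size=n_pairs))
    sample_factor = np.exp(rng.normal(0.0, config.sample_sigma, size=2 * n_pairs))

    baseline = truth.table["baseline_expression"].to_numpy()
    l2fc = truth.table["true_log2fc"].to_numpy()
    if not np.any(baseline > 0):
        warnings.warn("all genes have zero expression; FASTQ output will be empty")

    contigs = {f.contig for fs in tracks.values() for f in fs}
    if len(contigs) > 1:
        raise NotImplementedError("read simulation expects a single contig")
    contig = next(iter(contigs)) if contigs else next(iter(genome))
    contig_seq = genome[contig]

    start_blocks: dict[str, list[np.ndarray]] = {s: [] for s in samples}
    junctions: dict[str, list[str]] = {s: [] for s in samples}
    rl = config.read_length
    for gi, gene in enumerate(genes):
        exons = [f for f in tracks[gene] if f.category == "exon"]
        starts, weights = _gene_start_weights(rng, exons, rl, config.spikiness)
        prob = weights / weights.sum()
        exon_total = sum(e.length for e in exons)
        base_n = baseline[gi] * exon_total / rl
        for si, sample in enumerate(samples):
            treated = si >= n_pairs
            lam = base_n * pair_factor[si % n_pairs] * sample_factor[si]
            if treated:
                lam *= 2.0 ** l2fc[gi]
            n_frag = rng.poisson(lam)
            if n_frag == 0:
                continue
            frag_starts = rng.choice(starts, size=n_frag, p=prob)
            if config.dup_rate > 1:
                mult = 1 + rng.poisson(config.dup_rate - 1.0, size=n_frag)
                frag_starts = np.repeat(frag_starts, mult)
            start_blocks[sample].append(frag_starts)
            if config.junction_frac > 0 and len(exons) >= 2:
                n_j = rng.poisson(config.junction_frac * n_frag)
                half = rl // 2
                a, b = exons[0], exons[1]
                junctions[sample].extend(
                    contig_seq[a.end - half : a.end]
                    + contig_seq[b.start : b.start + (rl - half)]
                    for _ in range(n_j)
                )
    starts_by_sample = {
        s: np.concatenate(blocks) if blocks else np.empty(0, dtype=np.int64)
        for s, blocks in start_blocks.items()
    }
    return starts_by_sample, junctions, contig


def simulate_reads(
    genome: dict[str, str],
    annotation: FeatureModel,
    truth: TruthTable,
    config: SimConfig,
) -> dict[str, list[str]]:
    """Generate per-sample read lists (duplicates expanded, in order).

    Expected read count per gene scales with its baseline, times
    2**true_log2fc in treated samples for DE genes, times a pair-shared
    lognormal depth offset (making the pairing informative) and a small
    per-sample factor. Duplicate multiplicity per unique fragment is
    1 + Poisson(dup_rate - 1). Reads lie entirely within single exons;
    ``junction_frac`` optionally adds exon-exon junction reads that are
    unplaceable by exact genomic match.
    """
    starts_by_sample, junctions, contig = simulate_read_starts(
        genome, annotation, truth, config
    )
    contig_seq = genome[contig]
    rl = config.read_length
    reads: dict[str, list[str]] = {}
    for sample, starts in starts_by_sample.items():
        reads[sample] = [contig_seq[s : s + rl] for s in starts.tolist()]
        reads[sample].extend(junctions[sample])
    return reads


# -- file output -------------------------------------------------------


def write_fasta(genome: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome):
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: list[str], path, sample: str, quality: str = "I") -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{sample}.{i + 1}\n{seq}\n+\n{quality * len(seq)}\n")


# -- proliferation assay -----------------------------------------------


@dataclass(frozen=True)
class AssayConfig:
    """Design of the synthetic nuclear-count assay.

    Each condition gets ``n_coverslips`` coverslips with
    ``fields_per_coverslip`` imaged fields; EdU+ counts are binomial draws
    out of the field's DAPI+ count at a condition-specific proliferation
    probability ``control_p * multiplier``. When ``paired``, coverslip i
    of every condition shares a logit-scale batch offset with coverslip i
    of the others.
    """

    seed: int = 0
    control_p: float = 0.1
    multipliers: dict[str, float] = field(
        default_factory=lambda: {"sham": 1.0, "ES": 2.0}
    )
    n_coverslips: int = 5
    fields_per_coverslip: int = 9
    mean_dapi: float = 200.0
    pair_sigma: float = 0.25
    paired: bool = True

    def __post_init__(self) -> None:
        for cond, m in self.multipliers.items():
            p = self.control_p * m
            if not 0.0 <= p <= 1.0:
                raise ValueError(
                    f"condition {cond!r}: proliferation probability {p} outside [0, 1]"
                )


def simulate_assay_counts(config: AssayConfig) -> pd.DataFrame:
    """Rows of (coverslip_id, condition, field_index, dapi_count, edu_count)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    offsets = rng.normal(0.0, config.pair_sigma, size=config.n_coverslips)
    rows = []
    for cond, mult in config.multipliers.items():
        base = config.control_p * mult
        logit = np.log(base / (1.0 - base))
        for ci in range(config.n_coverslips):
            off = offsets[ci] if config.paired else rng.normal(0.0, config.pair_sigma)
            p = 1.0 / (1.0 + np.exp(-(logit + off)))
            for fi in range(config.fields_per_coverslip):
                dapi = int(rng.poisson(config.mean_dapi))
                edu = int(rng.binomial(dapi, p)) if dapi > 0 else 0
                rows.append((f"{cond}-cs{ci + 1}", cond, fi + 1, dapi, edu))
    return pd.DataFrame(
        rows,
        columns=["coverslip_id", "condition", "field_index", "dapi_count", "edu_count"],
    )


def simulate_dataset(config: SimConfig, outdir=None):
    """Genome + annotation + truth + reads in one call; optionally write
    FASTA/GFF3/FASTQ/TSV artifacts under ``outdir``."""
    from pathlib import Path

    from .features import write_gff3

    genome, annotation = simulate_genome(config)
    truth = make_truth(annotation, config)
    reads = simulate_reads(genome, annotation, truth, config)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(genome, outdir / "genome.fa")
        write_gff3(annotation, outdir / "features.gff3")
        truth.to_tsv(outdir / "truth.tsv")
        for sample, rs in reads.items():
            write_fastq(rs, outdir / f"{sample}.fastq", sample)
    return genome, annotation, truth, reads
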