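"""Seed-tissue stages: expression binning, siren calling, phasing, methylation
quantification and integrative siRNA24 target prediction.

A protein-coding gene is called a putative siRNA24 target in a region class
(promoter / gene body / downstream) when (i) at least one tissue-expressed
siRNA24 locus overlaps that region by >= 1 bp, (ii) the region's methylation
fraction reaches the tissue's upper-quantile threshold (embryo 20%, endosperm
12% by default, or computed as the upper quartile), and (iii) the gene's own
FPKM in the tissue is <= 2.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .core_io import (
    AlignedRead,
    FeatureRecord,
    GenomicInterval,
    MethylationCall,
)
from .locus_profiler import AnalysisConfig, ExpressionTable, SRNALocus

logger = logging.getLogger(__name__)

REGION_CLASSES = ("promoter", "gene_body", "downstream")


@dataclass(frozen=True)
class GeneExpressionBin:
    gene_id: str
    mean_fpkm: float
    bin: str  # high / medium / low / none


@dataclass(frozen=True)
class MethylationRegionSummary:
    gene_id: str
    region_class: str
    total_cytosines: int
    methylated_cytosines: int

    @property
    def fraction(self) -> float | None:
        if self.total_cytosines == 0:
            return None
        return self.methylated_cytosines / self.total_cytosines


@dataclass(frozen=True)
class TargetCall:
    gene_id: str
    region_class: str
    supporting_loci: tuple[str, ...]
    methylation_fraction: float
    gene_fpkm: float
    tissue: str


def bin_gene_expression(expr: Mapping[str, float]) -> list[GeneExpressionBin]:
    """Bin genes by mean FPKM: >10 high, (2,10] medium, (0,2] low, 0 none."""
    out: list[GeneExpressionBin] = []
    for gene_id, fpkm in expr.items():
        if fpkm < 0:
            raise ValueError(f"gene {gene_id}: negative FPKM {fpkm}")
        if fpkm > 10:
            label = "high"
        elif fpkm > 2:
            label = "medium"
        elif fpkm > 0:
            label = "low"
        else:
            label = "none"
        out.append(GeneExpressionBin(gene_id, fpkm, label))
    return out


def gene_flanks(
    genes: Sequence[FeatureRecord],
    chrom_sizes: Mapping[str, int],
    flank_bp: int = 1000,
) -> dict[str, dict[str, GenomicInterval | None]]:
    """Strand-aware promoter / gene body / downstream regions per gene.

    For minus-strand genes the promoter lies at higher coordinates. Flanks
    are truncated at chromosome edges; a fully truncated flank is None.
    """
    out: dict[str, dict[str, GenomicInterval | None]] = {}
    for gene in genes:
        iv = gene.interval
        size = chrom_sizes[iv.chrom]
        up = _clip(iv.chrom, iv.start - flank_bp, iv.start, iv.strand, size)
        down = _clip(iv.chrom, iv.end, iv.end + flank_bp, iv.strand, size)
        if iv.strand == "-":
            promoter, downstream = down, up
        else:
            promoter, downstream = up, down
        out[gene.feature_id] = {
            "promoter": promoter,
            "gene_body": iv,
            "downstream": downstream,
        }
    return out


def _clip(chrom: str, start: int, end: int, strand: str, size: int):
    start = max(0, start)
    end = min(size, end)
    if end <= start:
        return None
    return GenomicInterval(chrom, start, end, strand)


class MethylationIndex:
    """Per-chromosome position-sorted methylated-call index."""

    def __init__(self, calls: Iterable[MethylationCall]):
        by_chrom: dict[str, list[int]] = {}
        for c in calls:
            if c.methylated:
                by_chrom.setdefault(c.chrom, []).append(c.pos)
        self._pos = {chrom: sorted(ps) for chrom, ps in by_chrom.items()}

    def count_in(self, interval: GenomicInterval) -> int:
        pos = self._pos.get(interval.chrom)
        if not pos:
            return 0
        return bisect_left(pos, interval.end) - bisect_left(pos, interval.start)


def methylation_fraction(
    region: GenomicInterval,
    genome: Mapping[str, str],
    calls: MethylationIndex | Iterable[MethylationCall],
    gene_id: str = "",
    region_class: str = "",
) -> MethylationRegionSummary:
    """Fraction of methylated cytosines over all cytosines in the region.

    Cytosines on both strands count: the denominator is the number of C plus
    G bases in the region's plus-strand sequence. A region without cytosines
    yields fraction None (missing), never 0.
    """
    seq = genome[region.chrom][region.start : region.end]
    total_c = seq.count("C") + seq.count("G")
    index = calls if isinstance(calls, MethylationIndex) else MethylationIndex(calls)
    methylated = index.count_in(region) if total_c else 0
    return MethylationRegionSummary(
        gene_id=gene_id,
        region_class=region_class,
        total_cytosines=total_c,
        methylated_cytosines=methylated,
    )


def call_sirens(
    loci: Sequence[SRNALocus],
    table: ExpressionTable,
    samples,
    tissue: str,
    config: AnalysisConfig | None = None,
    sirna_class: int = 21,
) -> set[str]:
    """Siren loci: siRNA<class> loci whose mean FPKM over the tissue's
    replicates exceeds 10**siren_log10_fpkm (~177.8 by default)."""
    config = config or AnalysisConfig()
    reps = samples.samples_for_tissue(tissue)
    if not reps:
        raise ValueError(f"no replicates for tissue {tissue!r}")
    threshold = 10 ** config.siren_log10_fpkm
    label = f"siRNA{sirna_class}"
    out: set[str] = set()
    for locus in loci:
        if locus.class_label != label or locus.locus_id not in table.fpkm.index:
            continue
        if float(table.fpkm.loc[locus.locus_id, reps].mean()) > threshold:
            out.add(locus.locus_id)
    return out


def phasing_fraction(
    reads: Sequence[AlignedRead],
    phase: int = 21,
    register_threshold: float = 0.5,
    min_reads: int = 10,
) -> tuple[float, bool] | None:
    """Max-register fraction of read 5' ends modulo the phase length.

    Implementation-defined stand-in for a phasing caller: the fraction is the
    largest share of reads whose 5' start falls in a single register modulo
    ``phase``; the locus is phased when it reaches ``register_threshold``.
    Returns None (excluded) below ``min_reads``.
    """
    if len(reads) < min_reads:
        return None
    registers = Counter()
    for r in reads:
        five_prime = r.interval.start if r.interval.strand != "-" else r.interval.end - 1
        registers[five_prime % phase] += 1
    frac = max(registers.values()) / len(reads)
    return frac, frac >= register_threshold


def chi_square_2x2(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table, no continuity correction, df=1."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if (obs < 0).any():
        raise ValueError("negative cell counts")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    n = obs.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero margin")
    expected = np.outer(row, col) / n
    statistic = float(((obs - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(statistic, df=1))
    return statistic, p


def quantile_methylation_threshold(
    fractions: Sequence[float], quantile: float = 0.75
) -> float:
    """Upper-quantile threshold computed from a methylation distribution."""
    if not len(fractions):
        raise ValueError("no methylation fractions")
    return float(np.quantile(np.asarray(fractions, dtype=float), quantile))


def predict_targets(
    sirna24_loci: Sequence[SRNALocus],
    expressed_ids: set[str],
    flanks: Mapping[str, Mapping[str, GenomicInterval | None]],
    gene_fpkm: Mapping[str, float],
    methylation: Mapping[tuple[str, str], MethylationRegionSummary],
    tissue: str,
    config: AnalysisConfig | None = None,
) -> list[TargetCall]:
    """Integrative siRNA24 target prediction (see module docstring).

    ``methylation`` maps (gene_id, region_class) to a region summary; regions
    with a missing summary or no cytosines are skipped with a warning. Genes
    may appear under several region classes.
    """
    config = config or AnalysisConfig()
    threshold = config.methylation_quantile.get(tissue)
    if threshold is None:
        raise ValueError(f"no methylation quantile configured for {tissue!r}")
    active = [l for l in sirna24_loci
              if l.locus_id in expressed_ids and l.class_label == "siRNA24"]
    calls: list[TargetCall] = []
    for gene_id in sorted(flanks):
        fpkm = gene_fpkm.get(gene_id)
        if fpkm is None:
            continue
        for region_class in REGION_CLASSES:
            region = flanks[gene_id][region_class]
            if region is None:
                continue
            support = tuple(
                l.locus_id for l in active if l.interval.overlaps(region)
            )
            if not support:
                continue
            summary = methylation.get((gene_id, region_class))
            if summary is None or summary.fraction is None:
                logger.warning(
                    "no methylation summary for %s %s; region skipped",
                    gene_id, region_class,
                )
                continue
            if summary.fraction < threshold:
                continue
            if fpkm > config.fpkm_expressed:
                continue
            calls.append(
                TargetCall(
                    gene_id=gene_id,
                    region_class=region_class,
                    supporting_loci=support,
                    methylation_fraction=summary.fraction,
                    gene_fpkm=fpkm,
                    tissue=tissue,
                )
            )
    return calls


class StageError(RuntimeError):
    """Pipeline failure annotated with the stage that raised it."""


def run_seed_pipeline(
    input_dir: str | Path,
    output_dir: str | Path,
    config: AnalysisConfig | None = None,
) -> dict:
    """Run quantification -> classification -> expressed calls -> siren calling
    -> flank/methylation computation -> target prediction on a dataset
    directory written by the synthetic generator (or matching its layout).

    Writes loci GFF3 and TSV reports to ``output_dir`` plus a run log with
    the configuration; outputs are deterministic for identical inputs.
    """
    from . import core_io
    from .locus_profiler import (
        classify_locus,
        cluster_reads,
        call_expressed,
        expression_table_from_loci,
        write_counts_tsv,
        write_expression_tsv,
    )

    config = config or AnalysisConfig()
    input_dir = Path(input_dir)
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)

    def stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(f"stage '{name}' failed: {exc}") from exc

    genome = stage("load_genome", core_io.read_fasta, input_dir / "genome.fa")
    chrom_sizes = {c: len(s) for c, s in genome.items()}
    features = stage(
        "load_features", core_io.parse_features, input_dir / "features.gff3",
        "gff3", chrom_sizes=chrom_sizes,
    )
    samples = stage("load_samples", core_io.load_sample_table, input_dir / "samples.tsv")
    reads = stage(
        "load_reads", core_io.load_read_alignments, input_dir / "reads.tsv", samples
    )
    meth_path = input_dir / "methylation.tsv"
    if not meth_path.exists():
        raise StageError(f"stage 'load_methylation' failed: missing {meth_path}")
    calls = stage("load_methylation", core_io.load_methylation_calls, meth_path)
    expr_path = input_dir / "gene_expression.tsv"
    if not expr_path.exists():
        raise StageError(f"stage 'load_gene_expression' failed: missing {expr_path}")
    import pandas as pd

    gene_expr = stage(
        "load_gene_expression", pd.read_csv, expr_path, sep="\t", index_col="gene_id"
    )

    loci = stage("cluster_reads", cluster_reads, reads, samples, config)
    for locus in loci:
        stage("classify_locus", classify_locus, locus, config)
    table = stage("quantify", expression_table_from_loci, loci, samples)
    expressed = stage("call_expressed", call_expressed, table, samples, config)
    sirens = stage(
        "call_sirens", call_sirens, loci, table, samples, "endosperm", config, 21
    )

    genes = [f for f in features if f.feature_type == "gene"]
    flanks = stage("gene_flanks", gene_flanks, genes, chrom_sizes, config.flank_bp)
    index = MethylationIndex(calls)
    summaries: dict[tuple[str, str], MethylationRegionSummary] = {}
    for gene in genes:
        for region_class in REGION_CLASSES:
            region = flanks[gene.feature_id][region_class]
            if region is None:
                continue
            summaries[(gene.feature_id, region_class)] = stage(
                "methylation_fraction", methylation_fraction,
                region, genome, index, gene.feature_id, region_class,
            )

    sirna24 = [l for l in loci if l.class_label == "siRNA24"]
    targets: dict[str, list[TargetCall]] = {}
    for tissue in ("embryo", "endosperm"):
        if tissue not in samples.tissues or tissue not in gene_expr.columns:
            continue
        fpkm = gene_expr[tissue].to_dict()
        targets[tissue] = stage(
            "predict_targets", predict_targets,
            sirna24, expressed.get(tissue, set()), flanks, fpkm,
            summaries, tissue, config,
        )

    # --- outputs (no timestamps: reruns must be byte-identical) ---------------
    core_io.write_locus_gff3(loci, output_dir / "loci.gff3")
    write_counts_tsv(table, output_dir / "counts.tsv")
    write_expression_tsv(table, output_dir / "fpkm.tsv")
    with open(output_dir / "expressed.tsv", "w") as fh:
        fh.write("tissue\tlocus_id\n")
        for tissue in sorted(expressed):
            for lid in sorted(expressed[tissue]):
                fh.write(f"{tissue}\t{lid}\n")
    with open(output_dir / "sirens.tsv", "w") as fh:
        fh.write("locus_id\n")
        for lid in sorted(sirens):
            fh.write(f"{lid}\n")
    with open(output_dir / "methylation_summary.tsv", "w") as fh:
        fh.write("gene_id\tregion_class\ttotal_cytosines\tmethylated\tfraction\n")
        for (gid, rc) in sorted(summaries):
            s = summaries[(gid, rc)]
            frac = "NA" if s.fraction is None else f"{s.fraction:.6f}"
            fh.write(f"{gid}\t{rc}\t{s.total_cytosines}\t"
                     f"{s.methylated_cytosines}\t{frac}\n")
    for tissue, calls_t in targets.items():
        write_targets_tsv(calls_t, output_dir / f"targets_{tissue}.tsv")
    with open(output_dir / "run_log.txt", "w") as fh:
        fh.write("srnaland seed pipeline\n")
        fh.write(f"input_dir: {input_dir.name}\n")
        for key, value in sorted(vars(config).items()):
            fh.write(f"config.{key}: {value}\n")
        fh.write(f"n_loci: {len(loci)}\n")
        fh.write(f"n_sirens: {len(sirens)}\n")
        for tissue, calls_t in sorted(targets.items()):
            fh.write(f"n_targets_{tissue}: {len(calls_t)}\n")

    return {
        "loci": loci,
        "table": table,
        "expressed": expressed,
        "sirens": sirens,
        "flanks": flanks,
        "methylation": summaries,
        "targets": targets,
    }


def write_targets_tsv(calls: Sequence[TargetCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tregion_class\ttissue\tmethylation_fraction\t"
                 "gene_fpkm\tsupporting_loci\n")
        for c in calls:
            fh.write(
                f"{c.gene_id}\t{c.region_class}\t{c.tissue}\t"
                f"{c.methylation_fraction:.6f}\t{c.gene_fpkm:.6f}\t"
                f"{','.join(c.supporting_loci)}\n"
            )
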