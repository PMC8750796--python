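"""Small-RNA locus calling, classification and expression filtering.

Loci are called by merging nearby read placements (strand-agnostic, default
merge gap 75 nt) and discarding clusters below a pooled reads-per-million
coverage floor. Each locus is then classified by the fraction of its reads in
the 20-24 nt window: >= 80% means the locus is treated as Dicer-processed and
labelled siRNA<x> after its modal read length; anything else is OtherRNA.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_io import AlignedRead, FeatureRecord, GenomicInterval, SampleTable

DCL_MIN_LEN = 20
DCL_MAX_LEN = 24


@dataclass
class AnalysisConfig:
    """Numeric thresholds used across the pipeline."""

    fpkm_expressed: float = 2.0
    dcl_fraction: float = 0.8
    min_rpm: float = 0.5
    cluster_merge_gap: int = 75
    siren_log10_fpkm: float = 2.25
    flank_bp: int = 1000
    n_permutations: int = 1000
    methylation_quantile: dict[str, float] = field(
        default_factory=lambda: {"embryo": 0.20, "endosperm": 0.12}
    )
    trf_len: tuple[int, int] = (14, 30)
    tir_len: tuple[int, int] = (31, 40)
    trailer_bp: int = 40
    novel_min_samples: int = 2
    ncrna_overlap_fraction: float = 0.5
    known_locus_overlap_fraction: float = 1.0
    # anchor of the ncRNA 50%-overlap rule: 'feature' (default) or 'candidate'
    ncrna_overlap_anchor: str = "feature"
    phasing_min_reads: int = 10
    phasing_register_threshold: float = 0.5
    phasing_phase: int = 21
    # whether the 3' anchor of tRF-3/3tiR is the final CCA base ('cca')
    # or the final genomic base ('genomic')
    tsrna_three_prime_anchor: str = "cca"

    def __post_init__(self) -> None:
        for name in ("fpkm_expressed", "dcl_fraction", "min_rpm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("dcl_fraction", "ncrna_overlap_fraction",
                     "known_locus_overlap_fraction"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass
class SRNALocus:
    """A called sRNA cluster with its read-length histogram and counts."""

    locus_id: str
    interval: GenomicInterval
    length_histogram: dict[int, int]
    per_sample_counts: dict[str, int]
    class_label: str = "unclassified"
    major_rna: str = ""

    @property
    def total_reads(self) -> int:
        return sum(self.per_sample_counts.values())


@dataclass
class ExpressionTable:
    """Raw counts and FPKM per locus x sample, plus the normalization inputs."""

    counts: pd.DataFrame  # loci x samples, int
    fpkm: pd.DataFrame  # loci x samples, float
    locus_lengths: pd.Series  # nt per locus
    library_sizes: pd.Series  # mapped reads per sample

    @property
    def locus_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def coverage_floor(min_rpm: float, total_mapped_pooled: int) -> int:
    """Minimum pooled read count for a cluster to be kept.

    0.5 reads per million over ~14M mapped reads gives 7, matching the
    floor implied by requiring 0.5 RPM coverage.
    """
    return math.ceil(min_rpm * total_mapped_pooled / 1e6)


def cluster_reads(
    reads: Sequence[AlignedRead],
    samples: SampleTable,
    config: AnalysisConfig | None = None,
) -> list[SRNALocus]:
    """Merge reads into loci and drop clusters below the coverage floor.

    Reads on the same chromosome whose intervals are separated by at most
    ``cluster_merge_gap`` nt merge into one locus, strand-agnostically. The
    locus interval spans the min start to the max end of its member reads.
    """
    config = config or AnalysisConfig()
    if not reads:
        return []
    floor = coverage_floor(config.min_rpm, samples.total_mapped_pooled())

    by_chrom: dict[str, list[AlignedRead]] = defaultdict(list)
    for r in reads:
        by_chrom[r.interval.chrom].append(r)

    loci: list[SRNALocus] = []
    for chrom in sorted(by_chrom):
        chrom_reads = sorted(by_chrom[chrom], key=lambda r: (r.interval.start, r.interval.end))
        cluster: list[AlignedRead] = []
        cluster_end = -1
        for r in chrom_reads:
            if cluster and r.interval.start - cluster_end > config.cluster_merge_gap:
                loci.append(_make_locus(chrom, cluster))
                cluster = []
            cluster.append(r)
            cluster_end = max(cluster_end, r.interval.end)
        if cluster:
            loci.append(_make_locus(chrom, cluster))

    loci = [l for l in loci if l.total_reads >= floor]
    for i, locus in enumerate(loci):
        locus.locus_id = f"SL{i + 1:06d}"
    return loci


def _make_locus(chrom: str, cluster: list[AlignedRead]) -> SRNALocus:
    start = min(r.interval.start for r in cluster)
    end = max(r.interval.end for r in cluster)
    hist: Counter[int] = Counter(r.length for r in cluster)
    per_sample: Counter[str] = Counter(r.sample_id for r in cluster)
    seq_counts: Counter[str] = Counter(r.sequence for r in cluster)
    # most abundant read sequence; ties broken lexicographically for determinism
    major = min(seq_counts, key=lambda s: (-seq_counts[s], s))
    return SRNALocus(
        locus_id="",
        interval=GenomicInterval(chrom, start, end, "."),
        length_histogram=dict(sorted(hist.items())),
        per_sample_counts=dict(sorted(per_sample.items())),
        major_rna=major,
    )


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_histogram(length_histogram: Mapping[int, int],
                       config: AnalysisConfig | None = None) -> str:
    """Label a read-length histogram: siRNA<modal length> or OtherRNA.

    A locus is Dicer-like when >= ``dcl_fraction`` (default 0.8) of its reads
    are 20-24 nt; the label uses the modal length within that window, ties
    broken toward the longer length.
    """
    config = config or AnalysisConfig()
    total = sum(length_histogram.values())
    if total == 0:
        raise ValueError("empty length histogram")
    window = {
        l: c for l, c in length_histogram.items() if DCL_MIN_LEN <= l <= DCL_MAX_LEN
    }
    in_window = sum(window.values())
    if in_window / total < config.dcl_fraction:
        return "OtherRNA"
    modal = max(window, key=lambda l: (window[l], l))
    return f"siRNA{modal}"


def classify_locus(locus: SRNALocus, config: AnalysisConfig | None = None) -> str:
    label = classify_histogram(locus.length_histogram, config)
    locus.class_label = label
    return label


def apply_known_mirna_labels(
    loci: Iterable[SRNALocus], known_mirna: Iterable[FeatureRecord]
) -> None:
    """Pass-through miRNA labelling: a locus fully contained in an annotated
    miRNA feature keeps the label ``known_miRNA`` (no hairpin evaluation)."""
    mirna = [f for f in known_mirna
             if f.attributes.get("class", "") in ("miRNA", "known_miRNA")]
    for locus in loci:
        for feat in mirna:
            if feat.interval.contains(locus.interval):
                locus.class_label = "known_miRNA"
                break


# ---------------------------------------------------------------------------
# Quantification and filtering
# ---------------------------------------------------------------------------

def compute_fpkm(
    counts: pd.DataFrame,
    locus_lengths: Mapping[str, int] | pd.Series,
    library_sizes: Mapping[str, int] | pd.Series,
) -> ExpressionTable:
    """FPKM = count / (locus length in kb * library size in millions)."""
    lengths = pd.Series(locus_lengths).reindex(counts.index)
    libs = pd.Series(library_sizes).reindex(counts.columns)
    if (lengths <= 0).any():
        bad = lengths[lengths <= 0].index.tolist()
        raise ValueError(f"zero-length loci: {bad}")
    if (libs <= 0).any():
        raise ValueError("library sizes must be > 0")
    kb = lengths.astype(float) / 1e3
    millions = libs.astype(float) / 1e6
    fpkm = counts.astype(float).div(kb, axis=0).div(millions, axis=1)
    return ExpressionTable(
        counts=counts, fpkm=fpkm, locus_lengths=lengths, library_sizes=libs
    )


def expression_table_from_loci(
    loci: Sequence[SRNALocus], samples: SampleTable
) -> ExpressionTable:
    counts = pd.DataFrame(
        0, index=[l.locus_id for l in loci], columns=samples.sample_ids, dtype=int
    )
    for locus in loci:
        for sid, c in locus.per_sample_counts.items():
            counts.loc[locus.locus_id, sid] = c
    lengths = {l.locus_id: len(l.interval) for l in loci}
    libs = {s.sample_id: s.total_mapped for s in samples}
    return compute_fpkm(counts, lengths, libs)


def call_expressed(
    table: ExpressionTable,
    samples: SampleTable,
    config: AnalysisConfig | None = None,
) -> dict[str, set[str]]:
    """Per tissue: loci with FPKM strictly greater than the cutoff in every replicate."""
    config = config or AnalysisConfig()
    out: dict[str, set[str]] = {}
    for tissue in samples.tissues:
        reps = samples.samples_for_tissue(tissue)
        sub = table.fpkm[reps]
        mask = (sub > config.fpkm_expressed).all(axis=1)
        out[tissue] = set(sub.index[mask])
    return out


def filter_novel_loci(
    candidates: Sequence[SRNALocus],
    ncrna: Sequence[FeatureRecord],
    known_srna: Sequence[FeatureRecord],
    table: ExpressionTable,
    config: AnalysisConfig | None = None,
) -> list[SRNALocus]:
    """Keep candidate loci that are novel and expressed.

    Removes candidates overlapping an annotated ncRNA (rRNA/tRNA/snRNA/snoRNA)
    by >= 50% of the anchor length (the ncRNA feature by default), candidates
    fully contained within a known sRNA locus, and candidates without FPKM > 2
    in at least ``novel_min_samples`` samples (samples, not tissues).
    """
    config = config or AnalysisConfig()
    nc_types = {"rRNA", "tRNA", "snRNA", "snoRNA"}
    nc_feats = [f for f in ncrna if f.feature_type in nc_types]
    kept: list[SRNALocus] = []
    for cand in candidates:
        if _hits_ncrna(cand, nc_feats, config):
            continue
        if any(k.interval.contains(cand.interval) for k in known_srna):
            continue
        if cand.locus_id in table.fpkm.index:
            n_expr = int((table.fpkm.loc[cand.locus_id] > config.fpkm_expressed).sum())
            if n_expr < config.novel_min_samples:
                continue
        else:
            continue
        kept.append(cand)
    return kept


def _hits_ncrna(cand: SRNALocus, nc_feats: Sequence[FeatureRecord],
                config: AnalysisConfig) -> bool:
    for feat in nc_feats:
        inter = cand.interval.overlap_length(feat.interval)
        if inter == 0:
            continue
        anchor_len = (
            len(feat.interval)
            if config.ncrna_overlap_anchor == "feature"
            else len(cand.interval)
        )
        if inter / anchor_len >= config.ncrna_overlap_fraction:
            return True
    return False


def call_tissue_specific(
    table: ExpressionTable,
    groups: Mapping[str, Sequence[str]],
    config: AnalysisConfig | None = None,
) -> dict[str, set[str]]:
    """Per group: loci with FPKM > 2 in every sample of the group and a raw
    read count of zero in every sample outside the group.

    Groups may pool tissues (e.g. root = vegetative + generative root, or
    'embryo + endosperm'); membership in a pooled group does not imply
    membership in its single-tissue subsets.
    """
    config = config or AnalysisConfig()
    all_samples = list(table.counts.columns)
    out: dict[str, set[str]] = {}
    for group, members in groups.items():
        members = list(members)
        others = [s for s in all_samples if s not in members]
        expr = (table.fpkm[members] > config.fpkm_expressed).all(axis=1)
        if others:
            silent = (table.counts[others] == 0).all(axis=1)
        else:
            silent = pd.Series(True, index=table.counts.index)
        out[group] = set(table.counts.index[expr & silent])
    return out


# ---------------------------------------------------------------------------
# Read profiling
# ---------------------------------------------------------------------------

def profile_reads(
    reads: Sequence[AlignedRead],
) -> tuple[dict[int, int], dict[int, dict[str, float]]]:
    """Read-length distribution and 5'-nucleotide frequencies per length.

    Returns ``(length_counts, five_prime_freq)`` where ``five_prime_freq[l]``
    maps each 5' nucleotide of length-l reads to its frequency (sums to 1).
    """
    length_counts: Counter[int] = Counter()
    nt_counts: dict[int, Counter[str]] = defaultdict(Counter)
    for r in reads:
        length_counts[r.length] += 1
        nt_counts[r.length][r.sequence[0]] += 1
    freqs: dict[int, dict[str, float]] = {}
    for length, counter in nt_counts.items():
        total = sum(counter.values())
        freqs[length] = {nt: c / total for nt, c in sorted(counter.items())}
    return dict(sorted(length_counts.items())), dict(sorted(freqs.items()))


def write_expression_tsv(table: ExpressionTable, path) -> None:
    df = table.fpkm.round(6)
    df.to_csv(path, sep="\t", index_label="locus_id")


def write_counts_tsv(table: ExpressionTable, path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="locus_id")
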