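"""tRNA-derived small RNA identification and classification.

A dual reference is built per tRNA: the mature sequence (genomic span,
strand-aware, with the post-transcriptional 3' CCA appended) and the primary
sequence (genomic span extended 40 nt upstream and downstream, no CCA).
Reads of 14-40 nt are matched as exact, full-length substrings of either
reference and classified by position:

  - starts at mature base 1            -> tRF-5 (14-30 nt) or 5tiR (31-40 nt)
  - ends at the final mature(+CCA) base -> tRF-3 (14-30 nt) or 3tiR (31-40 nt)
  - entirely inside the 40-nt 3' trailer of the primary, 14-30 nt -> tRF-1

Exact matches that satisfy none of the positional rules (internal fragments)
are discarded. A read matching both anchors is assigned by the 5' anchor.
Matching is sense-strand only.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core_io import (
    FeatureRecord,
    GenomicInterval,
    SampleTable,
    extract_sequence,
)
from .locus_profiler import AnalysisConfig, ExpressionTable

TS_CLASSES = ("tRF-5", "tRF-3", "tRF-1", "5tiR", "3tiR")
READ_WINDOW = (14, 40)


@dataclass(frozen=True)
class TRNAReference:
    """Mature (+CCA) and primary (flanked, no CCA) sequences for one tRNA."""

    trna_id: str
    label: str  # amino acid + anticodon, free text
    mature_seq: str
    primary_seq: str
    mature_offset: int  # start of the genomic tRNA span within primary_seq
    trailer_bp: int = 40

    @property
    def span_length(self) -> int:
        """Length of the annotated genomic tRNA span (mature without CCA)."""
        return len(self.mature_seq) - 3

    @property
    def trailer_start(self) -> int:
        return self.mature_offset + self.span_length

    @property
    def trailer_seq(self) -> str:
        return self.primary_seq[self.trailer_start : self.trailer_start + self.trailer_bp]


@dataclass(frozen=True)
class TsRNAHit:
    read_id: str
    trna_id: str  # first supporting tRNA
    all_trna_ids: tuple[str, ...]  # every reference supporting the class
    match_start: int  # offset within mature (or primary for tRF-1)
    match_end: int
    length: int
    ts_class: str
    five_prime_nt: str
    reference_space: str  # 'mature' or 'primary'


@dataclass(frozen=True)
class TsRNAAbundance:
    sample_id: str
    trna_fraction: float  # tRNA-derived / all 14-40 nt reads
    mean_reference_fraction: float
    normalized: float
    log2fc: float


def build_trna_reference(
    genome: Mapping[str, str],
    trna_features: Sequence[FeatureRecord],
    flank_bp: int = 40,
) -> list[TRNAReference]:
    """Extract mature(+CCA) and flank-extended primary sequences per tRNA.

    Minus-strand tRNAs are reverse-complemented before extension, so both
    sequences are in transcript orientation. A tRNA without ``flank_bp`` of
    room on its chromosome is an error naming the tRNA.
    """
    refs: list[TRNAReference] = []
    for feat in trna_features:
        if feat.feature_type != "tRNA":
            continue
        iv = feat.interval
        chrom_len = len(genome[iv.chrom])
        if iv.start - flank_bp < 0 or iv.end + flank_bp > chrom_len:
            raise ValueError(
                f"tRNA {feat.feature_id}: {flank_bp} nt flank exceeds "
                f"chromosome {iv.chrom} bounds"
            )
        span = extract_sequence(genome, iv)
        extended = GenomicInterval(iv.chrom, iv.start - flank_bp, iv.end + flank_bp, iv.strand)
        primary = extract_sequence(genome, extended)
        refs.append(
            TRNAReference(
                trna_id=feat.feature_id,
                label=feat.attributes.get("label", feat.feature_id),
                mature_seq=span + "CCA",
                primary_seq=primary,
                mature_offset=flank_bp,
                trailer_bp=flank_bp,
            )
        )
    return refs


def _find_all(haystack: str, needle: str) -> list[int]:
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def _classes_for_read(seq: str, ref: TRNAReference,
                      config: AnalysisConfig) -> list[tuple[str, int, int, str]]:
    """All (class, start, end, space) assignments of one read on one reference."""
    out: list[tuple[str, int, int, str]] = []
    L = len(seq)
    trf_lo, trf_hi = config.trf_len
    tir_lo, tir_hi = config.tir_len
    mature = ref.mature_seq
    if config.tsrna_three_prime_anchor == "cca":
        three_prime_end = len(mature)
    else:
        three_prime_end = len(mature) - 3
    for pos in _find_all(mature, seq):
        if pos == 0:
            if trf_lo <= L <= trf_hi:
                out.append(("tRF-5", 0, L, "mature"))
            elif tir_lo <= L <= tir_hi:
                out.append(("5tiR", 0, L, "mature"))
        if pos + L == three_prime_end:
            if trf_lo <= L <= trf_hi:
                out.append(("tRF-3", pos, pos + L, "mature"))
            elif tir_lo <= L <= tir_hi:
                out.append(("3tiR", pos, pos + L, "mature"))
    if trf_lo <= L <= trf_hi:
        for pos in _find_all(ref.primary_seq, seq):
            if pos >= ref.trailer_start and pos + L <= ref.trailer_start + ref.trailer_bp:
                out.append(("tRF-1", pos, pos + L, "primary"))
    return out


# 5'-anchored classes take precedence over 3'-anchored, then trailer.
_CLASS_PRIORITY = {"tRF-5": 0, "5tiR": 0, "tRF-3": 1, "3tiR": 1, "tRF-1": 2}


def classify_tsrna_read(
    read,
    refs: Sequence[TRNAReference],
    config: AnalysisConfig | None = None,
) -> TsRNAHit | None:
    """Classify one read against the tRNA reference set; None means no hit.

    Accepts an AlignedRead or a plain sequence string. Reads outside the
    14-40 nt window are never candidates. A read matching several tRNAs
    counts once; the hit records all tRNA ids supporting the assigned class.
    """
    seq = read if isinstance(read, str) else read.sequence
    read_id = "" if isinstance(read, str) else read.read_id
    config = config or AnalysisConfig()
    if not READ_WINDOW[0] <= len(seq) <= READ_WINDOW[1]:
        return None
    best: tuple[str, int, int, str] | None = None
    supporting: list[str] = []
    for ref in refs:
        for assignment in _classes_for_read(seq, ref, config):
            if best is None or _CLASS_PRIORITY[assignment[0]] < _CLASS_PRIORITY[best[0]]:
                best = assignment
                supporting = [ref.trna_id]
            elif assignment[0] == best[0] and ref.trna_id not in supporting:
                supporting.append(ref.trna_id)
    if best is None:
        return None
    ts_class, start, end, space = best
    return TsRNAHit(
        read_id=read_id,
        trna_id=supporting[0],
        all_trna_ids=tuple(supporting),
        match_start=start,
        match_end=end,
        length=len(seq),
        ts_class=ts_class,
        five_prime_nt=seq[0],
        reference_space=space,
    )


def positional_profiles(
    hits: Sequence[TsRNAHit], refs: Sequence[TRNAReference]
) -> tuple[dict[int, int], dict[int, int]]:
    """Start and end histograms of hits in tRNA-relative coordinates.

    Starts are 1-based positions on the mature reference (tRF-5/5tiR mass sits
    at 1); trailer hits are mapped past the mature 3' end. Ends are recorded
    as distance from the final mature(+CCA) base (0 = final base, so the
    tRF-3/3tiR mass sits at 0; trailer hits get negative distances).
    """
    ref_by_id = {r.trna_id: r for r in refs}
    starts: Counter[int] = Counter()
    ends: Counter[int] = Counter()
    for hit in hits:
        ref = ref_by_id[hit.trna_id]
        if hit.reference_space == "mature":
            starts[hit.match_start + 1] += 1
            ends[len(ref.mature_seq) - hit.match_end] += 1
        else:  # trailer hit, primary coordinates
            offset_in_trailer = hit.match_start - ref.trailer_start
            starts[ref.span_length + offset_in_trailer + 1] += 1
            end_in_trailer = hit.match_end - ref.trailer_start
            # trailer base b sits (b - 3) bases past the final CCA base
            ends[3 - end_in_trailer] += 1
    return dict(sorted(starts.items())), dict(sorted(ends.items()))


def select_reference_loci(table: ExpressionTable, k: int = 4) -> list[str]:
    """Pick the k most stably expressed loci as normalization references.

    Eligible loci have FPKM > 2 in every sample; among them the k with the
    lowest coefficient of variation of FPKM win, ties broken by locus id.
    """
    eligible = table.fpkm.index[(table.fpkm > 2.0).all(axis=1)]
    if len(eligible) < k:
        raise ValueError(
            f"only {len(eligible)} loci have FPKM > 2 in all samples; need {k}"
        )
    sub = table.fpkm.loc[eligible]
    cv = sub.std(axis=1, ddof=1) / sub.mean(axis=1)
    ranked = sorted(eligible, key=lambda l: (cv[l], l))
    return ranked[:k]


def tsrna_abundance(
    trna_read_counts: Mapping[str, int],
    window_read_counts: Mapping[str, int],
    reference_fractions: Mapping[str, Sequence[float]],
    samples: SampleTable,
    baseline_tissue: str,
) -> dict[str, TsRNAAbundance]:
    """Reference-normalized tsRNA abundance per sample with log2FC vs baseline.

    ``reference_fractions[sample]`` holds, per reference locus, the fraction
    of the sample's 14-40 nt reads falling inside that locus. The normalized
    statistic divides the sample's tRNA-derived fraction by the mean reference
    fraction; log2FC compares against the mean normalized value over the
    baseline tissue's replicates.
    """
    baseline_samples = samples.samples_for_tissue(baseline_tissue)
    if not baseline_samples:
        raise ValueError(f"no samples for baseline tissue {baseline_tissue!r}")
    normalized: dict[str, float] = {}
    fractions: dict[str, float] = {}
    mean_refs: dict[str, float] = {}
    for sid in trna_read_counts:
        total = window_read_counts[sid]
        if total <= 0:
            raise ValueError(f"sample {sid}: zero 14-40 nt read total")
        ref_fracs = list(reference_fractions[sid])
        mean_ref = float(np.mean(ref_fracs))
        if mean_ref <= 0:
            raise ValueError(f"sample {sid}: zero reference fraction")
        frac = trna_read_counts[sid] / total
        fractions[sid] = frac
        mean_refs[sid] = mean_ref
        normalized[sid] = frac / mean_ref
    baseline_mean = float(np.mean([normalized[s] for s in baseline_samples]))
    out: dict[str, TsRNAAbundance] = {}
    for sid, norm in normalized.items():
        log2fc = math.log2(norm / baseline_mean) if norm > 0 else float("-inf")
        out[sid] = TsRNAAbundance(
            sample_id=sid,
            trna_fraction=fractions[sid],
            mean_reference_fraction=mean_refs[sid],
            normalized=norm,
            log2fc=log2fc,
        )
    return out


def kendall_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Kendall tau-b (tie-corrected) with a two-sided p-value."""
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    res = stats.kendalltau(x, y)
    return float(res.statistic), float(res.pvalue)


def write_hits_tsv(hits: Sequence[TsRNAHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttrna_id\tts_class\treference_space\t"
                 "match_start\tmatch_end\tlength\tfive_prime_nt\tall_trna_ids\n")
        for h in hits:
            fh.write(
                f"{h.read_id}\t{h.trna_id}\t{h.ts_class}\t{h.reference_space}\t"
                f"{h.match_start}\t{h.match_end}\t{h.length}\t{h.five_prime_nt}\t"
                f"{','.join(h.all_trna_ids)}\n"
            )


def write_reference_fasta(refs: Sequence[TRNAReference], path) -> None:
    with open(path, "w") as fh:
        for r in refs:
            fh.write(f">{r.trna_id}|mature\n{r.mature_seq}\n")
            fh.write(f">{r.trna_id}|primary\n{r.primary_seq}\n")
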