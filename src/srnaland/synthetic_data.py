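"""Self-contained toy dataset generator with a planted ground-truth manifest.

The generator emits a random genome, non-overlapping annotations (tRNAs,
genes, TEs of five families, a few ncRNAs), multi-tissue replicate read sets,
per-cytosine methylation calls and a gene expression table. Planted signal:

  - tsRNA reads of every class, exact substrings of the tRNA references at
    the class-defining positions;
  - siren loci: 21-nt clusters inside gene bodies with very high endosperm
    counts and zero reads elsewhere;
  - TE-enriched 24-nt clusters (placed inside TEs at a configurable multiple
    of the genomic TE fraction);
  - silenced target genes: a 24-nt cluster in one region (promoter, gene body
    or downstream), region methylation well above background, gene FPKM <= 2
    in the focal tissue.

Background read lengths mix modes at 21 and 24 nt, with an A-biased 5' end
for 24-nt reads and a U(T)-bias for 20-22-nt reads. All randomness flows
from a single generator seeded by ``SynthConfig.seed``; the same config
yields byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    AlignedRead,
    FeatureRecord,
    GenomicInterval,
    MethylationCall,
    Sample,
    SampleTable,
    write_fasta,
    write_features_gff3,
    write_methylation_calls,
    write_read_alignments,
    write_sample_table,
)
from .seed_analysis import gene_flanks
from .tsrna_pipeline import TRNAReference, build_trna_reference

DEFAULT_TISSUES = (
    "veg_root", "veg_shoot", "gen_root", "gen_shoot", "embryo", "endosperm",
)
TE_FAMILIES = ("DTM", "RSU", "RLC", "RLG", "RLX")
TS_CLASS_RANGES = {
    "tRF-5": (14, 30),
    "tRF-3": (14, 30),
    "tRF-1": (14, 30),
    "5tiR": (31, 40),
    "3tiR": (31, 40),
}


@dataclass
class SynthConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 150_000
    n_trna: int = 8
    n_te_per_family: int = 6
    n_genes: int = 20
    n_ncrna: int = 4
    n_samples_per_tissue: int = 3
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    planted_siren: int = 3
    siren_fpkm_multiplier: float = 20.0
    planted_tsrna: dict[str, int] = field(
        default_factory=lambda: {c: 10 for c in TS_CLASS_RANGES}
    )
    planted_targets: int = 6
    n_background_clusters: int = 40
    background_read_depth: int = 240  # background reads per sample (approx.)
    te_enrichment_factor: float = 5.0
    library_size: int = 1_000_000  # declared mapped reads per sample
    background_methylation_rate: float = 0.05
    target_methylation_rate: float = 0.30

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "chrom_length", "n_trna", "n_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        unknown = set(self.planted_tsrna) - set(TS_CLASS_RANGES)
        if unknown:
            raise ValueError(f"unknown tsRNA classes {sorted(unknown)}")


@dataclass
class GroundTruthManifest:
    tsrna_reads: dict[str, str]  # read_id -> intended class
    siren: list[dict]  # {siren_id, gene_id, chrom, start, end}
    te_clusters: list[dict]  # {chrom, start, end, te_id}
    targets: list[dict]  # {gene_id, region_class, tissue, methylation_rate, fpkm}

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


@dataclass
class SyntheticDataset:
    config: SynthConfig
    genome: dict[str, str]
    features: list[FeatureRecord]
    samples: SampleTable
    reads: list[AlignedRead]
    methylation: list[MethylationCall]
    gene_expression: pd.DataFrame  # genes x {embryo, endosperm} mean FPKM
    manifest: GroundTruthManifest
    trna_refs: list[TRNAReference]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.genome.items()}

    def features_of_type(self, ftype: str) -> list[FeatureRecord]:
        return [f for f in self.features if f.feature_type == ftype]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fa")
        write_features_gff3(self.features, outdir / "features.gff3")
        write_sample_table(self.samples, outdir / "samples.tsv")
        write_read_alignments(self.reads, outdir / "reads.tsv")
        write_methylation_calls(self.methylation, outdir / "methylation.tsv")
        self.gene_expression.to_csv(
            outdir / "gene_expression.tsv", sep="\t", index_label="gene_id"
        )
        (outdir / "manifest.json").write_text(self.manifest.to_json() + "\n")
        with open(outdir / "manifest.tsv", "w") as fh:
            fh.write("kind\tid\tdetail\n")
            for rid, cls in sorted(self.manifest.tsrna_reads.items()):
                fh.write(f"tsrna_read\t{rid}\t{cls}\n")
            for s in self.manifest.siren:
                fh.write(f"siren\t{s['siren_id']}\t"
                         f"{s['chrom']}:{s['start']}-{s['end']}\n")
            for t in self.manifest.targets:
                fh.write(f"target\t{t['gene_id']}\t"
                         f"{t['region_class']}:{t['tissue']}\n")


# ---------------------------------------------------------------------------
# tsRNA read simulation
# ---------------------------------------------------------------------------

def simulate_tsrna_reads(
    ref: TRNAReference,
    ts_class: str,
    n: int,
    rng: np.random.Generator | int,
    feature: FeatureRecord,
    sample_id: str = "sample",
    id_prefix: str = "ts",
) -> list[AlignedRead]:
    """Generate reads satisfying one tsRNA class rule exactly.

    Lengths are uniform over the class range; sequences are taken verbatim
    from the mature (+CCA) or primary reference so a downstream classifier
    recovers the class by construction. Genomic intervals are derived from
    the tRNA feature, strand-aware.
    """
    if ts_class not in TS_CLASS_RANGES:
        raise ValueError(f"unknown tsRNA class {ts_class!r}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    lo, hi = TS_CLASS_RANGES[ts_class]
    iv = feature.interval
    mature = ref.mature_seq
    reads: list[AlignedRead] = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        if ts_class in ("tRF-5", "5tiR"):
            seq = mature[:length]
            g_start, g_end = _transcript_to_genomic(iv, 0, length)
        elif ts_class in ("tRF-3", "3tiR"):
            seq = mature[len(mature) - length:]
            # footprint anchored at the 3' end of the span; the CCA tail
            # extends 3 bases into the trailer region on the genome
            span = len(mature) - 3
            g_start, g_end = _transcript_to_genomic(iv, span - (length - 3), span + 3)
        else:  # tRF-1
            offset = int(rng.integers(0, ref.trailer_bp - length + 1))
            seq = ref.trailer_seq[offset : offset + length]
            span = len(mature) - 3
            g_start, g_end = _transcript_to_genomic(
                iv, span + offset, span + offset + length
            )
        reads.append(
            AlignedRead(
                read_id=f"{id_prefix}_{ts_class}_{ref.trna_id}_{i}",
                sequence=seq,
                interval=GenomicInterval(iv.chrom, g_start, g_end, iv.strand),
                sample_id=sample_id,
            )
        )
    return reads


def _transcript_to_genomic(iv: GenomicInterval, t_start: int, t_end: int) -> tuple[int, int]:
    """Map transcript-space offsets (0 = 5' end of the span) to genomic coords."""
    if iv.strand == "-":
        return iv.end - t_end, iv.end - t_start
    return iv.start + t_start, iv.start + t_end


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def generate_dataset(config: SynthConfig) -> SyntheticDataset:
    rng = np.random.default_rng(config.seed)
    genome = _make_genome(config, rng)
    chrom_sizes = {c: len(s) for c, s in genome.items()}
    features = _place_features(config, chrom_sizes, rng)
    trna_feats = [f for f in features if f.feature_type == "tRNA"]
    gene_feats = [f for f in features if f.feature_type == "gene"]
    te_feats = [f for f in features if f.feature_type == "TE"]
    trna_refs = build_trna_reference(genome, trna_feats)

    samples = SampleTable(
        Sample(f"{t}_r{i + 1}", t, i + 1, config.library_size)
        for t in config.tissues
        for i in range(config.n_samples_per_tissue)
    )
    sample_ids = samples.sample_ids

    reads: list[AlignedRead] = []
    manifest_tsrna: dict[str, str] = {}
    manifest_siren: list[dict] = []
    manifest_te: list[dict] = []
    manifest_targets: list[dict] = []

    # --- planted tsRNA reads -------------------------------------------------
    feat_by_id = {f.feature_id: f for f in trna_feats}
    for ts_class in sorted(config.planted_tsrna):
        count = config.planted_tsrna[ts_class]
        if count and not trna_refs:
            raise ValueError("cannot plant tsRNA reads without tRNAs")
        for i in range(count):
            ref = trna_refs[i % len(trna_refs)]
            sid = sample_ids[i % len(sample_ids)]
            read = simulate_tsrna_reads(
                ref, ts_class, 1, rng, feat_by_id[ref.trna_id],
                sample_id=sid, id_prefix=f"ts{i:04d}",
            )[0]
            reads.append(read)
            manifest_tsrna[read.read_id] = ts_class

    # --- reserve planted cluster windows first --------------------------------
    cluster_width = 120
    ref_seqs = [r.mature_seq for r in trna_refs] + [r.primary_seq for r in trna_refs]
    flanks = gene_flanks(gene_feats, chrom_sizes)
    endosperm_samples = samples.samples_for_tissue("endosperm")
    if config.planted_siren and not endosperm_samples:
        raise ValueError("siren planting requires an 'endosperm' tissue")
    if config.planted_targets and not (
        "embryo" in config.tissues and "endosperm" in config.tissues
    ):
        raise ValueError("target planting requires embryo and endosperm tissues")
    if config.planted_siren + config.planted_targets > len(gene_feats):
        raise ValueError("not enough genes for planted sirens and targets")

    siren_windows: list[GenomicInterval] = []
    for si in range(config.planted_siren):
        gene = gene_feats[si]
        window = _place_window_inside(gene.interval, cluster_width, rng)
        siren_windows.append(window)
        manifest_siren.append(
            {"siren_id": f"siren{si:02d}", "gene_id": gene.feature_id,
             "chrom": window.chrom, "start": window.start, "end": window.end}
        )

    region_cycle = ("promoter", "gene_body", "downstream")
    target_tissues = ("embryo", "endosperm")
    target_regions: dict[tuple[str, str], float] = {}
    target_windows: list[tuple[GenomicInterval, str]] = []
    for ti in range(config.planted_targets):
        gene = gene_feats[config.planted_siren + ti]
        region_class = region_cycle[ti % 3]
        tissue = target_tissues[ti % 2]
        region = flanks[gene.feature_id][region_class]
        if region is None:
            raise ValueError(f"gene {gene.feature_id}: truncated {region_class}")
        window = _place_window_inside(region, cluster_width, rng)
        target_windows.append((window, tissue))
        manifest_targets.append(
            {"gene_id": gene.feature_id, "region_class": region_class,
             "tissue": tissue,
             "methylation_rate": config.target_methylation_rate, "fpkm": 0.5}
        )
        target_regions[(gene.feature_id, region_class)] = (
            config.target_methylation_rate
        )

    # --- background clusters (avoiding tRNA zones and planted windows) -------
    forbidden = [
        GenomicInterval(f.interval.chrom,
                        max(0, f.interval.start - 50),
                        min(chrom_sizes[f.interval.chrom], f.interval.end + 50))
        for f in trna_feats
    ]
    used: list[GenomicInterval] = list(siren_windows)
    used.extend(w for w, _ in target_windows)
    te_fraction = sum(len(f.interval) for f in te_feats) / sum(chrom_sizes.values())
    p_te = min(0.95, te_fraction * config.te_enrichment_factor)
    lam = max(1.0, config.background_read_depth / max(1, config.n_background_clusters))

    for ci in range(config.n_background_clusters):
        is24 = rng.random() < 0.6
        in_te = is24 and te_feats and rng.random() < p_te
        if in_te:
            te = te_feats[int(rng.integers(0, len(te_feats)))]
            window = _place_window_inside(te.interval, cluster_width, rng)
            manifest_te.append(
                {"chrom": window.chrom, "start": window.start,
                 "end": window.end, "te_id": te.feature_id}
            )
        else:
            window = _place_window_free(
                chrom_sizes, cluster_width, forbidden + used, rng
            )
        used.append(window)
        for sid in sample_ids:
            count = 1 + int(rng.poisson(max(lam - 1.0, 0.5)))
            reads.extend(
                _cluster_reads(genome, window, is24, count, sid,
                               f"bg{ci:03d}_{sid}", rng, ref_seqs)
            )

    # --- planted siren and target reads ---------------------------------------
    siren_count = max(12, int(round(12 * config.siren_fpkm_multiplier)))
    for si, window in enumerate(siren_windows):
        for sid in endosperm_samples:
            reads.extend(
                _cluster_reads(genome, window, False, siren_count, sid,
                               f"siren{si:02d}_{sid}", rng, ref_seqs,
                               strict_window=True)
            )
    for ti, (window, tissue) in enumerate(target_windows):
        for sid in samples.samples_for_tissue(tissue):
            count = 5 + int(rng.poisson(3))
            reads.extend(
                _cluster_reads(genome, window, True, count, sid,
                               f"tg{ti:02d}_{sid}", rng, ref_seqs,
                               strict_window=True)
            )

    # --- methylation ---------------------------------------------------------
    methylation = _simulate_methylation(
        genome, gene_feats, flanks, target_regions, config, rng
    )

    # --- gene expression table ------------------------------------------------
    expr = _gene_expression_table(gene_feats, manifest_siren, manifest_targets, rng)

    manifest = GroundTruthManifest(
        tsrna_reads=manifest_tsrna,
        siren=manifest_siren,
        te_clusters=manifest_te,
        targets=manifest_targets,
    )
    reads.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.read_id))
    return SyntheticDataset(
        config=config,
        genome=genome,
        features=features,
        samples=samples,
        reads=reads,
        methylation=methylation,
        gene_expression=expr,
        manifest=manifest,
        trna_refs=trna_refs,
    )


def _make_genome(config: SynthConfig, rng: np.random.Generator) -> dict[str, str]:
    bases = np.array(list("ACGT"))
    return {
        f"chr{i + 1}": "".join(
            bases[rng.integers(0, 4, size=config.chrom_length)]
        )
        for i in range(config.n_chromosomes)
    }


def _place_features(
    config: SynthConfig,
    chrom_sizes: Mapping[str, int],
    rng: np.random.Generator,
) -> list[FeatureRecord]:
    """Place annotations non-overlapping, sequentially with random gaps."""
    specs: list[tuple[str, int, str | None]] = []
    for i in range(config.n_trna):
        specs.append((f"trna{i:02d}", int(rng.integers(70, 81)), None))
    for i in range(config.n_genes):
        specs.append((f"gene{i:02d}", 2000, None))
    for fam in TE_FAMILIES:
        for i in range(config.n_te_per_family):
            specs.append((f"te_{fam}{i:02d}", int(rng.integers(300, 801)), fam))
    for i in range(config.n_ncrna):
        ntype = ("rRNA", "snoRNA")[i % 2]
        specs.append((f"nc_{ntype}{i:02d}", 120, None))
    order = rng.permutation(len(specs))

    margin = 1100  # leave room for gene flanks and tRNA extensions
    chroms = list(chrom_sizes)
    cursors = {c: margin for c in chroms}
    features: list[FeatureRecord] = []
    for k, idx in enumerate(order):
        name, length, fam = specs[int(idx)]
        # gaps exceed 2 * flank_bp so 1 kb gene flanks never reach a
        # neighbouring feature (keeps planted methylation regions clean)
        gap = int(rng.integers(2100, 2601))
        placed = False
        for attempt in range(len(chroms)):
            chrom = chroms[(k + attempt) % len(chroms)]
            start = cursors[chrom] + gap
            if start + length + margin <= chrom_sizes[chrom]:
                strand = "+" if rng.random() < 0.5 else "-"
                ftype = _spec_type(name)
                features.append(
                    FeatureRecord(
                        feature_id=name,
                        feature_type=ftype,
                        interval=GenomicInterval(chrom, start, start + length, strand),
                        te_family=fam if ftype == "TE" else None,
                    )
                )
                cursors[chrom] = start + length
                placed = True
                break
        if not placed:
            raise ValueError(
                f"infeasible placement: feature {name} does not fit on any "
                f"chromosome (chrom_length={config.chrom_length})"
            )
    features.sort(key=lambda f: (f.interval.chrom, f.interval.start))
    return features


def _spec_type(name: str) -> str:
    if name.startswith("trna"):
        return "tRNA"
    if name.startswith("gene"):
        return "gene"
    if name.startswith("te_"):
        return "TE"
    if name.startswith("nc_rRNA"):
        return "rRNA"
    return "snoRNA"


def _place_window_inside(
    region: GenomicInterval, width: int, rng: np.random.Generator
) -> GenomicInterval:
    if len(region) <= width:
        return GenomicInterval(region.chrom, region.start, region.end)
    start = region.start + int(rng.integers(0, len(region) - width + 1))
    return GenomicInterval(region.chrom, start, start + width)


def _place_window_free(
    chrom_sizes: Mapping[str, int],
    width: int,
    avoid: Sequence[GenomicInterval],
    rng: np.random.Generator,
    max_tries: int = 2000,
) -> GenomicInterval:
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    weights = sizes / sizes.sum()
    pad = 100  # keep clusters from merging with neighbours
    for _ in range(max_tries):
        ci = int(rng.choice(len(chroms), p=weights))
        start = int(rng.integers(0, chrom_sizes[chroms[ci]] - width))
        cand = GenomicInterval(chroms[ci], max(0, start - pad), start + width + pad)
        if not any(cand.overlaps(a) for a in avoid):
            return GenomicInterval(chroms[ci], start, start + width)
    raise ValueError("could not place background cluster; genome too crowded")


_LEN_CHOICES_24 = np.array([24] * 17 + [20, 21, 22, 23] + [26, 28])  # ~0.74 at 24
_LEN_CHOICES_21 = np.array([21] * 17 + [20, 22, 23, 24] + [30, 33])
# planted clusters are small (tens of reads), so they draw Dicer-window
# lengths only — a sampled out-of-window tail could randomly push a small
# cluster under the 80% rule and break the planted ground truth
_LEN_CHOICES_24_STRICT = np.array([24] * 17 + [20, 21, 22, 23])
_LEN_CHOICES_21_STRICT = np.array([21] * 17 + [20, 22, 23, 24])


def _cluster_reads(
    genome: Mapping[str, str],
    window: GenomicInterval,
    is24: bool,
    count: int,
    sample_id: str,
    id_prefix: str,
    rng: np.random.Generator,
    ref_seqs: Sequence[str],
    strict_window: bool = False,
) -> list[AlignedRead]:
    """Reads inside one cluster window, with length mode and 5'-nt bias.

    24-nt reads prefer a 5' A, 20-22-nt reads a 5' T; the bias is realised by
    picking start offsets whose genome base matches a draw from the biased
    distribution. Reads whose sequence happens to be a substring of a tRNA
    reference are re-drawn so background never aliases planted tsRNAs.
    """
    chrom_seq = genome[window.chrom]
    if strict_window:
        choices = _LEN_CHOICES_24_STRICT if is24 else _LEN_CHOICES_21_STRICT
    else:
        choices = _LEN_CHOICES_24 if is24 else _LEN_CHOICES_21
    reads: list[AlignedRead] = []
    for i in range(count):
        for _attempt in range(20):
            length = int(choices[rng.integers(0, len(choices))])
            span = len(window) - length
            if span <= 0:
                length = len(window) - 1
                span = 1
            if (is24 and length == 24) or (not is24 and 20 <= length <= 22):
                want = ("A" if is24 else "T") if rng.random() < 0.6 else None
            else:
                want = None
            offset = int(rng.integers(0, span + 1))
            if want is not None:
                candidates = [
                    o for o in range(span + 1)
                    if chrom_seq[window.start + o] == want
                ]
                if candidates:
                    offset = candidates[int(rng.integers(0, len(candidates)))]
            start = window.start + offset
            seq = chrom_seq[start : start + length]
            if "N" in seq or any(seq in ref for ref in ref_seqs):
                continue
            reads.append(
                AlignedRead(
                    read_id=f"{id_prefix}_{i}",
                    sequence=seq,
                    interval=GenomicInterval(window.chrom, start, start + length, "+"),
                    sample_id=sample_id,
                )
            )
            break
    return reads


def _simulate_methylation(
    genome: Mapping[str, str],
    genes: Sequence[FeatureRecord],
    flanks: Mapping[str, Mapping[str, GenomicInterval | None]],
    target_regions: Mapping[tuple[str, str], float],
    config: SynthConfig,
    rng: np.random.Generator,
) -> list[MethylationCall]:
    """Bernoulli per-cytosine calls over gene regions (both strands)."""
    calls: list[MethylationCall] = []
    seen: set[tuple[str, int]] = set()
    for gene in genes:
        for region_class in ("promoter", "gene_body", "downstream"):
            region = flanks[gene.feature_id][region_class]
            if region is None:
                continue
            rate = target_regions.get(
                (gene.feature_id, region_class),
                config.background_methylation_rate,
            )
            seq = genome[region.chrom][region.start : region.end]
            for off, base in enumerate(seq):
                pos = region.start + off
                if (region.chrom, pos) in seen:
                    continue
                if base == "C":
                    strand = "+"
                elif base == "G":
                    strand = "-"
                else:
                    continue
                seen.add((region.chrom, pos))
                calls.append(
                    MethylationCall(
                        region.chrom, pos, strand,
                        bool(rng.random() < rate),
                    )
                )
    calls.sort(key=lambda c: (c.chrom, c.pos))
    return calls


def _gene_expression_table(
    genes: Sequence[FeatureRecord],
    siren: Sequence[dict],
    targets: Sequence[dict],
    rng: np.random.Generator,
) -> pd.DataFrame:
    siren_hosts = {s["gene_id"] for s in siren}
    target_info = {t["gene_id"]: t for t in targets}
    rows = {}
    for gene in genes:
        gid = gene.feature_id
        if gid in target_info:
            t = target_info[gid]
            focal = t["tissue"]
            other = "endosperm" if focal == "embryo" else "embryo"
            rows[gid] = {focal: t["fpkm"], other: 8.0}
        elif gid in siren_hosts:
            rows[gid] = {"embryo": 5.0, "endosperm": 20.0}
        else:
            rows[gid] = {
                "embryo": float(np.round(rng.uniform(3, 50), 3)),
                "endosperm": float(np.round(rng.uniform(3, 50), 3)),
            }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df[["embryo", "endosperm"]]
    df.index.name = "gene_id"
    return df.sort_index()
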