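"""Shared coordinate model and readers/writers for the formats the pipeline touches.

Internal coordinates are 0-based, half-open. GFF3 input/output converts at the
boundary (GFF3 is 1-based, inclusive); BED is already half-open and passes
through unchanged. Unknown chromosomes are hard errors: silently dropping
records would corrupt downstream permutation nulls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_STRANDS = frozenset({"+", "-", "."})
FEATURE_TYPES = frozenset(
    {"tRNA", "rRNA", "snRNA", "snoRNA", "sRNA_locus", "gene", "TE"}
)
DNA_ALPHABET = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class AlignedRead:
    """One ungapped small-RNA read placement."""

    read_id: str
    sequence: str
    interval: GenomicInterval
    sample_id: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"read {self.read_id}: non-DNA characters {sorted(bad)}"
            )
        if len(self.sequence) != len(self.interval):
            raise ValueError(
                f"read {self.read_id}: sequence length {len(self.sequence)} "
                f"!= interval length {len(self.interval)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FeatureRecord:
    """An annotated genomic feature (tRNA, gene, TE, known sRNA locus, ...)."""

    feature_id: str
    feature_type: str
    interval: GenomicInterval
    te_family: str | None = None
    attributes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.feature_type!r}")
        if self.te_family is not None and self.feature_type != "TE":
            raise ValueError("te_family is only valid for TE features")


@dataclass(frozen=True)
class Sample:
    sample_id: str
    tissue: str
    replicate: int
    total_mapped: int

    def __post_init__(self) -> None:
        if self.total_mapped <= 0:
            raise ValueError(f"sample {self.sample_id}: total_mapped must be > 0")


class SampleTable:
    """Registry of sequencing samples keyed by sample id."""

    def __init__(self, samples: Iterable[Sample]):
        self._samples: dict[str, Sample] = {}
        seen: set[tuple[str, int]] = set()
        for s in samples:
            if s.sample_id in self._samples:
                raise ValueError(f"duplicate sample id {s.sample_id}")
            key = (s.tissue, s.replicate)
            if key in seen:
                raise ValueError(
                    f"duplicate replicate index {s.replicate} in tissue {s.tissue}"
                )
            seen.add(key)
            self._samples[s.sample_id] = s

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._samples

    def __getitem__(self, sample_id: str) -> Sample:
        return self._samples[sample_id]

    def __iter__(self):
        return iter(self._samples.values())

    def __len__(self) -> int:
        return len(self._samples)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._samples)

    @property
    def tissues(self) -> list[str]:
        out: list[str] = []
        for s in self._samples.values():
            if s.tissue not in out:
                out.append(s.tissue)
        return out

    def samples_for_tissue(self, tissue: str) -> list[str]:
        return [s.sample_id for s in self._samples.values() if s.tissue == tissue]

    def total_mapped_pooled(self) -> int:
        return sum(s.total_mapped for s in self._samples.values())


@dataclass(frozen=True)
class MethylationCall:
    """One per-cytosine methylation call (position of the C on its strand)."""

    chrom: str
    pos: int
    strand: str
    methylated: bool


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into an ordered name -> uppercase sequence map."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genome[rec.id] = str(rec.seq).upper()
    return genome


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_sequence(genome: Mapping[str, str], interval: GenomicInterval) -> str:
    """Extract the sequence of an interval; minus strand is reverse-complemented."""
    if interval.chrom not in genome:
        raise KeyError(f"unknown chromosome {interval.chrom!r}")
    chrom_seq = genome[interval.chrom]
    if interval.end > len(chrom_seq):
        raise ValueError(
            f"interval {interval.chrom}:{interval.start}-{interval.end} exceeds "
            f"chromosome length {len(chrom_seq)}"
        )
    seq = chrom_seq[interval.start : interval.end]
    if interval.strand == "-":
        seq = reverse_complement(seq)
    return seq


# ---------------------------------------------------------------------------
# Feature annotations (GFF3 / BED6)
# ---------------------------------------------------------------------------

_GFF3_COLUMNS = 9
_TYPE_ALIASES = {
    "transposable_element": "TE",
    "protein_coding_gene": "gene",
}


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        if "=" not in item:
            raise FormatError(f"malformed attribute {item!r}")
        key, value = item.split("=", 1)
        attrs[key.strip()] = value.strip()
    return attrs


def parse_features(
    path: str | Path,
    format: str = "gff3",
    *,
    chrom_sizes: Mapping[str, int] | None = None,
    default_type: str = "sRNA_locus",
) -> list[FeatureRecord]:
    """Parse GFF3 or BED6 annotations into FeatureRecords sorted by (chrom, start).

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    BED is consumed as-is. When ``chrom_sizes`` is given, records on unknown
    chromosomes or out of bounds raise ``FormatError``.
    """
    if format not in ("gff3", "bed"):
        raise ValueError(f"unsupported format {format!r}")
    records: list[FeatureRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                if format == "gff3":
                    records.append(_parse_gff3_line(line, lineno, default_type))
                else:
                    records.append(_parse_bed_line(line, lineno, default_type))
            except FormatError:
                raise
            except Exception as exc:  # re-raise with line context
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    if chrom_sizes is not None:
        for rec in records:
            iv = rec.interval
            if iv.chrom not in chrom_sizes:
                raise FormatError(
                    f"{path}: feature {rec.feature_id} on unknown chromosome "
                    f"{iv.chrom!r}"
                )
            if iv.end > chrom_sizes[iv.chrom]:
                raise FormatError(
                    f"{path}: feature {rec.feature_id} exceeds chromosome "
                    f"{iv.chrom} length {chrom_sizes[iv.chrom]}"
                )
    records.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.feature_id))
    return records


def _parse_gff3_line(line: str, lineno: int, default_type: str) -> FeatureRecord:
    fields = line.split("\t")
    if len(fields) != _GFF3_COLUMNS:
        raise FormatError(
            f"line {lineno}: expected {_GFF3_COLUMNS} tab-separated fields, "
            f"got {len(fields)}"
        )
    chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = fields
    start = int(start_s) - 1  # GFF3 is 1-based inclusive
    end = int(end_s)
    if end <= start:
        raise FormatError(f"line {lineno}: end < start ({start_s}, {end_s})")
    attrs = _parse_gff3_attributes(attr_s)
    ftype = _TYPE_ALIASES.get(ftype, ftype)
    if ftype not in FEATURE_TYPES:
        ftype = default_type
    feature_id = attrs.get("ID", f"feature_{lineno}")
    te_family = attrs.get("te_family") if ftype == "TE" else None
    return FeatureRecord(
        feature_id=feature_id,
        feature_type=ftype,
        interval=GenomicInterval(chrom, start, end, strand),
        te_family=te_family,
        attributes=attrs,
    )


def _parse_bed_line(line: str, lineno: int, default_type: str) -> FeatureRecord:
    fields = line.split()
    if len(fields) < 3:
        raise FormatError(f"line {lineno}: BED needs at least 3 fields")
    chrom = fields[0]
    start, end = int(fields[1]), int(fields[2])
    if end <= start:
        raise FormatError(f"line {lineno}: end <= start")
    name = fields[3] if len(fields) > 3 else f"feature_{lineno}"
    strand = fields[5] if len(fields) > 5 else "."
    return FeatureRecord(
        feature_id=name,
        feature_type=default_type,
        interval=GenomicInterval(chrom, start, end, strand),
    )


def write_features_gff3(
    features: Iterable[FeatureRecord], path: str | Path, source: str = "srnaland"
) -> None:
    """Write FeatureRecords as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in features:
            iv = rec.interval
            attrs = dict(rec.attributes)
            attrs.setdefault("ID", rec.feature_id)
            if rec.te_family is not None:
                attrs.setdefault("te_family", rec.te_family)
            attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
            fh.write(
                f"{iv.chrom}\t{source}\t{rec.feature_type}\t{iv.start + 1}\t"
                f"{iv.end}\t.\t{iv.strand}\t.\t{attr_s}\n"
            )


def write_locus_gff3(loci, path: str | Path) -> None:
    """Write SRNALocus records as GFF3 with the class label in the attributes.

    Round-trip safe: re-parsing with :func:`parse_features` reproduces every
    interval and class label.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for locus in loci:
            iv = locus.interval
            attr_s = f"ID={locus.locus_id};class={locus.class_label}"
            if locus.major_rna:
                attr_s += f";major_rna={locus.major_rna}"
            fh.write(
                f"{iv.chrom}\tsrnaland\tsRNA_locus\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attr_s}\n"
            )


# ---------------------------------------------------------------------------
# Read alignments (tabular dialect)
# ---------------------------------------------------------------------------

_ALIGNMENT_HEADER = ["read_id", "sequence", "chrom", "start", "end", "strand", "sample_id"]


def load_read_alignments(path: str | Path, samples: SampleTable) -> list[AlignedRead]:
    """Load the ungapped tabular alignment dialect.

    Columns: read_id, sequence, chrom, start, end, strand, sample_id
    (tab-separated, header required). Every read must belong to a known
    sample and have sequence length equal to its interval length.
    """
    reads: list[AlignedRead] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _ALIGNMENT_HEADER:
            raise FormatError(
                f"{path}: bad header {header!r}, expected {_ALIGNMENT_HEADER!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(_ALIGNMENT_HEADER):
                raise FormatError(f"{path}: line {lineno}: wrong field count")
            read_id, seq, chrom, start_s, end_s, strand, sample_id = fields
            if sample_id not in samples:
                raise FormatError(
                    f"{path}: line {lineno}: unknown sample_id {sample_id!r}"
                )
            interval = GenomicInterval(chrom, int(start_s), int(end_s), strand)
            if len(seq) != len(interval):
                raise FormatError(
                    f"{path}: line {lineno}: sequence length {len(seq)} != "
                    f"interval length {len(interval)}"
                )
            reads.append(AlignedRead(read_id, seq, interval, sample_id))
    return reads


def write_read_alignments(reads: Iterable[AlignedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_ALIGNMENT_HEADER) + "\n")
        for r in reads:
            iv = r.interval
            fh.write(
                f"{r.read_id}\t{r.sequence}\t{iv.chrom}\t{iv.start}\t{iv.end}\t"
                f"{iv.strand}\t{r.sample_id}\n"
            )


# ---------------------------------------------------------------------------
# Sample table / methylation TSV
# ---------------------------------------------------------------------------

def load_sample_table(path: str | Path) -> SampleTable:
    samples: list[Sample] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["sample_id", "tissue", "replicate", "total_mapped"]
        if header != expected:
            raise FormatError(f"{path}: bad header {header!r}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            sid, tissue, rep, total = line.split("\t")
            samples.append(Sample(sid, tissue, int(rep), int(total)))
    return SampleTable(samples)


def write_sample_table(samples: SampleTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\ttissue\treplicate\ttotal_mapped\n")
        for s in samples:
            fh.write(f"{s.sample_id}\t{s.tissue}\t{s.replicate}\t{s.total_mapped}\n")


def load_methylation_calls(path: str | Path) -> list[MethylationCall]:
    calls: list[MethylationCall] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["chrom", "pos", "strand", "methylated"]
        if header != expected:
            raise FormatError(f"{path}: bad header {header!r}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            chrom, pos, strand, meth = line.split("\t")
            calls.append(MethylationCall(chrom, int(pos), strand, meth == "1"))
    return calls


def write_methylation_calls(calls: Iterable[MethylationCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tstrand\tmethylated\n")
        for c in calls:
            fh.write(f"{c.chrom}\t{c.pos}\t{c.strand}\t{int(c.methylated)}\n")
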