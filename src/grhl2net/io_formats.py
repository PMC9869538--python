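"""Readers/writers for the genomic and tabular formats the pipeline touches.

Coordinate convention: BED-style 0-based half-open intervals everywhere.
The transcription start site (TSS) of a minus-strand gene is ``end - 1``;
strand "." is treated as "+" wherever strand-aware windowing applies (ChIP
peaks are unstranded).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

VALID_STRANDS = ("+", "-", ".")

FLOAT_FORMAT = "%.6g"


class ParseError(ValueError):
    """A line of an input file could not be parsed."""


class ValidationError(ValueError):
    """Parsed content violates an interval or matrix invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based, half-open genomic interval.

    ``summit`` is the narrowPeak point-source offset from ``start``
    (-1 when absent).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: float = 0.0
    summit: int = -1

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if self.start < 0:
            raise ValidationError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end must be > start, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def summit_pos(self) -> int | None:
        """Absolute summit coordinate, or None when no summit was recorded."""
        return self.start + self.summit if self.summit >= 0 else None

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Stable total sort by (chrom lexicographic, start, end)."""
    return sorted(intervals, key=GenomicInterval.sort_key)


def is_sorted(intervals: Sequence[GenomicInterval]) -> bool:
    keys = [iv.sort_key() for iv in intervals]
    return all(a <= b for a, b in zip(keys, keys[1:]))


def _data_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def _parse_int(value: str, what: str, lineno: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise ParseError(f"line {lineno}: non-integer {what}: {value!r}") from None


def read_peaks(path: str | Path, format: str | None = None) -> list[GenomicInterval]:
    """Read a BED (>=3 columns) or ENCODE narrowPeak (10 columns) peak file.

    Returns intervals sorted by (chrom, start, end). Names are auto-generated
    (``peak_<n>``) when the name column is absent or ".". The narrowPeak
    summit offset (column 10) is retained; -1 means absent.
    """
    path = Path(path)
    if format is None:
        format = "narrowPeak" if path.suffix.lower() == ".narrowpeak" else "BED"
    if format not in ("BED", "narrowPeak"):
        raise ValueError(f"unknown peak format {format!r}")

    peaks: list[GenomicInterval] = []
    for lineno, fields in _data_lines(path):
        if format == "narrowPeak" and len(fields) != 10:
            raise ParseError(
                f"line {lineno}: narrowPeak requires 10 columns, got {len(fields)}"
            )
        if len(fields) < 3:
            raise ParseError(
                f"line {lineno}: BED requires >=3 columns, got {len(fields)}"
            )
        chrom = fields[0]
        start = _parse_int(fields[1], "start", lineno)
        end = _parse_int(fields[2], "end", lineno)
        if end <= start:
            raise ValidationError(f"line {lineno}: end <= start ({start}, {end})")
        name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else ""
        score = 0.0
        if len(fields) > 4 and fields[4] not in ("", "."):
            try:
                score = float(fields[4])
            except ValueError:
                raise ParseError(f"line {lineno}: non-numeric score {fields[4]!r}")
        strand = fields[5] if len(fields) > 5 and fields[5] in VALID_STRANDS else "."
        summit = -1
        if format == "narrowPeak":
            summit = _parse_int(fields[9], "summit offset", lineno)
            if summit >= end - start:
                raise ValidationError(
                    f"line {lineno}: summit offset {summit} outside peak"
                )
        peaks.append(
            GenomicInterval(chrom, start, end, strand, name, score, summit)
        )
    out = sort_intervals(peaks)
    return [
        dataclasses.replace(p, name=f"peak_{i:05d}") if not p.name else p
        for i, p in enumerate(out, start=1)
    ]


def write_peaks(
    peaks: Sequence[GenomicInterval], path: str | Path, format: str = "BED"
) -> None:
    """Write peaks as BED6 or narrowPeak (lossless for summit offsets)."""
    with open(path, "w") as handle:
        for p in peaks:
            base = f"{p.chrom}\t{p.start}\t{p.end}\t{p.name or '.'}\t{p.score:g}\t{p.strand}"
            if format == "narrowPeak":
                handle.write(f"{base}\t0\t-1\t-1\t{p.summit}\n")
            else:
                handle.write(base + "\n")


@dataclass(frozen=True)
class Gene:
    """A gene model with exon blocks and a CDS span (thickStart/thickEnd)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[int, int]  # cds[0] == cds[1] for non-coding genes

    @property
    def tss(self) -> int:
        """Strand-aware transcription start site (end - 1 on minus strand)."""
        return self.start if self.strand != "-" else self.end - 1

    @property
    def tts(self) -> int:
        """Strand-aware transcription termination site."""
        return self.end - 1 if self.strand != "-" else self.start

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exon blocks."""
        return tuple(
            (a_end, b_start)
            for (_, a_end), (b_start, _) in zip(self.exons, self.exons[1:])
            if b_start > a_end
        )


class GenomeAnnotation:
    """Gene models indexed by id and by chromosome (sorted by start)."""

    def __init__(self, genes: Iterable[Gene]):
        self.genes: dict[str, Gene] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValidationError(f"duplicate gene id {g.gene_id!r}")
            self.genes[g.gene_id] = g
        self._by_chrom: dict[str, list[Gene]] = {}
        for g in self.genes.values():
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for lst in self._by_chrom.values():
            lst.sort(key=lambda g: (g.start, g.end, g.gene_id))

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def genes_on(self, chrom: str) -> list[Gene]:
        return self._by_chrom.get(chrom, [])


def read_gene_models(path: str | Path) -> GenomeAnnotation:
    """Read BED12 gene models into a :class:`GenomeAnnotation`.

    Exons come from the block columns; introns are the gaps between them.
    Blocks outside the gene span raise :class:`ValidationError`.
    """
    genes = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 12:
            raise ParseError(f"line {lineno}: BED12 requires 12 columns")
        chrom = fields[0]
        start = _parse_int(fields[1], "start", lineno)
        end = _parse_int(fields[2], "end", lineno)
        if end <= start:
            raise ValidationError(f"line {lineno}: end <= start")
        gene_id = fields[3]
        strand = fields[5]
        if strand not in VALID_STRANDS:
            raise ParseError(f"line {lineno}: invalid strand {strand!r}")
        thick_start = _parse_int(fields[6], "thickStart", lineno)
        thick_end = _parse_int(fields[7], "thickEnd", lineno)
        n_blocks = _parse_int(fields[9], "blockCount", lineno)
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        starts = [int(x) for x in fields[11].rstrip(",").split(",")]
        if len(sizes) != n_blocks or len(starts) != n_blocks:
            raise ValidationError(
                f"line {lineno}: blockCount does not match block lists"
            )
        exons = []
        for off, size in zip(starts, sizes):
            ex_start = start + off
            ex_end = ex_start + size
            if ex_start < start or ex_end > end or size <= 0:
                raise ValidationError(
                    f"line {lineno}: block [{ex_start},{ex_end}) outside "
                    f"gene span [{start},{end})"
                )
            exons.append((ex_start, ex_end))
        exons.sort()
        for (_, a_end), (b_start, _) in zip(exons, exons[1:]):
            if b_start < a_end:
                raise ValidationError(f"line {lineno}: overlapping blocks")
        genes.append(
            Gene(gene_id, chrom, start, end, strand, tuple(exons),
                 (thick_start, thick_end))
        )
    return GenomeAnnotation(genes)


def write_gene_models(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write gene models as BED12 (inverse of :func:`read_gene_models`)."""
    with open(path, "w") as handle:
        for chrom in annotation.chroms:
            for g in annotation.genes_on(chrom):
                sizes = ",".join(str(e - s) for s, e in g.exons)
                starts = ",".join(str(s - g.start) for s, e in g.exons)
                handle.write(
                    f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}"
                    f"\t{g.cds[0]}\t{g.cds[1]}\t0\t{len(g.exons)}\t{sizes}\t{starts}\n"
                )


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a TSV with header; floats rendered as %.6g for stable reruns."""
    if records.columns.empty:
        raise ValidationError("table must have a non-empty header")
    records.to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT, lineterminator="\n"
    )


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {name: uppercase sequence}."""
    from Bio import SeqIO

    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    seqio_write(records, str(path), "fasta")


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters with the study's defaults.

    The promoter window is the strand-aware interval [TSS-1000, TSS+100);
    the TTS window mirrors it on the 3' end. Fold-change thresholds (2.0 /
    0.5 at alpha 0.05) define the regulated-gene filter; the signature rule
    uses the (0.75, 1.5) control band and the >=3-of-4-timepoint guide rule.
    """

    promoter_upstream_bp: int = 1000
    promoter_downstream_bp: int = 100
    tss_profile_halfwidth: int = 6000
    tss_profile_binsize: int = 200
    flank_bp: int = 1000
    fc_up: float = 2.0
    fc_down: float = 0.5
    alpha: float = 0.05
    sig_ctrl_low: float = 0.75
    sig_ctrl_high: float = 1.5
    sig_guide_low: float = 0.75
    sig_guide_high: float = 1.5
    sig_min_timepoints: int = 3
    timepoints_days: tuple[int, ...] = (0, 2, 4, 8, 16)
    pseudocount_rpkm: float = 0.1
    heatmap_halfwidth: int = 2000
    heatmap_binsize: int = 50
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (self.fc_down < 1 < self.fc_up):
            raise ValidationError("need fc_down < 1 < fc_up")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must be in (0, 1)")
        if not (self.sig_ctrl_low < 1 < self.sig_ctrl_high):
            raise ValidationError("control band must bracket 1")
        tp = tuple(self.timepoints_days)
        if tp != tuple(sorted(tp)) or tp[0] != 0:
            raise ValidationError("timepoints must be ascending and start at 0")
        if self.promoter_upstream_bp < 0 or self.promoter_downstream_bp < 0:
            raise ValidationError("promoter window sizes must be >= 0")
        if self.tss_profile_halfwidth <= 0:
            raise ValidationError("tss_profile_halfwidth must be > 0")
        if 2 * self.tss_profile_halfwidth % self.tss_profile_binsize:
            raise ValidationError("binsize must divide 2*halfwidth")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "AnalysisConfig":
        """Build from a flat key=value mapping, coercing field types."""
        kwargs = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for key, value in mapping.items():
            if key not in fields:
                continue
            if key == "timepoints_days":
                kwargs[key] = tuple(int(x) for x in str(value).split(","))
            else:
                ftype = fields[key].type
                caster = float if "float" in str(ftype) else int
                kwargs[key] = caster(value)
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_mapping(read_config_file(path))


def read_config_file(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key = value`` config file (``#`` comments allowed)."""
    out: dict[str, str] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(f"line {lineno}: expected key = value")
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def write_config_file(mapping: Mapping[str, object], path: str | Path) -> None:
    with open(path, "w") as handle:
        for key, value in mapping.items():
            if isinstance(value, (tuple, list)):
                value = ",".join(str(v) for v in value)
            handle.write(f"{key} = {value}\n")
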