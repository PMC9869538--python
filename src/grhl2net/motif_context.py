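"""IUPAC consensus motif scanning and motif/peak co-occurrence analysis.

Motifs are degenerate consensus strings (e.g. the GRHL2 site AACCGGTT, the
estrogen-receptor palindrome AGGTCANNNTGACCT, FOXA1 TGTTTRC, GATA3 WGATAR)
matched exactly on both strands. Peak-level binary coverage stands in for
read coverage, since the pipeline consumes peak calls rather than
alignments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_formats import GenomicInterval, ValidationError

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "W": "AT", "S": "CG",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "W": "W", "S": "S",
    "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}


@dataclass(frozen=True)
class MotifPattern:
    motif_id: str
    consensus: str

    def __post_init__(self) -> None:
        norm = self.consensus.upper()
        if len(norm) < 4:
            raise ValidationError("motif length must be >= 4")
        bad = set(norm) - set(IUPAC)
        if bad:
            raise ValidationError(f"invalid IUPAC code(s): {sorted(bad)}")
        object.__setattr__(self, "consensus", norm)

    def __len__(self) -> int:
        return len(self.consensus)

    @property
    def reverse_complement(self) -> str:
        return "".join(_COMPLEMENT[c] for c in reversed(self.consensus))

    @property
    def is_palindromic(self) -> bool:
        return self.consensus == self.reverse_complement

    @property
    def match_probability(self) -> float:
        """Match probability per position under i.i.d. uniform bases."""
        p = 1.0
        for c in self.consensus:
            p *= len(IUPAC[c]) / 4.0
        return p


@dataclass(frozen=True)
class MotifHit:
    interval: GenomicInterval
    motif_id: str
    strand: str


def _regex(consensus: str) -> re.Pattern:
    # lookahead so overlapping occurrences are all reported
    body = "".join(
        c if len(IUPAC[c]) == 1 else "[" + IUPAC[c] + "]" for c in consensus
    )
    return re.compile(f"(?=({body}))")


def scan_motif(
    sequence: str, pattern: MotifPattern, chrom: str = "seq"
) -> list[MotifHit]:
    """Exact IUPAC matching on both strands of an uppercase sequence.

    Reverse-complement matches are reported on the "-" strand. A position
    matching on both strands (always the case for palindromic consensi) is
    deduplicated to a single "+" hit.
    """
    seq = sequence.upper()
    k = len(pattern)
    fwd_starts = {m.start() for m in _regex(pattern.consensus).finditer(seq)}
    rev_starts = {
        m.start() for m in _regex(pattern.reverse_complement).finditer(seq)
    }
    hits = []
    for start in sorted(fwd_starts | rev_starts):
        strand = "+" if start in fwd_starts else "-"
        hits.append(
            MotifHit(
                GenomicInterval(chrom, start, start + k, strand,
                                name=f"{pattern.motif_id}_{start}"),
                pattern.motif_id,
                strand,
            )
        )
    return hits


def scan_genome(
    sequences: Mapping[str, str], pattern: MotifPattern
) -> list[MotifHit]:
    """Scan every chromosome of a {name: sequence} genome."""
    hits: list[MotifHit] = []
    for chrom in sorted(sequences):
        hits.extend(scan_motif(sequences[chrom], pattern, chrom))
    return hits


def flank_cooccurrence(
    peaks: Sequence[GenomicInterval],
    sites: Sequence[GenomicInterval],
    flank_bp: int = 1000,
) -> tuple[float, list[GenomicInterval]]:
    """Fraction of peaks with >=1 site within +/- ``flank_bp`` of their span.

    A peak is flagged iff some site interval overlaps
    [peak.start - flank_bp, peak.end + flank_bp). Sites may be motif hits
    or an external peak list; both are treated identically.
    """
    if not peaks:
        raise ValidationError("flank_cooccurrence requires >=1 peak")
    if flank_bp < 0:
        raise ValidationError("flank_bp must be >= 0")
    site_starts: dict[str, np.ndarray] = {}
    site_maxend: dict[str, np.ndarray] = {}
    for chrom in {s.chrom for s in sites}:
        on_chrom = sorted(
            ((s.start, s.end) for s in sites if s.chrom == chrom)
        )
        site_starts[chrom] = np.array([s for s, _ in on_chrom])
        site_maxend[chrom] = np.maximum.accumulate(
            np.array([e for _, e in on_chrom])
        )
    flagged = []
    for p in peaks:
        lo = max(0, p.start - flank_bp)
        hi = p.end + flank_bp
        starts = site_starts.get(p.chrom)
        if starts is None or starts.size == 0:
            continue
        cut = int(np.searchsorted(starts, hi, side="left"))
        if cut > 0 and int(site_maxend[p.chrom][cut - 1]) > lo:
            flagged.append(p)
    return len(flagged) / len(peaks), flagged


def sites_of(hits: Sequence[MotifHit]) -> list[GenomicInterval]:
    return [h.interval for h in hits]


def motif_coverage_matrix(
    sites: Sequence[MotifHit],
    peaks: Sequence[GenomicInterval],
    halfwidth: int = 2000,
    binsize: int = 50,
) -> tuple[np.ndarray, list[str]]:
    """Binary peak coverage in bins around each motif site center.

    Cell (s, b) is 1 iff any peak overlaps bin b positioned relative to the
    site center; for minus-strand sites the bin axis is flipped so upstream
    is always on the left. Rows are sorted by row sum descending (stable).
    Returns (matrix, site names in row order).
    """
    if (2 * halfwidth) % binsize:
        raise ValidationError("binsize must divide 2*halfwidth")
    nbins = 2 * halfwidth // binsize
    peak_starts: dict[str, np.ndarray] = {}
    peak_ends: dict[str, np.ndarray] = {}
    for chrom in {p.chrom for p in peaks}:
        on_chrom = sorted(((p.start, p.end) for p in peaks if p.chrom == chrom))
        peak_starts[chrom] = np.array([s for s, _ in on_chrom])
        peak_ends[chrom] = np.array([e for _, e in on_chrom])
    matrix = np.zeros((len(sites), nbins), dtype=np.int8)
    for i, site in enumerate(sites):
        center = site.interval.midpoint
        chrom = site.interval.chrom
        starts = peak_starts.get(chrom)
        if starts is None:
            continue
        ends = peak_ends[chrom]
        edges = center - halfwidth + np.arange(nbins + 1) * binsize
        for b in range(nbins):
            lo, hi = int(edges[b]), int(edges[b + 1])
            covered = bool(np.any((starts < hi) & (ends > lo)))
            col = b if site.strand != "-" else nbins - 1 - b
            matrix[i, col] = covered
    order = np.argsort(-matrix.sum(axis=1), kind="stable")
    names = [sites[i].interval.name for i in order]
    return matrix[order], names


def read_motifs(path) -> list[MotifPattern]:
    """Read a 2-column TSV (motif_id, IUPAC consensus)."""
    out = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValidationError(f"line {lineno}: expected id<TAB>consensus")
            out.append(MotifPattern(parts[0], parts[1]))
    return out
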