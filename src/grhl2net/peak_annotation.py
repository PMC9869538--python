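"""Feature-category assignment of ChIP peaks and TSS-centered profiling.

Each peak is assigned to exactly one category using its midpoint,
HOMER-style: promoter > TTS > 5UTR > 3UTR > exon > intron > intergenic,
with "unknown" reserved for peaks on chromosomes absent from the gene
annotation. The promoter window is the strand-aware [TSS-1000, TSS+100)
interval; the TTS window mirrors it at the 3' end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import (
    AnalysisConfig,
    Gene,
    GenomeAnnotation,
    GenomicInterval,
    ValidationError,
)

CATEGORIES = (
    "promoter",
    "TTS",
    "5UTR",
    "3UTR",
    "exon",
    "intron",
    "intergenic",
    "unknown",
)

_PRIORITY = {c: i for i, c in enumerate(
    ("promoter", "TTS", "5UTR", "3UTR", "exon", "intron")
)}


@dataclass(frozen=True)
class FeatureCall:
    peak_id: str
    category: str
    gene_id: str  # empty for intergenic/unknown
    distance_to_tss: int | None  # signed, strand-aware; None when unknown


def _signed_distance(pos: int, anchor: int, strand: str) -> int:
    """Signed strand-aware offset of pos from anchor (negative = upstream)."""
    return pos - anchor if strand != "-" else anchor - pos


def _gene_category(mid: int, gene: Gene, cfg: AnalysisConfig) -> str | None:
    """Category of a midpoint with respect to one gene, or None."""
    d_tss = _signed_distance(mid, gene.tss, gene.strand)
    if -cfg.promoter_upstream_bp <= d_tss < cfg.promoter_downstream_bp:
        return "promoter"
    d_tts = _signed_distance(mid, gene.tts, gene.strand)
    if -cfg.promoter_downstream_bp <= d_tts < cfg.promoter_upstream_bp:
        return "TTS"
    if not (gene.start <= mid < gene.end):
        return None
    in_exon = any(s <= mid < e for s, e in gene.exons)
    if not in_exon:
        return "intron"
    cds_start, cds_end = gene.cds
    if cds_start < cds_end:
        if mid < cds_start:
            return "5UTR" if gene.strand != "-" else "3UTR"
        if mid >= cds_end:
            return "3UTR" if gene.strand != "-" else "5UTR"
    return "exon"


def assign_feature(
    peak: GenomicInterval,
    annotation: GenomeAnnotation,
    config: AnalysisConfig | None = None,
) -> FeatureCall:
    """Assign one peak to a feature category using its midpoint.

    When several genes' windows contain the midpoint, the highest-priority
    category wins; remaining ties break by smaller ``|distance_to_tss|``,
    then lexicographic gene id. The reported ``distance_to_tss`` is relative
    to the nearest TSS on the chromosome, strand-aware for that gene.
    """
    cfg = config or AnalysisConfig()
    peak_id = peak.name or f"{peak.chrom}:{peak.start}-{peak.end}"
    genes = annotation.genes_on(peak.chrom)
    if not genes:
        return FeatureCall(peak_id, "unknown", "", None)
    mid = peak.midpoint

    nearest = min(
        genes, key=lambda g: (abs(mid - g.tss), g.gene_id)
    )
    dist = _signed_distance(mid, nearest.tss, nearest.strand)

    flank = max(cfg.promoter_upstream_bp, cfg.promoter_downstream_bp)
    best: tuple[int, int, str, str] | None = None
    for gene in genes:
        if mid < gene.start - flank or mid >= gene.end + flank:
            continue
        category = _gene_category(mid, gene, cfg)
        if category is None:
            continue
        d = _signed_distance(mid, gene.tss, gene.strand)
        key = (_PRIORITY[category], abs(d), gene.gene_id, category)
        if best is None or key < best:
            best = key
    if best is None:
        return FeatureCall(peak_id, "intergenic", "", dist)
    return FeatureCall(peak_id, best[3], best[2], dist)


def annotate_peaks(
    peaks: list[GenomicInterval],
    annotation: GenomeAnnotation,
    config: AnalysisConfig | None = None,
) -> list[FeatureCall]:
    return [assign_feature(p, annotation, config) for p in peaks]


def calls_to_frame(calls: list[FeatureCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peak_id": [c.peak_id for c in calls],
            "category": [c.category for c in calls],
            "gene_id": [c.gene_id for c in calls],
            "distance_to_tss": [
                c.distance_to_tss if c.distance_to_tss is not None else ""
                for c in calls
            ],
        }
    )


def feature_fractions(calls: list[FeatureCall]) -> dict[str, float]:
    """Fraction of peaks per category; fractions sum to 1."""
    if not calls:
        raise ValidationError("feature_fractions requires at least one call")
    n = len(calls)
    counts: dict[str, int] = {}
    for c in calls:
        counts[c.category] = counts.get(c.category, 0) + 1
    return {cat: counts.get(cat, 0) / n for cat in CATEGORIES if cat in counts}


def tss_profile(
    peaks: list[GenomicInterval],
    annotation: GenomeAnnotation,
    halfwidth: int = 6000,
    binsize: int = 200,
) -> pd.DataFrame:
    """Count peak midpoints per strand-aware offset bin around every TSS.

    Bin b counts peaks whose midpoint lies in [TSS + b_lo, TSS + b_hi) for
    any TSS (upstream offsets negative). The density column normalizes the
    counts to sum to 1 (all-zero when no peak is near any TSS).
    """
    if halfwidth <= 0:
        raise ValidationError("halfwidth must be > 0")
    if (2 * halfwidth) % binsize:
        raise ValidationError("binsize must divide 2*halfwidth")
    nbins = 2 * halfwidth // binsize
    counts = np.zeros(nbins, dtype=int)
    mids_by_chrom: dict[str, np.ndarray] = {}
    for chrom in {p.chrom for p in peaks}:
        mids_by_chrom[chrom] = np.array(
            sorted(p.midpoint for p in peaks if p.chrom == chrom)
        )
    for chrom in annotation.chroms:
        mids = mids_by_chrom.get(chrom)
        if mids is None or mids.size == 0:
            continue
        for gene in annotation.genes_on(chrom):
            lo = np.searchsorted(mids, gene.tss - halfwidth, side="left")
            hi = np.searchsorted(mids, gene.tss + halfwidth, side="left")
            if lo == hi:
                continue
            offsets = np.array(
                [_signed_distance(int(m), gene.tss, gene.strand) for m in mids[lo:hi]]
            )
            offsets = offsets[(offsets >= -halfwidth) & (offsets < halfwidth)]
            idx = (offsets + halfwidth) // binsize
            np.add.at(counts, idx.astype(int), 1)
    total = counts.sum()
    density = counts / total if total else np.zeros(nbins)
    centers = np.arange(nbins) * binsize - halfwidth + binsize / 2
    return pd.DataFrame(
        {"bin_center": centers, "count": counts, "density": density}
    )


def chrom_coverage(
    peaks: list[GenomicInterval], chrom_sizes: dict[str, int]
) -> pd.DataFrame:
    """Per-chromosome peak count and union bp covered (Fig. S5-style)."""
    for p in peaks:
        if p.chrom not in chrom_sizes:
            raise ValidationError(f"unknown chromosome {p.chrom!r}")
        if p.end > chrom_sizes[p.chrom]:
            raise ValidationError(
                f"peak {p.name or p.chrom} extends beyond {p.chrom} end"
            )
    rows = []
    for chrom in sorted(chrom_sizes):
        on_chrom = sorted(
            ((p.start, p.end) for p in peaks if p.chrom == chrom)
        )
        covered = 0
        cur_start, cur_end = None, None
        for s, e in on_chrom:
            if cur_end is None or s > cur_end:
                if cur_end is not None:
                    covered += cur_end - cur_start
                cur_start, cur_end = s, e
            else:
                cur_end = max(cur_end, e)
        if cur_end is not None:
            covered += cur_end - cur_start
        rows.append(
            {
                "chrom": chrom,
                "size_bp": chrom_sizes[chrom],
                "n_peaks": len(on_chrom),
                "covered_bp": covered,
            }
        )
    return pd.DataFrame(rows)
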