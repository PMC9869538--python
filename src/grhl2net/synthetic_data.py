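"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes:
three cell-line peak sets with a controlled shared fraction and controlled
promoter placement, motif-site lists with a controlled flanking
co-occurrence rate, nascent-RNA count matrices with genes planted into the
five dynamic-response classes (plus null and control-responsive genes), and
a patient cohort with planted per-gene correlation to the driver gene and
ER-status labels. Counts are negative binomial around the expected
RPKM x length x depth (``dispersion = 0`` switches to deterministic rounded
means so noise-free recovery is exact); cohort log2 expression is Gaussian.

Geometry is controlled so that planted truth is exact: background peaks
avoid promoter windows, peaks are spaced far enough apart that a flanking
site planted for one peak can never flag a neighbour, and sample-unique
peaks never overlap across samples (so the three-way consensus count equals
the planted shared count).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bruseq_response import CountsMatrix
from .cohort_validation import CohortDataset
from .io_formats import Gene, GenomeAnnotation, GenomicInterval, sort_intervals

DEFAULT_SAMPLES = ("MCF7", "BT474", "T47D")
DEFAULT_GUIDES = ("sgCTR", "sgGRHL2_1", "sgGRHL2_2")
TIMEPOINTS = (0, 2, 4, 8, 16)

# Planted knockout fold-change patterns at days 2, 4, 8, 16. Reset classes
# return into the open day-16 bands (1, 2) / (0.5, 1), so their day-16 FC is
# planted at the geometric centre of the band.
CLASS_PATTERNS: dict[str, tuple[float, ...]] = {
    "sustained_induction": (4.0, 4.0, 4.0, 4.0),
    "sustained_repression": (0.25, 0.25, 0.25, 0.25),
    "induction_reset": (4.0, 4.0, 4.0, 1.4),
    "repression_reset": (0.25, 0.25, 0.25, 0.7),
    "dynamic": (4.0, 0.25, 4.0, 0.25),
    "null": (1.0, 1.0, 1.0, 1.0),
    "control_responsive": (4.0, 4.0, 4.0, 4.0),
}


class GenerationError(ValueError):
    """Requested synthetic dataset is geometrically or logically infeasible."""


@dataclass
class SyntheticTruth:
    """Planted ground truth against which every stage is validated."""

    shared_peak_ids: tuple[str, ...] = ()
    shared_members: dict[str, dict[str, str]] = field(default_factory=dict)
    promoter_peak_gene_map: dict[str, str] = field(default_factory=dict)
    planted_cooccurrence_rate: float | None = None
    flagged_peak_ids: frozenset[str] = frozenset()
    class_of_gene: dict[str, str] = field(default_factory=dict)
    planted_effect: dict[str, tuple[float, ...]] = field(default_factory=dict)
    cohort_rho: dict[str, float] = field(default_factory=dict)
    er_status: dict[str, str] = field(default_factory=dict)

    def merge(self, other: "SyntheticTruth") -> "SyntheticTruth":
        merged = SyntheticTruth(
            shared_peak_ids=self.shared_peak_ids or other.shared_peak_ids,
            shared_members={**self.shared_members, **other.shared_members},
            promoter_peak_gene_map={
                **self.promoter_peak_gene_map, **other.promoter_peak_gene_map
            },
            planted_cooccurrence_rate=(
                self.planted_cooccurrence_rate
                if other.planted_cooccurrence_rate is None
                else other.planted_cooccurrence_rate
            ),
            flagged_peak_ids=self.flagged_peak_ids | other.flagged_peak_ids,
            class_of_gene={**self.class_of_gene, **other.class_of_gene},
            planted_effect={**self.planted_effect, **other.planted_effect},
            cohort_rho={**self.cohort_rho, **other.cohort_rho},
            er_status={**self.er_status, **other.er_status},
        )
        return merged


@dataclass
class SimulatedGenome:
    annotation: GenomeAnnotation
    chrom_sizes: dict[str, int]
    sequences: dict[str, str] | None = None
    planted_motif_sites: tuple[tuple[str, int], ...] = ()  # (chrom, offset)


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def simulate_genome(
    n_genes: int,
    chrom_sizes: Mapping[str, int],
    seed: int,
    gene_length: tuple[int, int] = (2000, 10000),
    max_exons: int = 10,
    with_sequence: bool = False,
    planted_motif: str | None = None,
    n_motif_instances: int = 0,
) -> tuple[SimulatedGenome, SyntheticTruth]:
    """Place ``n_genes`` non-overlapping genes with 1-10 exons each.

    Genes are placed on a slot grid (one gene per slot, >= 6 kb apart edge to
    edge) so that promoter/TTS windows of neighbouring genes never collide.
    Optionally generates uniform random sequence with planted motif copies.
    """
    if n_genes < 1:
        raise GenerationError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    min_len, max_len = gene_length
    slot_w = max_len + 6000
    slots: list[tuple[str, int]] = []
    for chrom in sorted(chrom_sizes):
        for k in range(int(chrom_sizes[chrom]) // slot_w):
            slots.append((chrom, k * slot_w))
    if len(slots) < n_genes:
        raise GenerationError(
            f"insufficient space: {len(slots)} slots for {n_genes} genes"
        )
    chosen = sorted(rng.choice(len(slots), size=n_genes, replace=False))
    genes = []
    for i, slot_idx in enumerate(chosen, start=1):
        chrom, slot_start = slots[slot_idx]
        length = int(rng.integers(min_len, max_len + 1))
        start = slot_start + 3000 + int(rng.integers(0, max_len - length + 1))
        end = start + length
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(1, max_exons + 1))
        n_ex = max(1, min(n_ex, length // 100))
        n_seg = 2 * n_ex - 1
        weights = rng.random(n_seg) + 0.2
        sizes = np.floor(weights / weights.sum() * (length - 30 * n_seg)).astype(int) + 30
        sizes[-1] += length - int(sizes.sum())
        bounds = np.concatenate([[0], np.cumsum(sizes)]) + start
        exons = tuple(
            (int(bounds[2 * j]), int(bounds[2 * j + 1])) for j in range(n_ex)
        )
        first_len = exons[0][1] - exons[0][0]
        last_len = exons[-1][1] - exons[-1][0]
        cds_start = exons[0][0] + min(100, max(first_len - 1, 0))
        cds_end = exons[-1][1] - min(100, max(last_len - 1, 0))
        if cds_start >= cds_end:
            cds_start = cds_end = exons[0][0]
        genes.append(
            Gene(f"gene_{i:04d}", chrom, start, end, strand, exons,
                 (cds_start, cds_end))
        )
    annotation = GenomeAnnotation(genes)

    sequences = None
    motif_sites: list[tuple[str, int]] = []
    if with_sequence:
        arrays = {}
        for chrom in sorted(chrom_sizes):
            arrays[chrom] = _BASES[rng.integers(0, 4, int(chrom_sizes[chrom]))]
        if planted_motif:
            motif = np.frombuffer(planted_motif.upper().encode(), dtype="S1")
            k = len(planted_motif)
            for _ in range(n_motif_instances):
                chrom = sorted(chrom_sizes)[
                    int(rng.integers(0, len(chrom_sizes)))
                ]
                pos = int(rng.integers(0, int(chrom_sizes[chrom]) - k))
                arrays[chrom][pos:pos + k] = motif
                motif_sites.append((chrom, pos))
        sequences = {c: a.tobytes().decode() for c, a in arrays.items()}
    genome = SimulatedGenome(
        annotation, dict(chrom_sizes), sequences, tuple(sorted(motif_sites))
    )
    return genome, SyntheticTruth()


def _background_centers(
    genome: SimulatedGenome,
    stride: int,
    exclusion_radius: int,
) -> list[tuple[str, int]]:
    """Grid of candidate peak centers away from every promoter window."""
    centers = []
    for chrom in sorted(genome.chrom_sizes):
        size = genome.chrom_sizes[chrom]
        tss = np.array(
            sorted(g.tss for g in genome.annotation.genes_on(chrom))
        )
        for c in range(stride, size - stride, stride):
            if tss.size:
                idx = np.searchsorted(tss, c)
                near = min(
                    [abs(c - int(tss[j])) for j in (idx - 1, idx) if 0 <= j < tss.size]
                )
                if near <= exclusion_radius:
                    continue
            centers.append((chrom, c))
    return centers


def simulate_peaksets(
    genome: SimulatedGenome,
    n_peaks: int,
    shared_fraction: float,
    promoter_fraction: float,
    seed: int,
    samples: Sequence[str] = DEFAULT_SAMPLES,
    peak_width: int = 300,
    jitter: int = 25,
    flank_guard: int = 1000,
) -> tuple[dict[str, list[GenomicInterval]], SyntheticTruth]:
    """Three peak sets with planted shared and promoter-located peaks.

    Shared peaks appear in every sample at the same base interval (shifted
    by at most ``jitter`` bp per sample); promoter peaks are a subset of the
    shared peaks with midpoint inside the strand-aware [TSS-1000, TSS+100)
    window. All remaining peaks sit on a background grid that avoids
    promoter windows, spaced > 2 * ``flank_guard`` apart so flanking sites
    planted later cannot bleed onto neighbouring peaks.
    """
    if not (0 <= shared_fraction <= 1 and 0 <= promoter_fraction <= 1):
        raise GenerationError("fractions must be within [0, 1]")
    n_shared = round(shared_fraction * n_peaks)
    n_prom = round(promoter_fraction * n_peaks)
    if n_prom > n_shared:
        raise GenerationError(
            "promoter peaks are planted as shared peaks; "
            "promoter_fraction must not exceed shared_fraction"
        )
    rng = np.random.default_rng(seed)
    genes = [
        genome.annotation.genes[g] for g in sorted(genome.annotation.genes)
    ]
    if n_prom > len(genes):
        raise GenerationError("not enough genes for the promoter peaks")

    up, down = 1000, 100
    w = peak_width
    base_intervals: list[tuple[str, int, int]] = []  # (chrom, start, end)
    truth = SyntheticTruth()
    prom_gene_idx = rng.choice(len(genes), size=n_prom, replace=False)
    for i, gi in enumerate(sorted(int(x) for x in prom_gene_idx)):
        gene = genes[gi]
        d = int(rng.integers(-up + jitter, down - jitter))
        mid = gene.tss + d if gene.strand != "-" else gene.tss - d
        start = max(0, mid - w // 2)
        base_intervals.append((gene.chrom, start, start + w))
        truth.promoter_peak_gene_map[f"sh{i:05d}"] = gene.gene_id

    stride = w + 2 * jitter + 2 * flank_guard + 50
    exclusion = up + w + jitter + 2 * flank_guard
    centers = _background_centers(genome, stride, exclusion)
    n_bg_shared = n_shared - n_prom
    n_unique = n_peaks - n_shared
    needed = n_bg_shared + len(samples) * n_unique
    if needed > len(centers):
        raise GenerationError(
            f"insufficient genome space: need {needed} background slots, "
            f"have {len(centers)}"
        )
    picked = rng.choice(len(centers), size=needed, replace=False)
    picked_centers = [centers[int(i)] for i in picked]
    for chrom, c in picked_centers[:n_bg_shared]:
        base_intervals.append((chrom, c - w // 2, c - w // 2 + w))
    truth.shared_peak_ids = tuple(f"sh{i:05d}" for i in range(n_shared))

    peaksets: dict[str, list[GenomicInterval]] = {}
    cursor = n_bg_shared
    for s_idx, sample in enumerate(samples):
        peaks = []
        for i, (chrom, start, end) in enumerate(base_intervals):
            shift = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
            name = f"{sample}_sh{i:05d}"
            peaks.append(
                GenomicInterval(chrom, start + shift, end + shift, name=name)
            )
            truth.shared_members.setdefault(f"sh{i:05d}", {})[sample] = name
        for j in range(n_unique):
            chrom, c = picked_centers[cursor + j]
            peaks.append(
                GenomicInterval(
                    chrom, c - w // 2, c - w // 2 + w,
                    name=f"{sample}_uq{j:05d}",
                )
            )
        cursor += n_unique
        peaksets[sample] = sort_intervals(peaks)
    return peaksets, truth


def simulate_flanking_sites(
    peaksets: Mapping[str, Sequence[GenomicInterval]] | Sequence[GenomicInterval],
    rate: float,
    chrom_sizes: Mapping[str, int],
    seed: int,
    flank_bp: int = 1000,
    site_length: int = 8,
    n_background: int = 200,
) -> tuple[list[GenomicInterval], SyntheticTruth]:
    """Plant a flanking site for a Bernoulli(``rate``) fraction of peaks.

    Accepts either one peak list or a sample->peaks mapping (sites are then
    planted for the first sample's peaks). Background decoy sites are placed
    > ``flank_bp`` away from every peak so only planted peaks are flagged.
    Requires peaks generated with inter-peak gaps > 2 * flank_bp (as
    :func:`simulate_peaksets` guarantees with the default ``flank_guard``).
    """
    if not (0 <= rate <= 1):
        raise GenerationError("rate must be within [0, 1]")
    if isinstance(peaksets, Mapping):
        all_peaks = [p for peaks in peaksets.values() for p in peaks]
        target_peaks = list(next(iter(peaksets.values())))
    else:
        all_peaks = list(peaksets)
        target_peaks = list(peaksets)
    rng = np.random.default_rng(seed)
    sites: list[GenomicInterval] = []
    flagged: set[str] = set()
    for p in target_peaks:
        if rng.random() >= rate:
            continue
        lo = max(0, p.start - flank_bp)
        hi = p.end + flank_bp - site_length
        start = int(rng.integers(lo, hi))
        sites.append(
            GenomicInterval(p.chrom, start, start + site_length,
                            name=f"site_{p.name}")
        )
        flagged.add(p.name)

    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in all_peaks:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    chroms = sorted(chrom_sizes)
    placed = 0
    attempts = 0
    guard = flank_bp + 100
    while placed < n_background and attempts < 100 * max(n_background, 1):
        attempts += 1
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, int(chrom_sizes[chrom]) - site_length))
        clear = all(
            start + site_length + guard <= s or start >= e + guard
            for s, e in by_chrom.get(chrom, [])
        )
        if clear:
            sites.append(
                GenomicInterval(chrom, start, start + site_length,
                                name=f"bg_{placed:05d}")
            )
            placed += 1
    truth = SyntheticTruth(
        planted_cooccurrence_rate=rate, flagged_peak_ids=frozenset(flagged)
    )
    return sort_intervals(sites), truth


def simulate_bruseq_counts(
    annotation: GenomeAnnotation,
    class_of_gene: Mapping[str, str],
    seed: int,
    depth: int = 20_000_000,
    dispersion: float = 0.05,
    guides: Sequence[str] = DEFAULT_GUIDES,
    base_rpkm_mean: float = 30.0,
    base_rpkm_sigma: float = 0.4,
) -> tuple[CountsMatrix, SyntheticTruth]:
    """Count matrix for guides x timepoints with planted response classes.

    Expected counts are baseline RPKM x length(kb) x depth(millions) scaled
    by the class fold-change pattern; the two knockout guides realise the
    same planted pattern independently, the control guide stays at the null
    pattern except for ``control_responsive`` genes, which respond in every
    guide. Counts are negative binomial with Var = mu + dispersion * mu^2;
    ``dispersion = 0`` gives deterministic rounded means.
    """
    unknown = sorted(
        {c for c in class_of_gene.values() if c not in CLASS_PATTERNS}
    )
    if unknown:
        raise GenerationError(f"unknown class label(s): {unknown}")
    missing = sorted(set(class_of_gene) - set(annotation.genes))
    if missing:
        raise GenerationError(f"classified genes not in annotation: {missing}")
    rng = np.random.default_rng(seed)
    gene_ids = sorted(annotation.genes)
    lengths = pd.Series(
        {g: annotation.genes[g].end - annotation.genes[g].start for g in gene_ids}
    )
    base_rpkm = np.exp(
        rng.normal(np.log(base_rpkm_mean), base_rpkm_sigma, len(gene_ids))
    )
    treated = [t for t in TIMEPOINTS if t > 0]
    control = guides[0]

    def planted_fc(gene: str, guide: str, day: int) -> float:
        cls = class_of_gene.get(gene, "null")
        if day == 0:
            return 1.0
        idx = treated.index(day)
        if cls == "control_responsive":
            return CLASS_PATTERNS[cls][idx]
        if guide == control:
            return 1.0
        return CLASS_PATTERNS[cls][idx]

    columns = {}
    for guide in guides:
        for day in TIMEPOINTS:
            mu = np.array(
                [
                    base_rpkm[i]
                    * (lengths.iloc[i] / 1000.0)
                    * (depth / 1e6)
                    * planted_fc(gene_ids[i], guide, day)
                    for i in range(len(gene_ids))
                ]
            )
            if dispersion <= 0:
                counts = np.rint(mu).astype(int)
            else:
                r = 1.0 / dispersion
                counts = rng.negative_binomial(r, r / (r + mu))
            columns[f"{guide}:{day}"] = counts
    frame = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    totals = {
        col: int(max(depth, frame[col].sum())) for col in frame.columns
    }
    matrix = CountsMatrix(frame, lengths, totals)
    truth = SyntheticTruth(
        class_of_gene=dict(class_of_gene),
        planted_effect={
            g: CLASS_PATTERNS[c] for g, c in class_of_gene.items()
        },
    )
    return matrix, truth


def simulate_cohort(
    n_patients: int,
    gene_rho: Mapping[str, float],
    seed: int,
    er_pos_prob: float = 0.75,
    driver_gene: str = "GRHL2",
    driver_mean: float = 8.0,
    offset_range: tuple[float, float] = (4.0, 10.0),
) -> tuple[CohortDataset, SyntheticTruth]:
    """Patient cohort with planted per-gene correlation to the driver.

    Driver log2 expression is standard normal around ``driver_mean``; each
    gene is rho * driver_z + sqrt(1 - rho^2) * noise plus a gene-specific
    offset. ER status is Bernoulli(``er_pos_prob``).
    """
    if n_patients < 8:
        raise GenerationError("n_patients must be >= 8")
    bad = {g: r for g, r in gene_rho.items() if abs(r) > 1}
    if bad:
        raise GenerationError(f"|rho| must be <= 1, got {bad}")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n_patients)
    patients = [f"P{i:05d}" for i in range(1, n_patients + 1)]
    data = {driver_gene: driver_mean + z}
    for gene in sorted(gene_rho):
        if gene == driver_gene:
            continue
        rho = gene_rho[gene]
        offset = rng.uniform(*offset_range)
        noise = rng.standard_normal(n_patients)
        data[gene] = offset + rho * z + np.sqrt(1 - rho**2) * noise
    er = np.where(rng.random(n_patients) < er_pos_prob, "ER+", "ER-")
    expr = pd.DataFrame(data, index=pd.Index(patients, name="patient_id"))
    cohort = CohortDataset(expr, pd.Series(er, index=expr.index), driver_gene)
    truth = SyntheticTruth(
        cohort_rho=dict(gene_rho),
        er_status=dict(zip(patients, er.tolist())),
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# Composite scenarios reused by the end-to-end demo and validation checks
# ---------------------------------------------------------------------------


@dataclass
class IntegrationScenario:
    genome: SimulatedGenome
    peaksets: dict[str, list[GenomicInterval]]
    counts: CountsMatrix
    truth: SyntheticTruth
    reference: str
    n_reference_promoter_regulated: int
    n_conserved_promoter_regulated: int
    regulated_genes: tuple[str, ...]


def simulate_integration_scenario(
    seed: int,
    n_conserved: int = 4,
    n_reference_only: int = 8,
    n_unbound_regulated: int = 6,
    samples: Sequence[str] = DEFAULT_SAMPLES,
) -> IntegrationScenario:
    """Noise-free scenario with nested promoter-bound regulated gene sets.

    Plants ``n_conserved`` regulated genes with promoter peaks shared by all
    samples, ``n_reference_only`` regulated genes with a promoter peak in the
    reference sample only, and ``n_unbound_regulated`` regulated genes with
    no promoter binding, so the conserved / reference / regulated sets nest
    with known sizes.
    """
    rng = np.random.default_rng(seed)
    n_genes = 2 * (n_conserved + n_reference_only + n_unbound_regulated) + 8
    genome, _ = simulate_genome(
        n_genes, {"chr1": 2_000_000, "chr2": 2_000_000}, seed=seed
    )
    gene_ids = sorted(genome.annotation.genes)
    chosen = [gene_ids[int(i)] for i in
              rng.choice(len(gene_ids),
                         size=n_conserved + n_reference_only + n_unbound_regulated,
                         replace=False)]
    conserved_genes = chosen[:n_conserved]
    ref_only_genes = chosen[n_conserved:n_conserved + n_reference_only]
    unbound_genes = chosen[n_conserved + n_reference_only:]
    reference = samples[0]
    w = 300

    def promoter_peak(gene_id: str, name: str) -> GenomicInterval:
        gene = genome.annotation.genes[gene_id]
        d = int(rng.integers(-900, 50))
        mid = gene.tss + d if gene.strand != "-" else gene.tss - d
        start = max(0, mid - w // 2)
        return GenomicInterval(gene.chrom, start, start + w, name=name)

    peaksets: dict[str, list[GenomicInterval]] = {s: [] for s in samples}
    for i, gene_id in enumerate(conserved_genes):
        base = promoter_peak(gene_id, "")
        for s in samples:
            peaksets[s].append(replace(base, name=f"{s}_cons{i:03d}"))
    for i, gene_id in enumerate(ref_only_genes):
        peaksets[reference].append(
            promoter_peak(gene_id, f"{reference}_ref{i:03d}")
        )
    # shared intergenic background so the consensus list is non-trivial
    centers = _background_centers(genome, stride=5000, exclusion_radius=2500)
    bg = [centers[int(i)] for i in rng.choice(len(centers), 10, replace=False)]
    for i, (chrom, c) in enumerate(bg):
        for s in samples:
            peaksets[s].append(
                GenomicInterval(chrom, c - w // 2, c - w // 2 + w,
                                name=f"{s}_bg{i:03d}")
            )
    peaksets = {s: sort_intervals(p) for s, p in peaksets.items()}

    classes = ("sustained_induction", "sustained_repression",
               "induction_reset", "repression_reset", "dynamic")
    class_of_gene: dict[str, str] = {}
    regulated = conserved_genes + ref_only_genes + unbound_genes
    for i, gene_id in enumerate(regulated):
        class_of_gene[gene_id] = classes[i % len(classes)]
    counts, truth = simulate_bruseq_counts(
        genome.annotation, class_of_gene, seed=seed + 1, dispersion=0.0
    )
    truth.promoter_peak_gene_map = {
        f"cons{i:03d}": g for i, g in enumerate(conserved_genes)
    }
    return IntegrationScenario(
        genome=genome,
        peaksets=peaksets,
        counts=counts,
        truth=truth,
        reference=reference,
        n_reference_promoter_regulated=n_conserved + n_reference_only,
        n_conserved_promoter_regulated=n_conserved,
        regulated_genes=tuple(sorted(regulated)),
    )
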