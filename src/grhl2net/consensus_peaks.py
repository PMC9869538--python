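"""Consensus (conserved) peak intersection across samples and Venn counts.

A consensus peak is one peak from *every* input sample with a non-empty
common intersection (>= ``min_overlap_bp``). Each input peak contributes to
at most one consensus peak; candidates are chained greedily from the left
(core start ascending, ties by core length descending). Venn counts assign
every input peak once, to its maximal membership region, so per-sample
region counts always sum to that sample's peak count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenomicInterval, ValidationError, is_sorted


@dataclass(frozen=True)
class ConsensusPeak:
    """Union span, common core and member peaks of one consensus site."""

    interval: GenomicInterval  # union span of the contributing peaks
    core: GenomicInterval  # common intersection (length >= 1)
    members: Mapping[str, GenomicInterval]  # sample_id -> contributing peak


class _ChromIndex:
    """Per-chromosome sorted-start index with running max end.

    Entries carry each peak's index in the original (chrom, start, end)-sorted
    set so greedy chaining can mark peaks used across chromosomes.
    """

    def __init__(self, peaks: Sequence[GenomicInterval]):
        self.by_chrom: dict[
            str, tuple[list[tuple[int, GenomicInterval]], np.ndarray, np.ndarray]
        ] = {}
        grouped: dict[str, list[tuple[int, GenomicInterval]]] = {}
        for idx, p in enumerate(peaks):
            grouped.setdefault(p.chrom, []).append((idx, p))
        self.max_len: dict[str, int] = {}
        for chrom, lst in grouped.items():
            starts = np.array([p.start for _, p in lst])
            max_end = np.maximum.accumulate(np.array([p.end for _, p in lst]))
            self.by_chrom[chrom] = (lst, starts, max_end)
            self.max_len[chrom] = max(p.length for _, p in lst)

    def overlapping(self, chrom: str, lo: int, hi: int, min_bp: int = 1):
        """Peaks with overlap >= min_bp with [lo, hi), as (set index, peak)."""
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return []
        lst, starts, _ = entry
        cut = int(np.searchsorted(starts, hi - min_bp, side="right"))
        first = int(
            np.searchsorted(starts, lo + min_bp - self.max_len[chrom], side="left")
        )
        return [lst[j] for j in range(first, cut) if lst[j][1].end >= lo + min_bp]

    def any_overlap(self, chrom: str, lo: int, hi: int, min_bp: int = 1) -> bool:
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return False
        lst, starts, max_end = entry
        cut = int(np.searchsorted(starts, hi - min_bp, side="right"))
        return cut > 0 and int(max_end[cut - 1]) >= lo + min_bp


def intersect_sets(
    sets: Mapping[str, Sequence[GenomicInterval]], min_overlap_bp: int = 1
) -> tuple[list[ConsensusPeak], pd.DataFrame]:
    """Intersect >=2 sorted peak sets.

    Returns the consensus peak list and a Venn table with one row per
    non-empty membership region (column ``region`` holds "&"-joined sample
    names) and one count column per sample.
    """
    if len(sets) < 2:
        raise ValidationError("need at least 2 peak sets")
    if min_overlap_bp < 1:
        raise ValidationError("min_overlap_bp must be >= 1")
    sets = {name: list(peaks) for name, peaks in sets.items()}
    for name, peaks in sets.items():
        if not is_sorted(peaks):
            raise ValidationError(f"peak set {name!r} is not sorted")
    names = list(sets)
    indexes = {name: _ChromIndex(peaks) for name, peaks in sets.items()}

    # ---- consensus peaks (greedy single-use chaining) ----
    consensus: list[ConsensusPeak] = []
    if all(len(peaks) for peaks in sets.values()):
        candidates: list[tuple[str, int, int, tuple[tuple[str, int], ...]]] = []

        def extend(i: int, chosen, chrom: str, lo: int, hi: int) -> None:
            if hi - lo < min_overlap_bp:
                return
            if i == len(names):
                candidates.append((chrom, lo, hi, tuple(chosen)))
                return
            for j, p in indexes[names[i]].overlapping(chrom, lo, hi, min_overlap_bp):
                extend(i + 1, chosen + [(names[i], j)], chrom,
                       max(lo, p.start), min(hi, p.end))

        for j, p in enumerate(sets[names[0]]):
            extend(1, [(names[0], j)], p.chrom, p.start, p.end)

        candidates.sort(
            key=lambda c: (c[0], c[1], -(c[2] - c[1]),
                           tuple(j for _, j in c[3]))
        )
        used: set[tuple[str, int]] = set()
        for chrom, lo, hi, members in candidates:
            if any(m in used for m in members):
                continue
            used.update(members)
            member_map = {s: sets[s][j] for s, j in members}
            union = GenomicInterval(
                chrom,
                min(p.start for p in member_map.values()),
                max(p.end for p in member_map.values()),
            )
            consensus.append(
                ConsensusPeak(union, GenomicInterval(chrom, lo, hi), member_map)
            )
        consensus.sort(key=lambda c: c.interval.sort_key())

    # ---- Venn: each peak assigned once to its maximal membership region ----
    region_counts: dict[tuple[str, ...], dict[str, int]] = {}
    for sample in names:
        for p in sets[sample]:
            membership = tuple(
                other
                for other in names
                if other == sample
                or indexes[other].any_overlap(p.chrom, p.start, p.end, min_overlap_bp)
            )
            region_counts.setdefault(membership, {n: 0 for n in names})
            region_counts[membership][sample] += 1
    rows = []
    for region in sorted(region_counts, key=lambda r: (len(r), r)):
        row = {"region": "&".join(region)}
        row.update(region_counts[region])
        rows.append(row)
    venn = pd.DataFrame(rows, columns=["region", *names])
    return consensus, venn


def conserved_promoter_peaks(
    consensus: Sequence[ConsensusPeak],
    calls: Mapping[str, Mapping[str, str]],
    reference: str,
) -> list[ConsensusPeak]:
    """Retain consensus peaks whose reference-sample member is a promoter peak.

    ``calls`` maps sample -> {peak_id -> category}; use :func:`calls_lookup`
    to build the inner mapping from a FeatureCall table.
    """
    if reference not in calls:
        raise ValidationError(f"no feature calls for reference {reference!r}")
    ref_calls = calls[reference]
    out = []
    for cp in consensus:
        if reference not in cp.members:
            raise ValidationError("consensus peak lacks a reference member")
        peak_id = cp.members[reference].name
        if peak_id not in ref_calls:
            raise ValidationError(f"missing feature call for peak {peak_id!r}")
        if ref_calls[peak_id] == "promoter":
            out.append(cp)
    return out


def consensus_from_frame(frame: pd.DataFrame) -> list[ConsensusPeak]:
    """Rebuild consensus peaks from a :func:`consensus_to_frame` table.

    Member peaks are restored by name with the union span as a placeholder
    interval (sufficient for promoter filtering and target integration).
    """
    out = []
    for row in frame.itertuples(index=False):
        members = {}
        for item in str(row.members).split(";"):
            sample, peak_name = item.split("=", 1)
            members[sample] = GenomicInterval(
                row.chrom, int(row.start), int(row.end), name=peak_name
            )
        out.append(
            ConsensusPeak(
                GenomicInterval(row.chrom, int(row.start), int(row.end)),
                GenomicInterval(row.chrom, int(row.core_start), int(row.core_end)),
                members,
            )
        )
    return out


def calls_lookup(frame: pd.DataFrame) -> dict[str, str]:
    """{peak_id -> category} from a FeatureCall table."""
    return dict(zip(frame["peak_id"], frame["category"]))


def consensus_to_frame(consensus: Sequence[ConsensusPeak]) -> pd.DataFrame:
    rows = []
    for i, cp in enumerate(consensus, start=1):
        rows.append(
            {
                "chrom": cp.interval.chrom,
                "start": cp.interval.start,
                "end": cp.interval.end,
                "name": f"consensus_{i:05d}",
                "core_start": cp.core.start,
                "core_end": cp.core.end,
                "members": ";".join(
                    f"{s}={p.name}" for s, p in sorted(cp.members.items())
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "core_start", "core_end",
                 "members"],
    )
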