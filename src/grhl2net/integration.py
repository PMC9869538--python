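"""Intersection of promoter binding with transcriptional response.

Nominates candidate direct targets: regulated genes with a promoter-bound
peak in the reference cell line, and the stricter nested subset whose
promoter peak is conserved across all cell lines. A gene is "promoter
bound" when at least one promoter feature call points to it (genes are
counted, not peaks).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Mapping, Sequence

import pandas as pd
from scipy import stats

from .consensus_peaks import ConsensusPeak, conserved_promoter_peaks
from .io_formats import ValidationError


@dataclass(frozen=True)
class TargetCall:
    gene_id: str
    promoter_bound_reference: bool
    promoter_bound_conserved: bool
    regulated: bool
    response_class: str
    direction: str


def _promoter_genes(calls_frame: pd.DataFrame) -> set[str]:
    mask = (calls_frame["category"] == "promoter") & (calls_frame["gene_id"] != "")
    return set(calls_frame.loc[mask, "gene_id"])


def direct_targets(
    feature_calls: Mapping[str, pd.DataFrame],
    consensus: Sequence[ConsensusPeak],
    responses: pd.DataFrame,
    reference: str,
    gene_universe: Collection[str],
) -> list[TargetCall]:
    """Candidate direct promoter targets among regulated genes.

    ``feature_calls`` maps sample -> FeatureCall table; ``responses`` is the
    output of :func:`grhl2net.bruseq_response.compute_responses`. Regulated
    genes absent from ``gene_universe`` raise a validation error listing the
    offending ids. Output is sorted by gene id; the conserved-promoter set
    is nested inside the reference-promoter set by construction.
    """
    if reference not in feature_calls:
        raise ValidationError(f"no feature calls for reference {reference!r}")
    regulated = responses.index[responses["regulated"]]
    unknown = sorted(set(regulated) - set(gene_universe))
    if unknown:
        raise ValidationError(
            f"regulated gene ids not in annotation: {', '.join(unknown)}"
        )
    ref_promoter = _promoter_genes(feature_calls[reference])

    lookup = {
        sample: dict(zip(frame["peak_id"], frame["category"]))
        for sample, frame in feature_calls.items()
    }
    gene_of_ref_peak = dict(
        zip(feature_calls[reference]["peak_id"], feature_calls[reference]["gene_id"])
    )
    conserved = conserved_promoter_peaks(consensus, lookup, reference)
    conserved_genes = {
        gene_of_ref_peak[cp.members[reference].name]
        for cp in conserved
        if gene_of_ref_peak.get(cp.members[reference].name)
    }

    calls = []
    for gene in sorted(regulated):
        in_ref = gene in ref_promoter
        calls.append(
            TargetCall(
                gene_id=gene,
                promoter_bound_reference=in_ref,
                promoter_bound_conserved=in_ref and gene in conserved_genes,
                regulated=True,
                response_class=str(responses.at[gene, "response_class"]),
                direction=str(responses.at[gene, "direction"]),
            )
        )
    return calls


def targets_to_frame(calls: Sequence[TargetCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "promoter_bound_reference": [c.promoter_bound_reference for c in calls],
            "promoter_bound_conserved": [c.promoter_bound_conserved for c in calls],
            "response_class": [c.response_class for c in calls],
            "direction": [c.direction for c in calls],
        }
    )


def class_by_binding_table(
    calls: Sequence[TargetCall],
) -> tuple[pd.DataFrame, float, float]:
    """Contingency of response class x reference promoter binding.

    Returns (table, chi-square statistic, p). The chi-square independence
    test is computed without continuity correction; degenerate tables
    (a single class or a single binding level) report statistic 0, p = 1.
    """
    if not calls:
        raise ValidationError("need at least one target call")
    frame = pd.DataFrame(
        {
            "response_class": [c.response_class for c in calls],
            "promoter_bound": [c.promoter_bound_reference for c in calls],
        }
    )
    table = pd.crosstab(frame["response_class"], frame["promoter_bound"])
    if table.shape[0] < 2 or table.shape[1] < 2:
        return table, 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table.values, correction=False)
    return table, float(chi2), float(p)
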