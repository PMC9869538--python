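"""Validation of knockout-derived gene clusters in a patient cohort.

From the knockout time course, the positively associated cluster contains
genes repressed upon knockout (control guide fold change inside (0.75, 1.5)
at every timepoint, both knockout guides FC < 0.75 at >= 3 of 4
timepoints); the negatively associated cluster mirrors it with FC > 1.5.
In the cohort, patients are ranked into quartiles of the driver gene's
(GRHL2) expression; per-patient cluster scores (unweighted mean log2
expression) are compared between Q1 and Q4 with a two-sided Welch t-test,
and per-gene Pearson correlations with the driver are reported with
Benjamini-Hochberg q-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import AnalysisConfig, ValidationError

SUBGROUPS = ("All", "ER+", "ER-")


@dataclass(frozen=True)
class SignatureClusters:
    positive_genes: tuple[str, ...]  # down upon knockout
    negative_genes: tuple[str, ...]  # up upon knockout

    def __post_init__(self) -> None:
        if set(self.positive_genes) & set(self.negative_genes):
            raise ValidationError("signature clusters must be disjoint")


@dataclass
class CohortDataset:
    """Patient x gene log2 expression with per-patient ER status."""

    expression: pd.DataFrame  # index patient_id, columns gene ids
    er_status: pd.Series  # "ER+" / "ER-"
    driver_gene: str = "GRHL2"

    def __post_init__(self) -> None:
        if self.driver_gene not in self.expression.columns:
            raise ValidationError(f"driver gene {self.driver_gene!r} absent")
        if not self.er_status.index.equals(self.expression.index):
            raise ValidationError("er_status index must match expression index")
        if self.expression[self.driver_gene].isna().any():
            raise ValidationError("driver gene expression must be complete")

    def subset(self, subgroup: str) -> pd.DataFrame:
        if subgroup == "All":
            return self.expression
        if subgroup not in SUBGROUPS:
            raise ValidationError(f"unknown subgroup {subgroup!r}")
        return self.expression[self.er_status == subgroup]


def write_cohort(cohort: CohortDataset, path) -> None:
    out = cohort.expression.copy()
    out.insert(0, "ER_status", cohort.er_status)
    out.index.name = "patient_id"
    out.reset_index().to_csv(path, sep="\t", index=False,
                             float_format="%.6g", lineterminator="\n")


def read_cohort(path, driver_gene: str = "GRHL2") -> CohortDataset:
    frame = pd.read_csv(path, sep="\t").set_index("patient_id")
    er = frame.pop("ER_status")
    return CohortDataset(frame, er, driver_gene)


def select_signature(
    responses: pd.DataFrame,
    config: AnalysisConfig | None = None,
    control: str = "sgCTR",
) -> SignatureClusters:
    """Select the positively / negatively associated gene clusters from the
    knockout fold-change profiles (see module docstring for the rule)."""
    cfg = config or AnalysisConfig()
    treated = [t for t in cfg.timepoints_days if t > 0]
    guides = sorted(
        {c.split(":")[1] for c in responses.columns if c.startswith("FC:")}
    )
    ko_guides = [g for g in guides if g != control]
    if control not in guides or len(ko_guides) != 2:
        raise ValidationError("responses must cover the control and two guides")

    ctrl_ok = np.ones(len(responses), dtype=bool)
    for t in treated:
        fc = responses[f"FC:{control}:{t}"].to_numpy()
        ctrl_ok &= (fc > cfg.sig_ctrl_low) & (fc < cfg.sig_ctrl_high)

    def guide_hits(bound_low: bool) -> np.ndarray:
        ok = np.ones(len(responses), dtype=bool)
        for g in ko_guides:
            hits = np.zeros(len(responses), dtype=int)
            for t in treated:
                fc = responses[f"FC:{g}:{t}"].to_numpy()
                hits += (fc < cfg.sig_guide_low) if bound_low else (fc > cfg.sig_guide_high)
            ok &= hits >= cfg.sig_min_timepoints
        return ok

    positive = ctrl_ok & guide_hits(bound_low=True)
    negative = ctrl_ok & guide_hits(bound_low=False)
    genes = responses.index
    return SignatureClusters(
        tuple(sorted(genes[positive])), tuple(sorted(genes[negative]))
    )


@dataclass
class QuartileReport:
    quartile: pd.Series  # patient -> "Q1".."Q4" (Q1 = lowest driver expression)
    cluster_score: pd.Series  # per-patient mean log2 expression over the cluster
    summary: pd.DataFrame  # per-quartile distribution summaries
    t_p: float  # two-sided Welch t-test, Q1 vs Q4 cluster scores


def quartile_analysis(
    cohort: CohortDataset,
    cluster_genes: Sequence[str],
    subgroup: str = "All",
) -> QuartileReport:
    """Quartile analysis of mean cluster expression against driver quartiles.

    Patients are ranked by driver expression (stable ties by patient id) and
    split into four groups whose sizes differ by at most one.
    """
    if not cluster_genes:
        raise ValidationError("cluster_genes must be non-empty")
    missing = sorted(set(cluster_genes) - set(cohort.expression.columns))
    if missing:
        raise ValidationError(f"cluster genes absent from cohort: {missing}")
    expr = cohort.subset(subgroup)
    if len(expr) < 8:
        raise ValidationError(f"subgroup {subgroup!r} has fewer than 8 patients")
    order = expr[cohort.driver_gene].reset_index()
    order.columns = ["patient_id", "driver"]
    order = order.sort_values(["driver", "patient_id"], kind="mergesort")
    chunks = np.array_split(order["patient_id"].to_numpy(), 4)
    quartile = pd.Series(index=expr.index, dtype=object)
    for i, chunk in enumerate(chunks, start=1):
        quartile.loc[chunk] = f"Q{i}"
    score = expr[list(cluster_genes)].mean(axis=1)
    rows = []
    for q in ("Q1", "Q2", "Q3", "Q4"):
        vals = score[quartile == q]
        rows.append(
            {
                "quartile": q,
                "n": len(vals),
                "mean": vals.mean(),
                "median": vals.median(),
                "q25": vals.quantile(0.25),
                "q75": vals.quantile(0.75),
            }
        )
    t_p = float(
        stats.ttest_ind(
            score[quartile == "Q1"], score[quartile == "Q4"], equal_var=False
        ).pvalue
    )
    return QuartileReport(quartile, score, pd.DataFrame(rows), t_p)


def per_gene_correlation(
    cohort: CohortDataset,
    genes: Sequence[str],
    subgroup: str = "All",
) -> pd.DataFrame:
    """Pearson R of each gene vs the driver, two-sided p and BH q-values.

    Constant expression vectors yield undefined correlations, reported as
    missing and excluded from the BH correction.
    """
    expr = cohort.subset(subgroup)
    if len(expr) < 3:
        raise ValidationError("need at least 3 patients")
    driver = expr[cohort.driver_gene].to_numpy()
    records = []
    for gene in genes:
        if gene not in expr.columns:
            raise ValidationError(f"gene {gene!r} absent from cohort")
        values = expr[gene].to_numpy()
        if np.ptp(values) == 0 or np.ptp(driver) == 0:
            records.append((gene, np.nan, np.nan))
            continue
        r, p = stats.pearsonr(values, driver)
        records.append((gene, float(r), float(p)))
    frame = pd.DataFrame(records, columns=["gene_id", "R", "p"])
    frame["q"] = np.nan
    defined = frame["p"].notna()
    if defined.any():
        frame.loc[defined, "q"] = multipletests(
            frame.loc[defined, "p"], method="fdr_bh"
        )[1]
    return frame
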