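"""Nascent-transcription (Bru-seq) time-course response analysis.

Per guide line (non-targeting control sgCTR plus two knockout guides), each
doxycycline timepoint is compared with that line's untreated day-0 sample:
RPKM-based fold change with a small pseudocount, and a two-sided
two-library proportion test on the gene's read counts (exact conditional
binomial when the smaller count is < 25, normal approximation otherwise).
Genes are "regulated" when both knockout guides respond (p < 0.05 and
FC > 2 or FC < 0.5 at >= 1 timepoint each) while the control guide never
does. The average fold change (AFC) over the two knockout guides is the
geometric mean, and genes are classified into the five dynamic-response
patterns (sustained induction/repression, induction/repression reset,
dynamic) or "other". ChIP-qPCR arithmetic (percent input, 2^-ddCt) is
included for completeness.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AnalysisConfig, ValidationError

RESPONSE_CLASSES = (
    "sustained_induction",
    "sustained_repression",
    "induction_reset",
    "repression_reset",
    "dynamic",
    "other",
)

_COLUMN_RE = re.compile(r"^(?P<guide>[^:]+):(?P<day>\d+)$")


@dataclass
class CountsMatrix:
    """Gene x sample read counts with per-sample guide/day metadata.

    Columns are named ``guide:day`` (e.g. ``sgGRHL2_1:8``). ``library_total``
    holds mapped reads per sample and must be >= the column sum.
    """

    counts: pd.DataFrame  # index gene_id, int counts
    lengths: pd.Series  # gene length in bp
    library_total: dict[str, int]

    def __post_init__(self) -> None:
        for col in self.counts.columns:
            if not _COLUMN_RE.match(col):
                raise ValidationError(f"bad sample column {col!r} (want guide:day)")
        pairs = [self.sample_meta(c) for c in self.counts.columns]
        if len(set(pairs)) != len(pairs):
            raise ValidationError("one sample per (guide, timepoint) required")
        if (self.counts.values < 0).any():
            raise ValidationError("counts must be non-negative")
        if not self.lengths.index.equals(self.counts.index):
            raise ValidationError("lengths index must match counts index")
        if (self.lengths <= 0).any():
            raise ValidationError("gene lengths must be > 0")
        for col in self.counts.columns:
            total = self.library_total.get(col)
            if total is None:
                raise ValidationError(f"missing library_total for {col!r}")
            if total < int(self.counts[col].sum()):
                raise ValidationError(f"library_total < column sum for {col!r}")

    @staticmethod
    def sample_meta(column: str) -> tuple[str, int]:
        m = _COLUMN_RE.match(column)
        if m is None:
            raise ValidationError(f"bad sample column {column!r}")
        return m.group("guide"), int(m.group("day"))

    @property
    def guides(self) -> list[str]:
        return sorted({self.sample_meta(c)[0] for c in self.counts.columns})

    @property
    def timepoints(self) -> list[int]:
        return sorted({self.sample_meta(c)[1] for c in self.counts.columns})

    def column(self, guide: str, day: int) -> str:
        col = f"{guide}:{day}"
        if col not in self.counts.columns:
            raise ValidationError(f"missing sample {col!r}")
        return col


def write_counts(matrix: CountsMatrix, path) -> None:
    with open(path, "w") as handle:
        totals = " ".join(
            f"{c}={matrix.library_total[c]}" for c in matrix.counts.columns
        )
        handle.write(f"# library_total: {totals}\n")
        out = matrix.counts.copy()
        out.insert(0, "length_bp", matrix.lengths)
        out.index.name = "gene_id"
        out.reset_index().to_csv(handle, sep="\t", index=False,
                                 lineterminator="\n")


def read_counts(path) -> CountsMatrix:
    totals: dict[str, int] = {}
    with open(path) as handle:
        first = handle.readline()
        if not first.startswith("# library_total:"):
            raise ValidationError("counts file must start with a library_total line")
        for item in first.split(":", 1)[1].split():
            col, value = item.split("=")
            totals[col] = int(value)
        frame = pd.read_csv(handle, sep="\t")
    frame = frame.set_index("gene_id")
    lengths = frame.pop("length_bp")
    return CountsMatrix(frame, lengths, totals)


def rpkm(counts, length_bp, library_total):
    """Reads per kilobase of gene per million mapped reads."""
    if np.any(np.asarray(library_total) <= 0):
        raise ValidationError("library_total must be > 0")
    if np.any(np.asarray(length_bp) <= 0):
        raise ValidationError("length_bp must be > 0")
    return counts / (np.asarray(length_bp) / 1000.0) / (library_total / 1e6)


def two_library_proportion_p(x1: int, n1: int, x0: int, n0: int) -> float:
    """Two-sided test that a gene's counts are in equal proportion in two
    libraries.

    Exact conditional (binomial) test when min(x0, x1) < 25, pooled normal
    approximation otherwise.
    """
    total = x0 + x1
    if total == 0:
        return 1.0
    if min(x0, x1) < 25:
        return float(
            stats.binomtest(x1, total, n1 / (n0 + n1)).pvalue
        )
    p1, p0 = x1 / n1, x0 / n0
    pooled = total / (n0 + n1)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n0 + 1 / n1))
    if se == 0:
        return 1.0
    z = (p1 - p0) / se
    return float(2 * stats.norm.sf(abs(z)))


def fold_change_and_p(
    matrix: CountsMatrix,
    guide: str,
    day: int,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Per-gene fold change and p-value of one treated sample vs its day 0.

    FC = (RPKM_t + eps) / (RPKM_0 + eps) with pseudocount eps in RPKM units.
    """
    cfg = config or AnalysisConfig()
    col_t = matrix.column(guide, day)
    col_0 = matrix.column(guide, 0)
    n_t, n_0 = matrix.library_total[col_t], matrix.library_total[col_0]
    rpkm_t = rpkm(matrix.counts[col_t], matrix.lengths, n_t)
    rpkm_0 = rpkm(matrix.counts[col_0], matrix.lengths, n_0)
    eps = cfg.pseudocount_rpkm
    fc = (rpkm_t + eps) / (rpkm_0 + eps)
    pvals = [
        two_library_proportion_p(int(xt), n_t, int(x0), n_0)
        for xt, x0 in zip(matrix.counts[col_t], matrix.counts[col_0])
    ]
    return pd.DataFrame({"FC": fc, "p": pvals}, index=matrix.counts.index)


def average_fold_change(fc_guide1, fc_guide2):
    """Geometric-mean AFC of the two knockout guides (mean in log2 space)."""
    return np.sqrt(np.asarray(fc_guide1) * np.asarray(fc_guide2))


def classify_response(
    afc: Mapping[int, float],
    significant: Mapping[int, bool],
    config: AnalysisConfig | None = None,
) -> str:
    """Assign one gene's AFC profile to a dynamic-response class.

    ``significant[t]`` must hold p < alpha in *both* knockout guides.
    "Early" timepoints are all treated timepoints before the last one; the
    reset classes require a return into (1, 2) / (0.5, 1) at the final day.
    Evaluation order: sustained induction, sustained repression, induction
    reset, repression reset, dynamic, other.
    """
    cfg = config or AnalysisConfig()
    treated = [t for t in cfg.timepoints_days if t > 0]
    missing = [t for t in treated if t not in afc or t not in significant]
    if missing:
        raise ValidationError(f"missing timepoint(s) {missing} in AFC profile")
    early, last = treated[:-1], treated[-1]

    def up(t):
        return afc[t] > cfg.fc_up and significant[t]

    def down(t):
        return afc[t] < cfg.fc_down and significant[t]

    if all(up(t) for t in treated):
        return "sustained_induction"
    if all(down(t) for t in treated):
        return "sustained_repression"
    if all(up(t) for t in early) and 1 < afc[last] < cfg.fc_up:
        return "induction_reset"
    if all(down(t) for t in early) and cfg.fc_down < afc[last] < 1:
        return "repression_reset"
    if any(up(t) for t in treated) and any(down(t) for t in treated):
        return "dynamic"
    return "other"


def compute_responses(
    matrix: CountsMatrix,
    config: AnalysisConfig | None = None,
    control: str = "sgCTR",
) -> pd.DataFrame:
    """Full per-gene response table: FC/p per guide and timepoint, AFC,
    regulated flag, direction and response class.

    Requires exactly two non-control guides. Regulated genes must pass the
    dual-guide filter (both knockout guides respond at >= 1 timepoint) with
    the control guide passing at none.
    """
    cfg = config or AnalysisConfig()
    guides = matrix.guides
    if control not in guides:
        raise ValidationError(f"control guide {control!r} absent")
    ko_guides = [g for g in guides if g != control]
    if len(ko_guides) != 2:
        raise ValidationError("expected exactly two knockout guides")
    treated = [t for t in cfg.timepoints_days if t > 0]

    fc: dict[tuple[str, int], pd.Series] = {}
    pv: dict[tuple[str, int], pd.Series] = {}
    for guide in guides:
        for t in treated:
            table = fold_change_and_p(matrix, guide, t, cfg)
            fc[(guide, t)] = table["FC"]
            pv[(guide, t)] = table["p"]

    out = pd.DataFrame(index=matrix.counts.index)
    for guide in guides:
        for t in treated:
            out[f"FC:{guide}:{t}"] = fc[(guide, t)]
            out[f"p:{guide}:{t}"] = pv[(guide, t)]
    g1, g2 = ko_guides
    for t in treated:
        out[f"AFC:{t}"] = average_fold_change(fc[(g1, t)], fc[(g2, t)])

    def passes(guide, t):
        return (pv[(guide, t)] < cfg.alpha) & (
            (fc[(guide, t)] > cfg.fc_up) | (fc[(guide, t)] < cfg.fc_down)
        )

    ko_pass = {g: np.column_stack([passes(g, t) for t in treated]) for g in ko_guides}
    ctrl_pass = np.column_stack([passes(control, t) for t in treated])
    regulated = (
        ko_pass[g1].any(axis=1)
        & ko_pass[g2].any(axis=1)
        & ~ctrl_pass.any(axis=1)
    )
    out["regulated"] = regulated

    directions = []
    classes = []
    for i, gene in enumerate(out.index):
        # class is a property of the AFC profile; the regulated flag is a
        # separate (dual-guide + control-exclusion) filter
        afc = {t: out.at[gene, f"AFC:{t}"] for t in treated}
        sig = {
            t: bool(pv[(g1, t)].iloc[i] < cfg.alpha and pv[(g2, t)].iloc[i] < cfg.alpha)
            for t in treated
        }
        classes.append(classify_response(afc, sig, cfg))
        if not regulated[i]:
            directions.append("")
            continue
        passing_fcs = [
            fc[(g, t)].iloc[i]
            for g in ko_guides
            for j, t in enumerate(treated)
            if ko_pass[g][i, j]
        ]
        if all(f > cfg.fc_up for f in passing_fcs):
            directions.append("up")
        elif all(f < cfg.fc_down for f in passing_fcs):
            directions.append("down")
        else:
            directions.append("mixed")
    out["direction"] = directions
    out["response_class"] = classes
    out.index.name = "gene_id"
    return out


def regulated_genes(responses: pd.DataFrame) -> list[str]:
    return sorted(responses.index[responses["regulated"]])


def heatmap_matrix(
    responses: pd.DataFrame, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Regulated genes x timepoints log2 AFC matrix with class labels.

    Rows ordered by response class, then by day-2 log2 AFC descending.
    """
    cfg = config or AnalysisConfig()
    treated = [t for t in cfg.timepoints_days if t > 0]
    sub = responses[responses["regulated"]]
    if sub.empty:
        raise ValidationError("no regulated genes to plot")
    matrix = pd.DataFrame(
        {f"log2AFC:{t}": np.log2(sub[f"AFC:{t}"]) for t in treated},
        index=sub.index,
    )
    matrix["response_class"] = sub["response_class"]
    class_rank = {c: i for i, c in enumerate(RESPONSE_CLASSES)}
    matrix = matrix.sort_values(
        by=["response_class", f"log2AFC:{treated[0]}"],
        key=lambda col: col.map(class_rank) if col.name == "response_class" else -col,
        kind="mergesort",
    )
    return matrix


def optimal_cluster_count(
    afc_matrix: np.ndarray, k_max: int, seed: int = 0, n_init: int = 25
) -> tuple[int, np.ndarray]:
    """k-means within-cluster sum of squares for k = 1..k_max; elbow at the
    maximum second difference of log WSS.

    The curvature is taken on the log scale because raw WSS drops are
    dominated by the first split, which hides elbows at larger k; on the log
    scale the sharp relative drop when k reaches the planted cluster count
    dominates. Degenerate inputs (all rows identical) return k = 1.
    """
    X = np.asarray(afc_matrix, dtype=float)
    if X.shape[0] < k_max + 1:
        raise ValidationError("need more rows than k_max")
    from sklearn.cluster import KMeans

    wss = np.empty(k_max)
    for k in range(1, k_max + 1):
        model = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        model.fit(X)
        wss[k - 1] = model.inertia_
    if wss[0] <= 1e-12:
        return 1, wss
    if k_max < 3:
        return int(np.argmin(wss) + 1), wss
    log_wss = np.log(np.maximum(wss, 1e-12 * wss[0]))
    second_diff = log_wss[:-2] - 2 * log_wss[1:-1] + log_wss[2:]  # k = 2..k_max-1
    return int(np.argmax(second_diff) + 2), wss


@dataclass
class QPCRRecord:
    """Ct values for qPCR quantification (missing fields stay None)."""

    ct_target_cond: float | None = None
    ct_ref_cond: float | None = None
    ct_target_ctrl: float | None = None
    ct_ref_ctrl: float | None = None
    ct_ip: float | None = None
    ct_input: float | None = None
    dilution_factor: float = 1.0


def qpcr_quantify(record: QPCRRecord, mode: str) -> float:
    """ChIP-qPCR quantification: "percent_input" or relative "ddct" (2^-ddCt)."""
    if mode == "percent_input":
        if record.ct_ip is None or record.ct_input is None:
            raise ValidationError("percent_input needs ct_ip and ct_input")
        if record.dilution_factor <= 0:
            raise ValidationError("dilution_factor must be > 0")
        adj_input = record.ct_input - math.log2(record.dilution_factor)
        return 100.0 * 2 ** (adj_input - record.ct_ip)
    if mode == "ddct":
        needed = (record.ct_target_cond, record.ct_ref_cond,
                  record.ct_target_ctrl, record.ct_ref_ctrl)
        if any(v is None for v in needed):
            raise ValidationError("ddct needs all four Ct values")
        ddct = (record.ct_target_cond - record.ct_ref_cond) - (
            record.ct_target_ctrl - record.ct_ref_ctrl
        )
        return 2.0 ** (-ddct)
    raise ValueError(f"unknown mode {mode!r}")
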