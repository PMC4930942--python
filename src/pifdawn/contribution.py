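"""Percent contribution of PIFq to the night response.

For each gene, log2 fold changes of WT-SD and pifq-SD are taken
relative to the WT-LL reference (the no-night, free-running state set
to 0).  The contribution of PIFq to the change the night elicits in the
wild type is

    contribution% = 100 * (FC_WT - FC_pifq) / FC_WT

on those log2-scale fold changes: 100% when the mutant fully reverts to
the LL level, 0% when the mutant retains the full WT response, and
values above 100% (no clipping) when the mutant overshoots the LL
level.  Genes whose WT night response is below a documented floor
(default log2(1.5)) have an undefined contribution and are excluded
from set summaries.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix, PipelineError

#: |FC_WT| below this makes the denominator unstable; SS1.5F genes are
#: always above it, so the floor only guards ad-hoc gene lists.
DEFAULT_FC_FLOOR = float(np.log2(1.5))

#: Combined sample size at or below which the rank-sum test uses the
#: exact null distribution (no ties); above it, the normal
#: approximation with continuity and tie correction.
EXACT_RANKSUM_MAX_N = 20


def contribution_pct(fc_wt_log2: float, fc_pifq_log2: float) -> float:
    """The contribution formula on a single pair of log2 fold changes."""
    return 100.0 * (fc_wt_log2 - fc_pifq_log2) / fc_wt_log2


def per_gene_contribution(
    matrix: ExpressionMatrix,
    genes: set[str] | list[str],
    fc_floor: float = DEFAULT_FC_FLOOR,
) -> pd.DataFrame:
    """Per-gene fold changes relative to WT-LL and percent contribution.

    Columns: fc_wt_log2, fc_pifq_log2, contribution_pct, defined.
    Genes with |fc_wt_log2| < fc_floor are flagged undefined
    (contribution_pct = NaN), not dropped.
    """
    genes = list(genes)
    missing = sorted(set(genes) - set(matrix.gene_ids))[:10]
    if missing:
        raise PipelineError(f"genes absent from matrix: {missing}")
    wt_ll = matrix.group_means("WT", "LL").loc[genes]
    fc_wt = matrix.group_means("WT", "SD").loc[genes] - wt_ll
    fc_pifq = matrix.group_means("pifq", "SD").loc[genes] - wt_ll
    defined = fc_wt.abs() >= fc_floor
    contrib = pd.Series(np.nan, index=fc_wt.index)
    contrib[defined] = 100.0 * (fc_wt[defined] - fc_pifq[defined]) / fc_wt[defined]
    return pd.DataFrame(
        {
            "fc_wt_log2": fc_wt,
            "fc_pifq_log2": fc_pifq,
            "contribution_pct": contrib,
            "defined": defined,
        }
    )


def set_mean_fc(
    matrix: ExpressionMatrix,
    genes: set[str] | list[str],
    group: tuple[str, str],
) -> tuple[float, float]:
    """Mean and SE over a gene set of the group's log2 FC vs WT-LL.

    WT-LL itself returns (0, 0) by construction.
    """
    genes = list(genes)
    if not genes:
        raise PipelineError("empty gene set")
    fc = matrix.group_means(*group).loc[genes] - matrix.group_means("WT", "LL").loc[genes]
    se = float(fc.std(ddof=1) / np.sqrt(len(fc))) if len(fc) > 1 else 0.0
    return float(fc.mean()), se


def _ranksum_exact_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact rank-sum p by full enumeration (ties allowed).

    Enumerates all C(n_a + n_b, n_a) assignments of the pooled
    mid-ranks; used for small samples.
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a = len(a)
    w_obs = ranks[:n_a].sum()
    mean_w = n_a * (len(pooled) + 1) / 2.0
    dev = abs(w_obs - mean_w)
    total = comb(len(pooled), n_a)
    hits = sum(
        1
        for idx in combinations(range(len(pooled)), n_a)
        if abs(ranks[list(idx)].sum() - mean_w) >= dev - 1e-12
    )
    return hits / total


def group_distribution_test(
    matrix: ExpressionMatrix,
    genes: set[str] | list[str],
    group_a: tuple[str, str],
    group_b: tuple[str, str],
) -> float:
    """Two-sided Wilcoxon rank-sum p comparing two groups over a gene set.

    Compares the per-gene group-mean log2 expression distributions.
    Exact null when the combined size is <= 20, normal approximation
    with continuity correction (and mid-rank tie handling) otherwise;
    fully tied data returns p = 1.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise PipelineError("need >= 2 genes for a distribution test")
    a = matrix.group_means(*group_a).loc[genes].to_numpy()
    b = matrix.group_means(*group_b).loc[genes].to_numpy()
    return rank_sum_test(a, b)


def rank_sum_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p-value on two samples (see group_distribution_test)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    if len(pooled) <= EXACT_RANKSUM_MAX_N:
        if len(np.unique(pooled)) == len(pooled):
            return float(
                stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            )
        return _ranksum_exact_p(a, b)
    return float(
        stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        ).pvalue
    )


def contribution_ranking(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, float, float]:
    """Rank defined contributions and report threshold fractions.

    Returns (records sorted descending by contribution_pct,
    fraction strictly above 50%, fraction at or above 100%).
    """
    defined = records[records["defined"]] if "defined" in records else records
    if defined.empty:
        raise PipelineError("no defined contribution records to rank")
    ranked = defined.sort_values("contribution_pct", ascending=False)
    vals = ranked["contribution_pct"]
    return ranked, float((vals > 50).mean()), float((vals >= 100).mean())
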