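"""Two-group contrasts with the SS1.5F gate.

Each contrast (WT-SD vs WT-LL for night regulation; pifq-SD vs WT-SD
for PIFq regulation) is a per-gene two-sample test on log2 intensities,
Benjamini-Hochberg corrected across the genes of that contrast.  A gene
is SS1.5F ("statistically significant, 1.5-fold") when its BH q-value
passes alpha AND its absolute fold change reaches the 1.5-fold
threshold, i.e. |log2FC| >= log2(1.5).

Proprietary array-analysis suites gain power at 2-4 replicates by
weighting each gene's test with error information pooled across the
whole array.  The default test here does the same from first
principles: an empirical-Bayes moderated two-sample t-test that
shrinks per-gene pooled variances toward a global prior fitted by the
scaled-F moments method (Smyth 2004), adding the prior's degrees of
freedom to each gene's own.  The test function is injectable, so plain
Welch (also provided) or any other two-sample test can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix, PipelineError

#: Test statistic signature: (test values, reference values), each
#: genes x replicates, -> two-sided p-value per gene.
TestFn = Callable[[np.ndarray, np.ndarray], np.ndarray]


@dataclass(frozen=True)
class ContrastSpec:
    name: str
    test_group: tuple[str, str]
    reference_group: tuple[str, str]

    def __post_init__(self) -> None:
        if self.test_group == self.reference_group:
            raise PipelineError(
                f"contrast {self.name!r}: test and reference groups are identical"
            )


#: The two contrasts of the dawn experiment.
SD_CONTRAST = ContrastSpec("SD", test_group=("WT", "SD"), reference_group=("WT", "LL"))
PIF_CONTRAST = ContrastSpec(
    "PIF", test_group=("pifq", "SD"), reference_group=("WT", "SD")
)


@dataclass
class ContrastResult:
    """Per-gene statistics of one two-group contrast.

    ``table`` columns: log2fc, fold_change_linear (signed, magnitude
    >= 1), p_value, q_value, ss15f.
    """

    name: str
    table: pd.DataFrame
    alpha: float
    fc_threshold: float

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index


def welch_test(test: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Vectorized Welch two-sample t-test, two-sided, per gene (row).

    Zero-variance rows, where the t statistic is undefined, use the
    noiseless convention: p = 1 when the group means are equal, p = 0
    when they differ (a deterministic separation).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = stats.ttest_ind(test, reference, axis=1, equal_var=False)
    p = np.asarray(stat.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        equal = np.isclose(test.mean(axis=1), reference.mean(axis=1))
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = 0.0
    return p


def _trigamma_inverse(x: float, iters: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on 1/trigamma)."""
    from scipy.special import polygamma

    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(iters):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moments fit of a scaled F prior to sample variances.

    Models s2 ~ s0^2 * F(df, d0) and returns (d0, s0^2), the prior
    degrees of freedom and prior variance; d0 = inf when the observed
    spread of log variances is no larger than the sampling spread.
    """
    from scipy.special import digamma, polygamma

    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise PipelineError("too few positive variances to fit a prior")
    e = np.log(s2[ok]) - float(digamma(df / 2.0)) + np.log(df / 2.0)
    e_var = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if e_var <= 0:
        return np.inf, float(np.exp(np.mean(e)))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_sq = float(np.exp(np.mean(e) + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_t_test(test: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Empirical-Bayes moderated two-sample t-test, two-sided, per gene.

    Per-gene pooled variances are shrunk toward a global prior fitted
    across all genes; the moderated t has df = d_gene + d_prior.
    Degenerate inputs (all variances zero) fall back to the noiseless
    convention of :func:`welch_test`.
    """
    n1, n2 = test.shape[1], reference.shape[1]
    df = n1 + n2 - 2
    if df <= 0:
        raise PipelineError("need >= 2 replicates combined beyond the group count")
    delta = test.mean(axis=1) - reference.mean(axis=1)
    ss = test.var(axis=1, ddof=1) * (n1 - 1) + reference.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df
    if (s2 <= 0).all():
        return np.where(np.isclose(delta, 0.0), 1.0, 0.0)
    d0, s0_sq = fit_f_dist(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.asarray(p, dtype=float)
    bad = ~np.isfinite(p)
    if bad.any():
        p[bad & np.isclose(delta, 0.0)] = 1.0
        p[bad & ~np.isclose(delta, 0.0)] = 0.0
    return np.minimum(p, 1.0)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q(i) = min over ranks j >= i of m * p(j) / j on the ascending-sorted
    p-values, clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise PipelineError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def run_contrast(
    matrix: ExpressionMatrix,
    spec: ContrastSpec,
    alpha: float = 0.05,
    fc_threshold: float = 1.5,
    test_fn: TestFn = moderated_t_test,
) -> ContrastResult:
    """Per-gene contrast, BH correction, SS1.5F flags.

    log2fc is the difference of group means of log2 values (test minus
    reference); fold_change_linear is 2**|log2fc| signed by direction.
    """
    if not 0 < alpha < 1:
        raise PipelineError("alpha must lie in (0, 1)")
    if fc_threshold <= 1:
        raise PipelineError("fc_threshold must exceed 1")
    for role, (genotype, condition) in (
        ("test", spec.test_group),
        ("reference", spec.reference_group),
    ):
        n = len(matrix.group_samples(genotype, condition))
        if n < 2:
            raise PipelineError(
                f"contrast {spec.name!r}: {role} group ({genotype}, {condition}) "
                f"has {n} replicate(s); need >= 2"
            )

    test_vals = matrix.group_values(*spec.test_group).to_numpy(dtype=float)
    ref_vals = matrix.group_values(*spec.reference_group).to_numpy(dtype=float)

    log2fc = test_vals.mean(axis=1) - ref_vals.mean(axis=1)
    p = test_fn(test_vals, ref_vals)
    q = benjamini_hochberg(p)
    log2_thresh = np.log2(fc_threshold)
    ss15f = (q <= alpha) & (np.abs(log2fc) >= log2_thresh)
    linear = np.where(log2fc >= 0, 2.0 ** log2fc, -(2.0 ** (-log2fc)))

    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "fold_change_linear": linear,
            "p_value": p,
            "q_value": q,
            "ss15f": ss15f,
        },
        index=matrix.gene_ids,
    )
    return ContrastResult(spec.name, table, alpha, fc_threshold)


def ss15f_gate(
    result: ContrastResult,
    alpha: float | None = None,
    fc_threshold: float | None = None,
) -> set[str]:
    """Gene ids passing the SS1.5F gate, optionally re-thresholded."""
    alpha = result.alpha if alpha is None else alpha
    fc_threshold = result.fc_threshold if fc_threshold is None else fc_threshold
    t = result.table
    mask = (t["q_value"] <= alpha) & (
        t["log2fc"].abs() >= np.log2(fc_threshold)
    )
    return set(t.index[mask])
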