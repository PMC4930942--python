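"""Sign-concordant classification of the two SS1.5F gene lists.

Genes SS1.5F in both contrasts fall into three classes by the signs of
their two log2 fold changes: night- and PIF-induced (up in WT under
short days vs continuous light, down in the pifq mutant vs WT),
night- and PIF-repressed (the mirror pattern), or ambiguous (same sign
in both contrasts).  Genes SS1.5F in only one contrast are night-only
or PIF-only responders; the rest are unregulated.  The reciprocal-sign
association is scored with a one-sided exact binomial test on quadrant
membership.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .core import PipelineError
from .diffexpr import ContrastResult, ss15f_gate

LABELS = ("pifsd_induced", "pifsd_repressed", "ambiguous", "sd_only", "pif_only", "none")


@dataclass
class GeneClassification:
    """Per-gene label plus the two log2 fold changes behind it.

    ``table`` columns: label, sd_log2fc, pif_log2fc.
    """

    table: pd.DataFrame

    def genes_with_label(self, *labels: str) -> set[str]:
        return set(self.table.index[self.table["label"].isin(labels)])

    def counts(self) -> dict[str, int]:
        vc = self.table["label"].value_counts()
        return {lab: int(vc.get(lab, 0)) for lab in LABELS}


def classify_genes(sd: ContrastResult, pif: ContrastResult) -> GeneClassification:
    """Assign each gene its sign-concordance class from the two contrasts."""
    if not sd.gene_ids.equals(pif.gene_ids):
        diff = sd.gene_ids.symmetric_difference(pif.gene_ids)
        raise PipelineError(
            f"contrasts cover different gene universes ({len(diff)} genes differ)"
        )
    sd_fc = sd.table["log2fc"]
    pif_fc = pif.table["log2fc"].reindex(sd_fc.index)
    in_sd = np.asarray(sd.table["ss15f"], dtype=bool)
    in_pif = np.asarray(pif.table["ss15f"].reindex(sd_fc.index), dtype=bool)

    sd_sign = np.sign(sd_fc.to_numpy())
    pif_sign = np.sign(pif_fc.to_numpy())
    both = in_sd & in_pif
    # SS1.5F implies |log2fc| >= log2(1.5) > 0, so signs are never zero here
    label = np.full(len(sd_fc), "none", dtype=object)
    label[in_sd & ~in_pif] = "sd_only"
    label[~in_sd & in_pif] = "pif_only"
    label[both & (sd_sign > 0) & (pif_sign < 0)] = "pifsd_induced"
    label[both & (sd_sign < 0) & (pif_sign > 0)] = "pifsd_repressed"
    label[both & (sd_sign == pif_sign)] = "ambiguous"

    table = pd.DataFrame(
        {"label": label, "sd_log2fc": sd_fc, "pif_log2fc": pif_fc},
        index=sd_fc.index,
    )
    return GeneClassification(table)


def _pct(numer: int, denom: int) -> float | None:
    """Percentage to one decimal (round-half-to-even); None when undefined."""
    if denom == 0:
        return None
    return round(100.0 * numer / denom, 1)


@dataclass
class VennSummary:
    n_sd_regulated: int
    n_pif_regulated: int
    n_common: int
    n_induced: int
    n_repressed: int
    n_ambiguous: int
    pct_common_of_pif: float | None
    pct_induced_of_common: float | None
    pct_repressed_of_common: float | None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def venn_summary_from_counts(
    n_sd_regulated: int,
    n_pif_regulated: int,
    n_common: int,
    n_induced: int,
    n_repressed: int,
    n_ambiguous: int,
) -> VennSummary:
    """Summary ratios from raw intersection counts."""
    if n_induced + n_repressed + n_ambiguous != n_common:
        raise PipelineError("induced + repressed + ambiguous must equal n_common")
    return VennSummary(
        n_sd_regulated=n_sd_regulated,
        n_pif_regulated=n_pif_regulated,
        n_common=n_common,
        n_induced=n_induced,
        n_repressed=n_repressed,
        n_ambiguous=n_ambiguous,
        pct_common_of_pif=_pct(n_common, n_pif_regulated),
        pct_induced_of_common=_pct(n_induced, n_common),
        pct_repressed_of_common=_pct(n_repressed, n_common),
    )


def venn_summary(classification: GeneClassification) -> VennSummary:
    """Venn counts and one-decimal percentages from a classification."""
    c = classification.counts()
    n_common = c["pifsd_induced"] + c["pifsd_repressed"] + c["ambiguous"]
    return venn_summary_from_counts(
        n_sd_regulated=n_common + c["sd_only"],
        n_pif_regulated=n_common + c["pif_only"],
        n_common=n_common,
        n_induced=c["pifsd_induced"],
        n_repressed=c["pifsd_repressed"],
        n_ambiguous=c["ambiguous"],
    )


def quadrant_binomial_test(classification: GeneClassification) -> float:
    """One-sided exact binomial tail for reciprocal-sign concordance.

    Among the n genes SS1.5F in both contrasts, x sit in the
    reciprocal-sign quadrants (induced + repressed); returns
    P(X >= x | n, p = 0.5).
    """
    c = classification.counts()
    n = c["pifsd_induced"] + c["pifsd_repressed"] + c["ambiguous"]
    if n == 0:
        raise PipelineError("no common SS1.5F genes; binomial test undefined")
    x = c["pifsd_induced"] + c["pifsd_repressed"]
    return float(stats.binom.sf(x - 1, n, 0.5))


def set_overlap(set_a: Iterable[str], set_b: Iterable[str]) -> dict[str, int]:
    """Exact partition counts of two gene id sets."""
    a, b = set(set_a), set(set_b)
    return {
        "n_a_only": len(a - b),
        "n_b_only": len(b - a),
        "n_both": len(a & b),
    }
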