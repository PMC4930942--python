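"""Core containers shared across the pipeline.

The analysis operates on a normalized log2 expression matrix (genes x
samples) from a 2x2 design: two genotypes (wild type ``WT`` and the
quadruple phytochrome-interacting-factor mutant ``pifq``) under two
light regimes (short days ``SD`` and free-running continuous light
``LL``), with replicate seedling pools harvested at dawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOTYPES = ("WT", "pifq")
CONDITIONS = ("SD", "LL")

#: (genotype, condition) pairs in canonical order.
GROUPS = tuple((g, c) for g in GENOTYPES for c in CONDITIONS)


class PipelineError(ValueError):
    """Raised on invalid inputs or configuration."""


@dataclass
class ExpressionMatrix:
    """Log2 intensities (genes x samples) with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame of log2 intensities, index = gene ids, columns = sample ids.
    samples
        DataFrame indexed by sample id with columns ``genotype``,
        ``condition`` and ``replicate``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise PipelineError(f"duplicated gene ids: {list(dupes[:5])}")
        if self.values.columns.duplicated().any():
            raise PipelineError("duplicated sample ids in matrix")
        if self.samples.index.duplicated().any():
            raise PipelineError("duplicated sample ids in sample sheet")
        missing = self.values.columns.difference(self.samples.index)
        if len(missing):
            raise PipelineError(
                f"samples present in matrix but absent from sheet: {list(missing)}"
            )
        for col in ("genotype", "condition", "replicate"):
            if col not in self.samples.columns:
                raise PipelineError(f"sample sheet lacks required column {col!r}")
        bad = set(self.samples["genotype"]) - set(GENOTYPES)
        if bad:
            raise PipelineError(f"unknown genotypes: {sorted(bad)}")
        bad = set(self.samples["condition"]) - set(CONDITIONS)
        if bad:
            raise PipelineError(f"unknown conditions: {sorted(bad)}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise PipelineError("expression matrix contains non-finite values")
        # align sheet to matrix column order
        self.samples = self.samples.loc[self.values.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def group_samples(self, genotype: str, condition: str) -> list[str]:
        mask = (self.samples["genotype"] == genotype) & (
            self.samples["condition"] == condition
        )
        return list(self.samples.index[mask])

    def group_values(self, genotype: str, condition: str) -> pd.DataFrame:
        ids = self.group_samples(genotype, condition)
        if not ids:
            raise PipelineError(f"no samples for group ({genotype}, {condition})")
        return self.values[ids]

    def group_means(self, genotype: str, condition: str) -> pd.Series:
        return self.group_values(genotype, condition).mean(axis=1)


@dataclass
class TruthRecord:
    """Planted ground truth for one synthetic gene."""

    class_label: str
    planted_fc_wt_log2: float = 0.0
    planted_fc_pifq_log2: float = 0.0
    planted_phase_h: float | None = None
    arrhythmic: bool = False
    planted_motifs: list[str] = field(default_factory=list)


@dataclass
class SyntheticTruth:
    """Gene id -> planted truth, emitted alongside every synthetic dataset."""

    records: dict[str, TruthRecord]

    def __getitem__(self, gene_id: str) -> TruthRecord:
        return self.records[gene_id]

    def __len__(self) -> int:
        return len(self.records)

    def gene_ids(self) -> list[str]:
        return list(self.records)

    def labels(self) -> pd.Series:
        return pd.Series(
            {g: r.class_label for g, r in self.records.items()}, name="class_label"
        )

    def genes_of_class(self, *labels: str) -> set[str]:
        return {g for g, r in self.records.items() if r.class_label in labels}

    def to_frame(self) -> pd.DataFrame:
        rows = {
            g: {
                "class_label": r.class_label,
                "planted_fc_wt_log2": r.planted_fc_wt_log2,
                "planted_fc_pifq_log2": r.planted_fc_pifq_log2,
                "planted_phase_h": np.nan
                if r.planted_phase_h is None
                else r.planted_phase_h,
                "arrhythmic": r.arrhythmic,
                "planted_motifs": ",".join(r.planted_motifs),
            }
            for g, r in self.records.items()
        }
        return pd.DataFrame.from_dict(rows, orient="index")
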