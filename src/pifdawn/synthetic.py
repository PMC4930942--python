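"""Synthetic data with planted truth.

Emulates the statistical structure the downstream analysis assumes:

* a 2x2 expression experiment (WT/pifq x SD/LL, replicated) in which
  gene classes are planted with known log2 effects — genes induced or
  repressed at the end of the short-day night in a PIF-dependent way,
  genes responding to the night only, genes responding to loss of PIFq
  only, same-sign "ambiguous" responders, and unregulated nulls;
* promoter windows in which IUPAC motifs are implanted with
  class-dependent probabilities over a uniform background;
* diurnal time courses as cosine profiles with planted peak phases,
  plus flat arrhythmic profiles.

Every generator is deterministic given its seed.  The truth stream and
the noise stream are separate generators derived from the config seed
by fixed offsets, so tests can vary the noise realization while holding
the planted structure fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core import (
    ExpressionMatrix,
    PipelineError,
    SyntheticTruth,
    TruthRecord,
)
from .motifs import IUPAC_CODES, MotifDefinition

CLASS_LABELS = (
    "pifsd_induced",
    "pifsd_repressed",
    "sd_only",
    "pif_only",
    "ambiguous",
    "null",
)

#: Default planted class mix.  Preserves the induced:repressed ratio
#: (~57:43) and the dominance of night-only over pifq-only responders
#: seen in real dawn transcriptomes, scaled so each class carries enough
#: genes for recovery statistics at n_genes ~ 2000.
DEFAULT_CLASS_FRACTIONS: dict[str, float] = {
    "pifsd_induced": 0.06,
    "pifsd_repressed": 0.045,
    "sd_only": 0.10,
    "pif_only": 0.04,
    "ambiguous": 0.005,
    "null": 0.75,
}


@dataclass
class SimulationConfig:
    """Parameters of the planted expression experiment.

    effect_size_log2 is the planted |log2 fold change| of every
    regulated class (default 1.5, i.e. a linear fold change of ~2.8).
    repressed_contribution is the fraction of the WT night repression
    attributable to PIFq (default 0.69): repressed genes lose only that
    fraction of their repression in the mutant, so the contribution
    statistic on noiseless data returns exactly 100 x this value.
    """

    n_genes: int = 2000
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    effect_size_log2: float = 1.5
    repressed_contribution: float = 0.69
    noise_sd_log2: float = 0.3
    n_replicates: int = 3
    baseline_log2: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise PipelineError("n_genes must be positive")
        if self.n_replicates <= 0:
            raise PipelineError("n_replicates must be positive")
        if self.effect_size_log2 <= 0:
            raise PipelineError("effect_size_log2 must be positive")
        if not 0 < self.repressed_contribution <= 1.5:
            raise PipelineError("repressed_contribution must lie in (0, 1.5]")
        if self.noise_sd_log2 < 0:
            raise PipelineError("noise_sd_log2 must be nonnegative")
        unknown = set(self.class_fractions) - set(CLASS_LABELS)
        if unknown:
            raise PipelineError(f"unknown class labels: {sorted(unknown)}")
        fracs = np.array(
            [self.class_fractions.get(c, 0.0) for c in CLASS_LABELS], dtype=float
        )
        if (fracs < 0).any():
            raise PipelineError("class fractions must be nonnegative")
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise PipelineError(
                f"class fractions must sum to 1 (got {fracs.sum():.12g})"
            )


def _class_counts(config: SimulationConfig) -> dict[str, int]:
    """Largest-remainder apportionment of n_genes over the class mix."""
    fracs = {c: config.class_fractions.get(c, 0.0) for c in CLASS_LABELS}
    raw = {c: config.n_genes * f for c, f in fracs.items()}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = config.n_genes - sum(counts.values())
    by_remainder = sorted(
        CLASS_LABELS, key=lambda c: (-(raw[c] - counts[c]), CLASS_LABELS.index(c))
    )
    for c in by_remainder[:short]:
        counts[c] += 1
    return counts


def simulate_expression(
    config: SimulationConfig, noise_seed: int | None = None
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate a replicated 2x2 log2 expression matrix with planted truth.

    Group means per class (b = baseline, e = effect, r = repressed
    contribution; order WT-SD, WT-LL, pifq-SD, pifq-LL):

    ==================  =========  =====  ===========  =======
    class               WT-SD      WT-LL  pifq-SD      pifq-LL
    ==================  =========  =====  ===========  =======
    null                b          b      b            b
    pifsd_induced       b + e      b      b            b
    pifsd_repressed     b - e      b      b - e(1-r)   b
    sd_only             b + s*e    b      b + s*e      b
    pif_only            b          b      b + s*e      b
    ambiguous           b + s*e    b      b + 2s*e     b
    ==================  =========  =====  ===========  =======

    where s is a per-gene random sign.  Induced genes therefore carry a
    planted PIFq contribution of exactly 100% and repressed genes of
    100*r.  i.i.d. Gaussian noise (SD ``noise_sd_log2``) is added per
    gene x replicate.

    Returns the matrix and the planted truth (WT-SD vs WT-LL and
    pifq-SD vs WT-SD planted log2 fold changes per gene).
    """
    rng_truth = np.random.default_rng(config.seed)
    rng_noise = np.random.default_rng(
        config.seed + 1 if noise_seed is None else noise_seed
    )

    counts = _class_counts(config)
    labels: list[str] = []
    for c in CLASS_LABELS:
        labels.extend([c] * counts[c])
    # deterministic shuffle so classes are interleaved across the matrix
    order = rng_truth.permutation(config.n_genes)
    labels = [labels[i] for i in order]

    width = max(4, len(str(config.n_genes)))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(config.n_genes)]

    b = config.baseline_log2
    e = config.effect_size_log2
    r = config.repressed_contribution

    signs = rng_truth.choice([-1.0, 1.0], size=config.n_genes)

    # group-mean matrix: columns WT-SD, WT-LL, pifq-SD, pifq-LL
    means = np.full((config.n_genes, 4), b, dtype=float)
    records: dict[str, TruthRecord] = {}
    for i, (gid, label) in enumerate(zip(gene_ids, labels)):
        s = signs[i]
        if label == "pifsd_induced":
            means[i, 0] = b + e
        elif label == "pifsd_repressed":
            means[i, 0] = b - e
            means[i, 2] = b - e * (1.0 - r)
        elif label == "sd_only":
            means[i, 0] = b + s * e
            means[i, 2] = b + s * e
        elif label == "pif_only":
            means[i, 2] = b + s * e
        elif label == "ambiguous":
            means[i, 0] = b + s * e
            means[i, 2] = b + 2.0 * s * e
        fc_wt = means[i, 0] - means[i, 1]
        fc_pifq = means[i, 2] - means[i, 0]
        records[gid] = TruthRecord(
            class_label=label,
            planted_fc_wt_log2=fc_wt,
            planted_fc_pifq_log2=fc_pifq,
        )

    group_order = [("WT", "SD"), ("WT", "LL"), ("pifq", "SD"), ("pifq", "LL")]
    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    cols: list[np.ndarray] = []
    for gi, (genotype, condition) in enumerate(group_order):
        for rep in range(1, config.n_replicates + 1):
            sample_ids.append(f"{genotype}_{condition}_{rep}")
            meta_rows.append(
                {"genotype": genotype, "condition": condition, "replicate": rep}
            )
            noise = rng_noise.normal(0.0, config.noise_sd_log2, size=config.n_genes)
            cols.append(means[:, gi] + noise)

    values = pd.DataFrame(
        np.column_stack(cols), index=pd.Index(gene_ids, name="gene_id"),
        columns=sample_ids,
    )
    samples = pd.DataFrame(meta_rows, index=pd.Index(sample_ids, name="sample_id"))
    return ExpressionMatrix(values, samples), SyntheticTruth(records)


def _expand_iupac_once(iupac: str, rng: np.random.Generator) -> str:
    return "".join(
        code if len(opts := IUPAC_CODES[code]) == 1 else opts[rng.integers(len(opts))]
        for code in iupac
    )


def simulate_promoters(
    truth: SyntheticTruth,
    motif_config: Mapping[str, Mapping],
    length: int = 3000,
    seed: int = 0,
) -> dict[str, str]:
    """Generate one promoter window per gene with class-dependent motifs.

    ``motif_config`` maps motif name -> ``{iupac, prob_in_target,
    prob_in_background}`` plus an optional ``target_classes`` list
    (default ``["pifsd_induced"]``) naming the planted classes in which
    the target probability applies.  Implanted motifs overwrite a
    uniform-ACGT background at a random position; each implant picks one
    concrete expansion of the IUPAC pattern and is recorded in
    ``truth.planted_motifs``.
    """
    if length <= 0:
        raise PipelineError("promoter length must be positive")
    rng = np.random.default_rng(seed)
    parsed: list[tuple[str, str, float, float, set[str]]] = []
    for name, cfg in motif_config.items():
        motif = MotifDefinition(name, cfg["iupac"])  # validates the pattern
        p_t = float(cfg.get("prob_in_target", 0.0))
        p_b = float(cfg.get("prob_in_background", 0.0))
        for p in (p_t, p_b):
            if not 0.0 <= p <= 1.0:
                raise PipelineError(f"motif {name}: probability {p} outside [0, 1]")
        if len(motif.iupac) > length:
            raise PipelineError(
                f"motif {name} ({len(motif.iupac)} bp) longer than promoter ({length} bp)"
            )
        targets = set(cfg.get("target_classes", ["pifsd_induced"]))
        parsed.append((name, motif.iupac, p_t, p_b, targets))

    bases = np.array(list("ACGT"))
    promoters: dict[str, str] = {}
    for gid in truth.gene_ids():
        rec = truth[gid]
        rec.planted_motifs = []
        seq = rng.choice(bases, size=length)
        for name, iupac, p_t, p_b, targets in parsed:
            p = p_t if rec.class_label in targets else p_b
            if rng.random() < p:
                word = _expand_iupac_once(iupac, rng)
                pos = int(rng.integers(0, length - len(word) + 1))
                seq[pos : pos + len(word)] = list(word)
                rec.planted_motifs.append(name)
        promoters[gid] = "".join(seq)
    return promoters


def simulate_diurnal(
    truth: SyntheticTruth,
    timepoints: np.ndarray | list[float],
    period: float = 24.0,
    amplitude: float = 1.0,
    noise_sd: float = 0.2,
    frac_arrhythmic: float = 0.0,
    baseline: float = 8.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate diurnal time courses (genes x timepoints).

    Rhythmic genes follow ``baseline + amplitude * cos(2*pi*(t - phase)
    / period) + noise``; arrhythmic genes are flat plus noise.  Genes
    without a planted phase receive one uniform on [0, period); a random
    fraction ``frac_arrhythmic`` of genes is flagged arrhythmic.  Phases
    and flags are written back into ``truth``.
    """
    t = np.asarray(timepoints, dtype=float)
    if t.size == 0:
        raise PipelineError("timepoints must be non-empty")
    if t.size < 8 or t.max() - t.min() < period:
        raise PipelineError(
            "need >= 8 timepoints spanning at least one full period"
        )
    if not 0.0 <= frac_arrhythmic <= 1.0:
        raise PipelineError("frac_arrhythmic must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    gids = truth.gene_ids()
    n = len(gids)
    n_arr = int(round(frac_arrhythmic * n))
    arr_idx = set(rng.choice(n, size=n_arr, replace=False)) if n_arr else set()
    rows = np.empty((n, t.size))
    for i, gid in enumerate(gids):
        rec = truth[gid]
        rec.arrhythmic = i in arr_idx
        if rec.arrhythmic:
            rec.planted_phase_h = None
            rows[i] = baseline
        else:
            if rec.planted_phase_h is None:
                rec.planted_phase_h = float(rng.uniform(0.0, period))
            rows[i] = baseline + amplitude * np.cos(
                2.0 * np.pi * (t - rec.planted_phase_h) / period
            )
        rows[i] += rng.normal(0.0, noise_sd, size=t.size)
    return pd.DataFrame(
        rows, index=pd.Index(gids, name="gene_id"),
        columns=[f"ZT{g:g}" for g in t],
    )
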