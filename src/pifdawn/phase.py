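"""Diurnal phase assignment and rhythmicity calling.

Each gene's time course is z-scored and correlated (Pearson) against a
bank of single-harmonic cosine templates ``cos(2*pi*(t - phi)/period)``
over a grid of candidate phases phi (0.5-h steps).  The best-matching
phi is the gene's peak phase, the maximum correlation is its rhythm
score, and genes scoring at or above the cutoff (default 0.7) are
called rhythmic.  Phase distributions of a gene set are summarized as
count/expected enrichment over time-of-day bins against a background
phase distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import PipelineError

PHASE_GRID_STEP_H = 0.5


@dataclass
class PhaseCall:
    phase_h: float
    rhythm_score: float
    rhythmic: bool


def _template_bank(
    timepoints: np.ndarray, period: float, step: float
) -> tuple[np.ndarray, np.ndarray]:
    phis = np.arange(0.0, period, step)
    templ = np.cos(2.0 * np.pi * (timepoints[None, :] - phis[:, None]) / period)
    mean = templ.mean(axis=1, keepdims=True)
    sd = templ.std(axis=1, keepdims=True)
    if (sd == 0).any():
        raise PipelineError("degenerate sampling: a cosine template is constant")
    return phis, (templ - mean) / sd


def _validate_timepoints(timepoints: np.ndarray, period: float) -> np.ndarray:
    t = np.asarray(timepoints, dtype=float)
    if t.size < 8 or t.max() - t.min() < period:
        raise PipelineError("need >= 8 timepoints spanning at least one full period")
    return t


def assign_phases(
    profiles: pd.DataFrame,
    timepoints: np.ndarray | list[float] | None = None,
    period: float = 24.0,
    cutoff: float = 0.7,
) -> pd.DataFrame:
    """Phase, rhythm score and rhythmic flag for every gene (row).

    ``timepoints`` defaults to parsing the column labels as ``ZT<t>``.
    Constant profiles get rhythm_score 0 and are not rhythmic.  Ties on
    the phase grid break toward the smaller phase.
    """
    if timepoints is None:
        timepoints = [float(str(c).removeprefix("ZT")) for c in profiles.columns]
    t = _validate_timepoints(np.asarray(timepoints), period)
    x = profiles.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise PipelineError("time courses contain non-finite values")
    phis, templ_z = _template_bank(t, period, PHASE_GRID_STEP_H)

    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    constant = np.ptp(x, axis=1) == 0
    sd[constant, :] = 1.0
    z = (x - mean) / sd
    corr = z @ templ_z.T / t.size  # genes x phases
    best = corr.argmax(axis=1)  # first max -> smallest phi on ties
    score = corr[np.arange(len(x)), best]
    phase = phis[best]
    score[constant] = 0.0
    phase[constant] = 0.0
    return pd.DataFrame(
        {
            "phase_h": phase % period,
            "rhythm_score": score,
            "rhythmic": score >= cutoff,
        },
        index=profiles.index,
    )


def assign_phase(
    profile: np.ndarray | list[float],
    timepoints: np.ndarray | list[float],
    period: float = 24.0,
    cutoff: float = 0.7,
) -> PhaseCall:
    """Single-profile convenience wrapper around :func:`assign_phases`."""
    df = pd.DataFrame([np.asarray(profile, dtype=float)])
    row = assign_phases(df, timepoints, period=period, cutoff=cutoff).iloc[0]
    return PhaseCall(float(row["phase_h"]), float(row["rhythm_score"]), bool(row["rhythmic"]))


def rhythmic_fraction(calls: pd.DataFrame, gene_set: set[str] | list[str]) -> float:
    """Percentage of the gene set called rhythmic."""
    genes = list(gene_set)
    if not genes:
        raise PipelineError("empty gene set")
    missing = sorted(set(genes) - set(calls.index))[:10]
    if missing:
        raise PipelineError(f"genes without phase calls: {missing}")
    return float(100.0 * calls.loc[genes, "rhythmic"].mean())


def phase_bin_enrichment(
    calls: pd.DataFrame,
    gene_set: set[str] | list[str],
    background: set[str] | list[str],
    n_bins: int = 24,
    period: float = 24.0,
) -> pd.DataFrame:
    """Count/expected phase enrichment of a gene set over time-of-day bins.

    Bins are left-closed right-open, width period/n_bins, starting at
    ZT0.  Only rhythmic genes enter; expected counts allocate the set
    total according to the background's rhythmic phase distribution.
    Bins with zero expectation have undefined (NaN) fold.
    """
    def _phases(genes: set[str] | list[str]) -> np.ndarray:
        sub = calls.loc[list(genes)]
        return sub.loc[sub["rhythmic"], "phase_h"].to_numpy()

    set_ph = _phases(gene_set)
    bg_ph = _phases(background)
    if set_ph.size == 0 or bg_ph.size == 0:
        raise PipelineError("no rhythmic genes in set or background")
    edges = np.linspace(0.0, period, n_bins + 1)
    observed, _ = np.histogram(set_ph, bins=edges)
    bg_counts, _ = np.histogram(bg_ph, bins=edges)
    expected = set_ph.size * bg_counts / bg_ph.size
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(expected > 0, observed / expected, np.nan)
    return pd.DataFrame(
        {
            "bin_start_h": edges[:-1],
            "observed": observed,
            "expected": expected,
            "fold": fold,
        }
    )


def set_median_profile(
    timecourses: pd.DataFrame, gene_set: set[str] | list[str]
) -> pd.DataFrame:
    """Median and quartile curves of a gene set's time courses.

    Rows = timepoints; columns median, q25, q75.
    """
    genes = list(gene_set)
    if not genes:
        raise PipelineError("empty gene set")
    sub = timecourses.loc[genes]
    return pd.DataFrame(
        {
            "median": sub.median(axis=0),
            "q25": sub.quantile(0.25, axis=0),
            "q75": sub.quantile(0.75, axis=0),
        }
    )
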