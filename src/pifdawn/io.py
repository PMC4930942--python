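"""Readers, writers, configuration and the end-to-end pipeline.

Table dialect: tab-delimited, header row, '.' decimal, no quoting.
Promoters travel as FASTA (record id = gene id); reports as JSON.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import classify as _classify
from . import contribution as _contribution
from . import motifs as _motifs
from . import phase as _phase
from .core import ExpressionMatrix, PipelineError
from .diffexpr import PIF_CONTRAST, SD_CONTRAST, ContrastResult, run_contrast
from .motifs import DEFAULT_MOTIFS, IUPAC_CODES, MotifDefinition

logger = logging.getLogger("pifdawn")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


# ---------------------------------------------------------------- tables

def write_expression(
    matrix: ExpressionMatrix, matrix_path: str | Path, sheet_path: str | Path
) -> None:
    matrix.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
    matrix.samples.to_csv(sheet_path, sep="\t", index_label="sample_id")


def read_expression(
    matrix_path: str | Path, sample_sheet_path: str | Path
) -> ExpressionMatrix:
    """Read and validate a log2 matrix TSV plus its sample sheet."""
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    if raw.index.duplicated().any():
        dupe = raw.index[raw.index.duplicated()][0]
        line = int(np.where(raw.index == dupe)[0][-1]) + 2  # +1 header, +1 1-based
        raise PipelineError(
            f"{matrix_path}: duplicate gene id {dupe!r} (line {line})"
        )
    values = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            gene = raw.index[bad][0]
            line = int(np.where(bad)[0][0]) + 2
            raise PipelineError(
                f"{matrix_path}: non-numeric value {raw.loc[gene, col]!r} "
                f"for gene {gene!r}, sample {col!r} (line {line})"
            )
        if converted.isna().any():
            gene = raw.index[converted.isna()][0]
            raise PipelineError(f"{matrix_path}: missing value for gene {gene!r}")
        values[col] = converted
    samples = pd.read_csv(sample_sheet_path, sep="\t", index_col=0, dtype={0: str})
    missing = values.columns.difference(samples.index)
    if len(missing):
        raise PipelineError(
            f"{sample_sheet_path}: no metadata for sample(s) {list(missing)}"
        )
    return ExpressionMatrix(values, samples.loc[values.columns])


def write_timecourses(timecourses: pd.DataFrame, path: str | Path) -> None:
    timecourses.to_csv(path, sep="\t", index_label="gene_id")


def read_timecourses(path: str | Path) -> pd.DataFrame:
    """Read a genes x timepoints TSV with ZT<t> column headers."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        if not str(col).startswith("ZT"):
            raise PipelineError(f"{path}: column {col!r} is not of the form ZT<t>")
        try:
            float(str(col)[2:])
        except ValueError:
            raise PipelineError(f"{path}: cannot parse timepoint from {col!r}") from None
    if df.index.duplicated().any():
        raise PipelineError(f"{path}: duplicated gene ids")
    return df.astype(float)


# ---------------------------------------------------------------- FASTA

def write_fasta(promoters: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=gid, description="") for gid, seq in promoters.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read promoters from FASTA; uppercased, nucleotide-validated."""
    allowed = set(IUPAC_CODES)
    promoters: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        gid = record.id
        if gid in promoters:
            raise PipelineError(f"{path}: duplicate record id {gid!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise PipelineError(f"{path}: empty sequence for record {gid!r}")
        bad = sorted(set(seq) - allowed)
        if bad:
            raise PipelineError(
                f"{path}: record {gid!r} has non-nucleotide letter(s) {bad}"
            )
        promoters[gid] = seq
    return promoters


def write_truth_json(truth, path: str | Path) -> None:
    payload = {
        gid: {
            "class_label": r.class_label,
            "planted_fc_wt_log2": r.planted_fc_wt_log2,
            "planted_fc_pifq_log2": r.planted_fc_pifq_log2,
            "planted_phase_h": r.planted_phase_h,
            "arrhythmic": r.arrhythmic,
            "planted_motifs": r.planted_motifs,
        }
        for gid, r in truth.records.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------- config

@dataclass
class PipelineConfig:
    """Thresholds and constants of the full workflow."""

    alpha: float = 0.05
    fc_threshold: float = 1.5
    promoter_window: int = 3000
    rhythm_cutoff: float = 0.7
    period: float = 24.0
    motifs: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_MOTIFS))
    seed: int = 0
    out_dir: str = "pifdawn_out"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise PipelineError("alpha must lie in (0, 1)")
        for name in ("fc_threshold", "promoter_window", "rhythm_cutoff", "period"):
            if getattr(self, name) <= 0:
                raise PipelineError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load from YAML; keyword overrides take precedence over the file."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def motif_definitions(self) -> list[MotifDefinition]:
        return [MotifDefinition(n, p) for n, p in self.motifs.items()]


# ---------------------------------------------------------------- pipeline

def _round6(x):
    if x is None:
        return None
    return round(float(x), 6)


def run_full_pipeline(
    config: PipelineConfig,
    matrix: ExpressionMatrix,
    promoters: Mapping[str, str] | None = None,
    timecourses: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Contrasts -> SS1.5F -> classification -> contribution -> motif
    enrichment -> (optional) phase analysis; writes a TSV+JSON bundle.

    Returns the report dict (also written as ``report.json``).  The
    report carries no timestamps, so a rerun with the same inputs and
    seed is byte-identical.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info(
        "pipeline start: seed=%d alpha=%g fc_threshold=%g genes=%d",
        config.seed, config.alpha, config.fc_threshold, len(matrix.gene_ids),
    )
    report: dict = {
        "config": {
            "alpha": config.alpha,
            "fc_threshold": config.fc_threshold,
            "promoter_window": config.promoter_window,
            "rhythm_cutoff": config.rhythm_cutoff,
            "period": config.period,
            "motifs": dict(config.motifs),
            "seed": config.seed,
        },
        "n_genes": int(len(matrix.gene_ids)),
    }

    def _stage(name):
        logger.info("stage: %s", name)

    try:
        _stage("contrasts")
        sd = run_contrast(matrix, SD_CONTRAST, config.alpha, config.fc_threshold)
        pif = run_contrast(matrix, PIF_CONTRAST, config.alpha, config.fc_threshold)
        for res in (sd, pif):
            res.table.to_csv(out / f"contrast_{res.name}.tsv", sep="\t",
                             index_label="gene_id")
    except PipelineError as exc:
        raise PipelineError(f"stage 'contrasts' failed: {exc}") from exc

    try:
        _stage("classification")
        cls = _classify.classify_genes(sd, pif)
        cls.table.to_csv(out / "classification.tsv", sep="\t", index_label="gene_id")
        venn = _classify.venn_summary(cls)
        report["venn"] = venn.as_dict()
        report["quadrant_binomial_p"] = (
            float(_classify.quadrant_binomial_test(cls)) if venn.n_common else None
        )
        (out / "venn_summary.json").write_text(
            json.dumps(venn.as_dict(), indent=1, sort_keys=True)
        )
    except PipelineError as exc:
        raise PipelineError(f"stage 'classification' failed: {exc}") from exc

    induced = cls.genes_with_label("pifsd_induced")
    repressed = cls.genes_with_label("pifsd_repressed")

    try:
        _stage("contribution")
        contrib_report = {}
        for set_name, genes in (("induced", induced), ("repressed", repressed)):
            if not genes:
                contrib_report[set_name] = None
                continue
            records = _contribution.per_gene_contribution(matrix, sorted(genes))
            records.to_csv(out / f"contribution_{set_name}.tsv", sep="\t",
                           index_label="gene_id")
            _, frac_gt50, frac_ge100 = _contribution.contribution_ranking(records)
            means = {
                f"{g}_{c}": _round6(
                    _contribution.set_mean_fc(matrix, sorted(genes), (g, c))[0]
                )
                for g, c in (("WT", "SD"), ("pifq", "SD"), ("pifq", "LL"))
            }
            tests = {
                "wt_sd_vs_pifq_sd": _round6(
                    _contribution.group_distribution_test(
                        matrix, sorted(genes), ("WT", "SD"), ("pifq", "SD"))
                ),
                "pifq_sd_vs_pifq_ll": _round6(
                    _contribution.group_distribution_test(
                        matrix, sorted(genes), ("pifq", "SD"), ("pifq", "LL"))
                ),
            }
            contrib_report[set_name] = {
                "n_defined": int(records["defined"].sum()),
                "mean_contribution_pct": _round6(
                    records.loc[records["defined"], "contribution_pct"].mean()
                ),
                "frac_gt_50": _round6(frac_gt50),
                "frac_ge_100": _round6(frac_ge100),
                "mean_fc_vs_wt_ll": means,
                "wilcoxon_p": tests,
            }
        report["contribution"] = contrib_report
    except PipelineError as exc:
        raise PipelineError(f"stage 'contribution' failed: {exc}") from exc

    if promoters is not None:
        try:
            _stage("motif_enrichment")
            background = set(matrix.gene_ids)
            motif_report = {}
            for set_name, genes in (("induced", induced), ("repressed", repressed)):
                if not genes:
                    motif_report[set_name] = None
                    continue
                results = _motifs.enrich_gene_set(
                    promoters, config.motif_definitions(), genes, background,
                    composites={"GBOX+PBE": ["GBOX", "PBE"]}
                    if {"GBOX", "PBE"} <= set(config.motifs) else None,
                )
                pd.DataFrame([r.__dict__ for r in results]).to_csv(
                    out / f"motif_enrichment_{set_name}.tsv", sep="\t", index=False
                )
                motif_report[set_name] = {
                    r.name: {"k": r.k, "n": r.n, "K": r.K, "N": r.N,
                             "fraction": _round6(r.fraction_in_set),
                             "p_value": float(r.p_value)}
                    for r in results
                }
            report["motif_enrichment"] = motif_report
        except PipelineError as exc:
            raise PipelineError(f"stage 'motif_enrichment' failed: {exc}") from exc

    if timecourses is not None:
        try:
            _stage("phase")
            calls = _phase.assign_phases(
                timecourses, period=config.period, cutoff=config.rhythm_cutoff
            )
            calls.to_csv(out / "phase_calls.tsv", sep="\t", index_label="gene_id")
            background = [g for g in matrix.gene_ids if g in calls.index]
            phase_report = {}
            for set_name, genes in (("induced", induced), ("repressed", repressed)):
                genes = sorted(g for g in genes if g in calls.index)
                if not genes:
                    phase_report[set_name] = None
                    continue
                entry = {
                    "pct_rhythmic": _round6(_phase.rhythmic_fraction(calls, genes)),
                }
                if calls.loc[genes, "rhythmic"].any():
                    enr = _phase.phase_bin_enrichment(
                        calls, genes, background, period=config.period
                    )
                    enr.to_csv(out / f"phase_enrichment_{set_name}.tsv",
                               sep="\t", index=False)
                    peak = enr.loc[enr["fold"].idxmax()]
                    entry["peak_bin_start_h"] = float(peak["bin_start_h"])
                    entry["peak_fold"] = _round6(peak["fold"])
                phase_report[set_name] = entry
            report["phase"] = phase_report
        except PipelineError as exc:
            raise PipelineError(f"stage 'phase' failed: {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    logger.info("pipeline done: report at %s", out / "report.json")
    return report
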