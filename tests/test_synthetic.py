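"""Generator contracts: planted group means, determinism, fixtures."""

import numpy as np
import pytest

from pifdawn import (
    PipelineError,
    SimulationConfig,
    scan_motif,
    MotifDefinition,
    simulate_diurnal,
    simulate_expression,
    simulate_promoters,
)

GROUPS = (("WT", "SD"), ("WT", "LL"), ("pifq", "SD"), ("pifq", "LL"))


def _only(fractions):
    base = {k: 0.0 for k in
            ("pifsd_induced", "pifsd_repressed", "sd_only", "pif_only",
             "ambiguous", "null")}
    base.update(fractions)
    return base


class TestSimulateExpression:
    def test_zero_noise_induced_gene_means_are_exact(self):
        cfg = SimulationConfig(
            n_genes=10, noise_sd_log2=0.0, effect_size_log2=1.5, seed=0,
            class_fractions=_only({"pifsd_induced": 0.1, "null": 0.9}),
        )
        matrix, truth = simulate_expression(cfg)
        (gene,) = truth.genes_of_class("pifsd_induced")
        wt_sd = matrix.group_means("WT", "SD")[gene]
        wt_ll = matrix.group_means("WT", "LL")[gene]
        pifq_sd = matrix.group_means("pifq", "SD")[gene]
        assert wt_sd - wt_ll == pytest.approx(1.5, abs=1e-12)
        assert pifq_sd - wt_sd == pytest.approx(-1.5, abs=1e-12)

    def test_all_null_means_equal_baseline(self):
        cfg = SimulationConfig(
            n_genes=20, noise_sd_log2=0.0, baseline_log2=6.5, seed=0,
            class_fractions=_only({"null": 1.0}),
        )
        matrix, _ = simulate_expression(cfg)
        for g, c in GROUPS:
            assert np.allclose(matrix.group_means(g, c), 6.5)

    def test_sample_means_match_planted_group_means(self):
        """Brute-force averaging of the emitted columns recovers the
        planted group means within 3*sigma/sqrt(n) for >= 99% of genes."""
        cfg = SimulationConfig(n_genes=2000, noise_sd_log2=0.3, seed=1)
        matrix, truth = simulate_expression(cfg)
        tol = 3 * cfg.noise_sd_log2 / np.sqrt(cfg.n_replicates)
        b = cfg.baseline_log2
        planted_wt_sd = np.array(
            [b + truth[g].planted_fc_wt_log2 for g in matrix.gene_ids]
        )
        planted_pifq_sd = np.array(
            [b + truth[g].planted_fc_wt_log2 + truth[g].planted_fc_pifq_log2
             for g in matrix.gene_ids]
        )
        for group, planted in (
            (("WT", "SD"), planted_wt_sd),
            (("WT", "LL"), np.full(cfg.n_genes, b)),
            (("pifq", "SD"), planted_pifq_sd),
        ):
            observed = matrix.group_values(*group).to_numpy().mean(axis=1)
            assert (np.abs(observed - planted) <= tol).mean() >= 0.99

    def test_same_seed_bit_identical_and_noise_seed_varies_only_noise(self):
        cfg = SimulationConfig(n_genes=100, seed=5)
        m1, t1 = simulate_expression(cfg)
        m2, t2 = simulate_expression(cfg)
        assert m1.values.equals(m2.values)
        m3, t3 = simulate_expression(cfg, noise_seed=999)
        assert t3.labels().equals(t1.labels())
        assert not np.allclose(m3.values, m1.values)

    def test_truth_sign_invariants(self, default_bundle):
        _, _, truth = default_bundle
        for g in truth.genes_of_class("pifsd_induced"):
            assert truth[g].planted_fc_wt_log2 > 0 > truth[g].planted_fc_pifq_log2
        for g in truth.genes_of_class("pifsd_repressed"):
            assert truth[g].planted_fc_wt_log2 < 0 < truth[g].planted_fc_pifq_log2

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_genes": 0},
            {"n_replicates": 0},
            {"class_fractions": _only({"null": 0.5})},
            {"class_fractions": _only({"null": 1.5, "sd_only": -0.5})},
            {"noise_sd_log2": -0.1},
            {"repressed_contribution": 0.0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(PipelineError):
            SimulationConfig(**kwargs)


class TestSimulatePromoters:
    def test_forced_implant_reaches_every_target_gene(self, noiseless_bundle):
        _, _, truth = noiseless_bundle
        cfg = {"GBOX": {"iupac": "CACGTG", "prob_in_target": 1.0,
                        "prob_in_background": 0.0}}
        promoters = simulate_promoters(truth, cfg, length=200, seed=2)
        for g in truth.genes_of_class("pifsd_induced"):
            assert "CACGTG" in promoters[g]
            assert truth[g].planted_motifs == ["GBOX"]

    def test_background_hit_rate_matches_closed_form(self, noiseless_bundle):
        """With no implants, chance G-box genes follow the closed form
        1 - (1 - 4^-6)^(L-5) per gene: the motif is palindromic, so
        minus-strand hits coincide with plus-strand hits and the strand
        factor is 1, not 2."""
        _, _, truth = noiseless_bundle
        cfg = {"GBOX": {"iupac": "CACGTG", "prob_in_target": 0.0,
                        "prob_in_background": 0.0}}
        promoters = simulate_promoters(truth, cfg, length=100, seed=3)
        n = len(promoters)
        p_hit = 1.0 - (1.0 - 4.0 ** -6) ** 95
        observed = sum("CACGTG" in s for s in promoters.values())
        sd = np.sqrt(n * p_hit * (1 - p_hit))
        assert abs(observed - n * p_hit) <= 3 * sd

    def test_degenerate_length_equals_motif(self, noiseless_bundle):
        _, _, truth = noiseless_bundle
        cfg = {"GBOX": {"iupac": "CACGTG", "prob_in_target": 1.0,
                        "prob_in_background": 1.0}}
        promoters = simulate_promoters(truth, cfg, length=6, seed=4)
        assert set(promoters.values()) == {"CACGTG"}

    def test_iupac_expansion_respects_pattern(self, noiseless_bundle):
        _, _, truth = noiseless_bundle
        cfg = {"EXT": {"iupac": "CACRTGGG", "prob_in_target": 1.0,
                       "prob_in_background": 1.0}}
        promoters = simulate_promoters(truth, cfg, length=50, seed=5)
        ext = MotifDefinition("EXT", "CACRTGGG")
        assert all(scan_motif(s, ext) for s in promoters.values())

    def test_motif_longer_than_promoter_rejected(self, noiseless_bundle):
        _, _, truth = noiseless_bundle
        cfg = {"GBOX": {"iupac": "CACGTG", "prob_in_target": 1.0,
                        "prob_in_background": 0.0}}
        with pytest.raises(PipelineError):
            simulate_promoters(truth, cfg, length=5, seed=0)


class TestSimulateDiurnal:
    def test_noiseless_cosine_peaks_at_planted_phase(self, noiseless_bundle):
        _, _, truth = noiseless_bundle
        gene = truth.gene_ids()[0]
        truth[gene].planted_phase_h = 20.0
        t = np.arange(0, 48.25, 0.25)  # dense grid
        tc = simulate_diurnal(truth, t, amplitude=1.0, noise_sd=0.0, seed=6)
        peak_t = t[np.argmax(tc.loc[gene].to_numpy())]
        assert peak_t % 24 == pytest.approx(20.0)

    def test_zero_amplitude_profile_variance_is_noise_variance(self, noiseless_bundle):
        _, _, truth = noiseless_bundle
        t = np.arange(0, 49, 2.0)
        tc = simulate_diurnal(truth, t, amplitude=0.0, noise_sd=0.5, seed=8)
        pooled_var = tc.to_numpy().var(axis=1, ddof=1).mean()
        assert pooled_var == pytest.approx(0.25, rel=0.1)

    def test_too_few_timepoints_rejected(self, noiseless_bundle):
        _, _, truth = noiseless_bundle
        with pytest.raises(PipelineError):
            simulate_diurnal(truth, [0, 4, 8, 12], seed=0)
        with pytest.raises(PipelineError):
            simulate_diurnal(truth, [], seed=0)
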