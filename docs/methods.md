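# Methods

## Experimental design and data model

The pipeline assumes a normalized log2 expression matrix (genes ×
samples) from a 2×2 factorial: genotype ∈ {WT, *pifq*} × condition ∈
{SD, LL}, with ≥ 2 (default 3) biological replicates per cell, all
sampled at dawn. Two contrasts carry the biology:

* **SD contrast** — WT-SD vs WT-LL: what the long night does to the
  wild type, relative to the free-running light control;
* **PIF contrast** — *pifq*-SD vs WT-SD: what removing the four PIF
  factors does under the same night.

All statistics operate on the log2 scale; a "fold change" is a
difference of group means of log2 intensities, reported alongside its
signed linear equivalent `sign(log2FC) · 2^|log2FC|`.

## Differential expression and the SS1.5F gate

Commercial array-analysis suites achieve usable power at 2–4
replicates by weighting each gene's test with error information pooled
across the whole array. We reproduce that behaviour from first
principles with an **empirical-Bayes moderated two-sample t-test**:
per-gene pooled variances s²_g (d = n₁+n₂−2 df) are modelled as draws
from a scaled inverse-chi-square prior, the prior's parameters (d₀,
s₀²) are fitted by the standard moments method on log s² (matching the
mean and excess variance of log s² against digamma/trigamma terms, with
Newton inversion of the trigamma function), and each gene's test uses
the shrunken variance `(d₀·s₀² + d·s²_g)/(d₀ + d)` with d₀ + d degrees
of freedom. When the observed spread of log-variances is no larger
than its sampling spread, d₀ → ∞ and all genes share s₀². A plain
Welch unequal-variance t-test is also provided, and the test function
is an injectable parameter of `run_contrast`, so any two-sample test
with the same signature can be swapped in. We chose the moderated test
as the default because per-gene Welch at 3+3 replicates (4 df) loses
the majority of true 1.5-log2-fold effects after FDR correction at
realistic array noise, which defeats the purpose of the gate.

Degenerate inputs follow a documented noiseless convention: a gene
with zero variance in both groups gets p = 1 when the group means are
equal and p = 0 when they differ (deterministic separation); this keeps
noise-free simulations free of NaNs.

P-values are corrected per contrast (not jointly) by the
Benjamini–Hochberg step-up, implemented directly
(q(i) = min over ranks j ≥ i of m·p(j)/j, clipped at 1) and
cross-checked in the tests against both a brute-force rank enumeration
and `statsmodels.multipletests`. A gene is **SS1.5F** when
q ≤ α (default 0.05) *and* |log2FC| ≥ log2(fc_threshold) (default 1.5,
closed boundary — boundary genes are at noise level either way, and a
deterministic convention beats an open/closed ambiguity).

## Sign-concordant classification

Genes SS1.5F in both contrasts are labelled by the signs of their two
log2 fold changes: `pifsd_induced` (SD contrast +, PIF contrast −),
`pifsd_repressed` (−, +), `ambiguous` (same sign). SS1.5F in one
contrast only gives `sd_only` / `pif_only`; otherwise `none`. A gene
with log2FC exactly 0 cannot be SS1.5F (|FC| < 1.5), so the sign rules
never see a zero. Venn percentages are reported to one decimal with
round-half-to-even — a deterministic, documented convention.

The association between the two regulations is scored with a one-sided
exact binomial test: among the n common genes, x sit in the
reciprocal-sign quadrants (induced + repressed), and the statistic is
P(X ≥ x | n, p = ½). The null "half the common genes reciprocal by
chance" is the weakest exchangeable baseline for the quadrant picture;
other nulls (e.g. marginal-sign products) would need per-gene sign
probabilities the two-list design does not constrain.

## Percent contribution of PIFq

With WT-LL as the zero reference, each gene carries FC_WT (WT-SD mean
minus WT-LL mean) and FC_pifq (*pifq*-SD mean minus WT-LL mean), and

    contribution% = 100 · (FC_WT − FC_pifq) / FC_WT.

It is 100% when the mutant fully reverts to the LL level, 0% when the
mutant retains the full WT response, and intentionally unclipped: a
mutant that overshoots the reference yields > 100%. Genes with
|FC_WT| below a floor (default log2 1.5) have an undefined
contribution and are flagged rather than dropped silently; SS1.5F
genes always clear the floor, so it only guards ad-hoc gene lists.
The statistic is location-invariant (adding a constant to all of a
gene's log2 values cancels in both numerator and denominator).

Set-level summaries report the mean ± SE of FC values over a gene set,
the ranked contribution table, and the fractions above 50% and at or
above 100%. Distribution comparisons between sample groups over a
gene set use a two-sided Wilcoxon rank-sum test on per-gene group
means: the exact null distribution when the combined sample size
is ≤ 20 (full enumeration when ties are present, since the classical
exact tables assume none), and the normal approximation with
continuity correction and mid-rank tie variance correction above that.
Fully tied data returns p = 1.

## Promoter motif enrichment

Motifs are IUPAC strings (defaults: G-box `CACGTG`, PBE `CACATG`,
extended element `CACRTGGG`, ABRE `ACGTGGC`). Scanning is
strand-aware: the pattern and its reverse complement are both matched
against the promoter with overlapping hits reported; a palindromic
motif's minus-strand duplicate at the same locus is collapsed to one
site. An `N` in the sequence matches nothing except an `N` motif
position — unknown bases should not create hits.

The gene-level statistic is presence/absence (≥ 1 hit on either
strand). Enrichment of a gene set (k of n genes with the motif)
against a background (K of N) is the hypergeometric upper tail
P(X ≥ k), delegated to `scipy.stats.hypergeom.sf` (log-space
internally) and verified against full enumeration for all tables with
N ≤ 30. Composite elements (e.g. "G-box+PBE") count a gene on
presence of *any* listed motif by default — the weaker, more
conservative reading — with co-occurrence (`all`) available as a flag.
The same machinery serves generic category enrichment for
user-supplied annotation maps. Promoter extraction from genome
coordinates is out of scope: promoters arrive as FASTA, with the
intended window being up to 3 kb upstream of the translation start,
strand-aware, truncated at sequence edges.

## Diurnal phase and rhythmicity

Each time course (≥ 8 points spanning ≥ 1 period) is z-scored and
Pearson-correlated against cosine templates
`cos(2π(t − φ)/period)` for φ on a 0.5-h grid over [0, period). The
best φ is the peak phase (ties break toward smaller φ), the best
correlation is the rhythm score, and the gene is rhythmic when the
score reaches the cutoff (default 0.7). A single-harmonic template
bank with a correlation cutoff is the transparent core of the
established phase-calling tools; Pearson-vs-Spearman and richer
template families are deliberate non-goals. Constant profiles get
score 0 (not NaN) and are never rhythmic. The score inherits
correlation's affine invariance, and relabelling sample times by a
constant shift moves all calls by exactly that shift on the grid.

Phase-distribution summaries use left-closed, right-open bins of width
period/n_bins starting at ZT0 (dawn): observed = rhythmic set genes
per bin, expected = set total × background bin fraction, fold =
observed/expected with zero-expectation bins flagged undefined rather
than infinite.

## Synthetic data: what is emulated, what is not

The generator plants, per gene class (b = baseline, e = effect size,
r = repressed contribution; group order WT-SD, WT-LL, *pifq*-SD,
*pifq*-LL):

| class            | WT-SD   | pifq-SD     | planted meaning                         |
|------------------|---------|-------------|-----------------------------------------|
| null             | b       | b           | unregulated                             |
| pifsd_induced    | b + e   | b           | night induction fully PIF-dependent     |
| pifsd_repressed  | b − e   | b − e(1−r)  | repression partially (r) PIF-dependent  |
| sd_only          | b ± e   | b ± e       | night response independent of PIFq      |
| pif_only         | b       | b ± e       | PIFq effect without a night response    |
| ambiguous        | b ± e   | b ± 2e      | same-sign response in both contrasts    |

so induced genes carry a planted contribution of exactly 100% and
repressed genes of 100·r (default r = 0.69). Defaults: n_genes 2000,
effect 1.5 log2 (linear ≈ 2.8×), noise SD 0.3 log2 units, 3
replicates, baseline 8.0 log2 units, class mix 6% induced / 4.5%
repressed / 0.5% ambiguous / 10% SD-only / 4% PIF-only / 75% null —
the mix preserves the ≈ 57:43 induced:repressed ratio and the
dominance of night-only responders seen in real dawn transcriptomes
while keeping every class large enough for recovery statistics. The
noise level is a configuration choice, not a claim about any
particular array platform. Exact recovery in the noiseless limit
additionally requires e·r ≥ log2 1.5, otherwise repressed genes
cannot pass the PIF-contrast gate even without noise.

Noise is i.i.d. Gaussian on the log2 scale per gene × replicate. Real
arrays have intensity-dependent variance, probe effects,
normalization artifacts and correlated replicates; none of that is
emulated, so green recovery tests certify the *logic* of the pipeline
under its stated noise model, not performance on any specific
platform. Promoters are i.i.d. uniform A/C/G/T with motif implants at
class-dependent probabilities (each implant one concrete IUPAC
expansion at a uniform position); real promoter composition (GC skew,
repeats, motif clustering) is not modelled — the uniform null is
exactly the regime the hypergeometric test assumes, which is what the
fixture exercises. Diurnal profiles are single cosines plus noise, or
flat for arrhythmic genes.

Determinism: the truth stream seeds from `config.seed` and the noise
stream from `config.seed + 1` (overridable), so tests can redraw noise
while holding the planted structure fixed; every generator is
bit-reproducible given its seed.

## Problem sizes and numerical choices

Recovery experiments in the tests and the acceptance script run at
n_genes = 2000 (10 seeds), 500-gene phase panels, and 1000-replicate
null calibrations — sizes at which every binomial/hypergeometric
standard error in the assertions is a few percent or less, while the
whole suite stays interactive. Tolerances follow the statistics:
exact identities to 1e-12, hand-computed test statistics to 1e-6,
sampling-based checks to 3 standard deviations of the relevant null.
Report JSON is written with sorted keys and no timestamps, so a rerun
with identical inputs and seed is byte-identical.

## Known limitations

* No normalization, batch correction, probe summarization or
  missing-value handling: the pipeline starts from a clean normalized
  log2 matrix.
* The moderated test assumes exchangeable per-gene variances around a
  single prior; strongly heteroscedastic designs should inject their
  own test function.
* The published gene counts from the original dawn-transcriptome
  experiments depend on the underlying arrays and genome annotation
  and are not recomputable here; the package reproduces the
  *procedure* and the printed ratios/means, and quantifies recovery on
  planted truth instead.
* Phase calling fits a single harmonic; strongly non-sinusoidal wave
  forms (e.g. sharp dawn spikes) are assigned the phase of their best
  cosine approximation.
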