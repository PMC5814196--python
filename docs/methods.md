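# Methods

## Study design and estimands

The package analyzes a paired design: each subject contributes one tumor
and one normal tissue sample, profiled for gene expression (RNA-Seq
counts) and miRNA expression (array intensities). Three estimands are
chained together:

1. the per-gene tumor/normal fold change and its significance;
2. the per-(gene, miRNA) slope linking subject-level differential
   expression profiles;
3. the presence of seed-complementary sites in the gene's 3′UTR for
   associated miRNAs.

## Negative-binomial mixed model

Counts are modelled as NB2 — variance $\mu + \mu^2/k$, with $k$ the size
parameter — with log link, fixed effects {intercept, tumor indicator}, an
offset equal to the log total protein-coding count of the sample, and a
normal random intercept per subject. The offset makes the tumor
coefficient a contrast of *relative* expression (RPMPCG scale), robust to
library-size differences; the random intercept absorbs the strong shared
baseline of a subject's two samples.

*Estimation.* The marginal likelihood integrates the random intercept out
per subject. The integrand's mode is found by a damped 1-D Newton
iteration (vectorized across subjects), and adaptive Gauss–Hermite
quadrature with 9 nodes (configurable) is centred and scaled at the mode.
All parameters — $\beta$, $\log\sigma$, $\log k$ — are maximized jointly
with L-BFGS-B; if its line search stalls (typical when $\hat\sigma$ sits on
the boundary) a Nelder–Mead polish confirms or improves the optimum, and
only then is the fit marked converged. Bounds: $\sigma \in [10^{-4}, 20]$,
$k \in [10^{-4}, 10^{4}]$. Start values come from a least-squares fit on
the log scale and a method-of-moments dispersion.

*Inference.* Default p-values are Wald tests on the tumor coefficient from
the numerically differentiated observed information (pseudo-inverse when
the boundary makes the Hessian singular); a likelihood-ratio test is
available via `NBMixedResults.lr_test`. Non-converged or inestimable
(all-zero) genes are flagged and excluded from FDR with a logged warning,
never silently dropped.

*Classification.* Fold change is $e^{\hat\beta_1}$; genes are `up` at
FC ≥ 1.50, `down` at FC ≤ 0.67 (inclusive cutpoints, matching the
"FCs of ≥1.50 or ≤0.67" criterion), `neither` otherwise. The ratio of
arithmetic mean RPMPCG values is reported alongside, because printed
summary tables conventionally show that ratio; both are kept at full
precision and rounded (half away from zero, 2 decimals) only at render
time. Benjamini–Hochberg adjustment runs across the genes of each run;
MSI and MSS strata are analyzed separately on their complete pairs.

## Normalization

* **RPMPCG** divides each count by the sample's total over the
  protein-coding gene set and multiplies by $10^6$; rows outside the set
  share the same denominator. Column sums over the protein-coding set are
  exactly $10^6$.
* **75th-percentile scaling** multiplies each miRNA sample by
  (median of per-sample 75th percentiles)/(own 75th percentile).
  Percentiles use linear interpolation between order statistics ("type 7");
  the convention is an argument because vendors differ. The percentile is
  computed over all rows (whether it should be detected-probes-only is not
  determinable from the published description; this choice is documented
  rather than hidden).
* The **expression filter** keeps miRNAs detected (> 0 by default) in
  strictly more than 20% of normal samples — strict, following the wording
  "greater than 20%".
* Zeros are preserved; no pseudocount is added at normalization time. A
  pseudocount for printed ratios exists as a reporting option only.

## Differential-profile association

Per subject, the differential profile is tumor − normal on the RPMPCG scale
(genes) or the q75-normalized intensity scale, untransformed (miRNAs). For
each candidate pair, ordinary least squares regresses the gene differential
on {intercept, miRNA differential, age in years (uncentered), sex as 0/1};
the test statistic is the partial F for the miRNA term.

The p-value comes from a residual-resampling bootstrap: fit the
covariates-only null model, resample its residuals with replacement onto
its fitted values B = 10,000 times, recompute the partial F, and report
$p = (1 + \#\{F^* \ge F_{\text{obs}}\})/(B+1)$ — a valid Monte-Carlo
p-value that is never exactly zero and has floor $1/(B+1)$. Each pair's
resampling stream is seeded from (run seed, gene id, miRNA id), so results
do not depend on candidate ordering. An ordinary i.i.d. bootstrap is the
default; B < 100 is rejected.

FDR is controlled *within each gene* across its tested miRNAs (the
published adjusted p-values differ across miRNAs within a gene, which is
consistent with this reading); global BH is available as an option. The
default tests every expressed miRNA per candidate gene and applies the
fold-change cutpoints only to the significant set: a pair only enters the
significant set if its adjusted p ≤ 0.05 *and* both fold changes lie
outside (0.67, 1.50) — the rule that excludes associations whose miRNA
barely moves.

## Seed matching

Seeds are the windows of length 6, 7 and 8 starting at position 2 of the
mature miRNA (1-based; the canonical seed anchor). Both the anchor and the
lengths are configurable since seed conventions vary. Matching is exact
string matching of the seed's reverse complement (RNA→DNA) against the
3′UTR sense strand; overlapping sites all count; no G:U wobble or mismatch
tolerance, because the procedure models sequence pairing, not
thermodynamics. A pair "has a seed match" if any length matches;
per-length records are kept. Associations with both fold changes on the
same side of 1 are `concordant`, opposite sides `inverse`; a fold change of
exactly 1 has no direction and is flagged degenerate.

## Synthetic cohort generator

The generator draws data from the assumed models so that downstream
estimators are correctly specified, then plants the effects the pipeline
should recover:

* counts: NB2 with mean $L_s \cdot u_i \cdot m_g \cdot FC_g^{\text{tumor}}$ —
  uniform library sizes $L_s$ (default 2–6 million), log-normal subject
  intercepts ($\sigma$ = 0.4 on the log scale), log-normal baseline
  abundances $m_g$ (normalized to proportions), and fold changes planted on
  a random fraction of genes (default 30%, half up in [1.5, 4.0], half down
  in [0.25, 0.67]);
* miRNA intensities: per-miRNA log-normal baselines, the same planted-FC
  scheme (the dysregulated fraction is shared with genes), multiplicative
  log-normal noise (SD 0.4);
* metadata: age $\sim N(64.8, 10.1^2)$ years, balanced sex, MSI fraction
  0.134, 217 subjects by default — the published cohort's composition at
  desk-scale gene/miRNA panel sizes (600 genes / 80 miRNAs by default);
* couplings: for chosen (pathway gene, miRNA) pairs, the tumor sample's
  counts are shifted by slope × (subject's centered miRNA differential),
  where the slope is a *standardized* effect (default 0.2–0.4) times the
  ratio of the gene's predicted RPMPCG-differential noise SD to the
  miRNA's differential SD. Standardizing makes statistical power depend on
  the effect and the number of pairs rather than on the features'
  arbitrary abundance scales; centering keeps the gene's planted fold
  change intact. The realized raw slope is recorded in the ground truth;
* seed sites: for a fraction of couplings (default 0.5), the reverse
  complement of a randomly chosen 6/7/8-nt seed is written into the gene's
  otherwise i.i.d.-uniform UTR at a recorded, non-overlapping offset.
  Uniform background makes the false-positive match rate quantifiable:
  about $(L-5)/4^6$ expected 6-mer sites per 1-kb UTR.

One `numpy` generator seeded by `SimConfig.seed` drives every draw in a
fixed, documented order, so cohorts are byte-identical across runs.

*What the generator does not emulate:* FFPE degradation, array QC
artifacts, read-level sequencing data, correlated co-expression modules,
realistic UTR composition (GC bias, repeats), or composition effects at
real-genome scale — at desk-scale gene counts a handful of abundant genes
dominate the protein-coding total, so normalization denominators are
noisier than with ~17,000 genes, and measured fold changes of coupled or
highly dysregulated genes can be mildly compressed. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
model, not robustness to every artifact of real FFPE data.

## Numerical and design choices

* Fold-change and percentage cells round half-away-from-zero at render
  time only (2 decimals for FCs, 1 for percentages).
* BH adjustment delegates to `statsmodels.stats.multitest`; the OLS
  partial F uses a QR decomposition shared by the observed fit and the
  vectorized bootstrap (the classical-F limit is verified in tests against
  `statsmodels.OLS`).
* The subject-sd → 0 limit of the mixed model is tested against an
  independent fixed-effects NB regression (`statsmodels.NegativeBinomial`).
* Degenerate inputs fail loudly with the offending sample/subject/field
  named: zero protein-coding totals, nonpositive 75th percentiles,
  unpaired subjects, rank-deficient designs, invalid configurations.
* Problem sizes in the test-suite simulation studies (for example 9
  replicates of 200 pairs for fold-change recovery, 400 null genes at 50
  pairs for FDR calibration, B = 1000 for bootstrap calibration) were
  chosen to give stable Monte-Carlo checks at desk scale; the acceptance
  script records the size used for every number it reports.

## Known limitations

* The mixed model requires balanced groups (the paired design); general
  unbalanced GLMMs are out of scope.
* Wald p-values at the $\sigma$ boundary are approximate; the LRT option
  shares the limitation (boundary null distributions are not mixture-
  corrected).
* The miRNA differential is analyzed on the untransformed normalized
  intensity scale; heavy-tailed array noise can make the bootstrap F
  conservative. A wild-bootstrap variant is a natural extension and is not
  implemented.
* Per-gene BH across miRNAs treats genes independently; correlated miRNAs
  within a gene are handled only through BH's robustness, not modelled.
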