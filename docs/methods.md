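# Methods

## The causal model

All estimators operate on summary statistics: for SNP *j*, the exposure
association γ̂ⱼ with standard error σₓⱼ and the outcome association Γ̂ⱼ with
standard error σᵧⱼ, after allele harmonization. Under the instrumental-
variable assumptions (relevance, independence from confounders, exclusion
restriction), Γⱼ = β·γⱼ for a common causal effect β, and each ratio
Γ̂ⱼ/γ̂ⱼ estimates β. Binary outcomes are handled on the log-odds scale;
the estimation machinery is scale-agnostic.

For mediation, the structural model is

    X --a--> M --b--> Y,    X --c'--> Y  (direct),

with total effect c = a·b + c′. Two-step MR estimates a (exposure
instruments against the mediator GWAS), b (mediator instruments against
the outcome GWAS) and c (exposure instruments against the outcome GWAS);
the indirect effect is a·b, the direct effect c − a·b, and the proportion
mediated a·b/c.

## Estimators

**IVW** is weighted regression of Γ̂ on γ̂ through the origin with weights
1/σᵧ²: β̂ = Σwγ̂Γ̂ / Σwγ̂². The fixed-effect SE is (Σwγ̂²)^(−1/2); the
default multiplicative random-effects model inflates it by
max(1, √(Q/(J−1))), absorbing balanced heterogeneity without changing the
point estimate. Which variant an applied analysis means by "IVW" is often
unstated; both are exposed and the default is the more conservative one.

**MR-Egger** adds an unconstrained intercept, estimating the average
directional pleiotropic effect; its p-value (t, J−2 df) is the pleiotropy
test. Rows are first oriented so γ̂ⱼ ≥ 0 (jointly negating γ̂ and Γ̂),
making the fit invariant to per-SNP allele recoding. SEs use the same
multiplicative overdispersion floor. Egger requires spread in γ̂ and is
sensitive to instruments with γ̂ near zero, whose orientation is decided
by noise — one reason the F > 10 filter precedes estimation.

**Weighted median**: order the Wald ratios, accumulate normalized inverse-
variance weights, and linearly interpolate the ratio at cumulative
midpoint 0.5. Consistent when valid instruments carry ≥50% of the weight.
The SE is a seeded parametric bootstrap (γ̂*, Γ̂* redrawn from their
sampling distributions; default 1000 replicates).

**Weighted mode**: Gaussian-kernel density over the ratios with weights
1/se(ratio)² and bandwidth h = φ·0.9·min(SD, MAD/0.6745)·J^(−1/5)
(modified Silverman; φ defaults to 1). The estimate is the argmax over a
512-point grid spanning [min−3h, max+3h]; tests confirm agreement with a
10⁵-point scan to within one grid step. If every ratio is identical
(h = 0) that ratio is returned with the fixed-effect IVW SE.

**Cochran's Q** = Σ(Γ̂ⱼ − β̂γ̂ⱼ)²/σᵧⱼ² — algebraically the usual
Σ(γ̂²/σᵧ²)(ratioⱼ − β̂)² but defined even at γ̂ⱼ = 0 — is referred to
χ²(J−1).

**BWMR** fits Γ̂ⱼ ~ N(β·γ̂ⱼ, vⱼ), vⱼ = β²σₓⱼ² + σᵧⱼ² + τ², under a
two-component scale mixture: with prior weight 1−η a SNP is a regular
instrument (variance vⱼ), with weight η an outlier (variance κ·vⱼ,
κ = 100). EM alternates per-SNP non-outlier responsibilities wⱼ with a
Nelder-Mead maximization of the responsibility-weighted log-likelihood
over (β, log τ²) and the closed-form update η = mean(1−wⱼ). τ² is
initialized from the DerSimonian-Laird moment estimator, η at 0.05;
convergence is |Δβ| < 1e-8 (max 200 iterations, error on failure carrying
the last iterate). The SE is the inverse root of the observed information
of the weighted likelihood at convergence (central finite difference).
The `fix_null=True` flag pins η = τ² = 0 **and** drops the β²σₓ² term, so
the model collapses exactly to fixed-effect IVW — retaining the
exposure-noise term would leave an O(σₓ²) gap to IVW, which is the point
of the collapse check. This EM formulation is a deliberate, documented
approximation to the variational Bayes algorithm of the original BWMR
proposal: it shares the model (per-SNP probabilistic down-weighting under
a heavy-tailed alternative) but not the exact prior machinery.

## MR-PRESSO

For each SNP the leave-one-out fixed-effect IVW slope β̂₍₋ⱼ₎ gives a
discrepancy dⱼ = (Γ̂ⱼ − β̂₍₋ⱼ₎γ̂ⱼ)²/σᵧⱼ²; RSSobs = Σdⱼ. Each of k
parametric replicates redraws Γ̂*ⱼ ~ N(β̂₍₋ⱼ₎γ̂ⱼ, σᵧⱼ²) and
γ̂*ⱼ ~ N(γ̂ⱼ, σₓⱼ²) and recomputes the same quantity. The global p is the
+1-corrected empirical tail probability (floor 1/(k+1), never zero); the
per-SNP outlier p compares dⱼ with its own simulated distribution, with a
Bonferroni-adjusted column alongside. Discrepancies are
variance-standardized by default so heteroskedastic SNPs share a scale;
`standardized=False` reproduces the unstandardized RSS. The recursive
filter removes the smallest-outlier-p SNP (ties broken by snp_id) and
re-runs the global test until p > α, refusing to shrink below 4 SNPs
(`IrreduciblePleiotropyError` with the partial report). The default
`retest` mode recomputes outlier p-values after every removal — the
stricter reading of "sequentially removed" — while `sort_once` removes in
the initial ranking order. Replicate draws fill (replicate, SNP)-ordered
arrays from one seeded stream, and each loop iteration derives its seed
from (seed, iteration), so reports are bit-reproducible. The distortion
test is out of scope: removal, not correction, is the supported remedy.

## Mediation arithmetic

`product_effect` returns a·b with the first-order delta-method SE
√(a²se_b² + b²se_a²). `mediate` adds the direct effect c − a·b
(SE √(se_c² + se_ab²)) and the proportion P = a·b/c with

    Var(P) = (b/c)²se_a² + (a/c)²se_b² + (ab/c²)²se_c²,

a normal 95% CI, and a Wald z p-value (the test behind a reported
proportion p is rarely stated; Wald-on-P is implemented and labelled as
such). The three inputs are treated as independent — they come from three
distinct GWAS pairings — although a and c share exposure instruments, a
documented approximation. Only the first-order delta term is used, which
keeps the decomposition direct + indirect = c exact (to a rounding ulp;
the constructor enforces this). The proportion is computed always but
flagged reportable only when direct and indirect effects share a sign
(`direction_rule="total"` offers the total-vs-indirect variant); c = 0
raises an undefined-proportion error rather than returning an infinity.

## Synthetic-data generator

`simulate_three_trait_gwas` emulates three non-overlapping GWAS of a
mediation design. Defaults: 200 SNPs, 50 exposure instruments, 50
mediator instruments, n = 50,000 per GWAS, a = 0.3, b = −0.2, c′ = −0.05
(total effect −0.11, 54.5% mediated), instrument-effect scale 0.08, MAF ~
U(0.1, 0.5), 10% palindromic allele pairs. Per-SNP truth: exposure
instruments carry γⱼ on X, a·γⱼ on M and c·γⱼ + αⱼ on Y (αⱼ the optional
pleiotropic direct effect: zero, balanced, or directional with
configurable mean/SD/fraction); mediator instruments carry δⱼ on M and
b·δⱼ on Y; optional outcome instruments carry εⱼ on Y (and
`reverse_effect`·εⱼ on X, for reverse-MR power studies). Observed effects
add independent Gaussian noise with se = 1/√(2·maf(1−maf)·n), the
standardized-trait first-order formula, so doubling n scales every SE by
exactly 1/√2 and n → ∞ recovers the truth.

Design choices worth knowing:

* **Instrument effects are half-normal (one-signed)** — instruments are
  exported oriented to the trait-increasing allele, the GWAS-reporting
  convention. This is load-bearing: with zero-mean effects, per-SNP
  orientation would cancel any directional pleiotropy mean (the Egger
  intercept would estimate 0 by symmetry) and directional pleiotropy
  would leave the through-origin IVW slope unbiased, emptying the
  robustness comparisons of content.
* **Locus attributes (positions, alleles, MAFs) come from a separate
  `locus_seed` stream**, so replicates with different noise seeds share a
  variant panel and can be cross-combined into multi-exposure screens.
* **LD is block-diagonal AR(1) and affects clumping only**: true effects
  sit on block representatives and estimation noise is drawn
  independently per SNP, keeping estimator null distributions exact for
  calibration tests.
* **Gross outliers** are injected as shifts in multiples of the outcome
  SE on the observed outcome beta.
* Binary outcomes use the same Gaussian sampling model on the log-odds
  scale; no liability-scale conversion, case-control ascertainment,
  sample overlap, or population structure is modelled. Passing tests
  therefore demonstrate correctness of the estimators under their stated
  assumptions — not robustness to the additional pathologies of real
  consortium GWAS (winner's curse across studies, cryptic overlap,
  mis-specified effect scales).

## Numerical and procedural choices

* Selection is strict (p < threshold, F > 10); clumping keeps the
  smallest-p index SNP and removes same-chromosome candidates within
  ±10,000 kb with r² ≥ 0.01; all orderings break p ties by snp_id so
  results are independent of input order.
* Harmonization drops palindromic SNPs unless both allele frequencies are
  at least 0.08 from 0.5 (configurable), resolves swapped and
  strand-complemented exports, and logs every drop with its reason; rows
  missing from the outcome or with irreconcilable alleles are dropped,
  never fatal.
* The QC pipeline order is select → clump → F-filter → harmonize →
  MR-PRESSO screen; estimation runs on the PRESSO-retained set. Screens
  gate on raw p < 0.05 by default (the practice the workflow emulates),
  with optional Benjamini-Hochberg gating recorded in the run metadata.
* Pipeline stage seeds derive from the run seed via CRC32 of stage/trait
  labels (not Python's salted `hash`), so full-run exports are
  byte-identical across processes.
* Readers reject invalid rows individually with logged line numbers and
  only fail wholesale when a majority of rows is invalid; write→read
  round trips are identity to 12 significant digits.
* Test problem sizes: recovery and robustness experiments use 200
  replicates of 50-instrument studies at n = 50,000; calibration uses
  1,000–2,000 replicates; MR-PRESSO experiments use 30-SNP sets at
  k = 200 simulations; the end-to-end mediation recovery uses 100 seeded
  screens. These sizes give Monte-Carlo errors comfortably inside the
  asserted bands.

## Known limitations

* Leg-b mediator instruments selected at p < 1e-5 can include strong
  exposure instruments (which see the mediator through the a-path); their
  Wald ratios estimate c/a rather than b, biasing the mediated proportion
  upward by a few percent at the default design. Steiger filtering, which
  would remove them, is deliberately out of scope.
* Correlated instruments are handled by clumping, not by generalized
  (LD-aware) IVW; proxy lookup for missing outcome SNPs is not provided.
* The BWMR SE reflects the weighted likelihood's curvature in β only
  (τ², η treated as fixed at their estimates).
* Winner's curse from selecting instruments on the same exposure GWAS
  used for estimation is present in simulations exactly as in the real
  workflow; it is mild at the default instrument strength but grows as
  σ_gamma approaches the noise floor.
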