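# Methods

## The estimation problem

Two-sample Mendelian randomization (MR) estimates the causal effect of an
exposure X on an outcome Y from published GWAS summary statistics alone.
For each instrument SNP j we observe the SNP–exposure association
β̂_ZX,j (SE σ_X,j) in one study and the SNP–outcome association β̂_ZY,j
(SE σ_Y,j) in a non-overlapping study.  Each SNP yields a Wald ratio
β̂_j = β̂_ZY,j / β̂_ZX,j, and the inverse-variance-weighted (IVW) estimate
is the weighted mean of the ratios with first-order weights
w_j = β̂_ZX,j² / σ_Y,j² — algebraically a zero-intercept weighted
regression of β̂_ZY on β̂_ZX.  Validity rests on the three instrumental
assumptions (relevance, independence from confounders, and exclusion of
direct SNP→outcome paths); the sensitivity battery exists because the third
assumption — no horizontal pleiotropy — is untestable SNP by SNP.

## Pipeline stages

1. **Instrument construction** — SNPs with P < 5×10⁻⁸ in the exposure
   study, greedily pruned so every accepted pair has LD r² < 0.01 (LD is
   supplied as a matrix; absent a matrix, SNPs are treated as independent).
   Visit order is ascending p-value with lexicographic rsid tie-breaks, so
   selection is reproducible.
2. **Harmonization** — outcome rows are aligned to the exposure's effect
   allele: direct match, allele swap (beta negated, frequency
   complemented), or strand complement, in that order.  Palindromic A/T and
   C/G variants carry no allele-label information across strands; the
   default policy orients them by comparing effect-allele frequencies to
   0.5 in both studies and drops them when either frequency falls inside
   the ambiguity band (0.42, 0.58).  A `drop` policy is available.  Every
   SNP's disposition is kept in a per-row audit table.
3. **Outlier removal** — the radial decomposition of Cochran's Q refers
   each SNP's contribution Q_j = w_j (β̂_j − β̂_radial)² to χ²(1);
   SNPs exceeding the α = 0.05 level (Bonferroni-divided by k by default)
   are removed, and diagnostics (R², F, Q) are recomputed on the retained
   set.
4. **Estimation** — IVW plus the sensitivity battery below; binary
   outcomes (log-odds scale) are additionally reported as odds ratios.
5. **Multiplicity** — across a batch of tests, the IVW p-values (for
   multivariable tests, the focal exposure's direct-effect p) receive a
   Benjamini–Hochberg FDR adjustment; raw and adjusted columns are both
   emitted.

## Estimators

* **IVW** (default multiplicative random effects): SE = (Σw_j)^{-1/2}
  scaled by √max(1, Q/(k−1)).  The floor keeps overdispersion corrections
  from ever shrinking the fixed-effects SE.  Normal inference.
* **MR-Egger**: weighted regression with free intercept on
  orientation-flipped data (all β̂_ZX ≥ 0).  The intercept estimates
  average directional pleiotropy; a nonzero value signals bias in the IVW.
  Residual variance scaling is floored at 1; inference uses t with k−2 df
  (the conservative choice for the small-k regimes where Egger is
  fragile).  The I²_GX statistic quantifies regression dilution from
  measurement error in β̂_ZX.
* **SIMEX-corrected Egger**: for each λ in {0, 0.5, 1, 1.5, 2} and B
  replicates (default 1000), β̂_ZX is perturbed with variance λσ_X²
  noise; the mean fit per λ is extrapolated quadratically to λ = −1 (the
  error-free state).  Variance uses the Stefanski–Cook difference method
  (mean model variance minus between-replicate variance, extrapolated on
  the same grid); a non-positive extrapolated variance falls back to the
  λ = 0 model variance.  When every σ_X is zero the plain Egger fit is
  returned unchanged — there is no error to extrapolate away, and the
  shortcut keeps the identity exact rather than subject to polynomial
  round-off.  A seed is mandatory; output is bit-reproducible.
* **Weighted median**: the weight-0.5 quantile of the ordered ratios,
  linearly interpolated on cumulative weights s_j = Σ_{i≤j} w'_i − w'_j/2;
  consistent when ≥ 50% of weight comes from valid SNPs.  SE by parametric
  bootstrap (resampling β̂_ZX,j and β̂_ZY,j from their reported normal
  distributions — the only resampling available in a summary-data design),
  1000 replicates by default.
* **Weighted mode**: argmax of a weighted normal-kernel density over the
  ratios on a 2048-point grid, bandwidth
  h = φ·0.9·min(sd, iqr/1.349)·k^{−1/5} (φ = 1 by default); consistent
  when the largest cluster of ratios is the valid one.  Identical ratios
  (zero bandwidth) return the common ratio directly.
* **Multivariable IVW**: zero-intercept weighted regression of β̂_ZY on
  the K ≥ 2 columns of exposure effects; each coefficient is that
  exposure's direct effect holding the others constant.  Residual scaling
  floored at 1, normal inference.  A condition number above 1e10 raises a
  collinearity error naming near-duplicate columns; an exactly-zero
  exposure column is therefore reported as collinear rather than fitted
  with a degenerate covariance.

All estimators consume the same harmonized rows — no estimator-specific
re-filtering — so magnitude/direction comparisons across the battery are
interpretable.  Confidence intervals are 95% throughout (±1.959964 SE).

Instrument strength: per-SNP variance explained is 2·eaf(1−eaf)·β̂_ZX²
when frequencies are available, else β̂²/(β̂² + n σ²); R² is their sum and
F = R²(n−1−k)/((1−R²)k), with F < 10 labelled weak.  These are the
standard summary-data approximations; published F values computed by other
toolchains are not generally reproducible from printed R², n, and k, so
the formula is documented rather than matched to any external figure.

## The synthetic-data generator

Summary statistics are simulated directly at the estimate level — no
individual-level genotypes — because that is all two-sample MR consumes.
For each SNP: EAF ~ Uniform(0.1, 0.5); σ = 1/√(2·eaf(1−eaf)·n) (the
single-SNP regression SE on a standardized trait); true instrument effects
γ_j = |Normal(0, γ_sd²)|; observed β̂_ZX ~ N(γ_j, σ_X²) and
β̂_ZY ~ N(θγ_j + α_j, σ_Y²) with independent noise per study.  Alleles are
drawn from non-palindromic pairs, and an optional `flip_fraction` reports a
random subset of SNPs on the opposite effect allele so harmonization is
exercised end to end.

γ is drawn as a folded normal (instruments coded so the effect allele
increases the exposure) deliberately: with sign-symmetric γ and pleiotropy
independent of γ, E[γα] = 0, so "directional" pleiotropy would leave the
IVW asymptotically unbiased and the orientation-flipped Egger intercept
centred on zero — the scenario would not exhibit the phenomenon it exists
to show.  Positive coding is also how robust-MR simulation studies are
conventionally built.

Scenario structure for the direct SNP→outcome effects α_j:

* **V** — α ≡ 0 (vertical pleiotropy only; the calibration benchmark).
* **H-directional** — a `prop_invalid` fraction (default 40%) of SNPs gets
  α ~ N(0.05, 0.02²), independent of γ (InSIDE holds, E[α] ≠ 0).
* **H-balanced** — same with mean 0.
* **C-inside-violation** — α correlated with γ (corr ρ, default 0.5).
* **TRIANGLE** — a confounder with its own k SNPs (γ^c) feeds an
  education-like exposure (δ₁ = 0.4) and the outcome (δ₂ = 0.5); the
  exposure has k own SNPs (γ^e) with direct effect θ₁ = 0.  Instruments
  selected from the exposure table alone include confounder-driven SNPs,
  reproducing the artefactual univariable association that multivariable
  adjustment removes.
* **Bidirectional** — two traits with disjoint core SNP sets and one-step
  transmitted effects (defaults θ_AB = 0.45, θ_BA = 0.3); strong SNPs
  reach genome-wide significance in both traits and must be excluded
  before either direction is estimated.

Default study conditions: k = 50 SNPs per core set (between small and
large real instruments), n = 50,000 per study, γ_sd = 0.2.  The strength
scale is chosen so the robust-estimator contrasts are visible above
sampling noise at these sample sizes: with weaker instruments the weighted
median's percentile shift under 40% contamination approaches the size of
its own bias bound and the qualitative split (biased IVW, robust median)
drowns in noise.  This makes per-SNP variance explained far larger than in
real behavioural GWAS — a deliberate property of the testbed, standard in
robust-MR simulation work.  The SIMEX study instead uses k = 200 weak-ish
SNPs from an exposure sample of n = 700 against a 500,000-sample outcome,
because regression dilution must dominate estimator noise for a
per-replicate improvement-rate criterion to be meaningful.

What the generator does *not* emulate: LD structure between SNPs, sample
overlap between studies, selection/collider effects, winner's-curse-free
discovery (instruments are selected on observed p-values in the same
simulated exposure study, so replicate studies show the expected mild
attenuation — e.g. bidirectional recovery of ≈0.40/0.27 against true
0.45/0.30), and genuine case-control sampling for binary outcomes (the
log-odds scale reuses the normal sampling model).  Passing tests therefore
certify the estimators and the pipeline logic, not the idiosyncrasies of
any real GWAS.

## Replicate studies and problem sizes

The calibration/robustness studies use 500 replicates (SIMEX and
bidirectional: 200, the former because each replicate itself contains
B×|λ| refits), with per-replicate RNG streams derived from
(study seed, replicate index).  At these sizes the Monte-Carlo SE of a
mean IVW estimate is ≈ 0.0003 and of a rejection rate ≈ 0.01–0.03, small
against every margin tested.

## Known limitations

* Correlated-SNP (generalized) IVW, MR-PRESSO, MR-RAPS, Steiger filtering
  and proxy-SNP lookup are out of scope.
* LD enters only as a user-supplied r² matrix; there is no reference-panel
  clumping.
* The bootstrap SEs for median/mode assume the reported per-SNP SEs are
  correct and independent across SNPs.
* Indels and VCF-encoded summary statistics are not supported.
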