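# Methods

## The model

`mrscreen` implements two-sample Mendelian randomisation (MR) over
published GWAS summary statistics.  A set of J genetic variants
instruments an exposure X; the causal effect θ of X on an outcome Y is
identified under the instrumental-variable assumptions — relevance
(variants associate with X), independence (no confounding of the
variant-outcome relationship) and exclusion restriction (variants affect Y
only through X) — plus, for the two-sample design, the assumptions that
the two GWAS samples represent the same population and do not overlap.
All effects are per allele on standardised (SD-unit) traits.

Per variant, the Wald ratio θ̂_j = β̂_Yj/β̂_Xj carries the first-order
delta-method SE σ_Yj/|β̂_Xj|; exposure-side uncertainty is ignored at
first order (a second-order SE including the β̂_X sampling term is
available behind `wald_ratios(..., second_order=True)`, default off).
Pooling and sensitivity methods are described in the README; the notes
below record the conventions and the reasoning behind choices the
published method descriptions leave open.

## Numerical and inferential conventions

* **Multiplicative random effects.**  The IVW SE is the fixed-effect SE
  inflated by √φ with φ = max(1, Q/(J−1)).  The floor at 1 matches common
  MR software behaviour and prevents anti-conservative SEs when variants
  are more homogeneous than chance expects.  A consequence worth knowing:
  at small J the test is mildly *conservative* — with J = 4 the exact null
  rejection rate of the α = 0.05 test is 0.0374, not 0.050 (the test
  statistic is Z/√max(1, Q/3) with Z ⊥ Q).  The calibration experiment
  `ivw_null_rejection_rate` measures exactly this.
* **Reference distributions.**  Normal for IVW and the medians; t with
  J−2 df for MR-Egger (small-J regression convention).  z₀.₉₇₅ is fixed at
  1.959964 so printed CIs are bit-reproducible.
* **Egger fitting.**  Weighted least squares (statsmodels) with weights
  σ_Y⁻²; SEs are rebuilt from the unscaled covariance (X′WX)⁻¹ times
  max(1, RSS_w/(J−2)), so the exact-linear (zero-residual) case is
  handled without 0/0.  Designs with identical β̂_X are rejected as
  singular.  Variants are oriented to β̂_X ≥ 0 before fitting.
* **Median bootstrap.**  θ*_j ~ Normal(θ̂_j, se_j²), n_boot = 1000 by
  default, SE = sd of the replicate medians; weights for the weighted
  median are held at their observed se⁻² values across replicates.  The
  weighted median interpolates the cumulative midpoint weights
  s_j = Σ_{k≤j} w′_k − w′_j/2 at 0.5.
* **MR-PRESSO.**  Observed RSS uses leave-one-out IVW expectations;
  Monte-Carlo p-values use the add-one estimator (never zero, floored at
  1/(n_sim+1)); per-variant outlier p-values are Bonferroni-multiplied by
  J; the distortion test compares the outlier-corrected shift against
  1000 random variant-sets of the same size.  Defaults n_sim = 1000,
  outlier α = 0.05.  J = 4 is accepted with a warning: the method's
  leave-one-out expectations are heterogeneous at small J, which both
  blunts outlier power (~0.6 for a 10·σ_Y outlier at J = 4) and makes the
  global test conservative; its advertised operating characteristics
  (power ≈ 1, calibrated global test) hold from J ≈ 20 with strong
  instruments, which is where the calibration experiments measure it.
* **Harmonisation.**  Outcome rows are aligned to the exposure's effect
  allele: identical coding kept; swapped coding negates β and mirrors
  EAF; strand flips resolved by base complementation (complement first,
  then the same rules).  Palindromic (A/T, G/C) variants are *retained*
  under a forward-strand assumption and flagged `is_palindromic`, because
  same-strand matches take precedence; irreconcilable rows are dropped
  with a logged reason, and shared = harmonised + dropped always holds.
  Duplicate rsids keep the first occurrence, deterministically.
* **Seeding.**  The screen derives each outcome's random streams from
  (master seed, CRC-32 of the outcome name) and spawns independent child
  streams per method, so the panel is order-invariant and adding an
  outcome never changes another outcome's draws.
* **Degenerate inputs.**  β̂_X = 0 raises a degenerate-instrument error
  naming the variant; J below a method's minimum (3 for Egger, 4 for
  PRESSO) yields an absent result with a reason in the screen rather than
  an aborted run; an outcome sharing no rsids yields a `no_overlap` row.

## Instrument construction

Selection keeps variants with p < 5 × 10⁻⁸ (optionally inside a
position window, e.g. 1000 kB around a cis locus).  LD pruning is greedy
with p-value priority and rsid tie-break against a *user-supplied* r²
matrix at r² < 0.3 — the package deliberately bundles no reference panel,
so it stays download-free; survivors are mutually uncorrelated below the
threshold and the result is row-order-invariant.  Strength diagnostics:
per-variant F = (β/σ)², variance explained r²_j = 2·EAF(1−EAF)β² when the
EAF is known, else the approximation F/(F+n−2); the EAF formula is
preferred when both are available.  Totals sum per-variant r², valid for
uncorrelated instruments.  Because published "R²" values are ambiguous
between proportion and percent, both scales are reported.

## What the generator emulates — and what it does not

`simulate_pair`/`simulate_panel` emulate a cis-instrument screen: J
uncorrelated SNPs (default 4) with MAF uniform on (0.1, 0.5), a
standardised exposure GWAS of n_x = 25,314 and outcome GWAS of
n_y = 8,293 (a 42-outcome panel by default), instrument variance
explained 0.954% in total.  For standardised traits the per-allele SE is
1/√(2·maf(1−maf)·n) exactly, so generated SEs match that closed form.
True SNP-exposure effects γ_j are non-negative — the effect allele is the
exposure-increasing allele, the usual reporting convention for selected
cis instruments — with magnitudes uniform on [0.5, 1.5] × scale: selected
instruments are genome-wide significant, so their effects are
heterogeneous but bounded away from zero.  SNP-outcome means are
θγ_j + α_j with pleiotropy α_j off (`none`), balanced (mean-zero),
directional (mean μ_α, the Egger recovery scenario) or InSIDE-violating
(α correlated with γ at a chosen ρ, the documented Egger negative
control).  Outcome files optionally scramble allele coding (swap and/or
strand-complement, non-palindromic pairs only) to exercise harmonisation;
after harmonisation the results are identical to the unscrambled pair.

Not emulated: LD between instrument SNPs (the motivating design uses
uncorrelated variants), sample overlap between the two GWAS, population
stratification, MAF-dependent effect-size architecture, binary traits,
and palindromic-plus-strand-ambiguous coding (unresolvable in principle
under the forward-strand rule).  Passing calibration tests therefore
demonstrate correctness of the estimators under the stated sampling
model, not robustness to those real-data complications.

## Calibration experiments and problem sizes

`mrscreen.calibration` defines the standing experiments shared by the
test suite and `scripts/acceptance.py`; sizes are chosen so each runs in
seconds to a couple of minutes on one core:

* IVW = zero-intercept-WLS identity on 100 random instruments (exact);
* type-I error and mean Cochran's Q at the study scale (J = 4, θ = 0,
  2000 screens) — expected ≈ 0.037 (see above) and J − 1 = 3;
* recovery: θ = 0.5, J = 50, total R² = 0.10 (per-SNP F ≈ 50), 1000
  screens; residual weak-instrument attenuation ≈ θ/F ≈ 0.01;
* Egger intercept: directional μ_α = 0.05, τ = 0.02, θ = 0, J = 50, 1000
  screens.  θ = 0 isolates the intercept: with θ ≠ 0 and finite per-SNP
  F, regression dilution attenuates the slope and leaks a bias of order
  θ·(1−λ)·E[β̂_X] into the intercept (λ the reliability ratio) — an
  intrinsic MR-Egger limitation, not an implementation artefact;
* MR-PRESSO: power on a 10·σ_Y injected outlier over 200 instruments and
  null global-test rate over 500, both at J = 20, per-SNP F ≈ 60;
* end-to-end screen: 42 outcomes, two with θ = −0.8, four-SNP instrument
  at the default strength — both recovered family-wise significant with
  IVW SE ≈ 0.11, z ≈ 7.

## Known limitations

Wald/IVW inference ignores exposure-side uncertainty (first-order
convention); weak instruments bias estimates toward the null by ≈ F/(F+1)
per SNP.  The weighted median's bootstrap SE is approximate for very
small J.  MR-Egger requires spread in β̂_X and suffers the dilution
described above.  MR-PRESSO's guarantees degrade below J ≈ 10.  The LD
pruner trusts the supplied r² matrix; no strand or build checking is done
beyond allele reconciliation, and proxy-variant lookup is out of scope.
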