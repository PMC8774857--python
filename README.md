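# mrscreen

Two-sample Mendelian randomisation (MR) screening of GWAS summary
statistics: allele harmonisation, the Wald/IVW estimator with
pleiotropy-robust sensitivity methods (simple median, weighted median,
MR-Egger, MR-PRESSO), instrument-strength and heterogeneity diagnostics,
and Bonferroni-classified multi-outcome screens — plus a synthetic
summary-statistics generator with known ground truth, so the entire
pipeline can be exercised and calibrated without downloading any GWAS.

The package is written for epidemiologists and statistical geneticists who
want a reproducible, scriptable screen of one genetically proxied exposure
(e.g. morning cortisol instrumented by a handful of cis variants at a
single locus) against a panel of outcomes (e.g. 42 circulating cytokines),
using only published summary statistics from two non-overlapping GWAS.

## The statistics

For each harmonised variant *j* with SNP-exposure association
β̂<sub>Xj</sub> (SE σ<sub>Xj</sub>) and SNP-outcome association
β̂<sub>Yj</sub> (SE σ<sub>Yj</sub>):

* **Wald ratio** θ̂<sub>j</sub> = β̂<sub>Yj</sub>/β̂<sub>Xj</sub>, with
  first-order delta-method SE σ<sub>Yj</sub>/|β̂<sub>Xj</sub>|.
* **IVW** (multiplicative random effects): θ̂ = Σw<sub>j</sub>θ̂<sub>j</sub> / Σw<sub>j</sub>
  with w<sub>j</sub> = se(θ̂<sub>j</sub>)<sup>−2</sup>; Cochran's
  Q = Σw<sub>j</sub>(θ̂<sub>j</sub> − θ̂)² with J−1 df; overdispersion
  φ = max(1, Q/(J−1)); se(θ̂) = √(φ/Σw<sub>j</sub>). Algebraically this is
  the zero-intercept WLS slope of β̂<sub>Y</sub> on β̂<sub>X</sub> with
  weights σ<sub>Y</sub><sup>−2</sup>.
* **Simple / weighted median**: the (weighted) median of the θ̂<sub>j</sub>,
  consistent when ≥ 50% of variants (of weight) are valid instruments;
  parametric-bootstrap SEs.
* **MR-Egger**: weighted regression of β̂<sub>Y</sub> on β̂<sub>X</sub>
  with an unconstrained intercept after orienting β̂<sub>X</sub> ≥ 0; the
  intercept estimates the average directional pleiotropic effect under the
  InSIDE assumption, and its p-value is a pleiotropy test.
* **MR-PRESSO**: a residual-sum-of-squares simulation framework giving a
  global pleiotropy test, per-variant outlier tests (Bonferroni-adjusted),
  an outlier-corrected IVW estimate, and a distortion test.

A screen over *m* outcomes classifies each outcome on the IVW p-value:
**significant** (p < α/m), **suggestive** (α/m ≤ p < α) or
**non-significant** (p ≥ α); with the defaults α = 0.05 and m = 42 the
family-wise cut-off is p < 0.00119.

## Worked example

Simulate a 42-outcome panel in which exactly two outcomes carry a true
causal effect of −0.8 SD per SD of exposure, instrumented by four
uncorrelated cis SNPs explaining ~0.95% of the exposure, then screen it:

```python
from mrscreen import ScreenConfig, SimulationConfig, run_screen, simulate_panel

cfg = SimulationConfig(n_outcomes=42, n_causal=2, theta=-0.8, seed=7)
exposure, outcomes, truth = simulate_panel(cfg)
rows = run_screen(exposure, outcomes, ScreenConfig(seed=7))

truth_map = truth.groupby("outcome_name").theta.first()
for r in rows:
    if r.classification != "non_significant":
        est = r.ivw
        print(f"{r.outcome_name:8s} {est.estimate:+.3f} "
              f"[{est.ci_low:+.3f}, {est.ci_high:+.3f}] p={est.pval:.2e} "
              f"{r.classification}  (true theta {truth_map[r.outcome_name]:+.1f})")
```

```
IL-12-P70 -0.784 [-1.004, -0.564] p=2.92e-12 significant  (true theta -0.8)
IL-16    -0.785 [-1.026, -0.545] p=1.63e-10 significant  (true theta -0.8)
```

Both planted effects are recovered as Bonferroni-significant with
estimates near −0.8 and none of the 40 null outcomes crosses the
family-wise threshold. `results_frame(rows)` gives the long outcome ×
method table (IVW, medians, Egger slope/intercept, PRESSO) and
`export_forest(rows, path)` writes the forest-plot data with the
green/blue/red classification colours.

The same pipeline runs from the shell on real summary-statistics files:

```bash
mr-screen simulate --seed 7 --out sim/            # or bring your own TSVs
mr-screen run --exposure sim/exposure.tsv --outcomes sim/outcomes \
              --seed 7 --out results/
```

`mr-screen run` selects genome-wide-significant variants (p < 5 × 10⁻⁸),
optionally prunes them against a user-supplied LD r² matrix (r² < 0.3),
harmonises each outcome onto the exposure's effect alleles (palindromic
variants retained under a forward-strand assumption and flagged), runs
every estimator and writes `results.tsv`, `forest.csv` and
`instrument_qc.tsv` (per-SNP F statistics and variance explained).

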