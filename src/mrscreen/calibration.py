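"""Simulation experiments that characterise the estimator suite.

These are the package's standing statistical checks — type-I error and
heterogeneity calibration of the IVW test, parameter recovery, Egger
intercept recovery under directional pleiotropy, MR-PRESSO power and
calibration, and end-to-end screen recovery — each run against the
synthetic generator with known ground truth.  They back both the test
suite and the reproduction script, so the conditions are defined once.

Problem sizes reflect the motivating study design (a four-SNP cis
instrument, n_x = 25,314 / n_y = 8,293, a 42-outcome panel).  Where a
check needs many variants to be meaningful (MR-Egger's intercept,
MR-PRESSO, which has limited power at its J = 4 minimum), a larger
instrument with proportionally scaled variance explained is used; the
strong-instrument conditions use a total R^2 giving per-SNP F ~ 50.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .estimators import egger, ivw, wald_ratios
from .presso import presso
from .screening import ScreenConfig, run_screen
from .simulate import SimulationConfig, simulate_pair, simulate_panel
from .summary_io import harmonise


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def ivw_wls_identity_gap(seed: int, n_fixtures: int = 100) -> float:
    """Max |IVW - zero-intercept WLS slope| over random instruments (exact 0)."""
    import statsmodels.api as sm

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_fixtures):
        j = int(rng.integers(2, 30))
        bx = rng.uniform(0.02, 0.2, j) * rng.choice([-1, 1], j)
        sy = rng.uniform(0.005, 0.05, j)
        by = rng.uniform(-1, 1) * bx + rng.normal(0, sy)
        est = ivw(wald_ratios(
            pd.DataFrame(dict(beta_x=bx, se_x=0.01, beta_y=by, se_y=sy))
        ))
        slope = float(sm.WLS(by, bx, weights=sy**-2).fit().params[0])
        worst = max(worst, abs(est.estimate - slope))
    return worst


def ivw_null_rejection_rate(seed: int, n_sims: int = 2000, alpha: float = 0.05
                            ) -> tuple[float, float]:
    """Type-I error of the IVW test and mean Cochran's Q under the null.

    theta = 0, no pleiotropy, the four-SNP study-scale instrument.
    Returns (rejection rate, mean Q); under homogeneity E[Q] = J - 1 = 3.
    """
    cfg = SimulationConfig(j_snps=4, theta=0.0)
    rng = np.random.default_rng(seed)
    rej = 0
    qs = np.empty(n_sims)
    for i in range(n_sims):
        exp, out, _ = simulate_pair(cfg, rng=rng)
        est = ivw(wald_ratios(harmonise(exp, out)))
        rej += est.pval < alpha
        qs[i] = est.q
    return rej / n_sims, float(qs.mean())


def ivw_recovery_mean(seed: int, n_sims: int = 1000, theta: float = 0.5,
                      j_snps: int = 50, target_r2: float = 0.10) -> float:
    """Mean IVW estimate under a strong many-SNP instrument (per-SNP F ~ 50)."""
    cfg = SimulationConfig(j_snps=j_snps, theta=theta, target_r2=target_r2)
    rng = np.random.default_rng(seed)
    ests = np.empty(n_sims)
    for i in range(n_sims):
        exp, out, _ = simulate_pair(cfg, rng=rng)
        ests[i] = ivw(wald_ratios(harmonise(exp, out))).estimate
    return float(ests.mean())


def egger_intercept_recovery(seed: int, n_sims: int = 1000, mu_alpha: float = 0.05,
                             tau: float = 0.02, j_snps: int = 50,
                             target_r2: float = 0.10) -> tuple[float, float]:
    """(mean Egger intercept, Monte-Carlo SE of that mean) under directional
    pleiotropy with InSIDE satisfied; theta = 0 so the intercept isolates the
    average direct effect without slope-dilution leakage."""
    cfg = SimulationConfig(j_snps=j_snps, theta=0.0, target_r2=target_r2,
                           pleiotropy="directional", plei_mean=mu_alpha,
                           plei_sd=tau)
    rng = np.random.default_rng(seed)
    ints = np.empty(n_sims)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_sims):
            exp, out, _ = simulate_pair(cfg, rng=rng)
            ints[i] = egger(harmonise(exp, out))[1].estimate
    return float(ints.mean()), float(ints.std(ddof=1) / np.sqrt(n_sims))


_PRESSO_CFG = dict(j_snps=20, theta=0.5, target_r2=0.048, scramble_alleles=False)


def presso_outlier_power(seed: int, n_instruments: int = 200,
                         magnitude: float = 10.0, n_sim: int = 1000) -> float:
    """Fraction of instruments in which a variant with an injected pleiotropic
    shift of ``magnitude`` x se_y lands in the outlier set."""
    cfg = SimulationConfig(**_PRESSO_CFG)
    rng = np.random.default_rng(seed)
    hits = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_instruments):
            exp, out, _ = simulate_pair(cfg, rng=rng)
            h = harmonise(exp, out)
            k = int(rng.integers(cfg.j_snps))
            h.table.loc[k, "beta_y"] += magnitude * h.table.loc[k, "se_y"]
            res = presso(h, n_sim=n_sim, seed=int(rng.integers(2**31)))
            hits += h.table.loc[k, "rsid"] in res.outlier_set
    return hits / n_instruments


def presso_null_rate(seed: int, n_instruments: int = 500, alpha: float = 0.05,
                     n_sim: int = 1000) -> float:
    """Fraction of pleiotropy-free instruments with global p below ``alpha``;
    calibrated behaviour puts this near alpha."""
    cfg = SimulationConfig(**_PRESSO_CFG)
    rng = np.random.default_rng(seed)
    low = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_instruments):
            exp, out, _ = simulate_pair(cfg, rng=rng)
            res = presso(harmonise(exp, out), n_sim=n_sim,
                         seed=int(rng.integers(2**31)))
            low += res.global_pval < alpha
    return low / n_instruments


def screen_recovery(seed: int, theta: float = -0.8, n_causal: int = 2,
                    n_outcomes: int = 42) -> dict:
    """End-to-end 42-outcome screen against a panel with known causal effects.

    Returns the counts of true causal outcomes recovered as
    Bonferroni-significant, of false significant outcomes, and the
    classification tallies.
    """
    sim_seed, screen_seed = _child_seeds(seed, 2)
    cfg = SimulationConfig(n_outcomes=n_outcomes, n_causal=n_causal,
                           theta=theta, seed=sim_seed)
    exposure, outcomes, truth = simulate_panel(cfg)
    causal = set(
        truth.loc[truth.theta != 0, "outcome_name"].unique()
    )
    rows = run_screen(
        exposure, outcomes,
        ScreenConfig(seed=screen_seed, m=n_outcomes),
    )
    sig = {r.outcome_name for r in rows if r.classification == "significant"}
    tallies = {}
    for r in rows:
        tallies[r.classification] = tallies.get(r.classification, 0) + 1
    return dict(
        true_positives=len(sig & causal),
        false_positives=len(sig - causal),
        n_causal=len(causal),
        tallies=tallies,
        rows=rows,
    )
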