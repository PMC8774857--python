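"""Synthetic two-sample GWAS summary statistics with known ground truth.

Emulates the design of a cis-instrument cytokine screen: a small set of
uncorrelated SNPs at one locus instruments a standardised exposure measured
in one GWAS (default n = 25,314), and each of a panel of standardised
outcomes (default 42 cytokines, n = 8,293) is measured in a second,
non-overlapping GWAS.  For standardised traits the sampling SE of a
per-allele effect depends only on allele frequency and sample size,
se_j = 1/sqrt(2 maf_j (1 - maf_j) n); true SNP-exposure effects gamma_j
are scaled so the instrument explains a chosen total R^2, and SNP-outcome
effects are theta * gamma_j plus an optional pleiotropic term alpha_j:

* ``none`` — exclusion restriction holds by construction;
* ``balanced`` — alpha_j ~ Normal(0, tau^2), zero on average;
* ``directional`` — alpha_j ~ Normal(mu, tau^2), biasing IVW but leaving
  the Egger intercept to recover mu under InSIDE;
* ``inside_violated`` — alpha_j correlated (rho) with gamma_j, the precise
  condition that breaks MR-Egger.

Outcome files can optionally scramble allele coding (swap and/or strand
complement) to exercise harmonisation; the truth record stores gamma,
alpha and theta so every estimator's bias can be scored directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError
from .summary_io import SummaryDataset

#: The 42-cytokine/chemokine/growth-factor panel used for outcome naming.
CYTOKINE_PANEL = (
    "B-NGF", "CTACK", "Eotaxin", "FGF2", "G-CSF", "GROa", "HGF", "IFN-G",
    "IL-1B", "IL-1RA", "IL-2", "IL-2RA", "IL-4", "IL-5", "IL-6", "IL-7",
    "IL-8", "IL-9", "IL-10", "IL-12-P70", "IL-13", "IL-16", "IL-17",
    "IL-18", "IP-10", "M-CSF", "MCP-1-MCAF", "MCP-3", "MIF", "MIG",
    "MIP-1A", "MIP-1B", "PDGF-BB", "RANTES", "SCF", "SCGF-B", "SDF-1A",
    "TNF-A", "TNF-B", "TRAIL", "VEGF", "CRP",
)

_NONPALINDROMIC_PAIRS = (
    ("A", "C"), ("A", "G"), ("C", "A"), ("G", "A"),
    ("C", "T"), ("G", "T"), ("T", "C"), ("T", "G"),
)
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SimulationConfig:
    """Generative parameters for a synthetic two-sample MR dataset.

    Defaults mirror the motivating study design: a four-SNP cis instrument
    explaining ~0.95% of a standardised exposure in a 25,314-sample GWAS,
    against 42 standardised outcomes from an 8,293-sample GWAS.
    """

    j_snps: int = 4
    theta: float = 0.0                      # SD outcome per SD exposure
    n_x: int = 25314
    n_y: int = 8293
    maf_range: tuple[float, float] = (0.1, 0.5)
    target_r2: float = 0.00954              # instrument variance explained
    pleiotropy: str = "none"                # none|balanced|directional|inside_violated
    plei_mean: float = 0.0                  # mu_alpha (directional)
    plei_sd: float = 0.0                    # tau
    plei_rho: float = 0.0                   # corr(alpha, gamma) (inside_violated)
    n_outcomes: int = 42
    n_causal: int = 0
    scramble_alleles: bool = True
    seed: int | None = None

    def validate(self) -> None:
        if self.j_snps < 1:
            raise ConfigurationError("j_snps must be >= 1")
        if not (0.0 < self.target_r2 < 1.0):
            raise ConfigurationError("target_r2 must be in (0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if self.pleiotropy not in {"none", "balanced", "directional", "inside_violated"}:
            raise ConfigurationError(f"unknown pleiotropy model {self.pleiotropy!r}")
        if self.plei_sd < 0:
            raise ConfigurationError("plei_sd must be >= 0")
        if abs(self.plei_rho) > 1:
            raise ConfigurationError("plei_rho must be in [-1, 1]")
        if not (0 <= self.n_causal <= self.n_outcomes):
            raise ConfigurationError("n_causal must be in [0, n_outcomes]")
        if min(self.n_x, self.n_y) < 3:
            raise ConfigurationError("sample sizes must be >= 3")
        # Per-SNP r2 cannot exceed 1 even before noise; generous feasibility check.
        if self.target_r2 / self.j_snps >= 2 * lo * (1 - lo):
            raise ConfigurationError(
                "target_r2 infeasible for the given j_snps and maf_range"
            )


def _standard_se(maf: np.ndarray, n: int) -> np.ndarray:
    """Sampling SE of a per-allele effect on a standardised trait."""
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def _draw_alpha(cfg: SimulationConfig, gamma: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    j = len(gamma)
    if cfg.pleiotropy == "none":
        return np.zeros(j)
    if cfg.pleiotropy == "balanced":
        return rng.normal(0.0, cfg.plei_sd, j)
    if cfg.pleiotropy == "directional":
        return rng.normal(cfg.plei_mean, cfg.plei_sd, j)
    # inside_violated: alpha correlated with gamma
    z = (gamma - gamma.mean()) / (gamma.std() if gamma.std() > 0 else 1.0)
    eps = rng.standard_normal(j)
    return cfg.plei_mean + cfg.plei_sd * (
        cfg.plei_rho * z + np.sqrt(1.0 - cfg.plei_rho**2) * eps
    )


def _assign_alleles(j: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    idx = rng.integers(0, len(_NONPALINDROMIC_PAIRS), j)
    ea = np.array([_NONPALINDROMIC_PAIRS[i][0] for i in idx])
    oa = np.array([_NONPALINDROMIC_PAIRS[i][1] for i in idx])
    return ea, oa


def _instrument_truth(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-SNP MAFs, alleles and true exposure effects for one instrument."""
    j = cfg.j_snps
    maf = rng.uniform(*cfg.maf_range, j)
    # Effect alleles are taken as the exposure-increasing alleles (the
    # reporting convention for cis instruments), so true gamma_j >= 0 and
    # "directional" pleiotropy has a well-defined orientation.  Magnitudes
    # are uniform on [0.5, 1.5] x scale: selected instruments are genome-wide
    # significant, so their effects are heterogeneous but bounded away from 0.
    raw = rng.uniform(0.5, 1.5, j)
    het = 2.0 * maf * (1.0 - maf)
    scale = np.sqrt(cfg.target_r2 / np.sum(het * raw**2))
    gamma = raw * scale
    ea, oa = _assign_alleles(j, rng)
    return pd.DataFrame(
        {
            "rsid": [f"rs{100000 + i}" for i in range(j)],
            "chrom": "14",
            "pos": 94_300_000 + 5_000 * np.arange(j),
            "effect_allele": ea,
            "other_allele": oa,
            "maf": maf,
            "gamma": gamma,
        }
    )


def _exposure_dataset(truth: pd.DataFrame, cfg: SimulationConfig,
                      rng: np.random.Generator) -> SummaryDataset:
    se_x = _standard_se(truth["maf"].to_numpy(), cfg.n_x)
    beta_x = rng.normal(truth["gamma"].to_numpy(), se_x)
    df = truth[["rsid", "chrom", "pos", "effect_allele", "other_allele"]].copy()
    df["eaf"] = truth["maf"]
    df["beta"] = beta_x
    df["se"] = se_x
    df["pval"] = _two_sided_p(beta_x, se_x)
    df["n"] = cfg.n_x
    return SummaryDataset("exposure", df)


def _outcome_dataset(truth: pd.DataFrame, theta: float, alpha: np.ndarray,
                     cfg: SimulationConfig, rng: np.random.Generator,
                     name: str) -> SummaryDataset:
    maf = truth["maf"].to_numpy()
    se_y = _standard_se(maf, cfg.n_y)
    mean = theta * truth["gamma"].to_numpy() + alpha
    beta_y = rng.normal(mean, se_y)
    ea = truth["effect_allele"].to_numpy().copy()
    oa = truth["other_allele"].to_numpy().copy()
    eaf = maf.copy()
    if cfg.scramble_alleles:
        swap = rng.random(len(ea)) < 0.5
        comp = rng.random(len(ea)) < 0.5
        ea2 = np.where(swap, oa, ea)
        oa2 = np.where(swap, ea, oa)
        beta_y = np.where(swap, -beta_y, beta_y)
        eaf = np.where(swap, 1.0 - eaf, eaf)
        ea = np.array([_COMPLEMENT[a] if c else a for a, c in zip(ea2, comp)])
        oa = np.array([_COMPLEMENT[a] if c else a for a, c in zip(oa2, comp)])
    df = pd.DataFrame(
        {
            "rsid": truth["rsid"],
            "chrom": truth["chrom"],
            "pos": truth["pos"],
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta_y,
            "se": se_y,
            "pval": _two_sided_p(beta_y, se_y),
            "n": cfg.n_y,
        }
    )
    return SummaryDataset(name, df)


def simulate_pair(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    outcome_name: str = "outcome",
) -> tuple[SummaryDataset, SummaryDataset, pd.DataFrame]:
    """One exposure dataset, one outcome dataset, and the truth record.

    The truth record holds per-SNP maf, gamma (true SNP-exposure effect),
    alpha (pleiotropic effect) and the causal effect theta, sufficient to
    score any estimator without re-deriving the generator.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    truth = _instrument_truth(cfg, rng)
    exposure = _exposure_dataset(truth, cfg, rng)
    alpha = _draw_alpha(cfg, truth["gamma"].to_numpy(), rng)
    outcome = _outcome_dataset(truth, cfg.theta, alpha, cfg, rng, outcome_name)
    truth = truth.assign(alpha=alpha, theta=cfg.theta)
    return exposure, outcome, truth


def simulate_panel(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[SummaryDataset, list[SummaryDataset], pd.DataFrame]:
    """One shared exposure against a panel of outcomes, n_causal with effect.

    Outcome names cycle through the cytokine panel; which outcomes carry
    the causal effect is drawn at random.  The truth table has one row per
    (outcome, SNP) with the outcome's theta and per-SNP alpha.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    instrument = _instrument_truth(cfg, rng)
    exposure = _exposure_dataset(instrument, cfg, rng)

    names = [
        CYTOKINE_PANEL[i % len(CYTOKINE_PANEL)]
        + ("" if i < len(CYTOKINE_PANEL) else f"-{i // len(CYTOKINE_PANEL) + 1}")
        for i in range(cfg.n_outcomes)
    ]
    causal_idx = set(rng.choice(cfg.n_outcomes, size=cfg.n_causal, replace=False).tolist())
    outcomes, truth_rows = [], []
    for i, name in enumerate(names):
        theta_i = cfg.theta if i in causal_idx else 0.0
        alpha = _draw_alpha(cfg, instrument["gamma"].to_numpy(), rng)
        outcomes.append(_outcome_dataset(instrument, theta_i, alpha, cfg, rng, name))
        truth_rows.append(
            instrument.assign(alpha=alpha, theta=theta_i, outcome_name=name)
        )
    truth = pd.concat(truth_rows, ignore_index=True)
    return exposure, outcomes, truth


def write_panel(exposure: SummaryDataset, outcomes: list[SummaryDataset],
                truth: pd.DataFrame, out_dir) -> None:
    """Write a simulated panel as the TSV dialect ``summary_io`` reads."""
    import pathlib

    out = pathlib.Path(out_dir)
    (out / "outcomes").mkdir(parents=True, exist_ok=True)
    exposure.table.to_csv(out / "exposure.tsv", sep="\t", index=False)
    for ds in outcomes:
        ds.table.to_csv(out / "outcomes" / f"{ds.trait_name}.tsv", sep="\t", index=False)
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
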