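"""Multi-outcome MR screen: harmonise, estimate, test, classify, export.

One exposure instrument is screened against a panel of outcomes.  Each
outcome gets the full estimator suite (IVW primary; simple/weighted median,
MR-Egger and MR-PRESSO as pleiotropy-robust sensitivity analyses) and a
Bonferroni trichotomy on the IVW p-value:

* ``significant``  — p < alpha/m (family-wise significant; forest green);
* ``suggestive``   — alpha/m <= p < alpha (blue);
* ``non_significant`` — p >= alpha (red).

Randomness (median bootstraps, PRESSO simulations) is derived
deterministically from (master seed, outcome name), so adding or removing
an outcome never perturbs another outcome's draws and the screen is
order-invariant and bitwise reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .estimators import (
    EggerRegression,
    MREstimate,
    SimpleMedianEstimator,
    WeightedMedianEstimator,
    ivw,
    wald_ratios,
)
from .exceptions import ConfigurationError, EmptyInstrumentError, MRScreenError
from .instrument_qc import DEFAULT_LD_R2, GENOME_WIDE_P
from .presso import MRPresso, PressoResult
from .summary_io import HarmonisedInstrument, SummaryDataset, harmonise

CLASSIFICATION_COLOURS = {
    "significant": "green",
    "suggestive": "blue",
    "non_significant": "red",
    "no_overlap": "grey",
}


@dataclass
class ScreenConfig:
    """Screen-wide settings; ``seed`` is required for reproducibility."""

    seed: int
    alpha: float = 0.05
    m: int | None = None                 # Bonferroni denominator; default = panel size
    p_threshold: float = GENOME_WIDE_P
    r2_threshold: float = DEFAULT_LD_R2
    n_boot: int = 1000
    presso_n_sim: int = 1000
    presso_outlier_alpha: float = 0.05
    column_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.m is not None and self.m < 1:
            raise ConfigurationError("m must be >= 1")
        if self.seed is None:
            raise ConfigurationError("an explicit integer seed is required")

    @classmethod
    def from_yaml(cls, path) -> "ScreenConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)


@dataclass
class ScreenRow:
    """One outcome's results across methods plus its Bonferroni class."""

    outcome_name: str
    n_snps: int
    status: str                              # "ok" or "no_overlap"
    estimates: dict[str, MREstimate] = field(default_factory=dict)
    presso: PressoResult | None = None
    method_notes: dict[str, str] = field(default_factory=dict)
    classification: str = "no_overlap"

    @property
    def ivw(self) -> MREstimate | None:
        return self.estimates.get("IVW-MRE")


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise p-value threshold alpha/m (0.05/42 -> 0.00119)."""
    if m < 1:
        raise ConfigurationError("m must be >= 1")
    return alpha / m


def classify(ivw_pval: float, alpha: float, m: int) -> str:
    cut = bonferroni_threshold(alpha, m)
    if ivw_pval < cut:
        return "significant"
    if ivw_pval < alpha:
        return "suggestive"
    return "non_significant"


def _outcome_seed_seq(master_seed: int, outcome_name: str) -> np.random.SeedSequence:
    """Deterministic per-outcome entropy from the master seed and name."""
    return np.random.SeedSequence([int(master_seed), zlib.crc32(outcome_name.encode())])


def screen_one(
    instrument: SummaryDataset,
    outcome: SummaryDataset,
    cfg: ScreenConfig,
) -> ScreenRow:
    """Harmonise one outcome against the instrument and run every method."""
    try:
        h = harmonise(instrument, outcome)
    except EmptyInstrumentError:
        return ScreenRow(outcome.trait_name, 0, status="no_overlap")

    ss = _outcome_seed_seq(cfg.seed, outcome.trait_name)
    seed_simple, seed_weighted, seed_presso = ss.spawn(3)

    row = ScreenRow(outcome.trait_name, h.n_snps, status="ok")
    ratios = wald_ratios(h)
    est_ivw = ivw(ratios)
    row.estimates["IVW-MRE"] = est_ivw

    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        row.estimates["simple-median"] = (
            SimpleMedianEstimator(n_boot=cfg.n_boot, random_state=seed_simple)
            .fit(h).results_
        )
        row.estimates["weighted-median"] = (
            WeightedMedianEstimator(n_boot=cfg.n_boot, random_state=seed_weighted)
            .fit(h).results_
        )
        if h.n_snps >= 3:
            eg = EggerRegression().fit(h)
            row.estimates["Egger-slope"] = eg.slope_
            row.estimates["Egger-intercept"] = eg.intercept_
        else:
            row.method_notes["Egger"] = f"needs >= 3 variants, have {h.n_snps}"
        if h.n_snps >= 4:
            row.presso = (
                MRPresso(
                    n_sim=cfg.presso_n_sim,
                    outlier_alpha=cfg.presso_outlier_alpha,
                    random_state=seed_presso,
                )
                .fit(h).results_
            )
            if row.presso.corrected is not None:
                row.estimates["PRESSO-corrected"] = row.presso.corrected
        else:
            row.method_notes["PRESSO"] = f"needs >= 4 variants, have {h.n_snps}"

    m = cfg.m if cfg.m is not None else 1
    row.classification = classify(est_ivw.pval, cfg.alpha, m)
    return row


def run_screen(
    exposure: SummaryDataset,
    outcomes: list[SummaryDataset],
    cfg: ScreenConfig,
) -> list[ScreenRow]:
    """Screen every outcome against the exposure instrument.

    The exposure is assumed already selected/pruned (see
    :mod:`mrscreen.instrument_qc`); the Bonferroni denominator defaults to
    the number of outcomes supplied but is overridable via ``cfg.m``.
    An outcome sharing no variants yields a ``no_overlap`` row rather than
    aborting the screen.
    """
    if not outcomes:
        raise ConfigurationError("no outcomes supplied")
    m = cfg.m if cfg.m is not None else len(outcomes)
    rows = []
    for outcome in outcomes:
        row = screen_one(exposure, outcome, cfg)
        if row.status == "ok":
            row.classification = classify(row.ivw.pval, cfg.alpha, m)
        rows.append(row)
    return rows


def results_frame(rows: list[ScreenRow]) -> pd.DataFrame:
    """Long-format results: one line per outcome x method."""
    recs = []
    for row in rows:
        if row.status != "ok":
            recs.append(
                dict(outcome=row.outcome_name, method=None, estimate=np.nan,
                     se=np.nan, ci_low=np.nan, ci_high=np.nan, pval=np.nan,
                     n_snps=0, q=np.nan, q_pval=np.nan, phi=np.nan,
                     presso_global_pval=np.nan, status=row.status,
                     classification=row.classification)
            )
            continue
        gp = row.presso.global_pval if row.presso is not None else np.nan
        for method, est in row.estimates.items():
            recs.append(
                dict(outcome=row.outcome_name, method=method,
                     estimate=est.estimate, se=est.se, ci_low=est.ci_low,
                     ci_high=est.ci_high, pval=est.pval, n_snps=est.n_snps,
                     q=est.q if est.q is not None else np.nan,
                     q_pval=est.q_pval if est.q_pval is not None else np.nan,
                     phi=est.phi if est.phi is not None else np.nan,
                     presso_global_pval=gp, status=row.status,
                     classification=row.classification)
            )
    return pd.DataFrame(recs)


def export_forest(rows: list[ScreenRow], path) -> None:
    """Forest-plot-ready CSV: IVW estimate, 95% CI and colour per outcome.

    Rows keep the input panel order; the colour key follows the screen's
    legend (significant = green, suggestive = blue, non-significant = red).
    """
    if not rows:
        raise MRScreenError("no screen rows to export")
    recs = []
    for row in rows:
        est = row.ivw
        recs.append(
            dict(
                outcome=row.outcome_name,
                estimate=est.estimate if est else np.nan,
                ci_low=est.ci_low if est else np.nan,
                ci_high=est.ci_high if est else np.nan,
                classification=row.classification,
                colour=CLASSIFICATION_COLOURS[row.classification],
            )
        )
    pd.DataFrame(recs).to_csv(path, index=False)


def write_screen_outputs(rows: list[ScreenRow], out_dir) -> None:
    """Write results.tsv and forest.csv under ``out_dir``."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results_frame(rows).to_csv(out / "results.tsv", sep="\t", index=False)
    export_forest(rows, out / "forest.csv")
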