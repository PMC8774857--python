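"""Two-sample MR estimators over harmonised per-variant summary statistics.

Each variant j contributes a Wald ratio theta_j = beta_Yj / beta_Xj with a
first-order delta-method standard error se_Yj / |beta_Xj| (exposure
uncertainty ignored at first order).  The pooled estimators implemented
here are:

* inverse-variance weighted (IVW) with multiplicative random effects —
  algebraically the slope of a zero-intercept weighted regression of
  beta_Y on beta_X with weights se_Y^-2;
* simple and weighted medians, consistent when at least half the variants
  (half the weight) are valid instruments, with parametric-bootstrap SEs;
* MR-Egger weighted regression with an unconstrained intercept, whose
  intercept estimates the average directional pleiotropic effect under the
  InSIDE assumption;
* Cochran's Q heterogeneity statistic for the IVW model.

Estimators follow the scikit-learn protocol: construct with hyperparameters,
``fit(X)`` on a harmonised instrument (a :class:`HarmonisedInstrument`, a
DataFrame with beta_x/se_x/beta_y/se_y columns, or an (J, 4) array in that
column order), then read trailing-underscore attributes or ``results_``.
Thin module-level functions mirror each estimator for pipeline use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .exceptions import (
    ConfigurationError,
    DegenerateInstrumentError,
    InsufficientVariantsError,
    SingularFitError,
)
from .summary_io import HarmonisedInstrument

#: 97.5% standard-normal quantile at print precision, fixed for reproducibility.
Z975 = 1.959964

_INSTRUMENT_COLS = ("beta_x", "se_x", "beta_y", "se_y")


@dataclass
class MREstimate:
    """A pooled causal estimate with its uncertainty and heterogeneity stats.

    ``estimate`` is in SD units of the outcome per SD of the exposure.
    ``q``/``q_pval``/``phi`` are present only for methods with a
    heterogeneity model (IVW, Egger); ``phi`` is the multiplicative
    overdispersion factor, floored at 1.
    """

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    q: float | None = None
    q_pval: float | None = None
    phi: float | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("confidence interval must bracket the estimate")


def _coerce_instrument(X) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Extract (beta_x, se_x, beta_y, se_y, rsids) from any accepted input."""
    if isinstance(X, HarmonisedInstrument):
        df = X.table
    elif isinstance(X, pd.DataFrame):
        df = X
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 4:
            raise ConfigurationError(
                "array input must have shape (J, 4): beta_x, se_x, beta_y, se_y"
            )
        df = pd.DataFrame(arr, columns=list(_INSTRUMENT_COLS))
    missing = [c for c in _INSTRUMENT_COLS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"instrument input missing columns: {missing}")
    rsids = (
        df["rsid"].astype(str).to_numpy()
        if "rsid" in df.columns
        else np.array([f"snp{i}" for i in range(len(df))])
    )
    bx = df["beta_x"].to_numpy(dtype=float)
    sx = df["se_x"].to_numpy(dtype=float)
    by = df["beta_y"].to_numpy(dtype=float)
    sy = df["se_y"].to_numpy(dtype=float)
    if len(bx) == 0:
        raise InsufficientVariantsError("instrument has no variants")
    if np.any(sx <= 0) or np.any(sy <= 0):
        raise ConfigurationError("standard errors must be positive")
    return bx, sx, by, sy, rsids


def wald_ratios(h, second_order: bool = False) -> pd.DataFrame:
    """Per-variant Wald ratios with delta-method SEs.

    Returns a DataFrame with columns rsid, theta, se_theta, weight
    (weight = se_theta^-2).  The default first-order SE ignores exposure
    uncertainty; ``second_order=True`` adds the beta_x sampling term for
    sensitivity analyses.
    """
    bx, sx, by, sy, rsids = _coerce_instrument(h)
    zero = bx == 0
    if zero.any():
        raise DegenerateInstrumentError(
            f"zero SNP-exposure effect for {', '.join(rsids[zero])}"
        )
    theta = by / bx
    se = sy / np.abs(bx)
    if second_order:
        se = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    return pd.DataFrame(
        {"rsid": rsids, "theta": theta, "se_theta": se, "weight": se**-2}
    )


def _normal_ci_p(estimate: float, se: float) -> tuple[float, float, float]:
    ci_low = estimate - Z975 * se
    ci_high = estimate + Z975 * se
    pval = 2.0 * stats.norm.sf(abs(estimate) / se) if se > 0 else (1.0 if estimate == 0 else 0.0)
    return ci_low, ci_high, max(pval, np.finfo(float).tiny)


def _ivw_core(theta: np.ndarray, se_theta: np.ndarray) -> MREstimate:
    w = se_theta**-2.0
    j = len(theta)
    est = float(np.sum(w * theta) / np.sum(w))
    if j >= 2:
        q = float(np.sum(w * (theta - est) ** 2))
        q_pval = float(stats.chi2.sf(q, j - 1))
        phi = max(1.0, q / (j - 1))
    else:
        q = q_pval = None
        phi = 1.0
    se = float(np.sqrt(phi / np.sum(w)))
    ci_low, ci_high, pval = _normal_ci_p(est, se)
    return MREstimate(
        method="IVW-MRE", estimate=est, se=se, ci_low=ci_low, ci_high=ci_high,
        pval=pval, n_snps=j, q=q, q_pval=q_pval, phi=phi,
    )


class IVWEstimator(BaseEstimator):
    """Multiplicative random-effects inverse-variance weighted estimator.

    The pooled estimate is the precision-weighted mean of the Wald ratios,
    identically the zero-intercept WLS slope of beta_Y on beta_X with
    weights se_Y^-2.  Heterogeneity beyond chance inflates the fixed-effect
    SE by sqrt(phi) with phi = max(1, Q/(J-1)); the floor at 1 prevents
    anti-conservative SEs when the variants are more homogeneous than
    expected.  CIs use z = 1.959964 and p-values the standard normal.
    """

    def fit(self, X, y=None):
        ratios = wald_ratios(X)
        res = _ivw_core(ratios["theta"].to_numpy(), ratios["se_theta"].to_numpy())
        self._set_result(res)
        return self

    def _set_result(self, res: MREstimate) -> None:
        self.results_ = res
        self.estimate_ = res.estimate
        self.se_ = res.se
        self.ci_low_ = res.ci_low
        self.ci_high_ = res.ci_high
        self.pval_ = res.pval
        self.n_snps_ = res.n_snps
        self.q_ = res.q
        self.q_pval_ = res.q_pval
        self.phi_ = res.phi

    def predict(self, X):
        """Predicted SNP-outcome effects theta_hat * beta_x."""
        bx = _coerce_instrument(X)[0]
        return self.estimate_ * bx


def ivw(ratios: pd.DataFrame) -> MREstimate:
    """Pool per-variant Wald ratios by multiplicative random-effects IVW."""
    if len(ratios) == 0:
        raise InsufficientVariantsError("no ratio estimates to pool")
    return _ivw_core(ratios["theta"].to_numpy(float), ratios["se_theta"].to_numpy(float))


def cochran_q(ratios: pd.DataFrame, pooled: MREstimate) -> tuple[float | None, float | None]:
    """Cochran's Q about a pooled estimate; absent (None, None) when J < 2."""
    if len(ratios) < 2:
        return None, None
    w = ratios["weight"].to_numpy(float)
    theta = ratios["theta"].to_numpy(float)
    q = float(np.sum(w * (theta - pooled.estimate) ** 2))
    return q, float(stats.chi2.sf(q, len(ratios) - 1))


def _weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median: the weighted CDF of ordered ratios at 0.5."""
    order = np.argsort(theta, kind="mergesort")
    t = theta[order]
    wn = w[order] / np.sum(w)
    s = np.cumsum(wn) - wn / 2.0
    return float(np.interp(0.5, s, t))


def _median_bootstrap_se(
    theta: np.ndarray, se_theta: np.ndarray, weighted: bool,
    n_boot: int, rng: np.random.Generator,
) -> float:
    draws = rng.normal(theta, se_theta, size=(n_boot, len(theta)))
    if weighted:
        w = se_theta**-2.0
        meds = np.array([_weighted_median(d, w) for d in draws])
    else:
        meds = np.median(draws, axis=1)
    return float(np.std(meds, ddof=1))


class _MedianBase(BaseEstimator):
    _weighted = False
    _method = ""

    def __init__(self, n_boot: int = 1000, random_state=None):
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, X, y=None):
        if self.n_boot < 2:
            raise ConfigurationError("n_boot must be at least 2")
        ratios = wald_ratios(X)
        theta = ratios["theta"].to_numpy(float)
        se_theta = ratios["se_theta"].to_numpy(float)
        if len(theta) < 3:
            warnings.warn(
                f"{self._method}: fewer than 3 variants; estimate unreliable",
                stacklevel=2,
            )
        est = (
            _weighted_median(theta, se_theta**-2.0)
            if self._weighted
            else float(np.median(theta))
        )
        rng = np.random.default_rng(self.random_state)
        se = _median_bootstrap_se(theta, se_theta, self._weighted, self.n_boot, rng)
        ci_low, ci_high, pval = _normal_ci_p(est, se)
        res = MREstimate(
            method=self._method, estimate=est, se=se, ci_low=ci_low,
            ci_high=ci_high, pval=pval, n_snps=len(theta),
        )
        self.results_ = res
        self.estimate_, self.se_ = res.estimate, res.se
        self.ci_low_, self.ci_high_ = res.ci_low, res.ci_high
        self.pval_, self.n_snps_ = res.pval, res.n_snps
        return self


class SimpleMedianEstimator(_MedianBase):
    """Sample median of the Wald ratios (midpoint convention for even J).

    Consistent when at least half the variants are valid instruments.  The
    SE is the standard deviation of the median over ``n_boot`` parametric
    bootstrap replicates drawing theta*_j ~ Normal(theta_j, se_theta_j²).
    """

    _weighted = False
    _method = "simple-median"


class WeightedMedianEstimator(_MedianBase):
    """Inverse-variance weighted median of the Wald ratios.

    Ratios are ordered and the weighted CDF (cumulative midpoint weights)
    is interpolated at 0.5; consistent when valid instruments carry at
    least half the total weight.  Bootstrap SE as in the simple median,
    with weights held at their observed se_theta^-2 values.
    """

    _weighted = True
    _method = "weighted-median"


def simple_median(ratios: pd.DataFrame, n_boot: int = 1000, seed=None) -> MREstimate:
    est = SimpleMedianEstimator(n_boot=n_boot, random_state=seed)
    frame = ratios.assign(beta_x=1.0, se_x=1.0, beta_y=ratios["theta"], se_y=ratios["se_theta"])
    return est.fit(frame).results_


def weighted_median(ratios: pd.DataFrame, n_boot: int = 1000, seed=None) -> MREstimate:
    est = WeightedMedianEstimator(n_boot=n_boot, random_state=seed)
    frame = ratios.assign(beta_x=1.0, se_x=1.0, beta_y=ratios["theta"], se_y=ratios["se_theta"])
    return est.fit(frame).results_


class EggerRegression(BaseEstimator):
    """MR-Egger: weighted regression of beta_Y on beta_X with an intercept.

    Variants are first oriented so every beta_X >= 0 (negating both betas
    where needed), then beta_Y is regressed on beta_X with weights se_Y^-2.
    The slope is the causal estimate; the intercept estimates the average
    directional pleiotropic effect under InSIDE (pleiotropy independent of
    instrument strength), and its p-value is the pleiotropy test.  SEs are
    inflated by sqrt(max(1, RSS_w/(J-2))) and inference uses the t
    distribution with J-2 degrees of freedom.
    """

    def fit(self, X, y=None):
        import statsmodels.api as sm

        bx, sx, by, sy, _ = _coerce_instrument(X)
        j = len(bx)
        if j < 3:
            raise InsufficientVariantsError(
                f"MR-Egger needs at least 3 variants, got {j}"
            )
        flip = bx < 0
        bx = np.where(flip, -bx, bx)
        by = np.where(flip, -by, by)
        if np.ptp(bx) == 0:
            raise SingularFitError(
                "all SNP-exposure effects identical: intercept and slope collinear"
            )
        design = sm.add_constant(bx)
        fit = sm.WLS(by, design, weights=sy**-2.0).fit()
        phi = max(1.0, float(fit.scale))  # scale = weighted RSS / (J-2)
        se_unscaled = np.sqrt(np.diag(fit.normalized_cov_params))
        se = se_unscaled * np.sqrt(phi)
        params = fit.params
        df_resid = j - 2
        out = []
        for name, idx in (("Egger-slope", 1), ("Egger-intercept", 0)):
            est, s = float(params[idx]), float(se[idx])
            tcrit = float(stats.t.ppf(0.975, df_resid))
            if s > 0:
                pval = float(2.0 * stats.t.sf(abs(est) / s, df_resid))
            else:
                pval = 1.0 if est == 0 else np.finfo(float).tiny
            out.append(
                MREstimate(
                    method=name, estimate=est, se=s, ci_low=est - tcrit * s,
                    ci_high=est + tcrit * s, pval=max(pval, np.finfo(float).tiny),
                    n_snps=j, phi=phi,
                )
            )
        self.slope_, self.intercept_ = out
        self.results_ = tuple(out)
        self.estimate_ = self.slope_.estimate
        self.pleiotropy_pval_ = self.intercept_.pval
        self.phi_ = phi
        self.n_snps_ = j
        return self

    def predict(self, X):
        bx = _coerce_instrument(X)[0]
        return self.intercept_.estimate + self.slope_.estimate * np.abs(bx)


def egger(h) -> tuple[MREstimate, MREstimate]:
    """MR-Egger (slope, intercept) estimates for a harmonised instrument."""
    fit = EggerRegression().fit(h)
    return fit.slope_, fit.intercept_
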