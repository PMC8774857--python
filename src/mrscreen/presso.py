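"""MR-PRESSO: pleiotropy residual sum of squares and outlier detection.

The global test asks whether the observed leave-one-out residual sum of
squares (RSS) of the SNP-outcome effects about the IVW fit exceeds what
sampling noise alone would produce; the per-SNP outlier test compares each
variant's observed squared residual with its simulated distribution
(Bonferroni-adjusted over J); the distortion test asks whether removing
the flagged outliers shifts the pooled estimate more than removing random
variant sets of the same size would.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .estimators import MREstimate, _coerce_instrument, _ivw_core
from .exceptions import ConfigurationError, InsufficientVariantsError


@dataclass
class PressoResult:
    """Global, per-SNP and distortion test results.

    Monte-Carlo p-values use the add-one estimator (1 + exceedances) /
    (n_sim + 1), hence are bounded below by 1/(n_sim + 1) and never zero.
    ``corrected`` is the IVW estimate after removing ``outlier_set``; absent
    when no outliers are flagged or too few variants remain.
    """

    rss_obs: float
    global_pval: float
    outlier_pvals: pd.Series
    outlier_set: tuple[str, ...]
    corrected: MREstimate | None
    distortion_pval: float | None
    n_sim: int
    seed: object = None


def _loo_slopes(bx: np.ndarray, by: np.ndarray, wy: np.ndarray) -> np.ndarray:
    """Leave-one-out zero-intercept WLS slopes of by on bx, weights wy.

    Vectorised over the left-out index (and over a leading simulation axis
    when the inputs are 2-D).
    """
    num = np.sum(wy * bx * by, axis=-1, keepdims=True) - wy * bx * by
    den = np.sum(wy * bx * bx, axis=-1, keepdims=True) - wy * bx * bx
    return num / den


class MRPresso(BaseEstimator):
    """MR-PRESSO global, outlier and distortion tests.

    Parameters
    ----------
    n_sim : int
        Monte-Carlo replicates for the global/outlier tests (>= 100).
    outlier_alpha : float
        Threshold on the Bonferroni-adjusted per-SNP p-value.
    n_distortion : int
        Random outlier-set draws for the distortion test.
    random_state : int or numpy Generator/SeedSequence, optional
        Source of randomness; identical inputs and state give identical
        results.

    The method requires J >= 4 so that every leave-one-out fit retains at
    least 3 variants; at exactly J = 4 power is limited and a warning is
    issued rather than an error.
    """

    def __init__(self, n_sim: int = 1000, outlier_alpha: float = 0.05,
                 n_distortion: int = 1000, random_state=None):
        self.n_sim = n_sim
        self.outlier_alpha = outlier_alpha
        self.n_distortion = n_distortion
        self.random_state = random_state

    def fit(self, X, y=None):
        if self.n_sim < 100:
            raise ConfigurationError("n_sim must be at least 100")
        bx, sx, by, sy, rsids = _coerce_instrument(X)
        j = len(bx)
        if j < 4:
            raise InsufficientVariantsError(
                f"MR-PRESSO needs at least 4 variants, got {j}"
            )
        if j == 4:
            warnings.warn(
                "MR-PRESSO with exactly 4 variants has limited power",
                stacklevel=2,
            )
        rng = np.random.default_rng(self.random_state)
        wy = sy**-2.0

        theta_loo = _loo_slopes(bx, by, wy)
        resid = by - theta_loo * bx
        contrib = resid**2 * wy
        rss_obs = float(np.sum(contrib))

        # Simulated replicates under the no-pleiotropy expectation.
        bx_star = rng.normal(bx, sx, size=(self.n_sim, j))
        by_star = rng.normal(theta_loo * bx, sy, size=(self.n_sim, j))
        theta_star = _loo_slopes(bx_star, by_star, wy)
        resid_star = by_star - theta_star * bx_star
        rss_star = np.sum(resid_star**2 * wy, axis=1)

        global_pval = (1.0 + np.sum(rss_star >= rss_obs)) / (self.n_sim + 1.0)
        raw_p = (1.0 + np.sum(resid_star**2 >= resid**2, axis=0)) / (self.n_sim + 1.0)
        adj_p = np.minimum(raw_p * j, 1.0)
        outlier_pvals = pd.Series(adj_p, index=rsids, name="outlier_pval")
        outlier_mask = adj_p < self.outlier_alpha
        outlier_set = tuple(rsids[outlier_mask])

        corrected = None
        distortion_pval = None
        if outlier_mask.any():
            keep = ~outlier_mask
            if keep.sum() >= 2:
                corrected = _ivw_core(by[keep] / bx[keep], sy[keep] / np.abs(bx[keep]))
                corrected.method = "PRESSO-corrected"
                distortion_pval = self._distortion(
                    bx, by, wy, int(outlier_mask.sum()), corrected.estimate, rng
                )
            else:
                warnings.warn(
                    "MR-PRESSO flagged all but <2 variants; corrected estimate absent",
                    stacklevel=2,
                )

        self.results_ = PressoResult(
            rss_obs=rss_obs, global_pval=float(global_pval),
            outlier_pvals=outlier_pvals, outlier_set=outlier_set,
            corrected=corrected, distortion_pval=distortion_pval,
            n_sim=self.n_sim, seed=self.random_state,
        )
        self.rss_obs_ = rss_obs
        self.global_pval_ = float(global_pval)
        self.outlier_pvals_ = outlier_pvals
        self.outlier_set_ = outlier_set
        self.corrected_ = corrected
        self.distortion_pval_ = distortion_pval
        return self

    def _distortion(self, bx, by, wy, k: int, corrected_est: float,
                    rng: np.random.Generator) -> float:
        """Monte-Carlo p for the full-vs-corrected shift against random sets."""
        j = len(bx)
        full = float(np.sum(wy * bx * by) / np.sum(wy * bx * bx))
        d_obs = corrected_est - full
        diffs = np.empty(self.n_distortion)
        for b in range(self.n_distortion):
            drop = rng.choice(j, size=k, replace=False)
            keep = np.ones(j, dtype=bool)
            keep[drop] = False
            est = float(
                np.sum(wy[keep] * bx[keep] * by[keep])
                / np.sum(wy[keep] * bx[keep] * bx[keep])
            )
            diffs[b] = est - full
        return float((1.0 + np.sum(np.abs(diffs) >= abs(d_obs))) / (self.n_distortion + 1.0))


def presso(h, n_sim: int = 1000, outlier_alpha: float = 0.05, seed=None) -> PressoResult:
    """Run MR-PRESSO on a harmonised instrument; see :class:`MRPresso`."""
    return MRPresso(n_sim=n_sim, outlier_alpha=outlier_alpha, random_state=seed).fit(h).results_
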