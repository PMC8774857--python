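"""Instrument construction and strength diagnostics.

Covers genome-wide significance selection, greedy LD pruning against a
user-supplied r-squared matrix, per-variant F-statistics (beta/se)^2, and
the proportion of exposure variance explained.  The conventional rule of
thumb is that a mean F above 10 indicates a strong instrument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, EmptyInstrumentError
from .summary_io import SummaryDataset

GENOME_WIDE_P = 5e-8
DEFAULT_LD_R2 = 0.3


@dataclass
class InstrumentDiagnostics:
    """Per-variant and aggregate instrument-strength measures.

    ``per_variant`` columns: rsid, f_stat, r2.  ``total_r2`` is the sum of
    per-variant r2 values, valid for mutually uncorrelated variants;
    ``total_r2_percent`` is the same quantity on the percent scale (GWAS
    reports are ambiguous between the two, so both are exposed).
    """

    per_variant: pd.DataFrame
    mean_f: float
    total_r2: float
    n_snps: int

    @property
    def total_r2_percent(self) -> float:
        return 100.0 * self.total_r2

    def to_tsv(self, path) -> None:
        self.per_variant.to_csv(path, sep="\t", index=False)


def select_instruments(
    exposure: SummaryDataset,
    p_threshold: float = GENOME_WIDE_P,
    region: tuple[str, int, int] | None = None,
) -> SummaryDataset:
    """Retain variants with p < ``p_threshold``, optionally inside a region.

    ``region`` is (chrom, start, end), 1-based inclusive — e.g. a window of
    1000 kB around a cis locus.
    """
    df = exposure.table
    keep = df["pval"] < p_threshold
    if region is not None:
        chrom, start, end = region
        keep &= (
            df["chrom"].astype(str) == str(chrom)
        ) & (df["pos"] >= start) & (df["pos"] <= end)
    out = df.loc[keep].reset_index(drop=True)
    if out.empty:
        raise EmptyInstrumentError(
            f"{exposure.trait_name}: no variants pass p < {p_threshold:g}"
            + (f" within {region}" if region else "")
        )
    return SummaryDataset(exposure.trait_name, out, exposure.trait_unit)


def ld_prune(
    candidates: SummaryDataset,
    ld: pd.DataFrame,
    r2_threshold: float = DEFAULT_LD_R2,
) -> SummaryDataset:
    """Greedy LD pruning emulating standard clumping semantics.

    Candidates are ranked by ascending p-value (ties broken by rsid); the
    best remaining variant is kept and every other remaining variant with
    r² >= ``r2_threshold`` against it is discarded, until none remain.  The
    survivors are mutually uncorrelated below the threshold, and the result
    does not depend on the input row order.

    ``ld`` must be a square symmetric r² matrix with unit diagonal, indexed
    by rsid on both axes, covering every candidate.
    """
    rsids = list(candidates.table["rsid"])
    missing = [r for r in rsids if r not in ld.index or r not in ld.columns]
    if missing:
        raise ConfigurationError(f"LD matrix missing candidate rsids: {missing}")
    sub = ld.loc[rsids, rsids].to_numpy(dtype=float)
    if sub.shape[0] != sub.shape[1] or not np.allclose(sub, sub.T, atol=1e-8):
        raise ConfigurationError("LD matrix must be square and symmetric")
    if not np.allclose(np.diag(sub), 1.0, atol=1e-6):
        raise ConfigurationError("LD matrix diagonal must be 1 (r² with itself)")

    order = candidates.table.assign(_i=np.arange(len(rsids))).sort_values(
        ["pval", "rsid"], kind="mergesort"
    )["_i"].to_numpy()
    alive = np.ones(len(rsids), dtype=bool)
    kept: list[int] = []
    for i in order:
        if not alive[i]:
            continue
        kept.append(i)
        alive &= sub[i] < r2_threshold
        alive[i] = False
    kept_idx = sorted(kept)  # preserve original table order
    out = candidates.table.iloc[kept_idx].reset_index(drop=True)
    return SummaryDataset(candidates.trait_name, out, candidates.trait_unit)


def read_ld_matrix(path) -> pd.DataFrame:
    """Read a square delimited r² table with an rsid header row and column."""
    return pd.read_csv(path, sep=None, engine="python", index_col=0)


def f_statistics(exposure: SummaryDataset) -> InstrumentDiagnostics:
    """Per-variant F = (beta/se)² and their arithmetic mean."""
    df = exposure.table
    f = (df["beta"] / df["se"]) ** 2
    per = pd.DataFrame({"rsid": df["rsid"], "f_stat": f, "r2": np.nan})
    return InstrumentDiagnostics(
        per_variant=per.reset_index(drop=True),
        mean_f=float(f.mean()),
        total_r2=float("nan"),
        n_snps=len(df),
    )


def variance_explained(exposure: SummaryDataset, n: int | None = None) -> InstrumentDiagnostics:
    """Proportion of exposure variance explained per variant and in total.

    For SD-unit betas with known EAF, r2_j = 2·eaf·(1−eaf)·beta².  When the
    EAF is missing the F-statistic approximation r2_j = F/(F + n − 2) is
    used, which requires the exposure GWAS sample size ``n`` (taken from the
    per-row ``n`` column when not supplied).  The total sums per-variant
    values, valid for uncorrelated variants.
    """
    df = exposure.table
    f = (df["beta"] / df["se"]) ** 2
    eaf = pd.to_numeric(df["eaf"], errors="coerce")
    r2 = 2.0 * eaf * (1.0 - eaf) * df["beta"] ** 2
    need_f = eaf.isna()
    if need_f.any():
        nn = pd.to_numeric(df["n"], errors="coerce") if n is None else pd.Series(n, index=df.index)
        if nn.loc[need_f].isna().any() or (nn.loc[need_f] <= 2).any():
            raise ConfigurationError(
                "variance_explained needs n > 2 for variants with missing eaf"
            )
        r2 = r2.where(~need_f, f / (f + nn - 2.0))
    per = pd.DataFrame({"rsid": df["rsid"], "f_stat": f, "r2": r2})
    return InstrumentDiagnostics(
        per_variant=per.reset_index(drop=True),
        mean_f=float(f.mean()),
        total_r2=float(r2.sum()),
        n_snps=len(df),
    )


def instrument_diagnostics(exposure: SummaryDataset, n: int | None = None) -> InstrumentDiagnostics:
    """F-statistics and variance explained in one pass."""
    return variance_explained(exposure, n=n)
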