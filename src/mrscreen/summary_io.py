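"""Reading, validating and harmonising GWAS summary statistics.

A two-sample MR analysis starts from two per-variant association tables —
SNP-exposure and SNP-outcome — each reporting, per rsid, the effect allele,
the other allele, the effect-allele frequency (EAF), the effect size in SD
units of the trait, its standard error, a p-value and a sample size.
Before any estimation the two tables must be *harmonised*: the outcome
effect is re-expressed per copy of the exposure's effect allele, flipping
signs (and EAF) where the reported allele coding differs, and resolving
strand flips by base complementation.  Palindromic variants (A/T or G/C),
whose strand cannot be inferred from the alleles alone, are retained under
a forward-strand assumption and flagged so users can filter post hoc.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, EmptyDatasetError, EmptyInstrumentError

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Canonical internal column names and their roles.
REQUIRED_COLUMNS = ("rsid", "effect_allele", "other_allele", "beta", "se", "pval")
OPTIONAL_COLUMNS = ("chrom", "pos", "eaf", "n")

#: Default mapping from canonical names to on-disk header names.  Any GWAS
#: export dialect can be read by overriding entries (canonical -> file header).
DEFAULT_COLUMN_MAP = {
    "rsid": "snp",
    "chrom": "chr",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
}


def _complement_allele(a: str) -> str:
    return COMPLEMENT[a]


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True for A/T and G/C variants, whose strand is ambiguous."""
    return COMPLEMENT.get(effect_allele) == other_allele


@dataclass
class SummaryDataset:
    """One trait's GWAS summary statistics, one row per variant.

    ``table`` holds the canonical columns (see :data:`REQUIRED_COLUMNS` and
    :data:`OPTIONAL_COLUMNS`); rsids are unique; every row satisfies the
    per-variant invariants (valid distinct alleles, se > 0, p in (0, 1],
    EAF in (0, 1) when present).
    """

    trait_name: str
    table: pd.DataFrame
    trait_unit: str = "SD"

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.table.columns]
        if missing:
            raise ConfigurationError(f"summary table missing columns: {missing}")
        if self.table["rsid"].duplicated().any():
            raise ConfigurationError("rsids must be unique in a SummaryDataset")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def rsids(self) -> pd.Series:
        return self.table["rsid"]

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, trait_name: str, trait_unit: str = "SD"
    ) -> "SummaryDataset":
        """Validate a raw frame, dropping (and logging) rows that violate invariants.

        Dropped categories: non-finite beta/se, se <= 0, p outside (0, 1],
        invalid or identical alleles, EAF outside (0, 1), duplicated rsid
        (first occurrence kept).
        """
        df = frame.copy()
        for col in OPTIONAL_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
        df["other_allele"] = df["other_allele"].astype(str).str.upper()

        n0 = len(df)
        bad_allele = (
            ~df["effect_allele"].isin(VALID_BASES)
            | ~df["other_allele"].isin(VALID_BASES)
            | (df["effect_allele"] == df["other_allele"])
        )
        bad_se = ~np.isfinite(df["se"]) | (df["se"] <= 0)
        bad_beta = ~np.isfinite(df["beta"])
        bad_p = ~np.isfinite(df["pval"]) | (df["pval"] <= 0) | (df["pval"] > 1)
        eaf = pd.to_numeric(df["eaf"], errors="coerce")
        bad_eaf = eaf.notna() & ((eaf <= 0) | (eaf >= 1))
        bad = bad_allele | bad_se | bad_beta | bad_p | bad_eaf
        if bad.any():
            logger.warning(
                "%s: dropped %d/%d rows failing invariants "
                "(alleles=%d, se=%d, beta=%d, pval=%d, eaf=%d)",
                trait_name, int(bad.sum()), n0, int(bad_allele.sum()),
                int(bad_se.sum()), int(bad_beta.sum()), int(bad_p.sum()),
                int(bad_eaf.sum()),
            )
        df = df.loc[~bad]

        dup = df["rsid"].duplicated(keep="first")
        if dup.any():
            logger.warning(
                "%s: dropped %d duplicated rsid(s), keeping first occurrence: %s",
                trait_name, int(dup.sum()), ", ".join(df.loc[dup, "rsid"].astype(str)),
            )
            df = df.loc[~dup]

        if df.empty:
            raise EmptyDatasetError(f"{trait_name}: no rows survive validation")
        cols = list(REQUIRED_COLUMNS) + [c for c in OPTIONAL_COLUMNS if c in df.columns]
        return cls(trait_name=trait_name, table=df[cols].reset_index(drop=True),
                   trait_unit=trait_unit)


def read_summary_table(
    path,
    column_map: dict | None = None,
    trait_name: str | None = None,
    sep: str | None = None,
) -> SummaryDataset:
    """Read a delimited GWAS summary-statistics table.

    Parameters
    ----------
    path : str or Path
        Tab- or comma-delimited text file with a header row.
    column_map : dict, optional
        Canonical-name -> file-header overrides merged onto
        :data:`DEFAULT_COLUMN_MAP`.
    trait_name : str, optional
        Defaults to the file stem.
    sep : str, optional
        Field delimiter; sniffed when omitted.
    """
    import pathlib

    path = pathlib.Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")

    rename = {}
    for canonical, header in cmap.items():
        if header in raw.columns:
            rename[header] = canonical
        elif canonical in raw.columns:
            pass  # already canonical
        elif canonical in REQUIRED_COLUMNS:
            raise ConfigurationError(
                f"{path.name}: required column {canonical!r} "
                f"(mapped to header {header!r}) not found"
            )
    df = raw.rename(columns=rename)
    return SummaryDataset.from_frame(df, trait_name=trait_name or path.stem)


def write_summary_table(dataset: SummaryDataset, path) -> None:
    """Write a dataset back to TSV in the canonical dialect."""
    dataset.table.to_csv(path, sep="\t", index=False)


@dataclass
class HarmonisedInstrument:
    """Per-SNP exposure/outcome effect pairs on a common effect allele.

    ``table`` columns: rsid, effect_allele, other_allele, beta_x, se_x,
    beta_y, se_y, eaf, eaf_x, eaf_y, was_flipped, is_palindromic.  ``eaf``
    is the exposure EAF, falling back to the harmonised outcome EAF when the
    exposure file reports none.  ``dropped`` records shared rsids excluded
    during harmonisation with a reason, so that
    shared = harmonised + dropped always holds.
    """

    exposure_name: str
    outcome_name: str
    table: pd.DataFrame
    dropped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["rsid", "reason"])
    )

    def __post_init__(self) -> None:
        if len(self.table) < 1:
            raise EmptyInstrumentError(
                f"no harmonisable variants shared between {self.exposure_name} "
                f"and {self.outcome_name}"
            )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_snps(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def harmonise(exposure: SummaryDataset, outcome: SummaryDataset) -> HarmonisedInstrument:
    """Align outcome associations to the exposure's effect alleles.

    For each shared rsid, in order of preference:

    1. identical coding — keep as-is;
    2. swapped coding (effect and other alleles interchanged) — negate the
       outcome beta and replace its EAF by 1 − EAF;
    3. coding matches after complementing the outcome alleles (strand flip)
       — keep betas;
    4. complemented and swapped — negate and flip EAF;
    5. otherwise the variant is dropped with a logged reason.

    Palindromic variants (A/T, G/C) satisfy rules 1/2 and 3/4 simultaneously;
    the same-strand rules take precedence, which is the forward-strand
    assumption.  They are retained, not excluded, and flagged
    ``is_palindromic`` for post-hoc filtering.
    """
    merged = exposure.table.merge(
        outcome.table, on="rsid", suffixes=("_x", "_y"), how="inner"
    )
    if merged.empty:
        raise EmptyInstrumentError(
            f"no shared rsids between {exposure.trait_name} and {outcome.trait_name}"
        )

    rows, dropped = [], []
    for rec in merged.itertuples(index=False):
        ea_x, oa_x = rec.effect_allele_x, rec.other_allele_x
        ea_y, oa_y = rec.effect_allele_y, rec.other_allele_y
        beta_y, eaf_y = rec.beta_y, rec.eaf_y
        flipped = False
        if (ea_y, oa_y) == (ea_x, oa_x):
            pass
        elif (ea_y, oa_y) == (oa_x, ea_x):
            flipped = True
        else:
            cea, coa = COMPLEMENT[ea_y], COMPLEMENT[oa_y]
            if (cea, coa) == (ea_x, oa_x):
                pass
            elif (cea, coa) == (oa_x, ea_x):
                flipped = True
            else:
                dropped.append((rec.rsid, f"irreconcilable alleles {ea_x}/{oa_x} vs {ea_y}/{oa_y}"))
                continue
        if flipped:
            beta_y = -beta_y
            if pd.notna(eaf_y):
                eaf_y = 1.0 - eaf_y
        eaf = rec.eaf_x if pd.notna(rec.eaf_x) else eaf_y
        rows.append(
            dict(
                rsid=rec.rsid,
                effect_allele=ea_x,
                other_allele=oa_x,
                beta_x=rec.beta_x,
                se_x=rec.se_x,
                beta_y=beta_y,
                se_y=rec.se_y,
                eaf=eaf,
                eaf_x=rec.eaf_x,
                eaf_y=eaf_y,
                was_flipped=flipped,
                is_palindromic=is_palindromic(ea_x, oa_x),
            )
        )

    for rsid, reason in dropped:
        logger.warning("harmonise %s vs %s: dropped %s (%s)",
                       exposure.trait_name, outcome.trait_name, rsid, reason)
    table = pd.DataFrame(
        rows,
        columns=["rsid", "effect_allele", "other_allele", "beta_x", "se_x",
                 "beta_y", "se_y", "eaf", "eaf_x", "eaf_y", "was_flipped",
                 "is_palindromic"],
    )
    return HarmonisedInstrument(
        exposure_name=exposure.trait_name,
        outcome_name=outcome.trait_name,
        table=table,
        dropped=pd.DataFrame(dropped, columns=["rsid", "reason"]),
    )
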