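import numpy as np
import pandas as pd
import pytest

from mrscreen.summary_io import SummaryDataset


def make_dataset(rows, name="trait"):
    """Build a SummaryDataset from a list of per-variant dicts.

    Unspecified fields default to a well-formed variant.
    """
    defaults = dict(
        chrom="14", pos=94_300_000, effect_allele="A", other_allele="G",
        eaf=0.3, beta=0.1, se=0.01, pval=1e-9, n=25314,
    )
    recs = []
    for i, row in enumerate(rows):
        rec = dict(defaults, rsid=f"rs{i}", pos=defaults["pos"] + 5000 * i)
        rec.update(row)
        recs.append(rec)
    return SummaryDataset.from_frame(pd.DataFrame(recs), trait_name=name)


@pytest.fixture
def make_summary():
    return make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_instrument(rng, j=6, theta=0.3):
    """A random harmonised-instrument frame for estimator tests."""
    bx = rng.uniform(0.03, 0.15, j) * rng.choice([-1, 1], j)
    sx = rng.uniform(0.005, 0.02, j)
    sy = rng.uniform(0.01, 0.04, j)
    by = theta * bx + rng.normal(0, sy)
    return pd.DataFrame(dict(
        rsid=[f"rs{i}" for i in range(j)], beta_x=bx, se_x=sx, beta_y=by, se_y=sy,
    ))


@pytest.fixture
def make_instrument():
    return random_instrument
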