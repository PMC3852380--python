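import numpy as np
import pandas as pd
import pytest

from bindexpr.intervals import GenomicInterval
from bindexpr.io import CountMatrix, SampleSheet
from bindexpr.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20131018)


@pytest.fixture
def small_cfg():
    """Reduced-scale study configuration for fast end-to-end runs."""
    return SimulationConfig(seed=11, n_genes=600, n_brs=500)


@pytest.fixture
def sheet_4v4():
    rows = []
    for g in ("A", "B"):
        for i in range(1, 5):
            rows.append(
                {"library": f"{g}{i}_chip", "cell_line": f"{g}{i}",
                 "group": g, "assay": "binding", "replicate": 1}
            )
    return SampleSheet(pd.DataFrame(rows))


def nb_counts(rng, n_features, size_factors, groups, baseline, alpha,
              log2fc=None):
    """NB count matrix helper with optional planted group-A fold changes."""
    q = baseline if np.ndim(baseline) else np.full(n_features, float(baseline))
    lfc = np.zeros(n_features) if log2fc is None else np.asarray(log2fc)
    s = np.asarray(size_factors, dtype=float)
    grp = np.asarray(groups)
    mean = q[:, None] * s[None, :] * np.where(grp[None, :] == "A",
                                              2.0 ** lfc[:, None], 1.0)
    a = np.broadcast_to(np.asarray(alpha, dtype=float), (n_features,))
    if np.all(a == 0):
        k = rng.poisson(mean)
    else:
        r = 1.0 / np.where(a > 0, a, 1.0)
        p = r[:, None] / (r[:, None] + mean)
        k = np.where(a[:, None] > 0, rng.negative_binomial(r[:, None], p),
                     rng.poisson(mean))
    libs = [f"L{j}" for j in range(len(s))]
    return CountMatrix(
        pd.DataFrame(k.astype(np.int64),
                     index=[f"f{i:05d}" for i in range(n_features)],
                     columns=libs),
        pd.Series(grp, index=libs),
    )


@pytest.fixture
def make_nb_counts():
    return nb_counts


def random_intervals(rng, n, chrom="chr1", span=100_000, min_len=10,
                     max_len=500):
    starts = rng.integers(0, span - max_len, size=n)
    lengths = rng.integers(min_len, max_len, size=n)
    return [GenomicInterval(chrom, int(s), int(s + l))
            for s, l in zip(starts, lengths)]


@pytest.fixture
def make_intervals():
    return random_intervals
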