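"""Rarefaction, alpha diversity, Bray-Curtis dissimilarity, regressions.

Conventions: Shannon entropy in nats (natural log); Chao1 in its
bias-corrected form ``S_obs + F1*(F1-1) / (2*(F2+1))`` so samples without
doubletons are well-defined; rarefaction is subsampling without
replacement to a fixed depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from decaywood.tables_io import CountMatrix


@dataclass
class DiversityResult:
    sample_id: str
    observed_richness: int
    chao1: float
    shannon: float


@dataclass
class RegressionResult:
    """Ordinary least squares y ~ x with a two-sided slope t-test."""
    slope: float
    intercept: float
    r: float
    r_squared: float
    p_value: float


class RarefactionError(ValueError):
    """Sample has fewer reads than the requested depth."""


def rarefy(counts, depth: int, seed) -> np.ndarray:
    """Subsample one sample's counts to exactly ``depth`` reads.

    Draws a uniform multiset subsample without replacement. ``seed`` may
    be an int, a SeedSequence or a Generator. Raises
    :class:`RarefactionError` if the sample holds fewer than ``depth``
    reads (such samples are excluded upstream, mirroring low-yield
    sample exclusion in real studies).
    """
    counts = np.asarray(counts)
    if counts.ndim != 1:
        raise ValueError("rarefy expects a single sample's count vector")
    if (counts < 0).any():
        raise ValueError("negative counts")
    total = int(counts.sum())
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if total < depth:
        raise RarefactionError(
            f"sample total {total} is below rarefaction depth {depth}")
    if total == depth:
        return counts.astype(np.int64).copy()
    rng = np.random.default_rng(seed)
    reads = np.repeat(np.arange(counts.size), counts.astype(np.int64))
    picked = rng.choice(reads, size=depth, replace=False)
    return np.bincount(picked, minlength=counts.size).astype(np.int64)


def rarefy_matrix(cm: CountMatrix, depth: int, seed) -> tuple[CountMatrix, list[str]]:
    """Rarefy every sample of a count matrix; drop samples below depth.

    Returns the rarefied matrix and the list of excluded sample ids.
    Each sample gets an independent substream spawned from ``seed`` so
    the result does not depend on which other samples are present.
    """
    excluded = [s for s, t in cm.sample_totals().items() if t < depth]
    kept = [s for s in cm.sample_ids if s not in excluded]
    if not kept:
        raise RarefactionError(
            f"every sample is below depth {depth}: {excluded}")
    base = np.random.SeedSequence(seed)
    rows = {}
    for sid in kept:
        child = np.random.SeedSequence(
            entropy=base.entropy, spawn_key=(_stable_key(sid),))
        rows[sid] = rarefy(cm.data.loc[sid].to_numpy(), depth, child)
    out = pd.DataFrame(rows, index=cm.taxon_ids).T.astype(np.int64)
    return CountMatrix(out), excluded


def _stable_key(sample_id: str) -> int:
    """Deterministic 31-bit stream key from a sample id."""
    h = 0
    for ch in sample_id:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1)/(2(F2+1))."""
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("negative counts")
    s_obs = int((counts > 0).sum())
    if s_obs == 0:
        return 0.0
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon(counts) -> float:
    """Shannon entropy H = -sum p_i ln p_i (nats) over positive counts."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("negative counts")
    total = counts.sum()
    if total <= 0:
        raise ValueError("shannon undefined for an all-zero sample")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def diversity_table(cm: CountMatrix) -> pd.DataFrame:
    """Per-sample observed richness, Chao1 and Shannon."""
    rows = []
    for sid in cm.sample_ids:
        c = cm.data.loc[sid].to_numpy()
        rows.append(DiversityResult(
            sample_id=sid,
            observed_richness=int((c > 0).sum()),
            chao1=chao1(c),
            shannon=shannon(c),
        ))
    df = pd.DataFrame([r.__dict__ for r in rows]).set_index("sample_id")
    return df


def bray_curtis(matrix) -> pd.DataFrame:
    """All-pairs Bray-Curtis dissimilarity, d = sum|x-y| / sum(x+y).

    Accepts a CountMatrix, DataFrame or 2-D array (samples x taxa).
    Values lie in [0, 1] for non-negative input; the diagonal is 0.
    """
    if isinstance(matrix, CountMatrix):
        df = matrix.data.astype(float)
    elif isinstance(matrix, pd.DataFrame):
        df = matrix.astype(float)
    else:
        df = pd.DataFrame(np.asarray(matrix, dtype=float))
    if df.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    x = df.to_numpy()
    if (x < 0).any():
        raise ValueError("negative abundances")
    row_sums = x.sum(axis=1)
    pair_tot = row_sums[:, None] + row_sums[None, :]
    np.fill_diagonal(pair_tot, 1.0)
    if (pair_tot == 0).any():
        raise ValueError("a pair of all-zero samples has undefined "
                         "Bray-Curtis dissimilarity")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=df.index, columns=df.index)


def linear_fit(x, y) -> RegressionResult:
    """OLS fit of y on x with Pearson r and a two-sided slope p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression undefined")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        r_squared=float(res.rvalue) ** 2,
        p_value=float(res.pvalue),
    )
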