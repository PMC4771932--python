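"""Two-group permutation differential abundance (Metastats-style).

Counts are converted to relative abundances per sample; each taxon gets
an unequal-variance (Welch) t statistic between the two groups and a
two-sided permutation p-value from random relabelings of samples,
p = (1 + #{|t_perm| >= |t_obs|}) / (B + 1). Benjamini-Hochberg step-up
q-values control the FDR across taxa.

Taxa with fewer than two nonzero samples in either group are flagged
``low_information`` (they are still tested; the flag marks estimates a
reader should not over-interpret).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from decaywood.tables_io import CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class DiffAbundanceRow:
    taxon: str
    mean_a: float
    se_a: float
    mean_b: float
    se_b: float
    t_statistic: float
    p_value: float
    q_value: float
    low_information: bool


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} (m * p_(j) / j), clipped to 1, returned in the
    input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("need a non-empty 1-D p-value vector")
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _welch_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized Welch t per column; 0/0 cases give t = 0."""
    n1, n2 = a.shape[0], b.shape[0]
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    v1 = a.var(axis=0, ddof=1)
    v2 = b.var(axis=0, ddof=1)
    denom = np.sqrt(v1 / n1 + v2 / n2)
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
        t = np.where(denom == 0,
                     np.where(diff == 0, 0.0, np.inf * np.sign(diff)), t)
    return t


def metastats_test(cm: CountMatrix, group_a, group_b,
                   n_perm: int = 1000, seed: int = 0,
                   exact: bool = False,
                   with_replacement: bool = False) -> pd.DataFrame:
    """Permutation differential abundance between two sample groups.

    Parameters
    ----------
    cm
        Count matrix containing all samples of both groups.
    group_a, group_b
        Sample-id lists; each group needs >= 2 samples.
    n_perm
        Number of random relabelings (default 1000).
    exact
        Enumerate every distinct relabeling instead of sampling
        (feasible for small groups); ``n_perm`` is then ignored.
    with_replacement
        Resample group labels with replacement (bootstrap-style null)
        instead of permuting without replacement.

    Returns a DataFrame (one row per taxon, sorted by q-value) with
    group means, standard errors, t, permutation p and BH q.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"samples in both groups: {sorted(overlap)}")
    sub = cm.select_samples(group_a + group_b)
    empty = sub.data.columns[sub.data.sum(axis=0) == 0]
    if len(empty):
        logger.warning("dropping %d taxa absent from all samples", len(empty))
        sub = CountMatrix(sub.data.drop(columns=list(empty)))
    rel = sub.relative_abundances()
    taxa = list(rel.columns)
    x = rel.to_numpy()
    n1, n2 = len(group_a), len(group_b)
    n = n1 + n2

    t_obs = _welch_t(x[:n1], x[n1:])

    if exact:
        labelings = [np.array(c) for c in
                     itertools.combinations(range(n), n1)]
    else:
        rng = np.random.default_rng(seed)
        if with_replacement:
            labelings = [rng.integers(0, n, size=n) for _ in range(n_perm)]
        else:
            labelings = [rng.permutation(n)[:n1] for _ in range(n_perm)]
    b_total = len(labelings)
    exceed = np.zeros(len(taxa))
    full = np.arange(n)
    for lab in labelings:
        if with_replacement and not exact:
            idx_a, idx_b = lab[:n1], lab[n1:]
        else:
            mask = np.zeros(n, dtype=bool)
            mask[lab] = True
            idx_a, idx_b = full[mask], full[~mask]
        t_perm = _welch_t(x[idx_a], x[idx_b])
        exceed += np.abs(t_perm) >= np.abs(t_obs) - 1e-12
    p = (1.0 + exceed) / (b_total + 1.0)
    q = benjamini_hochberg(p)

    nz_a = (sub.data.loc[group_a].to_numpy() > 0).sum(axis=0)
    nz_b = (sub.data.loc[group_b].to_numpy() > 0).sum(axis=0)
    rows = []
    for j, taxon in enumerate(taxa):
        rows.append(DiffAbundanceRow(
            taxon=taxon,
            mean_a=float(x[:n1, j].mean()),
            se_a=float(x[:n1, j].std(ddof=1) / math.sqrt(n1)),
            mean_b=float(x[n1:, j].mean()),
            se_b=float(x[n1:, j].std(ddof=1) / math.sqrt(n2)),
            t_statistic=float(t_obs[j]),
            p_value=float(p[j]),
            q_value=float(q[j]),
            low_information=bool(nz_a[j] < 2 or nz_b[j] < 2),
        ))
    df = pd.DataFrame([r.__dict__ for r in rows]).set_index("taxon")
    return df.sort_values(["q_value", "p_value"], kind="stable")
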