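"""Multivariate regression tree for decay-stage partitioning.

Samples are recursively split on numeric environmental covariates so
that community dissimilarity within nodes is minimized. Node impurity
is the distance-based within-node sum of squares

    SS(node) = sum_{i<j in node} d(i,j)^2 / n_node,

the standard surrogate for sum-of-squares about the centroid when only
a dissimilarity matrix (here Bray-Curtis) is available. Each split is
greedy: among all (covariate, threshold) pairs — thresholds being
midpoints between consecutive sorted unique covariate values — the one
maximizing the impurity decrease is taken; among current leaves the
split with the largest decrease is applied first, until ``max_leaves``
is reached or nodes fall below ``min_node_size``. Ties are broken by
covariate order, then by the lower threshold.

Leaves are named early / middle / late by descending mean wood density,
mirroring the use of wood density as a decay-stage proxy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from decaywood.community_metrics import bray_curtis
from decaywood.tables_io import CountMatrix, SampleMetadata

logger = logging.getLogger(__name__)


@dataclass
class MRTNode:
    sample_ids: list[str]
    impurity: float
    split_variable: str | None = None
    split_threshold: float | None = None
    left: "MRTNode | None" = None   # samples with covariate <= threshold
    right: "MRTNode | None" = None
    name: str | None = None         # set on leaves by assign_stages

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def leaves(self) -> list["MRTNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def total_leaf_impurity(self) -> float:
        return float(sum(leaf.impurity for leaf in self.leaves()))

    def to_dict(self) -> dict:
        d = {"n": len(self.sample_ids), "impurity": self.impurity,
             "samples": list(self.sample_ids)}
        if self.name is not None:
            d["name"] = self.name
        if not self.is_leaf:
            d["split_variable"] = self.split_variable
            d["split_threshold"] = self.split_threshold
            d["left"] = self.left.to_dict()
            d["right"] = self.right.to_dict()
        return d

    def render(self, indent: int = 0) -> str:
        pad = "  " * indent
        if self.is_leaf:
            label = f" [{self.name}]" if self.name else ""
            return (f"{pad}leaf{label}: n={len(self.sample_ids)} "
                    f"impurity={self.impurity:.4f}\n")
        out = (f"{pad}{self.split_variable} <= {self.split_threshold:.4f} "
               f"(impurity={self.impurity:.4f})\n")
        return out + self.left.render(indent + 1) + self.right.render(indent + 1)


@dataclass
class StageAssignment:
    stages: dict[str, str]  # sample_id -> leaf name
    leaf_order: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"stage": pd.Series(self.stages)}) \
                 .rename_axis(index="sample_id")


def _node_impurity(d2: np.ndarray, idx: np.ndarray) -> float:
    """Within-node sum of squared dissimilarities divided by node size."""
    if idx.size < 2:
        return 0.0
    sub = d2[np.ix_(idx, idx)]
    return float(sub.sum() / 2.0 / idx.size)


def _candidate_thresholds(values: np.ndarray) -> np.ndarray:
    u = np.unique(values)
    return (u[:-1] + u[1:]) / 2.0


def _best_split(d2: np.ndarray, env: pd.DataFrame, idx: np.ndarray,
                min_node_size: int):
    """Best (variable, threshold) for one node, or None.

    Returns (decrease, variable, threshold, left_idx, right_idx) with
    ties broken by column order then lower threshold (strict > keeps
    the first-seen candidate).
    """
    parent = _node_impurity(d2, idx)
    best = None
    for var in env.columns:
        vals = env[var].to_numpy()[idx]
        for thr in _candidate_thresholds(vals):
            mask = vals <= thr
            left, right = idx[mask], idx[~mask]
            if left.size < min_node_size or right.size < min_node_size:
                continue
            dec = parent - _node_impurity(d2, left) - _node_impurity(d2, right)
            if best is None or dec > best[0] + 1e-15:
                best = (dec, var, float(thr), left, right)
    return best


def fit_mrt(community, env: SampleMetadata | pd.DataFrame,
            max_leaves: int = 3, min_node_size: int = 1,
            metric: str = "braycurtis") -> MRTNode:
    """Fit the multivariate regression tree.

    Parameters
    ----------
    community
        CountMatrix / abundance DataFrame (rows = samples), or a
        precomputed square dissimilarity DataFrame with matching ids.
    env
        Numeric covariates per sample (rows align with community ids).
        A :class:`SampleMetadata` is reduced to its numeric columns.
    max_leaves, min_node_size
        Tree-size controls; no cross-validation pruning is applied.
    metric
        ``"braycurtis"`` (default) or ``"euclidean"`` for the
        dissimilarity used to build the impurity.
    """
    if isinstance(env, SampleMetadata):
        env_df = env.data.drop(columns=["replicate_of"]).select_dtypes("number")
    else:
        env_df = env.select_dtypes("number")
    dist = _as_distance(community, metric)
    ids = list(dist.index)
    missing = [s for s in ids if s not in env_df.index]
    if missing:
        raise KeyError(f"samples without covariates: {missing}")
    env_df = env_df.loc[ids]
    if max_leaves < 1:
        raise ValueError("max_leaves must be >= 1")

    d2 = dist.to_numpy() ** 2
    all_idx = np.arange(len(ids))
    root = MRTNode(sample_ids=ids, impurity=_node_impurity(d2, all_idx))
    if env_df.shape[1] == 0 or all(env_df[c].nunique() <= 1
                                   for c in env_df.columns):
        logger.warning("all covariates constant; returning a single leaf")
        return root

    leaf_index = {id(root): all_idx}
    while len(root.leaves()) < max_leaves:
        best_leaf, best_split = None, None
        for leaf in root.leaves():
            idx = leaf_index[id(leaf)]
            if idx.size < 2 * min_node_size:
                continue
            cand = _best_split(d2, env_df, idx, min_node_size)
            if cand is None:
                continue
            if best_split is None or cand[0] > best_split[0] + 1e-15:
                best_leaf, best_split = leaf, cand
        if best_split is None:
            break
        dec, var, thr, left_idx, right_idx = best_split
        best_leaf.split_variable = var
        best_leaf.split_threshold = thr
        best_leaf.left = MRTNode([ids[i] for i in left_idx],
                                 _node_impurity(d2, left_idx))
        best_leaf.right = MRTNode([ids[i] for i in right_idx],
                                  _node_impurity(d2, right_idx))
        leaf_index[id(best_leaf.left)] = left_idx
        leaf_index[id(best_leaf.right)] = right_idx
    return root


def _as_distance(community, metric: str) -> pd.DataFrame:
    if isinstance(community, pd.DataFrame) and \
            community.shape[0] == community.shape[1] and \
            list(community.index) == list(community.columns):
        return community.astype(float)
    if metric == "braycurtis":
        return bray_curtis(community)
    if metric == "euclidean":
        df = community.data.astype(float) if isinstance(community, CountMatrix) \
            else pd.DataFrame(community).astype(float)
        x = df.to_numpy()
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        return pd.DataFrame(d, index=df.index, columns=df.index)
    raise ValueError(f"unknown metric {metric!r}")


def assign_stages(tree: MRTNode, env: SampleMetadata | pd.DataFrame,
                  density_column: str = "wood_density") -> StageAssignment:
    """Route samples down the tree and name leaves by mean wood density.

    Leaves are ordered by descending mean density of their member
    samples and named early, middle, late (then stage4, stage5, ... for
    deeper trees). Every sample in ``env`` is routed, so a fitted tree
    can stage samples it was not trained on.
    """
    env_df = env.data if isinstance(env, SampleMetadata) else env
    leaves = tree.leaves()
    means = []
    for leaf in leaves:
        dens = env_df.loc[[s for s in leaf.sample_ids
                           if s in env_df.index], density_column]
        means.append(float(dens.mean()) if len(dens) else float("-inf"))
    order = np.argsort(means)[::-1]
    base_names = ["early", "middle", "late"]
    for rank, leaf_i in enumerate(order):
        leaves[leaf_i].name = (base_names[rank] if rank < 3
                               else f"stage{rank + 1}")

    stages = {}
    for sid in env_df.index:
        node = tree
        while not node.is_leaf:
            val = env_df.at[sid, node.split_variable]
            if pd.isna(val):
                raise ValueError(
                    f"sample {sid!r} lacks split variable "
                    f"{node.split_variable!r}")
            node = node.left if val <= node.split_threshold else node.right
        stages[sid] = node.name
    return StageAssignment(stages, [leaves[i].name for i in order])
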