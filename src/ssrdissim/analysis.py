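"""Downstream comparison toolkit for dissimilarity matrices.

Covers the standard battery used to judge how well a dissimilarity measure
recovers known structure: through-origin regression of true differences on
dissimilarities (with RMSE, CV(RMSE), MAE and centred R^2), the Mantel
permutation test between matrices, UPGMA clustering with cophenetic
distances, the normalised Robinson-Foulds distance between tree
topologies, and group-level aggregation of individual dissimilarities
(DAD, the mean between-group dissimilarity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy.cluster import hierarchy

from .io import DissimilarityMatrix, SSRError

logger = logging.getLogger("ssrdissim")


# ---------------------------------------------------------------------------
# Zero-intercept goodness of fit

@dataclass(frozen=True)
class FitStats:
    """Goodness of fit of a through-origin linear model y = slope * x.

    Two coefficients of determination are reported, because they answer
    different questions for zero-intercept models:

    * ``r_squared`` — centred, 1 - SS_res / sum((y - mean(y))^2): fraction
      of the *variance* of y explained; can be strongly negative for a
      misspecified through-origin fit and is the stricter diagnostic.
    * ``r_squared_uncentered`` — 1 - SS_res / sum(y^2), the conventional
      statistic for models forced through the origin (what R's ``lm``
      prints for ``y ~ 0 + x``); algebraically the squared cosine
      similarity of x and y, so it is inflated whenever both variables are
      positive.

    ``cv_rmse`` = rmse / mean(y).
    """

    slope: float
    rmse: float
    cv_rmse: float
    mae: float
    r_squared: float
    r_squared_uncentered: float


def fit_zero_intercept(x: Sequence[float], y: Sequence[float]) -> FitStats:
    """Least-squares fit of the response y on the predictor x through the
    origin."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise SSRError("fit_zero_intercept needs two equal-length 1-d arrays")
    sxx = float(x @ x)
    if sxx == 0.0:
        raise SSRError("all predictors are zero; slope undefined")
    slope = float(x @ y) / sxx
    resid = y - slope * x
    ss_res = float(resid @ resid)
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    mae = float(np.mean(np.abs(resid)))
    ybar = float(np.mean(y))
    ss_tot = float(np.sum((y - ybar) ** 2))
    ss_raw = float(y @ y)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    r2u = 1.0 - ss_res / ss_raw if ss_raw > 0 else float("nan")
    cv = rmse / ybar if ybar != 0 else float("nan")
    return FitStats(slope=slope, rmse=rmse, cv_rmse=cv, mae=mae,
                    r_squared=r2, r_squared_uncentered=r2u)


# ---------------------------------------------------------------------------
# Mantel test

def mantel(m1: DissimilarityMatrix, m2: DissimilarityMatrix,
           n_perm: int = 9999, seed: int | None = None) -> tuple[float, float]:
    """Mantel correlation between two dissimilarity matrices.

    Pearson r over the off-diagonal upper triangles; the two-sided p-value
    comes from jointly permuting rows and columns of the second matrix
    ``n_perm`` times (the +1-corrected proportion of |r_perm| >= |r_obs|).
    """
    if m1.ids != m2.ids:
        raise SSRError("Mantel test requires identical ids in the same order")
    n = m1.n
    if n < 3:
        raise SSRError("Mantel test needs at least 3 individuals")
    iu = np.triu_indices(n, k=1)
    v1 = m1.values[iu]
    v2 = m2.values[iu]
    if v1.std() == 0 or v2.std() == 0:
        raise SSRError("Mantel test undefined for a constant matrix")
    r_obs = float(np.corrcoef(v1, v2)[0, 1])
    if n_perm <= 0:
        return r_obs, float("nan")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vp = m2.values[np.ix_(perm, perm)][iu]
        if abs(float(np.corrcoef(v1, vp)[0, 1])) >= abs(r_obs) - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return r_obs, float(p)


# ---------------------------------------------------------------------------
# UPGMA, cophenetic distances, Robinson-Foulds

@dataclass
class UltrametricTree:
    """Rooted binary UPGMA tree, stored as a scipy linkage matrix so
    cophenetic distances are exact rather than re-derived from rounded
    Newick branch lengths."""

    linkage: np.ndarray
    ids: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    def to_newick(self, precision: int = 6) -> str:
        """Newick string with branch lengths (node height = half the merge
        distance, the UPGMA convention)."""
        root = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height: float) -> str:
            height = node.dist / 2.0
            bl = parent_height - height
            if node.is_leaf():
                return f"{self.ids[node.id]}:{bl:.{precision}f}"
            left = rec(node.left, height)
            right = rec(node.right, height)
            return f"({left},{right}):{bl:.{precision}f}"

        height = root.dist / 2.0
        left = rec(root.left, height)
        right = rec(root.right, height)
        return f"({left},{right});"

    def to_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.to_newick(), schema="newick",
            taxon_namespace=taxon_namespace,
        )


def upgma(m: DissimilarityMatrix) -> UltrametricTree:
    """Average-linkage (UPGMA) agglomeration of a dissimilarity matrix."""
    if m.n < 2:
        raise SSRError("UPGMA needs at least 2 individuals")
    link = hierarchy.linkage(m.condensed(), method="average")
    return UltrametricTree(linkage=link, ids=list(m.ids))


def cophenetic(t: UltrametricTree) -> DissimilarityMatrix:
    """Tree-induced leaf-pair distances: twice the height of the most
    recent common ancestor, i.e. the merge distance of the clusters."""
    condensed = hierarchy.cophenet(t.linkage)
    n = t.n_leaves
    values = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    values[iu] = condensed
    values += values.T
    return DissimilarityMatrix(ids=list(t.ids), values=values,
                               measure="cophenetic")


def rf_normalized(t1: UltrametricTree, t2: UltrametricTree) -> float:
    """Normalised Robinson-Foulds distance between two tree topologies.

    The symmetric difference of the unrooted bipartition sets divided by
    its maximum for binary trees, 2 (n_leaves - 3); the proportion of
    partitions not shared between the trees, in [0, 1].
    """
    if sorted(t1.ids) != sorted(t2.ids):
        raise SSRError("trees must share the same leaf set")
    n = t1.n_leaves
    if n < 4:
        raise SSRError("Robinson-Foulds needs at least 4 leaves")
    tns = dendropy.TaxonNamespace()
    d1 = t1.to_dendropy(taxon_namespace=tns)
    d2 = t2.to_dendropy(taxon_namespace=tns)
    for tree in (d1, d2):
        tree.is_rooted = False
        tree.encode_bipartitions()
    rf = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
    return rf / (2.0 * (n - 3))


# ---------------------------------------------------------------------------
# DAD: group-level distances of average differences

def dad(groups: Mapping[str, Sequence[str]] | Sequence,
        m: DissimilarityMatrix) -> DissimilarityMatrix:
    """Distance of average differences between groups.

    ``DAD(G, H)`` is the mean of the individual dissimilarity over all
    cross pairs (g in G, h in H); the diagonal is 0.  ``groups`` is either
    a mapping group-label -> list of individual ids, or a sequence of
    group labels parallel to ``m.ids``.
    """
    if isinstance(groups, Mapping):
        labels_map = groups
    else:
        labels = list(groups)
        if len(labels) != m.n:
            raise SSRError("group labels must be parallel to matrix ids")
        labels_map = {}
        for lab, iid in zip(labels, m.ids):
            labels_map.setdefault(str(lab), []).append(iid)

    group_ids = list(labels_map)
    index = {iid: i for i, iid in enumerate(m.ids)}
    members = []
    for g in group_ids:
        idx = [index[i] for i in labels_map[g]]
        if not idx:
            raise SSRError(f"group {g!r} is empty")
        members.append(np.asarray(idx))

    k = len(group_ids)
    if k < 2:
        raise SSRError("DAD needs at least 2 groups")
    values = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            block = m.values[np.ix_(members[a], members[b])]
            values[a, b] = values[b, a] = float(block.mean())
    return DissimilarityMatrix(ids=group_ids, values=values,
                               measure=f"DAD({m.measure})")


def group_age_regression(pop, measure: str) -> FitStats:
    """End-to-end group experiment: pairwise dissimilarities of an
    age-group simulation, aggregated to DAD, regressed through the origin
    against the known between-group age gaps.

    The DAD dissimilarity is the response (y) and the age gap the
    predictor (x), so rmse and cv_rmse are on the dissimilarity scale —
    the convention under which the fit statistics of the different
    measures are directly comparable.
    """
    from .dissimilarity import pairwise_matrix

    if pop.group_labels is None:
        raise SSRError("population carries no group labels")
    m = pairwise_matrix(pop.to_dataset(), measure)
    d = dad([str(g) for g in pop.group_labels], m)
    centers = np.array([int(g) for g in d.ids]) * pop.group_age_step
    iu = np.triu_indices(d.n, k=1)
    gaps = np.abs(centers[:, None] - centers[None, :])[iu].astype(float)
    return fit_zero_intercept(gaps, d.values[iu])
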