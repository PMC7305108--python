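"""Differentially coexpressed modules and their eigengene summaries.

Gene pairs with a high DC score are *similar* for clustering purposes, so
the dissimilarity is ``dist = 1 - DC_Copula``.  Modules are cut from an
average-linkage (UPGMA) dendrogram on that distance; each module is
summarized by its eigengene — the first principal component of the members'
standardized expression — and module relationships are displayed as the
correlation matrix among eigengenes, computed separately within normal and
tumor samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import PairedExpression
from .scoring import DCMatrix

__all__ = [
    "ModuleSet",
    "Eigengene",
    "copula_distance_matrix",
    "detect_modules",
    "module_eigengene",
    "eigengene_network",
]


@dataclass
class ModuleSet:
    """Gene -> module assignment with labels 1..K."""

    genes: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != self.labels.size:
            raise ValueError("labels and genes must align")

    @property
    def k(self) -> int:
        return int(np.unique(self.labels).size)

    def members(self, module_id: int) -> list[str]:
        return [g for g, l in zip(self.genes, self.labels) if l == module_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes, "module": self.labels})


@dataclass
class Eigengene:
    """Unit-norm first principal component of a module, in sample space."""

    module_id: int | None
    vector: np.ndarray
    variance_explained: float


def copula_distance_matrix(d: DCMatrix) -> np.ndarray:
    """Dissimilarity ``1 - score`` off-diagonal, 0 on the diagonal."""
    dist = 1.0 - d.scores
    np.fill_diagonal(dist, 0.0)
    return dist


def _merge_small(labels: np.ndarray, dist: np.ndarray, min_size: int) -> np.ndarray:
    """Fold clusters below ``min_size`` into their nearest cluster by
    average inter-cluster distance, smallest cluster first."""
    labels = labels.copy()
    while True:
        ids, counts = np.unique(labels, return_counts=True)
        if ids.size <= 1:
            break
        small = ids[counts < min_size]
        if small.size == 0:
            break
        # smallest first; ties broken by label for determinism
        order = np.lexsort((small, counts[np.searchsorted(ids, small)]))
        victim = small[order[0]]
        vmask = labels == victim
        best, best_d = None, np.inf
        for other in ids:
            if other == victim:
                continue
            omask = labels == other
            avg = dist[np.ix_(vmask, omask)].mean()
            if avg < best_d:
                best, best_d = other, avg
        labels[vmask] = best
    return labels


def detect_modules(
    dist: np.ndarray,
    genes: list[str],
    k: int | None = None,
    cut_height: float | None = None,
    min_size: int = 5,
) -> ModuleSet:
    """Average-linkage modules from a gene dissimilarity matrix.

    Exactly one of ``k`` / ``cut_height`` may be given; with neither, the
    dendrogram is cut at 0.99 x its maximum merge height.  Clusters smaller
    than ``min_size`` are merged into their nearest cluster.  Labels are
    renumbered 1..K in order of first gene appearance.
    """
    dist = np.asarray(dist, dtype=float)
    p = dist.shape[0]
    if dist.shape != (p, p) or len(genes) != p:
        raise ValueError("dist must be square and match the gene list")
    if min_size < 1:
        raise ValueError("min_size must be at least 1")
    if k is not None and cut_height is not None:
        raise ValueError("give either k or cut_height, not both")
    if k is not None and k > p:
        raise ValueError(f"k={k} exceeds the number of genes ({p})")

    z = linkage(squareform(dist, checks=False), method="average")
    if k is not None:
        labels = fcluster(z, t=k, criterion="maxclust")
    else:
        if cut_height is None:
            cut_height = 0.99 * float(z[:, 2].max()) if p > 1 else 0.0
        labels = fcluster(z, t=cut_height, criterion="distance")

    labels = _merge_small(labels, dist, min_size)
    # deterministic relabeling by first appearance
    remap: dict[int, int] = {}
    out = np.empty(p, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        out[i] = remap[lab]
    return ModuleSet(genes=list(genes), labels=out)


def module_eigengene(
    expr: pd.DataFrame, member_genes: list[str], module_id: int | None = None
) -> Eigengene:
    """First principal component of the members' standardized expression.

    The eigengene lives in sample space, has unit Euclidean norm, and its
    sign is fixed so it correlates nonnegatively with the members' mean
    standardized profile (the usual eigengene orientation convention).
    Constant genes carry no direction and are dropped with a warning.
    """
    if len(member_genes) == 0:
        raise ValueError("module must have at least one member gene")
    x = expr.loc[member_genes].to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    sd = x.std(axis=1, ddof=1)
    const = sd == 0
    if const.all():
        raise ValueError("all module genes are constant; eigengene undefined")
    if const.any():
        dropped = [g for g, c in zip(member_genes, const) if c]
        warnings.warn(
            f"dropping constant genes from eigengene PCA: {dropped}",
            UserWarning,
            stacklevel=2,
        )
        x, sd = x[~const], sd[~const]
    xs = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    _, s, vt = np.linalg.svd(xs, full_matrices=False)
    vec = vt[0]
    mean_profile = xs.mean(axis=0)
    if float(vec @ mean_profile) < 0:
        vec = -vec
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    return Eigengene(module_id=module_id, vector=vec, variance_explained=var_explained)


def eigengene_network(
    modules: ModuleSet, paired: PairedExpression
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Eigengene correlation matrices per condition plus a composite display.

    Returns ``(corr_normal, corr_tumor, composite)`` where the composite has
    the normal correlations strictly above the diagonal, tumor strictly
    below, and 1 on the diagonal — opposite-signed entries across the
    diagonal flag module pairs whose relationship flips between conditions.
    """
    ids = sorted(np.unique(modules.labels))
    eg = {}
    for cond, expr in (("normal", paired.normal), ("tumor", paired.tumor)):
        eg[cond] = np.vstack(
            [module_eigengene(expr, modules.members(i), module_id=i).vector for i in ids]
        )
    names = [f"M{i}" for i in ids]
    corr = {
        cond: pd.DataFrame(np.atleast_2d(np.corrcoef(eg[cond])), index=names, columns=names)
        for cond in ("normal", "tumor")
    }
    comp = np.eye(len(ids))
    upper = np.triu_indices(len(ids), k=1)
    comp[upper] = corr["normal"].to_numpy()[upper]
    comp.T[upper] = corr["tumor"].to_numpy().T[upper]
    composite = pd.DataFrame(comp, index=names, columns=names)
    return corr["normal"], corr["tumor"], composite
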