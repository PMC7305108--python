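"""Differential-coexpression scoring of gene pairs.

The central statistic scores a gene pair by how far the pair's joint
dependence structure moves between conditions:

    DC_Copula(g_i, g_j) = KS_dist( e.c.(g_i^tumor, g_j^tumor),
                                   e.c.(g_i^normal, g_j^normal) ),

the Kolmogorov–Smirnov distance between the pair's empirical copulas in
tumor and in normal samples.  Because the copulas depend only on ranks, the
score is exactly invariant under strictly increasing per-gene, per-condition
transforms of the expression values.

The classical baseline it is compared against is the absolute correlation
difference |rho_normal - rho_tumor|, which conflates effect directions (it
prefers 0.2 vs 0.7 over -0.2 vs 0.2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import PairedExpression
from .copula import EmpiricalCopula, ks_distance, pseudo_observations

__all__ = [
    "DCMatrix",
    "dc_copula_score",
    "dc_copula_matrix",
    "baseline_dc_score",
    "extract_dc_pairs",
    "ratio_feature_matrix",
    "pattern_match_matrix",
]


@dataclass
class DCMatrix:
    """Symmetric gene x gene matrix of DC_Copula scores in [0, 1]."""

    genes: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        p = len(self.genes)
        if self.scores.shape != (p, p):
            raise ValueError("score matrix shape does not match gene list")
        if not np.allclose(self.scores, self.scores.T):
            raise ValueError("score matrix must be symmetric")
        if np.any(np.diag(self.scores) != 0):
            raise ValueError("score matrix diagonal must be zero")
        if np.any((self.scores < 0) | (self.scores > 1)):
            raise ValueError("scores must lie in [0, 1]")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.genes, columns=self.genes)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DCMatrix":
        if list(df.index) != list(df.columns):
            raise ValueError("DC matrix must have identical row and column genes")
        return cls(genes=list(df.index), scores=df.to_numpy(dtype=float))


def dc_copula_score(
    xi_n: np.ndarray,
    xi_t: np.ndarray,
    xj_n: np.ndarray,
    xj_t: np.ndarray,
    eval_mode: str = "pooled_points",
    grid_size: int = 100,
) -> float:
    """DC_Copula score of one gene pair from its four condition profiles."""
    for name, v in (("xi_n", xi_n), ("xi_t", xi_t), ("xj_n", xj_n), ("xj_t", xj_t)):
        if np.asarray(v).size < 3:
            raise ValueError(f"{name}: need at least 3 samples per profile")
    c_tumor = EmpiricalCopula(pseudo_observations(xi_t), pseudo_observations(xj_t))
    c_normal = EmpiricalCopula(pseudo_observations(xi_n), pseudo_observations(xj_n))
    return ks_distance(c_tumor, c_normal, eval_mode=eval_mode, grid_size=grid_size)


def dc_copula_matrix(
    paired: PairedExpression,
    eval_mode: str = "pooled_points",
    grid_size: int = 100,
) -> DCMatrix:
    """All-pairs DC_Copula matrix.

    Pseudo-observations are precomputed once per gene and condition; pair
    results are independent of evaluation order.
    """
    if paired.n_genes < 2:
        raise ValueError("need at least 2 genes")
    if paired.n_pairs < 3:
        raise ValueError("need at least 3 samples per condition")
    genes = paired.genes
    p = len(genes)
    po_n = np.vstack([pseudo_observations(row) for row in paired.normal.to_numpy(float)])
    po_t = np.vstack([pseudo_observations(row) for row in paired.tumor.to_numpy(float)])
    scores = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            try:
                d = ks_distance(
                    EmpiricalCopula(po_t[i], po_t[j]),
                    EmpiricalCopula(po_n[i], po_n[j]),
                    eval_mode=eval_mode,
                    grid_size=grid_size,
                )
            except Exception as exc:  # pragma: no cover - defensive
                raise RuntimeError(
                    f"failed scoring gene pair ({genes[i]}, {genes[j]})"
                ) from exc
            scores[i, j] = scores[j, i] = d
    return DCMatrix(genes=genes, scores=scores)


def baseline_dc_score(rho_p1: float, rho_p2: float) -> float:
    """Correlation-difference baseline ``|rho_p1 - rho_p2|``."""
    for r in (rho_p1, rho_p2):
        if not -1.0 <= r <= 1.0:
            raise ValueError("correlations must lie in [-1, 1]")
    return abs(rho_p1 - rho_p2)


def _condition_correlations(paired: PairedExpression, method: str) -> tuple[np.ndarray, np.ndarray]:
    if method == "pearson":
        rn = np.corrcoef(paired.normal.to_numpy(float))
        rt = np.corrcoef(paired.tumor.to_numpy(float))
    elif method == "spearman":
        from scipy import stats

        rn = stats.spearmanr(paired.normal.to_numpy(float), axis=1).statistic
        rt = stats.spearmanr(paired.tumor.to_numpy(float), axis=1).statistic
        rn = np.atleast_2d(rn)
        rt = np.atleast_2d(rt)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return rn, rt


def extract_dc_pairs(
    d: DCMatrix,
    paired: PairedExpression,
    threshold: float = 0.0,
    top_k: int | None = None,
    corr_method: str = "pearson",
) -> pd.DataFrame:
    """Gene pairs with score >= ``threshold`` (or the ``top_k`` best),
    annotated with per-condition correlations.

    Rows are ordered by descending score, ties broken by gene index, so the
    output is fully deterministic.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if list(d.genes) != paired.genes:
        raise ValueError("DC matrix and expression genes do not match")
    rn, rt = _condition_correlations(paired, corr_method)
    p = len(d.genes)
    iu, ju = np.triu_indices(p, k=1)
    scores = d.scores[iu, ju]
    keep = scores >= threshold
    iu, ju, scores = iu[keep], ju[keep], scores[keep]
    order = np.lexsort((ju, iu, -scores))
    if top_k is not None:
        order = order[:top_k]
    return pd.DataFrame(
        {
            "gene_i": [d.genes[i] for i in iu[order]],
            "gene_j": [d.genes[j] for j in ju[order]],
            "score": scores[order],
            "rho_normal": rn[iu[order], ju[order]],
            "rho_tumor": rt[iu[order], ju[order]],
        }
    )


def ratio_feature_matrix(
    pairs: pd.DataFrame, paired: PairedExpression, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Samples x pairs matrix of expression ratios, the feature matrix used
    to classify normal vs tumor samples from DC pairs.

    Row index is a MultiIndex (condition, pair_id), normal rows first; each
    column is ``(expr(gene_i) + pc) / (expr(gene_j) + pc)`` in that sample.
    """
    if len(pairs) == 0:
        raise ValueError("pairs must be nonempty")
    blocks = []
    for cond, expr in (("normal", paired.normal), ("tumor", paired.tumor)):
        num = expr.loc[pairs["gene_i"]].to_numpy(float) + pseudocount
        den = expr.loc[pairs["gene_j"]].to_numpy(float) + pseudocount
        if np.any(den == 0):
            raise ValueError("zero denominator; use a positive pseudocount")
        blocks.append(
            pd.DataFrame(
                (num / den).T,
                index=pd.MultiIndex.from_product(
                    [[cond], paired.pair_ids], names=["condition", "pair_id"]
                ),
                columns=[f"{i}/{j}" for i, j in zip(pairs["gene_i"], pairs["gene_j"])],
            )
        )
    return pd.concat(blocks)


def pattern_match_matrix(pairs: pd.DataFrame, expr: pd.DataFrame) -> pd.DataFrame:
    """Binary samples x pairs matrix: 1 where the two genes deviate from
    their medians in the same direction in that sample, else 0."""
    if len(pairs) == 0:
        raise ValueError("pairs must be nonempty")
    med = expr.median(axis=1)
    signs = np.sign(expr.sub(med, axis=0))
    si = signs.loc[pairs["gene_i"]].to_numpy()
    sj = signs.loc[pairs["gene_j"]].to_numpy()
    return pd.DataFrame(
        (si == sj).astype(int).T,
        index=list(expr.columns),
        columns=[f"{i}/{j}" for i, j in zip(pairs["gene_i"], pairs["gene_j"])],
    )
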