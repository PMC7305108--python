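"""Gene-set enrichment of modules.

Two complementary summaries are computed against user-supplied gene sets
(GMT format): a fold-enrichment ``pathway_score = n/m`` where ``n`` is the
fraction of the module covered by the set and ``m`` the fraction of the
universe covered by the set, and an upper-tail hypergeometric
over-representation p-value with Benjamini–Hochberg FDR control.  The CCDF
curve summarizes, per score threshold, how many modules achieve at least
that pathway score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .modules import ModuleSet

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "pathway_score",
    "hypergeom_enrich",
    "ccdf_pathway_scores",
]


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a gene universe."""

    sets: dict[str, frozenset[str]]
    universe: list[str]

    def __post_init__(self) -> None:
        if len(set(self.universe)) != len(self.universe):
            raise ValueError("universe genes must be unique")
        uni = set(self.universe)
        self.sets = {name: frozenset(g for g in s if g in uni) for name, s in self.sets.items()}

    def nonempty_sets(self) -> dict[str, frozenset[str]]:
        return {name: s for name, s in self.sets.items() if s}


def read_gmt(path: str | Path, universe: list[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (set name, description, tab-separated gene ids).

    When ``universe`` is omitted it defaults to the union of all set genes.
    """
    sets: dict[str, frozenset[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        name = fields[0]
        if name in sets:
            raise ValueError(f"duplicate gene set name {name!r}")
        sets[name] = frozenset(g for g in fields[2:] if g)
    if universe is None:
        universe = sorted(set().union(*sets.values())) if sets else []
    return GeneSetCollection(sets=sets, universe=list(universe))


def pathway_score(
    module_genes,
    set_genes,
    universe,
    denominator: str = "module",
) -> float:
    """Fold enrichment ``n/m`` of a gene set in a module.

    ``n`` = overlap / |module| (or overlap / |set in universe| with
    ``denominator="set"``), ``m`` = |set in universe| / |universe|.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe must be nonempty")
    module = set(module_genes) & uni
    if not module:
        raise ValueError("module has no genes in the universe")
    in_set = set(set_genes) & uni
    m_frac = len(in_set) / len(uni)
    if m_frac == 0:
        raise ValueError("gene set is absent from the universe")
    overlap = len(module & in_set)
    if denominator == "module":
        n_frac = overlap / len(module)
    elif denominator == "set":
        n_frac = overlap / len(in_set)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return n_frac / m_frac


def hypergeom_enrich(
    modules: ModuleSet,
    sets: GeneSetCollection,
    alpha: float = 0.05,
    score_denominator: str = "module",
) -> pd.DataFrame:
    """Hypergeometric over-representation of every (module, set) pair.

    p = P(X >= overlap) drawing |module| genes from a universe with
    |set| successes; BH-FDR is computed across all tests performed and a
    test is flagged significant when fdr <= alpha.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    uni = set(sets.universe)
    if not uni:
        raise ValueError("universe must be nonempty")
    n_uni = len(uni)
    rows = []
    for mod_id in sorted(np.unique(modules.labels)):
        members = set(modules.members(mod_id)) & uni
        if not members:
            continue
        for name, s in sets.nonempty_sets().items():
            overlap = len(members & s)
            p = float(stats.hypergeom.sf(overlap - 1, n_uni, len(s), len(members)))
            rows.append(
                {
                    "module_id": mod_id,
                    "set_name": name,
                    "overlap_count": overlap,
                    "module_size": len(members),
                    "set_size_in_universe": len(s),
                    "universe_size": n_uni,
                    "pathway_score": pathway_score(
                        members, s, sets.universe, denominator=score_denominator
                    ),
                    "p_value": min(p, 1.0),
                }
            )
    if not rows:
        raise ValueError("no (module, set) tests could be performed")
    out = pd.DataFrame(rows)
    out["fdr"] = stats.false_discovery_control(out["p_value"].to_numpy(), method="bh")
    out["significant"] = out["fdr"] <= alpha
    return out


def ccdf_pathway_scores(
    results: pd.DataFrame, thresholds: np.ndarray | None = None
) -> pd.DataFrame:
    """Fraction of modules whose best pathway score reaches each threshold.

    Uses the per-module maximum over sets; the curve is a non-increasing
    step function with values in [0, 1].
    """
    if len(results) == 0:
        raise ValueError("results must be nonempty")
    best = results.groupby("module_id")["pathway_score"].max()
    if thresholds is None:
        thresholds = np.linspace(0.0, float(best.max()) + 0.5, 25)
    thresholds = np.asarray(thresholds, dtype=float)
    frac = [(best >= t).mean() for t in thresholds]
    return pd.DataFrame({"threshold": thresholds, "fraction": frac})
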