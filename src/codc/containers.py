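"""In-memory containers shared across the pipeline.

Expression data is carried as pandas DataFrames with genes as rows.
:class:`PairedExpression` holds the two condition matrices of a matched-pair
design (each tumor column is the same patient as the normal column at the
same position), which is the object every scoring routine consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("normal", "tumor")


@dataclass
class RawCountMatrix:
    """Raw (UMI/read) counts plus a sample sheet.

    Parameters
    ----------
    counts
        genes x samples, nonnegative counts; row index = gene ids,
        column index = sample ids.
    samples
        One row per sample (index = sample id) with columns
        ``condition`` (``"normal"`` or ``"tumor"``) and ``pair_id``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise ValueError("gene ids must be unique")
        if not self.counts.columns.is_unique:
            raise ValueError("sample ids must be unique")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing from sample sheet: {sorted(missing)}")
        for col in ("condition", "pair_id"):
            if col not in self.samples.columns:
                raise ValueError(f"sample sheet needs a '{col}' column")
        bad = set(self.samples["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions {sorted(bad)}; expected {CONDITIONS}")
        vals = self.counts.to_numpy()
        if np.any(vals < 0):
            raise ValueError("counts must be nonnegative")
        # each pair id must occur exactly once per condition
        sheet = self.samples.loc[list(self.counts.columns)]
        for cond in CONDITIONS:
            pids = sheet.loc[sheet["condition"] == cond, "pair_id"]
            if pids.duplicated().any():
                dup = sorted(pids[pids.duplicated()].unique())
                raise ValueError(f"pair ids duplicated within {cond}: {dup}")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class PairedExpression:
    """Matched normal/tumor expression over a shared gene universe.

    ``normal`` and ``tumor`` are genes x pairs DataFrames with identical row
    (gene) order; column k of both matrices belongs to the same patient.
    """

    normal: pd.DataFrame
    tumor: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.normal.index) != list(self.tumor.index):
            raise ValueError("normal and tumor must share identical gene order")
        if self.normal.shape[1] != self.tumor.shape[1]:
            raise ValueError("normal and tumor must have the same number of pairs")
        if list(self.normal.columns) != list(self.tumor.columns):
            raise ValueError("normal and tumor must share identical pair order")
        if not self.normal.index.is_unique:
            raise ValueError("gene ids must be unique")
        if self.normal.isna().any().any() or self.tumor.isna().any().any():
            raise ValueError("expression matrices must not contain missing values")

    @property
    def genes(self) -> list[str]:
        return list(self.normal.index)

    @property
    def pair_ids(self) -> list[str]:
        return list(self.normal.columns)

    @property
    def n_genes(self) -> int:
        return self.normal.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.normal.shape[1]

    def subset(self, genes: list[str]) -> "PairedExpression":
        """Restrict to ``genes`` (kept in the given order)."""
        return PairedExpression(self.normal.loc[genes], self.tumor.loc[genes])


def pair_expression(expr: pd.DataFrame, samples: pd.DataFrame) -> PairedExpression:
    """Split a genes x samples matrix into a :class:`PairedExpression`.

    Keeps only pair ids present in both conditions; pairs are ordered by
    sorted pair id so the construction is deterministic.
    """
    sheet = samples.loc[[s for s in expr.columns if s in samples.index]]
    by_cond = {
        cond: dict(
            zip(
                sheet.loc[sheet["condition"] == cond, "pair_id"],
                sheet.index[sheet["condition"] == cond],
            )
        )
        for cond in CONDITIONS
    }
    shared = sorted(set(by_cond["normal"]) & set(by_cond["tumor"]), key=str)
    if not shared:
        raise ValueError("no pair ids shared between normal and tumor samples")
    normal = expr[[by_cond["normal"][p] for p in shared]].copy()
    tumor = expr[[by_cond["tumor"][p] for p in shared]].copy()
    normal.columns = shared
    tumor.columns = shared
    return PairedExpression(normal=normal, tumor=tumor)
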