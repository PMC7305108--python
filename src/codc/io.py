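"""Reading and writing the plain-text formats used by the CLI.

Expression matrices are TSV/CSV with genes as rows (first column = gene id)
and samples as columns; the sample sheet is a TSV with columns
``sample_id``, ``condition``, ``pair_id``.  Separators are inferred from the
file extension (``.csv`` -> comma, anything else -> tab).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .containers import PairedExpression, RawCountMatrix
from .simulation import PairSpec, SimConfig

__all__ = [
    "read_expression",
    "write_expression",
    "read_sample_sheet",
    "read_raw_counts",
    "read_paired",
    "load_sim_config",
]


def _sep(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    df.index = df.index.astype(str)
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep=_sep(path))


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep=_sep(path))
    required = {"sample_id", "condition", "pair_id"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return sheet.set_index("sample_id")


def read_raw_counts(counts_path: str | Path, samples_path: str | Path) -> RawCountMatrix:
    return RawCountMatrix(
        counts=read_expression(counts_path), samples=read_sample_sheet(samples_path)
    )


def read_paired(normal_path: str | Path, tumor_path: str | Path) -> PairedExpression:
    return PairedExpression(
        normal=read_expression(normal_path), tumor=read_expression(tumor_path)
    )


def load_sim_config(path: str | Path) -> SimConfig:
    """Build a :class:`SimConfig` from a flat YAML/JSON mapping.

    Pair specs are given as lists ``[gene_i, gene_j, rho_normal, rho_tumor]``
    with an optional fifth ``exact`` flag.  A seed is mandatory.
    """
    text = Path(path).read_text()
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    if "seed" not in raw:
        raise ValueError("config must set a seed")
    specs = [
        PairSpec(
            gene_i=int(s[0]),
            gene_j=int(s[1]),
            rho_normal=float(s[2]),
            rho_tumor=float(s[3]),
            exact=bool(s[4]) if len(s) > 4 else True,
        )
        for s in raw.pop("pair_specs", [])
    ]
    return SimConfig(pair_specs=specs, **raw)
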