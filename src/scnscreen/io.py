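"""Delimited-text readers and writers for every pipeline artifact.

All tables are TSV with a header row (probeset ID first column where
applicable); ground truth and run summaries are JSON.  Floats are written
with ``%.10g`` so that identical inputs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

FLOAT_FMT = "%.10g"

__all__ = [
    "write_table", "read_table",
    "write_light_pulse_set", "read_light_pulse_set",
    "write_json", "read_json",
    "write_actogram", "read_actogram",
    "write_mua", "read_mua",
    "write_newick",
]


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index)


def read_table(path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_light_pulse_set(pairs: pd.DataFrame, path) -> None:
    """Long format: probeset, condition, light_mean, dark_mean."""
    long = pairs.stack(level=0, future_stack=True).reset_index()
    long = long.rename(columns={long.columns[0]: "probeset",
                                "light": "light_mean", "dark": "dark_mean"})
    long = long[["probeset", "condition", "light_mean", "dark_mean"]]
    long.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=False)


def read_light_pulse_set(path) -> pd.DataFrame:
    long = pd.read_csv(path, sep="\t")
    wide = long.pivot(index="probeset", columns="condition",
                      values=["light_mean", "dark_mean"])
    conditions = list(dict.fromkeys(long["condition"]))
    cols = pd.MultiIndex.from_product([conditions, ["light", "dark"]],
                                      names=["condition", "arm"])
    out = pd.DataFrame(index=wide.index, columns=cols, dtype=float)
    for c in conditions:
        out[(c, "light")] = wide[("light_mean", c)]
        out[(c, "dark")] = wide[("dark_mean", c)]
    return out.loc[list(dict.fromkeys(long["probeset"]))]


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return json.loads(o.to_json(orient="index"))
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def write_actogram(data: pd.DataFrame, path) -> None:
    data.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=False)


def read_actogram(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_mua(data: pd.DataFrame, path) -> None:
    data.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_mua(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_newick(tree, path) -> None:
    tree.write(str(path), format="newick")
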