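"""Reading mixed tables with a declared column schema; writing results.

Input is an RFC-4180 CSV with a header plus a schema (YAML or JSON list of
``{name, role}``) declaring each column categorical, continuous, label, or
ignore.  Categorical level sets are built from the observed distinct values,
sorted lexicographically.  Rows with any missing value in a used column are
dropped (complete-case analysis) with a logged count; a non-missing but
unparseable value in a continuous column is a hard error naming the cell.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import MixedDataset
from .cluster import ClusterModel

logger = logging.getLogger(__name__)

__all__ = ["ColumnSchema", "load_schema", "read_mixed_csv", "write_memberships"]

ROLES = ("categorical", "continuous", "label", "ignore")


@dataclass
class ColumnSchema:
    """Declared role of one input column."""

    name: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role {self.role!r} not one of {ROLES}")


def load_schema(path) -> list[ColumnSchema]:
    """Load a schema file (YAML or JSON list of {name, role})."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, list):
        raise ValueError("schema must be a list of {name, role} mappings")
    return [ColumnSchema(name=str(e["name"]), role=str(e["role"])) for e in raw]


def read_mixed_csv(path, schema: list[ColumnSchema]) -> MixedDataset:
    """Read a mixed table into a :class:`MixedDataset` following the schema.

    Columns appear in schema order.  When clustering is requested at least
    one categorical and one continuous column are required; a schema name
    absent from the header is an error.
    """
    names = [s.name for s in schema]
    if len(set(names)) != len(names):
        raise ValueError("duplicate column names in schema")
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing_cols = [n for n in names if n not in df.columns]
    if missing_cols:
        raise ValueError(f"schema columns missing from header: {missing_cols}")
    cat_cols = [s.name for s in schema if s.role == "categorical"]
    cont_cols = [s.name for s in schema if s.role == "continuous"]
    label_cols = [s.name for s in schema if s.role == "label"]
    if len(label_cols) > 1:
        raise ValueError("at most one label column is allowed")
    if not cat_cols or not cont_cols:
        raise ValueError("need at least one categorical and one continuous column")

    used = cat_cols + cont_cols + label_cols
    raw_n = len(df)
    # continuous parse errors are distinguished from genuinely missing cells
    cont = {}
    for c in cont_cols:
        col = df[c]
        present = col.notna()
        vals = pd.to_numeric(col[present], errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad):
            row = int(bad[0])
            raise ValueError(
                f"non-numeric value {col.loc[row]!r} in continuous column "
                f"{c!r} at row {row}"
            )
        cont[c] = pd.to_numeric(col, errors="coerce")
    keep = df[used].notna().all(axis=1)
    dropped = int(raw_n - keep.sum())
    if dropped:
        logger.warning("dropped %d of %d rows with missing values", dropped, raw_n)
    df = df[keep]

    levels = []
    X = np.empty((len(df), len(cat_cols)), dtype=np.int64)
    for j, c in enumerate(cat_cols):
        lv, codes = np.unique(df[c].to_numpy(), return_inverse=True)
        levels.append(lv)
        X[:, j] = codes
    Z = np.column_stack([cont[c][keep].to_numpy(dtype=float) for c in cont_cols])
    labels = df[label_cols[0]].to_numpy() if label_cols else None
    return MixedDataset(X=X, levels=levels, Z=Z, ids=df.index.to_numpy(), labels=labels)


def write_memberships(model: ClusterModel, path, summary_path=None) -> None:
    """Write memberships CSV (id, cluster) and a JSON run summary.

    The summary records K, the chosen quantization level, centers, radii,
    and per-cluster test statistics.  Floats survive a round trip at full
    precision (repr serialization).
    """
    path = Path(path)
    ids = model.ids if model.ids is not None else np.arange(len(model.membership))
    pd.DataFrame({"id": ids, "cluster": model.membership}).to_csv(path, index=False)
    if summary_path is None:
        summary_path = path.with_suffix(".summary.json")
    summary = {
        "K": model.K,
        "chosen_M": model.chosen_M,
        "no_structure": model.no_structure,
        "stalled": model.stalled,
        "centers": [
            {"categorical": np.asarray(S).tolist(), "quantized": np.asarray(T).tolist()}
            for S, T in model.centers
        ],
        "radii_c": list(model.radii_c),
        "radii_q": list(model.radii_q),
        "per_cluster_tests": [
            {
                "chi_c": t.chi_c,
                "chi_q": t.chi_q,
                "chi_w": t.chi_w,
                "r_c": t.r_c,
                "r_q": t.r_q,
                "df": t.df,
                "crit": t.crit,
            }
            for t in model.per_cluster_tests
        ],
        "f_stats": {str(k): v for k, v in (model.f_stats or {}).items()},
        "config": model.config.to_dict() if model.config else None,
    }
    Path(summary_path).write_text(json.dumps(summary, indent=2, default=float))


def read_memberships(path) -> pd.DataFrame:
    """Read back a memberships CSV written by :func:`write_memberships`."""
    return pd.read_csv(path)
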