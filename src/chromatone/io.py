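"""Schema-checked CSV readers and writers for the pipeline tables.

All files are UTF-8 CSVs with a mandatory header row; floats are written at
full precision (presentation rounding happens only in table render mode).
Readers raise ``ValueError`` naming the offending column or row so the CLI
can exit with a validation error code.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .ratings import ATTRIBUTES, RatingTable
from .matching import validate_selections

__all__ = [
    "read_materials",
    "read_ratings",
    "read_stimuli",
    "read_selections",
    "read_pair_table",
    "write_table",
]

_MATERIAL_COLS = ["material_id", "category"]
_STIMULI_COLS = ["interval_id", "interval_class", "abbreviation", "I"]


def _require(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"{what} is missing columns: {sorted(missing)}")


def read_materials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, _MATERIAL_COLS, "materials table")
    if df["material_id"].duplicated().any():
        dup = df.loc[df["material_id"].duplicated(), "material_id"].iloc[0]
        raise ValueError(f"duplicate material_id {dup}")
    return df


def read_ratings(path: str | Path) -> RatingTable:
    df = pd.read_csv(path)
    bad = df[~df["score"].astype(float).mod(1).eq(0)] if "score" in df.columns else df.iloc[:0]
    if len(bad):
        raise ValueError(f"non-integer scores at rows {bad.index.tolist()[:5]}")
    return RatingTable(df)


def read_stimuli(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, _STIMULI_COLS, "stimuli table")
    if df["interval_id"].duplicated().any():
        raise ValueError("duplicate interval_id in stimuli table")
    return df


def read_selections(path: str | Path, materials: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read selections; joins material_category from a materials table if
    the column is absent."""
    df = pd.read_csv(path)
    if "material_category" not in df.columns:
        if materials is None:
            raise ValueError(
                "selections lack material_category; pass a materials table to join"
            )
        cat = materials.set_index("material_id")["category"]
        unknown = set(df["material_id"]) - set(cat.index)
        if unknown:
            raise ValueError(f"selections reference unknown materials: {sorted(unknown)[:5]}")
        df["material_category"] = cat.loc[df["material_id"]].to_numpy()
    return validate_selections(df)


def read_pair_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="interval_id", float_precision="round_trip")
    expected = ["I"] + [f"{p}_{a}" for p in ("matched", "mismatched") for a in ATTRIBUTES]
    _require(df, expected, "pair table")
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index)
    return path
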