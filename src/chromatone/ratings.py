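"""Per-subject 5-point ratings of multi-color materials.

Sixteen subjects rate fifty three-color materials on eight perceptual
attributes — five mid-level bipolar pairs (cool/warm, soft/hard,
transparent/turbid, far/near, weak/strong) plus the pleasure–arousal–
dominance emotion dimensions — each on a 1–5 scale.  This module validates
such tables, measures inter-rater reliability with Cronbach's alpha, and
reduces each material to its 8-dimensional mean attribute vector
F = [f1, …, f8].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ATTRIBUTES",
    "ATTRIBUTE_LABELS",
    "RatingTable",
    "cronbach_alpha",
    "attribute_vector",
    "attribute_vectors",
    "reliability_report",
]

#: Attribute short codes, in canonical order.
ATTRIBUTES: tuple[str, ...] = ("CW", "SH", "TT", "FN", "WS", "P", "A", "D")

ATTRIBUTE_LABELS: dict[str, str] = {
    "CW": "cool/warm",
    "SH": "soft/hard",
    "TT": "transparent/turbid",
    "FN": "far/near",
    "WS": "weak/strong",
    "P": "pleasure",
    "A": "arousal",
    "D": "dominance",
}

#: Conventional reliability floor for Cronbach's alpha.
ALPHA_THRESHOLD = 0.7


@dataclass
class RatingTable:
    """Complete subjects × materials × attributes grid of 1–5 scores.

    Backed by a long-format DataFrame with columns
    ``subject_id, material_id, attribute, score``.  Validation enforces
    integer scores in {1..5}, the canonical attribute set, and a complete
    grid with no duplicate or missing cells.
    """

    data: pd.DataFrame
    subjects: list = field(init=False)
    materials: list = field(init=False)

    def __post_init__(self) -> None:
        df = self.data
        required = {"subject_id", "material_id", "attribute", "score"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"ratings table missing columns: {sorted(missing)}")
        bad = df[~df["score"].isin([1, 2, 3, 4, 5])]
        if len(bad):
            rows = bad.index.tolist()[:5]
            raise ValueError(f"scores outside 1–5 at rows {rows}")
        extra = set(df["attribute"].unique()) - set(ATTRIBUTES)
        if extra:
            raise ValueError(f"unknown attributes: {sorted(extra)}")
        self.subjects = sorted(df["subject_id"].unique().tolist())
        self.materials = sorted(df["material_id"].unique().tolist())
        expected = len(self.subjects) * len(self.materials) * len(ATTRIBUTES)
        keys = df[["subject_id", "material_id", "attribute"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate rating cell: {dup}")
        if len(df) != expected:
            gaps = self._find_gaps(df)
            raise ValueError(f"incomplete rating grid; missing cells include: {gaps[:5]}")

    def _find_gaps(self, df: pd.DataFrame) -> list[tuple]:
        have = set(map(tuple, df[["subject_id", "material_id", "attribute"]].itertuples(index=False)))
        return [
            (s, m, a)
            for s in self.subjects
            for m in self.materials
            for a in ATTRIBUTES
            if (s, m, a) not in have
        ]

    def score_matrix(self, attribute: str) -> pd.DataFrame:
        """Materials × subjects score matrix for one attribute."""
        sub = self.data[self.data["attribute"] == attribute]
        return sub.pivot(index="material_id", columns="subject_id", values="score")


def cronbach_alpha(score_matrix: np.ndarray | pd.DataFrame, ddof: int = 1) -> float:
    """Cronbach's alpha for an items × raters score matrix.

    alpha = k/(k−1) · (1 − Σᵢ σᵢ² / σₓ²), where k is the number of raters
    (columns), σᵢ² the variance over items of rater i's scores, and σₓ² the
    variance over items of the per-item total across raters.

    Parameters
    ----------
    score_matrix
        Shape (n_items, k_raters), k ≥ 2 and n_items ≥ 2.
    ddof
        Variance convention: 1 (sample, default) or 0 (population).  Both
        give alpha = 1 for perfectly consistent raters.
    """
    X = np.asarray(score_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("score matrix must be 2-D (items × raters)")
    n_items, k = X.shape
    if k < 2 or n_items < 2:
        raise ValueError(f"need ≥2 raters and ≥2 items, got {k} raters × {n_items} items")
    item_totals = X.sum(axis=1)
    total_var = item_totals.var(ddof=ddof)
    if total_var == 0:
        raise ValueError("total score variance is zero; alpha undefined")
    rater_vars = X.var(axis=0, ddof=ddof)
    return k / (k - 1) * (1.0 - rater_vars.sum() / total_var)


def attribute_vector(table: RatingTable, material) -> np.ndarray:
    """8-dimensional mean attribute vector F for one material.

    Each component fᵢ is the arithmetic mean over subjects of the material's
    1–5 scores on attribute i, in canonical attribute order.
    """
    sub = table.data[table.data["material_id"] == material]
    if sub.empty:
        raise ValueError(f"no ratings for material {material!r}")
    means = sub.groupby("attribute")["score"].mean()
    return np.array([means[a] for a in ATTRIBUTES], dtype=float)


def attribute_vectors(table: RatingTable) -> pd.DataFrame:
    """Mean attribute vectors for every material (materials × 8)."""
    wide = (
        table.data.groupby(["material_id", "attribute"])["score"]
        .mean()
        .unstack("attribute")
        .loc[:, list(ATTRIBUTES)]
    )
    wide.columns.name = None
    return wide


def reliability_report(
    table: RatingTable, ddof: int = 1, threshold: float = ALPHA_THRESHOLD
) -> pd.DataFrame:
    """Cronbach's alpha per attribute, with materials as items and subjects
    as raters; attributes with alpha < threshold are flagged unreliable."""
    rows = []
    for attr in ATTRIBUTES:
        alpha = cronbach_alpha(table.score_matrix(attr).to_numpy(), ddof=ddof)
        rows.append(
            {
                "attribute": attr,
                "label": ATTRIBUTE_LABELS[attr],
                "alpha": alpha,
                "reliable": bool(alpha >= threshold),
            }
        )
    return pd.DataFrame(rows)
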