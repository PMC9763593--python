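"""Pearson correlation between consonance and aggregated color attributes.

For each interval class the consonance index I of its 13 intervals is
correlated with each rank-aggregated attribute column (8 attributes × 2
polarities), and |r| is classified into the conventional strength bands:
strong (|r| ≥ 0.8), medium (0.5 ≤ |r| < 0.8), weak (0.3 ≤ |r| < 0.5),
none (|r| < 0.3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matching import INTERVAL_CLASSES
from .ratings import ATTRIBUTES

__all__ = [
    "STRENGTH_BANDS",
    "CorrelationCell",
    "pearson_r",
    "strength_class",
    "correlation_matrix",
    "correlation_frame",
    "scatter_fit_export",
]

#: (lower |r| bound, label), highest band first.
STRENGTH_BANDS = ((0.8, "strong"), (0.5, "medium"), (0.3, "weak"), (0.0, "none"))


@dataclass(frozen=True)
class CorrelationCell:
    attribute: str
    polarity: str
    interval_class: str
    r: float
    p_value: float
    strength: str


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with two-sided p-value.

    Requires n ≥ 3 and non-constant inputs (r is undefined otherwise).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def strength_class(r: float) -> str:
    """Strength label for a correlation coefficient by its magnitude."""
    if not np.isfinite(r) or abs(r) > 1 + 1e-12:
        raise ValueError(f"|r| must be ≤ 1, got {r}")
    a = abs(r)
    for bound, label in STRENGTH_BANDS:
        if a >= bound:
            return label
    return "none"  # pragma: no cover — bands cover [0, 1]


def correlation_matrix(
    pair_tables: dict[str, pd.DataFrame], bh_correct: bool = False
) -> list[CorrelationCell]:
    """Correlation of I with every attribute column across all classes.

    Parameters
    ----------
    pair_tables
        Mapping interval_class → pair table (as from
        :func:`chromatone.matching.build_pair_table`).
    bh_correct
        Apply Benjamini–Hochberg adjustment to the p-values (opt-in; raw
        two-sided p-values are the default and always reflect n = rows per
        class with no correction).
    """
    missing = set(INTERVAL_CLASSES) - set(pair_tables)
    if missing:
        raise ValueError(f"missing pair tables for classes: {sorted(missing)}")
    cells = []
    for cls in INTERVAL_CLASSES:
        table = pair_tables[cls]
        for attr in ATTRIBUTES:
            for polarity in ("matched", "mismatched"):
                r, p = pearson_r(table["I"], table[f"{polarity}_{attr}"])
                cells.append(
                    CorrelationCell(
                        attribute=attr,
                        polarity=polarity,
                        interval_class=cls,
                        r=r,
                        p_value=p,
                        strength=strength_class(r),
                    )
                )
    if bh_correct:
        ps = np.array([c.p_value for c in cells])
        adj = _benjamini_hochberg(ps)
        cells = [
            CorrelationCell(c.attribute, c.polarity, c.interval_class, c.r, float(q), c.strength)
            for c, q in zip(cells, adj)
        ]
    return cells


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    return stats.false_discovery_control(p, method="bh")


def correlation_frame(cells: list[CorrelationCell]) -> pd.DataFrame:
    """Cells pivoted to the conventional 16 × 4 layout.

    Rows are attribute × polarity (matched rows first per attribute),
    columns the four interval classes; values are r.
    """
    df = pd.DataFrame([c.__dict__ for c in cells])
    df["row"] = np.where(
        df["polarity"] == "matched", df["attribute"] + " (M)", df["attribute"] + " (N)"
    )
    rows = [f"{a} ({p})" for a in ATTRIBUTES for p in ("M", "N")]
    wide = df.pivot(index="row", columns="interval_class", values="r")
    return wide.loc[rows, list(INTERVAL_CLASSES)]


def scatter_fit_export(
    pair_table: pd.DataFrame, attribute: str, polarity: str
) -> dict:
    """Scatter points (I, attribute value) and their OLS fit line.

    Returns a dict with the points as parallel lists plus slope, intercept
    and r of the least-squares line — the data behind a scatterplot, ready
    for serialization.
    """
    col = f"{polarity}_{attribute}"
    if col not in pair_table.columns:
        raise ValueError(f"pair table has no column {col!r}")
    x = pair_table["I"].to_numpy(dtype=float)
    y = pair_table[col].to_numpy(dtype=float)
    fit = stats.linregress(x, y)
    return {
        "attribute": attribute,
        "polarity": polarity,
        "I": x.tolist(),
        "value": y.tolist(),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r": float(fit.rvalue),
    }
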