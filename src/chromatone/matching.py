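"""Cross-modal matching selections and their rank-weighted aggregation.

After hearing an interval stimulus, each subject picks the first, second and
third best-matching color materials, and likewise the three most mismatched
ones.  Per interval and polarity the raw picks are cleaned by removing every
selection falling in the color categories chosen least often (outlier
categories), then each perceptual attribute is aggregated with 3:2:1 rank
weights:

    value = (3·v1 + 2·v2 + v3) / 6

where v_j is the mean attribute value of the surviving rank-j picks.  The
result is one row per interval, pairing the interval's consonance index I
with the 8 matched and 8 mismatched aggregated attribute values.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .ratings import ATTRIBUTES

__all__ = [
    "RANK_WEIGHTS",
    "validate_selections",
    "selection_histogram",
    "prune_least_frequent",
    "weighted_attribute",
    "build_pair_table",
    "selection_reliability",
]

logger = logging.getLogger(__name__)

#: Rank weights for the first/second/third pick; they sum to 1.
RANK_WEIGHTS = {1: 3.0 / 6.0, 2: 2.0 / 6.0, 3: 1.0 / 6.0}

_REQUIRED = ["subject_id", "interval_id", "interval_class", "polarity", "rank", "material_id"]

INTERVAL_CLASSES = (
    "piano-harmonic",
    "piano-melodic",
    "violin-harmonic",
    "violin-melodic",
)


def validate_selections(records: pd.DataFrame) -> pd.DataFrame:
    """Schema-check a selection table; returns the validated frame.

    Enforces polarity in {matched, mismatched}, rank in {1,2,3}, and
    uniqueness of (subject, interval, polarity, rank) per presentation.
    """
    missing = set(_REQUIRED) - set(records.columns)
    if missing:
        raise ValueError(f"selection table missing columns: {sorted(missing)}")
    bad_pol = set(records["polarity"].unique()) - {"matched", "mismatched"}
    if bad_pol:
        raise ValueError(f"unknown polarity values: {sorted(bad_pol)}")
    if not records["rank"].isin([1, 2, 3]).all():
        raise ValueError("ranks must be in {1, 2, 3}")
    key_cols = ["subject_id", "interval_id", "polarity", "rank"]
    if "is_repeat" in records.columns:
        key_cols = key_cols + ["is_repeat"]
    if records.duplicated(subset=key_cols).any():
        dup = records[records.duplicated(subset=key_cols)].iloc[0]
        raise ValueError(
            "duplicate selection for "
            f"(subject={dup['subject_id']}, interval={dup['interval_id']}, "
            f"polarity={dup['polarity']}, rank={dup['rank']})"
        )
    return records


def _slice(records: pd.DataFrame, interval_id, polarity: str) -> pd.DataFrame:
    sub = records[(records["interval_id"] == interval_id) & (records["polarity"] == polarity)]
    if sub.empty:
        raise ValueError(f"no selections for interval {interval_id!r} / {polarity!r}")
    return sub


def selection_histogram(
    records: pd.DataFrame, interval_id, polarity: str, n_categories: int = 16
) -> pd.Series:
    """Selection counts per color category for one interval and polarity.

    All subjects and all three ranks are pooled; categories never selected
    appear with count 0.
    """
    sub = _slice(records, interval_id, polarity)
    if "material_category" not in sub.columns:
        raise ValueError("records need a material_category column (join materials first)")
    counts = sub["material_category"].value_counts()
    return counts.reindex(range(1, n_categories + 1), fill_value=0).sort_index()


def prune_least_frequent(
    records: pd.DataFrame, interval_id, polarity: str, n_categories: int = 16
) -> pd.DataFrame:
    """Drop selections in the least-frequently chosen color categories.

    All categories attaining the minimum positive count are removed
    together (ties prune jointly).  Two degenerate cases skip pruning with
    a logged warning: a uniform histogram (every category equally frequent,
    removal would be arbitrary or total) and a pruning that would leave some
    rank with no surviving selections.
    """
    sub = _slice(records, interval_id, polarity)
    hist = selection_histogram(records, interval_id, polarity, n_categories)
    positive = hist[hist > 0]
    if positive.nunique() == 1 and len(positive) > 1 or len(positive) == 1:
        logger.warning(
            "interval %s/%s: uniform selection histogram, pruning skipped",
            interval_id, polarity,
        )
        return sub
    min_count = positive.min()
    doomed = set(positive[positive == min_count].index)
    kept = sub[~sub["material_category"].isin(doomed)]
    if set(kept["rank"].unique()) != {1, 2, 3}:
        logger.warning(
            "interval %s/%s: pruning would empty a rank, skipped",
            interval_id, polarity,
        )
        return sub
    return kept


def weighted_attribute(
    records: pd.DataFrame,
    interval_id,
    polarity: str,
    attribute: str,
    F: pd.DataFrame,
    consensus: str = "mean",
) -> float:
    """3:2:1 rank-weighted aggregate of one attribute over subjects' picks.

    Parameters
    ----------
    records
        (Pruned) selection records.
    F
        Materials × attributes table of mean attribute values.
    consensus
        Across-subject consensus per rank: ``"mean"`` (mean attribute value
        of that rank's picks, default) or ``"mode"`` (attribute value of the
        modal material at that rank; lowest id breaks ties).

    With a single subject both rules reduce to the plain weighted formula
    on that subject's three picks.
    """
    if attribute not in ATTRIBUTES:
        raise ValueError(f"unknown attribute {attribute!r}")
    if consensus not in ("mean", "mode"):
        raise ValueError(f"consensus must be 'mean' or 'mode', got {consensus!r}")
    sub = _slice(records, interval_id, polarity)
    unknown = set(sub["material_id"]) - set(F.index)
    if unknown:
        raise ValueError(f"materials without attribute vectors: {sorted(unknown)[:5]}")
    total = 0.0
    for rank, weight in RANK_WEIGHTS.items():
        picks = sub[sub["rank"] == rank]["material_id"]
        if picks.empty:
            raise ValueError(f"no surviving selections at rank {rank} for interval {interval_id}")
        if consensus == "mean":
            v = F.loc[picks, attribute].mean()
        else:
            modal = picks.mode().min()
            v = F.loc[modal, attribute]
        total += weight * float(v)
    return total


def build_pair_table(
    records: pd.DataFrame,
    interval_class: str,
    F: pd.DataFrame,
    stimuli: pd.DataFrame,
    prune: bool = True,
    consensus: str = "mean",
    n_categories: int = 16,
) -> pd.DataFrame:
    """Join consonance index with aggregated attributes for one class.

    Returns a 13-row table (one per interval of the class) indexed by
    interval_id with columns ``I`` plus ``matched_<attr>`` and
    ``mismatched_<attr>`` for each of the 8 attributes.

    ``stimuli`` maps interval_id to interval_class, abbreviation and the
    consonance index ``I``.
    """
    if interval_class not in INTERVAL_CLASSES:
        raise ValueError(f"unknown interval class {interval_class!r}")
    class_stim = stimuli[stimuli["interval_class"] == interval_class]
    if len(class_stim) != 13:
        raise ValueError(
            f"expected 13 stimuli for class {interval_class!r}, got {len(class_stim)}"
        )
    cls_records = records[records["interval_class"] == interval_class]
    rows = {}
    for _, stim in class_stim.iterrows():
        iid = stim["interval_id"]
        row = {"I": float(stim["I"])}
        for polarity in ("matched", "mismatched"):
            sel = cls_records[
                (cls_records["interval_id"] == iid) & (cls_records["polarity"] == polarity)
            ]
            if sel.empty:
                raise ValueError(
                    f"missing selections for interval {iid} ({stim['abbreviation']}) "
                    f"/ {polarity}"
                )
            use = (
                prune_least_frequent(cls_records, iid, polarity, n_categories)
                if prune
                else sel
            )
            for attr in ATTRIBUTES:
                row[f"{polarity}_{attr}"] = weighted_attribute(
                    use, iid, polarity, attr, F, consensus=consensus
                )
        rows[iid] = row
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "interval_id"
    return table


def selection_reliability(
    records: pd.DataFrame,
    F: pd.DataFrame,
    attribute: str = "CW",
    ddof: int = 1,
) -> pd.Series:
    """Cronbach's alpha of matched selections per interval class.

    Subjects are the raters and the class's intervals the items; each cell
    is the subject's own 3:2:1-weighted attribute value, so the alpha
    measures how consistently subjects translate intervals into colors.
    """
    from .ratings import cronbach_alpha

    out = {}
    matched = records[records["polarity"] == "matched"]
    for cls in INTERVAL_CLASSES:
        sub = matched[matched["interval_class"] == cls]
        if sub.empty:
            continue
        vals = sub.assign(value=F.loc[sub["material_id"], attribute].to_numpy())
        weights = vals["rank"].map(RANK_WEIGHTS)
        vals = vals.assign(weighted=vals["value"] * weights)
        cell = vals.groupby(["interval_id", "subject_id"])["weighted"].sum().unstack()
        out[cls] = cronbach_alpha(cell.to_numpy(), ddof=ddof)
    return pd.Series(out, name="alpha")
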