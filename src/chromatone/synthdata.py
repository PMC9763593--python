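"""Synthetic study data with a planted consonance → color-attribute link.

The generator emulates the structure of a two-part subjective experiment:

1. *Rating part* — 16 subjects score 50 three-color materials (grouped into
   16 perceptual categories) on 8 attributes, 1–5 scale.  Each material
   carries a latent "true" attribute profile drawn around its category's
   center; a subject's score is the true value plus Gaussian noise of scale
   (1−ρ)·σ0, rounded and clipped to the scale.  ρ ∈ [0, 1] is the
   consistency knob: ρ = 1 makes all subjects identical.

2. *Matching part* — 23 subjects hear 52 interval stimuli (13 two-tone
   relations × {piano, violin} × {harmonic, melodic}, plus 12 repeated
   presentations) and pick 3 matched and 3 mismatched materials each.  The
   planted ground truth is a target attribute profile that drifts linearly
   with the stimulus consonance index I: g_d(I) = 3 + b_d·(I − Ī).  Matched
   picks are drawn with probability ∝ exp(−‖F_mat − g(I)‖²/τ) and ranked by
   proximity; mismatched picks come from the complementary (far) tail.  The
   planted slopes b_d are zero for the violin classes, so those correlations
   are null by construction.  A small lapse probability replaces a pick with
   a uniformly random material, injecting the rare singleton categories the
   pruning rule exists to remove.

The Gaussian-round-clip rating model and the softmax choice rule are
modelling assumptions, not measured properties of human raters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .consonance import DEFAULT_Q, consonance_table
from .matching import INTERVAL_CLASSES, validate_selections
from .ratings import ATTRIBUTES, RatingTable

__all__ = [
    "GeneratorConfig",
    "gen_color_materials",
    "gen_ratings",
    "gen_interval_stimuli",
    "gen_matching",
    "generate_all",
    "write_fixtures",
]

#: Planted attribute drift per dB of consonance for the piano classes.
#: Signs: more consonant intervals map to cooler, softer, more transparent,
#: farther, weaker, less arousing, less dominant but more pleasant colors.
DEFAULT_SLOPES: dict[str, float] = {
    "CW": -0.03, "SH": -0.03, "TT": -0.03, "FN": -0.03,
    "WS": -0.03, "P": 0.03, "A": -0.03, "D": -0.03,
}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study, with the study-sized defaults."""

    n_materials: int = 50
    n_categories: int = 16
    n_color_subjects: int = 16
    n_match_subjects: int = 23
    n_repeats: int = 12
    rho: float = 0.8           # subject consistency in [0, 1]
    sigma0: float = 1.0        # rating noise scale at rho = 0
    slopes: dict = field(default_factory=lambda: dict(DEFAULT_SLOPES))
    violin_null: bool = True   # zero slopes for violin classes
    tau: float = 0.5           # softmax temperature on squared attr distance
    lapse: float = 0.02        # per-pick probability of a random material
    Q: float = DEFAULT_Q
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0.0 <= self.lapse < 1.0:
            raise ValueError("lapse must be in [0, 1)")
        for n in (self.n_materials, self.n_categories, self.n_color_subjects,
                  self.n_match_subjects):
            if n < 1:
                raise ValueError("counts must be positive")
        if self.n_repeats > 13 * len(INTERVAL_CLASSES):
            raise ValueError("more repeats than stimuli")
        if set(self.slopes) != set(ATTRIBUTES):
            raise ValueError("slopes must cover exactly the 8 attributes")

    @property
    def n_intervals(self) -> int:
        return 13 * len(INTERVAL_CLASSES)

    def class_slopes(self, interval_class: str) -> dict[str, float]:
        if self.violin_null and interval_class.startswith("violin"):
            return {a: 0.0 for a in ATTRIBUTES}
        return dict(self.slopes)


def gen_color_materials(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Materials with CIELAB triplets, category labels and latent attributes.

    Categories are attribute-coherent: each category has an attribute
    center drawn uniformly in [1.5, 4.5] and its materials scatter around
    it with sd (1−ρ), so at high consistency the within-category variance
    is far below the between-category variance.
    """
    n, n_cat = config.n_materials, config.n_categories
    # guarantee every category appears at least once
    categories = np.concatenate(
        [np.arange(1, n_cat + 1), rng.integers(1, n_cat + 1, size=n - n_cat)]
    )[:n]
    rng.shuffle(categories)
    centers = rng.uniform(1.5, 4.5, size=(n_cat, len(ATTRIBUTES)))
    within_sd = max(1.0 - config.rho, 0.05)
    true = np.clip(
        centers[categories - 1] + rng.normal(0, within_sd, size=(n, len(ATTRIBUTES))),
        1.0, 5.0,
    )
    out = {"material_id": np.arange(1, n + 1), "category": categories}
    for i in range(3):  # three colors per material
        out[f"L{i + 1}"] = rng.uniform(5, 95, size=n)
        out[f"a{i + 1}"] = rng.uniform(-100, 100, size=n)
        out[f"b{i + 1}"] = rng.uniform(-100, 100, size=n)
    for j, attr in enumerate(ATTRIBUTES):
        out[f"true_{attr}"] = true[:, j]
    return pd.DataFrame(out)


def gen_ratings(
    materials: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator
) -> RatingTable:
    """Complete subjects × materials × attributes grid of noisy 1–5 scores."""
    noise_sd = (1.0 - config.rho) * config.sigma0
    true = materials[[f"true_{a}" for a in ATTRIBUTES]].to_numpy()
    n_subj, n_mat = config.n_color_subjects, len(materials)
    noisy = true[None, :, :] + rng.normal(0, noise_sd, size=(n_subj, n_mat, len(ATTRIBUTES)))
    scores = np.clip(np.rint(noisy), 1, 5).astype(int)
    subj, mat, attr = np.meshgrid(
        np.arange(1, n_subj + 1),
        materials["material_id"].to_numpy(),
        np.arange(len(ATTRIBUTES)),
        indexing="ij",
    )
    df = pd.DataFrame(
        {
            "subject_id": subj.ravel(),
            "material_id": mat.ravel(),
            "attribute": np.array(ATTRIBUTES)[attr.ravel()],
            "score": scores.ravel(),
        }
    )
    return RatingTable(df)


def gen_interval_stimuli(
    config: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """52 stimuli (4 classes × 13 relations) tagged with consonance, plus
    a without-replacement sample of 12 repeat ids."""
    cons = consonance_table(Q=config.Q)
    rows = []
    iid = 0
    for cls in INTERVAL_CLASSES:
        for _, c in cons.iterrows():
            iid += 1
            rows.append(
                {
                    "interval_id": iid,
                    "interval_class": cls,
                    "abbreviation": c["abbreviation"],
                    "I": c["I"],
                    "category": c["category"],
                }
            )
    stim = pd.DataFrame(rows)
    repeat_ids = rng.choice(stim["interval_id"].to_numpy(), size=config.n_repeats, replace=False)
    stim["repeat"] = stim["interval_id"].isin(repeat_ids)
    return stim


def _selection_weights(
    F_true: np.ndarray, g: np.ndarray, tau: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(matched weights, mismatched weights, squared distances) over materials."""
    d2 = ((F_true - g[None, :]) ** 2).sum(axis=1)
    wm = np.exp(-(d2 - d2.min()) / tau)
    wn = np.exp((d2 - d2.max()) / tau)
    return wm / wm.sum(), wn / wn.sum(), d2


def gen_matching(
    materials: pd.DataFrame,
    stimuli: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Ranked matched/mismatched selections for every subject × stimulus.

    Repeated stimuli appear a second time with ``is_repeat=True`` under the
    same interval_id.
    """
    F_true = materials[[f"true_{a}" for a in ATTRIBUTES]].to_numpy()
    mat_ids = materials["material_id"].to_numpy()
    mat_cat = materials.set_index("material_id")["category"]
    I_bar = stimuli.groupby("interval_class")["I"].transform("mean")
    n_mat = len(materials)

    presentations = [(row, False) for _, row in stimuli.iterrows()]
    presentations += [(row, True) for _, row in stimuli.iterrows() if row["repeat"]]

    records = []
    for stim, is_repeat in presentations:
        slopes = config.class_slopes(stim["interval_class"])
        centered = stim["I"] - I_bar.loc[stim.name]
        g = np.array([3.0 + slopes[a] * centered for a in ATTRIBUTES])
        wm, wn, d2 = _selection_weights(F_true, g, config.tau)
        for subject in range(1, config.n_match_subjects + 1):
            for polarity, w, order_sign in (("matched", wm, 1.0), ("mismatched", wn, -1.0)):
                if np.count_nonzero(w) >= 3:
                    idx = rng.choice(n_mat, size=3, replace=False, p=w)
                else:
                    # tau -> 0 limit: weights degenerate, take the extreme 3
                    idx = np.argsort(order_sign * d2)[:3]
                # rank by proximity (matched) or remoteness (mismatched)
                idx = idx[np.argsort(order_sign * d2[idx])]
                picks = list(idx)
                for slot in range(3):
                    if rng.random() < config.lapse:
                        pool = np.setdiff1d(np.arange(n_mat), picks)
                        picks[slot] = int(rng.choice(pool))
                for rank, i in enumerate(picks, start=1):
                    records.append(
                        (
                            subject,
                            stim["interval_id"],
                            stim["interval_class"],
                            polarity,
                            rank,
                            mat_ids[i],
                            is_repeat,
                        )
                    )
    df = pd.DataFrame(
        records,
        columns=[
            "subject_id", "interval_id", "interval_class",
            "polarity", "rank", "material_id", "is_repeat",
        ],
    )
    df["material_category"] = mat_cat.loc[df["material_id"]].to_numpy()
    return validate_selections(df)


def generate_all(config: GeneratorConfig) -> dict[str, object]:
    """Run all four generators with a single seeded stream.

    Returns a dict with materials, ratings (RatingTable), stimuli and
    selections, plus the config used.
    """
    rng = np.random.default_rng(config.seed)
    materials = gen_color_materials(config, rng)
    ratings = gen_ratings(materials, config, rng)
    stimuli = gen_interval_stimuli(config, rng)
    selections = gen_matching(materials, stimuli, config, rng)
    return {
        "config": config,
        "materials": materials,
        "ratings": ratings,
        "stimuli": stimuli,
        "selections": selections,
    }


def write_fixtures(tables: dict[str, object], out_dir: str | Path) -> dict[str, Path]:
    """Write the generated tables as CSVs plus a config.yaml echo.

    Files round-trip losslessly through the readers in
    :mod:`chromatone.io`; writing the re-read tables reproduces the bytes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    frames = {
        "materials": tables["materials"],
        "ratings": tables["ratings"].data,
        "stimuli": tables["stimuli"],
        "selections": tables["selections"],
    }
    for name, df in frames.items():
        paths[name] = out / f"{name}.csv"
        df.to_csv(paths[name], index=False)
    config = tables["config"]
    paths["config"] = out / "config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump({"generator": asdict(config)}, fh, sort_keys=True)
    return paths
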