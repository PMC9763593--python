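"""End-to-end pipeline: consonance table → reliability → aggregation →
correlation → models, with a manifest recording seeds and output hashes."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .consonance import DEFAULT_Q, consonance_table
from .correlation import correlation_frame, correlation_matrix
from .matching import INTERVAL_CLASSES, build_pair_table
from .models import ModelSpec, kfold_cv
from .ratings import attribute_vectors, reliability_report
from . import io as cio

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths and parameters for a full analysis run."""

    materials: str
    ratings: str
    stimuli: str
    selections: str
    out_dir: str
    Q: float = DEFAULT_Q
    literal_amplitude: bool = False
    consensus: str = "mean"
    prune: bool = True
    cv_folds: int = 10
    model_families: tuple = ("MLR",)
    seed: int = 0


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle.

    Outputs under ``config.out_dir``: consonance.csv, alpha.csv, F.csv,
    pairs/<class>.csv, correlations.csv (+ .json), model reports and a
    manifest.json with the config echo and per-file SHA-256 hashes.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    materials = stage("read_materials", lambda: cio.read_materials(config.materials))
    ratings = stage("read_ratings", lambda: cio.read_ratings(config.ratings))
    stimuli = stage("read_stimuli", lambda: cio.read_stimuli(config.stimuli))
    selections = stage(
        "read_selections", lambda: cio.read_selections(config.selections, materials)
    )

    cons = stage(
        "consonance",
        lambda: consonance_table(Q=config.Q, literal_amplitude=config.literal_amplitude),
    )
    written["consonance"] = cio.write_table(cons, out / "consonance.csv")

    alphas = stage("reliability", lambda: reliability_report(ratings))
    written["alpha"] = cio.write_table(alphas, out / "alpha.csv")

    F = stage("attributes", lambda: attribute_vectors(ratings))
    written["F"] = cio.write_table(F, out / "F.csv", index=True)

    pair_tables = {}
    for cls in INTERVAL_CLASSES:
        pair_tables[cls] = stage(
            f"aggregate[{cls}]",
            lambda cls=cls: build_pair_table(
                selections, cls, F, stimuli,
                prune=config.prune, consensus=config.consensus,
            ),
        )
        written[f"pairs/{cls}"] = cio.write_table(
            pair_tables[cls], out / "pairs" / f"{cls}.csv", index=True
        )

    cells = stage("correlate", lambda: correlation_matrix(pair_tables))
    written["correlations"] = cio.write_table(
        correlation_frame(cells), out / "correlations.csv", index=True
    )
    corr_json = out / "correlations.json"
    corr_json.write_text(json.dumps([c.__dict__ for c in cells], indent=1))
    written["correlations_json"] = corr_json

    reports = []
    for family in config.model_families:
        for cls in INTERVAL_CLASSES:
            table = pair_tables[cls]
            X = table[[f"matched_{a}" for a in _attrs()]].to_numpy()
            y = table["I"].to_numpy()
            spec = ModelSpec(
                family=family, direction="audio", interval_class=cls, seed=config.seed
            )
            report = stage(
                f"fit[{family},{cls}]",
                lambda spec=spec, X=X, y=y: kfold_cv(spec, X, y, k=config.cv_folds),
            )
            reports.append(report.to_dict())
    models_json = out / "models.json"
    models_json.write_text(json.dumps(reports, indent=1))
    written["models"] = models_json

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "hashes": {k: _sha256(p) for k, p in written.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return {
        "pair_tables": pair_tables,
        "correlations": cells,
        "model_reports": reports,
        "manifest": manifest,
    }


def _attrs():
    from .ratings import ATTRIBUTES

    return ATTRIBUTES
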