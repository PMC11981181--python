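"""End-to-end orchestration: simulate -> extract -> stats -> model -> explain.

A single YAML config drives the whole reproduction run; every output
embeds the seed and a hash of the resolved config for provenance. The
report juxtaposes the computed cohort statistics and per-shape model
metrics with the published reference values so a reader can compare them
at a glance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_stats
from . import explain as interpretation
from . import model as screening
from . import recording_io, synthetic
from .features import FeatureConfig, extract_feature_table

#: Published reference values the report juxtaposes with computed ones.
REFERENCE = {
    "table1": {"srs2_t": 6.682, "srs2_df": 21, "age_df": 26, "n_high": 20, "n_low": 113},
    "table3": {
        "equilateral_triangle": {"accuracy": 0.985, "sensitivity": 0.900, "specificity": 1.000},
        "inverted_triangle": {"accuracy": 1.000, "sensitivity": 1.000, "specificity": 1.000},
        "square": {"accuracy": 0.985, "sensitivity": 0.900, "specificity": 1.000},
        "sun": {"accuracy": 0.977, "sensitivity": 0.850, "specificity": 1.000},
        "all_features": {"accuracy": 1.000, "sensitivity": 1.000, "specificity": 1.000},
    },
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    out_dir: str = "drawscreen_out"
    seed: int = 0
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    features: dict = field(default_factory=dict)  # FeatureConfig overrides
    search: dict = field(default_factory=dict)  # SearchConfig overrides
    write_recordings: bool = True
    include_all_features: bool = True
    make_plots: bool = False
    stages: tuple[str, ...] = ("simulate", "extract", "cohort_stats", "train", "explain")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown key(s) {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.resolved(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _provenance(cfg: PipelineConfig) -> dict:
    return {"seed": cfg.seed, "config_hash": cfg.config_hash}


def _dump_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=float) + "\n")


def cv_result_to_dict(spec: screening.ModelSpec, res: screening.CVResult) -> dict:
    return {
        "shape": spec.shape_id,
        "selected_features": list(spec.selected_features),
        "cost": spec.cost,
        "standardization": spec.standardization,
        "counts": dataclasses.asdict(res.counts),
        "accuracy": res.accuracy,
        "sensitivity": res.sensitivity,
        "specificity": res.specificity,
        "n_degenerate_folds": res.n_degenerate_folds,
        "predictions": res.predictions.to_dict(orient="records"),
    }


def run_end_to_end(cfg: PipelineConfig) -> dict:
    """Run the configured stages; returns a dict of produced paths.

    Produces cohort.csv, per-shape feature sheets, table1.json, per-shape
    result and SHAP files, and report.json. Deterministic under a fixed
    seed and config.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    report: dict = {"provenance": _provenance(cfg), "reference": REFERENCE}

    spec = synthetic.CohortSpec(**{**cfg.cohort, "seed": cfg.seed})
    fcfg = FeatureConfig(**cfg.features)

    try:
        cohort, recordings = synthetic.generate_cohort(spec)
    except Exception as exc:
        raise PipelineError(f"stage simulate failed: {exc}") from exc
    cohort_path = out / "cohort.csv"
    cohort.to_csv(cohort_path, index=False)
    paths["cohort"] = str(cohort_path)
    if cfg.write_recordings and "simulate" in cfg.stages:
        rec_dir = out / "recordings"
        rec_dir.mkdir(exist_ok=True)
        for rec in recordings:
            recording_io.write_recording(
                rec, rec_dir / f"{rec.participant_id}_{rec.shape_id}_{rec.phase}.csv"
            )
        paths["recordings"] = str(rec_dir)

    try:
        tables = extract_feature_table(recordings, fcfg)
    except Exception as exc:
        raise PipelineError(f"stage extract failed: {exc}") from exc
    labels_by_pid = dict(zip(cohort["participant_id"], cohort["group"]))
    sheets: dict[str, pd.DataFrame] = {}
    for shape, df in tables.items():
        df = df.copy()
        df.insert(1, "group", df["participant_id"].map(labels_by_pid))
        sheets[shape] = df
        p = out / f"features_{shape}.csv"
        recording_io.write_feature_sheet(df, p)
        paths[f"features_{shape}"] = str(p)

    if "cohort_stats" in cfg.stages:
        try:
            table1 = cohort_stats.cohort_summary(cohort)
        except Exception as exc:
            raise PipelineError(f"stage cohort_stats failed: {exc}") from exc
        table1.update(_provenance(cfg))
        _dump_json(table1, out / "table1.json")
        paths["table1"] = str(out / "table1.json")
        report["table1"] = table1

    if "train" in cfg.stages:
        search = screening.SearchConfig(**cfg.search)
        report["models"] = {}
        model_specs: dict[str, screening.ModelSpec] = {}
        targets = dict(sheets)
        if cfg.include_all_features and len(sheets) > 1:
            targets["all_features"] = screening.build_all_features_table(sheets)
        for shape, df in targets.items():
            try:
                sel = screening.select_model(df, df["group"], search, shape_id=shape)
            except Exception as exc:
                raise PipelineError(f"stage train failed for {shape}: {exc}") from exc
            model_specs[shape] = sel.spec
            result = cv_result_to_dict(sel.spec, sel.cv)
            result.update(_provenance(cfg))
            result["n_search_evaluations"] = sel.n_evaluations
            _dump_json(result, out / f"result_{shape}.json")
            paths[f"result_{shape}"] = str(out / f"result_{shape}.json")
            report["models"][shape] = {
                k: result[k]
                for k in ("accuracy", "sensitivity", "specificity", "selected_features", "cost")
            }

        if "explain" in cfg.stages:
            for shape, mspec in model_specs.items():
                df = targets[shape]
                try:
                    shap = interpretation.explain_model(df, df["group"], mspec)
                except Exception as exc:
                    raise PipelineError(f"stage explain failed for {shape}: {exc}") from exc
                sdf = shap.to_frame()
                sdf.insert(0, "participant_id", df["participant_id"].to_numpy())
                sdf["base_value"] = shap.base_value
                sdf["decision_value"] = shap.decision_values
                p = out / f"shap_{shape}.csv"
                sdf.to_csv(p, index=False, float_format="%.10g")
                paths[f"shap_{shape}"] = str(p)
                report.setdefault("feature_impact", {})[shape] = (
                    interpretation.feature_impact_ranking(shap)
                )
                if cfg.make_plots:
                    X = df[list(mspec.selected_features)].to_numpy(float)
                    interpretation.beeswarm_summary(shap, X, out / f"shap_{shape}.png")

    _dump_json(report, out / "report.json")
    paths["report"] = str(out / "report.json")
    return paths
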