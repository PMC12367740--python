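"""Configuration-driven orchestration of the full triage analysis.

Stages: simulate → assemble → tiers → select → train → fuse → cascade →
evaluate. Each stage reads its predecessor's artifacts from the output
directory and writes versioned CSV/JSON artifacts plus a manifest with a
config hash, per-stage seeds, row counts, file checksums and timings.
A rerun with the same config and seed reproduces identical artifacts
except the timings.

A single global seed derives per-stage seeds through a fixed counter
(simulate +0, split +1, select +2, train +3, fuse +4, evaluate +5), so
every stage is individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
import yaml

from stroketriage import assembly, cascade as cascade_mod, evaluation
from stroketriage.cohort import CohortSpec, cohort_tables, generate_cohort
from stroketriage.cohort import ValidationError
from stroketriage.models import (
    REFERENCE_MODELS,
    ModelSpec,
    TrainedModel,
    TuningConfig,
    stratified_split,
    tune_and_fit,
)
from stroketriage.moga import GAConfig, ga_select

logger = logging.getLogger(__name__)

STAGES = ("simulate", "assemble", "tiers", "select", "train", "fuse", "cascade", "evaluate")
_STAGE_SEED = {"simulate": 0, "split": 1, "select": 2, "train": 3, "fuse": 4, "evaluate": 5}

TASKS = ("ischemic", "hemorrhagic", "lvo")


@dataclass
class RunConfig:
    """Everything one analysis run needs; loadable from YAML/JSON."""

    n_episodes: int = 500
    seed: int = 0
    out_dir: str = "runs/default"
    stages: Sequence[str] = STAGES
    cutoffs: Sequence[float] = assembly.DEFAULT_CUTOFFS
    tier_cutoff: float = 0.05  # tier used for modeling
    ga_population: int = 20
    ga_generations: int = 10
    ga_enabled: bool = True
    #: classifier evaluated inside the GA wrapper: "surrogate" scores masks
    #: with a fast shallow decision tree; "reference" uses each task's
    #: reference model (slower, tighter coupling to the final fit)
    ga_wrapped_model: str = "surrogate"
    provided_features: Mapping[str, Sequence[str]] | None = None  # per task, bypasses GA
    use_reference_models: bool = True
    scoring: Mapping[str, str] = field(
        default_factory=lambda: {"ischemic": "recall", "hemorrhagic": "precision", "lvo": "auc"}
    )
    smote_tasks: Sequence[str] = ("hemorrhagic",)
    prior_grid: Sequence[float] = tuple(np.round(np.arange(0.05, 1.0, 0.05), 2).tolist())
    lvo_threshold: float = 0.5
    train_fraction: float = 0.7
    bootstrap_resamples: int = 200
    cohort_overrides: Mapping[str, object] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        order = [STAGES.index(s) for s in self.stages if s in STAGES]
        if sorted(order) != order or len(self.stages) == 0:
            raise ValidationError("stages must be a valid ordered subset of the pipeline")
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValidationError(f"unknown stage(s) {unknown}; valid: {list(STAGES)}")

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(n_episodes=self.n_episodes, **dict(self.cohort_overrides))

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)  # hash identifies the analysis, not its location
        return hashlib.sha256(
            json.dumps(_jsonable(payload), sort_keys=True).encode()
        ).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    return obj


def _write_json(path: Path, data) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(data), fh, indent=2, sort_keys=True)
        fh.write("\n")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise ValidationError(
            f"missing predecessor artifact {path.name!r}; run the {producer!r} stage first"
        )
    return path


class PipelineRunner:
    """Executes pipeline stages against one output directory."""

    def __init__(self, config: RunConfig):
        config.validate()
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.timings: dict[str, float] = {}

    # -- stages ------------------------------------------------------------

    def simulate(self) -> None:
        cfg = self.config
        records = generate_cohort(cfg.cohort_spec(), seed=cfg.seed + _STAGE_SEED["simulate"])
        clinical, hemo, histories = cohort_tables(records)
        clinical.to_csv(self.out / "clinical.csv", index=False)
        hemo.to_csv(self.out / "trends.csv", index=False)
        histories.to_csv(self.out / "histories.csv", index=False)

    def assemble(self) -> None:
        clinical = pd.read_csv(_require(self.out / "clinical.csv", "simulate"))
        hemo = pd.read_csv(_require(self.out / "trends.csv", "simulate"))
        histories = pd.read_csv(_require(self.out / "histories.csv", "simulate"))
        master = assembly.merge_sources(clinical, hemo, histories)
        master.features.to_csv(self.out / "master_features.csv")
        master.labels.to_csv(self.out / "master_labels.csv")
        master.variables.to_csv(self.out / "master_variables.csv", index=False)

    def _load_master(self) -> assembly.MasterDataset:
        features = pd.read_csv(_require(self.out / "master_features.csv", "assemble"), index_col=0)
        labels = pd.read_csv(_require(self.out / "master_labels.csv", "assemble"), index_col=0)
        variables = pd.read_csv(_require(self.out / "master_variables.csv", "assemble"))
        return assembly.MasterDataset(features, labels, variables)

    def tiers(self) -> None:
        master = self._load_master()
        tiers = assembly.completeness_cascade(master, self.config.cutoffs)
        _write_json(self.out / "tiers.json", [t.to_manifest() for t in tiers])

    def _tier_columns(self) -> list[str]:
        tiers = json.loads(_require(self.out / "tiers.json", "tiers").read_text())
        for t in tiers:
            if abs(t["cutoff"] - self.config.tier_cutoff) < 1e-9:
                return t["variables"]
        raise ValidationError(f"tier cutoff {self.config.tier_cutoff} not in tiers.json")

    def _numeric_matrix(self, X: pd.DataFrame) -> pd.DataFrame:
        """GA-facing all-numeric view (sex as indicator, ordinals as codes)."""
        out = X.copy()
        if "sex" in out.columns:
            out["sex"] = (out["sex"] == "female").astype(float)
        if "scale_result" in out.columns:
            out["scale_result"] = out["scale_result"].map(
                {"positive": 1.0, "negative": 0.0}
            )
        for c in out.columns:
            out[c] = pd.to_numeric(out[c], errors="coerce")
        return out.fillna(out.median(numeric_only=True)).fillna(0.0)

    def select(self) -> None:
        cfg = self.config
        master = self._load_master()
        columns = self._tier_columns()
        selected: dict[str, list[str]] = {}
        fronts: dict[str, list[dict]] = {}
        for task in TASKS:
            if not cfg.ga_enabled:
                provided = (cfg.provided_features or {}).get(task)
                if provided is None:
                    raise ValidationError(
                        f"GA disabled but no provided_features for task {task!r}"
                    )
                selected[task] = list(provided)
                fronts[task] = []
                continue
            X, y = assembly.build_task_matrix(master, task, variables=columns)
            Xn = self._numeric_matrix(X)
            ga_cfg = GAConfig(
                population_size=cfg.ga_population,
                generations=cfg.ga_generations,
                scoring="f1",
                seed=cfg.seed + _STAGE_SEED["select"],
            )
            if cfg.ga_wrapped_model == "reference":
                estimator = REFERENCE_MODELS[task].make_estimator(seed=ga_cfg.seed)
            else:
                from sklearn.tree import DecisionTreeClassifier

                estimator = DecisionTreeClassifier(max_depth=3, random_state=ga_cfg.seed)
            front, history = ga_select(Xn.to_numpy(), y.to_numpy(), estimator, ga_cfg)
            best = max(front, key=lambda ind: (ind.objectives[1], -ind.objectives[0]))
            selected[task] = [c for c, keep in zip(Xn.columns, best.mask) if keep]
            fronts[task] = [
                {
                    "mask": "".join("1" if b else "0" for b in ind.mask),
                    "n_selected": ind.objectives[0],
                    "cv_score": ind.objectives[1],
                }
                for ind in front
            ]
            _write_json(self.out / f"ga_history_{task}.json", history)
        _write_json(self.out / "selected_features.json", selected)
        _write_json(self.out / "ga_fronts.json", fronts)

    def train(self) -> None:
        cfg = self.config
        master = self._load_master()
        selected = json.loads(_require(self.out / "selected_features.json", "select").read_text())
        summaries = {}
        split_seed = cfg.seed + _STAGE_SEED["split"]
        for task in TASKS:
            X, y = assembly.build_task_matrix(master, task, variables=selected[task])
            X_tr, X_te, y_tr, y_te = stratified_split(
                X, y, train_fraction=cfg.train_fraction, seed=split_seed
            )
            spec = REFERENCE_MODELS[task] if cfg.use_reference_models else ModelSpec(REFERENCE_MODELS[task].family)
            tuning = TuningConfig(
                scoring=cfg.scoring.get(task, "f1"),
                seed=cfg.seed + _STAGE_SEED["train"],
                train_fraction=cfg.train_fraction,
            )
            model = tune_and_fit(
                X_tr, y_tr, spec, tuning, smote=task in cfg.smote_tasks
            )
            joblib.dump({"model": model, "test_index": list(X_te.index)}, self.out / f"model_{task}.joblib")
            summaries[task] = {
                "family": model.family,
                "params": model.chosen_params,
                "scoring": model.scoring,
                "cv_mean": model.cv_mean,
                "cv_sd": model.cv_sd,
                "cv_ci": list(model.cv_ci),
                "n_train": int(len(X_tr)),
                "n_test": int(len(X_te)),
                "features": selected[task],
            }
        _write_json(self.out / "models.json", summaries)

    def _load_model(self, task: str) -> tuple[TrainedModel, list[str]]:
        bundle = joblib.load(_require(self.out / f"model_{task}.joblib", "train"))
        return bundle["model"], bundle["test_index"]

    def fuse(self) -> None:
        cfg = self.config
        master = self._load_master()
        isch, _ = self._load_model("ischemic")
        hem, _ = self._load_model("hemorrhagic")
        # the fusion sample only needs the union of the specialists' features
        cols = sorted(set(isch.feature_names) | set(hem.feature_names))
        X, y = assembly.build_task_matrix(master, "ischemic", variables=cols)
        X_tr, X_te, y_tr, y_te = stratified_split(
            X, y, train_fraction=cfg.train_fraction, seed=cfg.seed + _STAGE_SEED["fuse"]
        )
        fusion = cascade_mod.fit_fusion(
            X_tr, y_tr, {"ischemic": isch, "hemorrhagic": hem},
            prior_grid=cfg.prior_grid, seed=cfg.seed + _STAGE_SEED["fuse"],
        )
        joblib.dump({"fusion": fusion, "test_index": list(X_te.index)}, self.out / "fusion.joblib")
        _write_json(
            self.out / "fusion.json",
            {
                "class_prior": fusion.class_prior_,
                "grid_score": fusion.grid_score_,
                "prior_grid": list(cfg.prior_grid),
                "n_train": int(len(X_tr)),
                "n_test": int(len(X_te)),
            },
        )

    def cascade(self) -> None:
        cfg = self.config
        master = self._load_master()
        bundle = joblib.load(_require(self.out / "fusion.joblib", "fuse"))
        fusion, test_index = bundle["fusion"], bundle["test_index"]
        lvo_model, _ = self._load_model("lvo")
        clf = cascade_mod.CascadeClassifier(fusion, lvo_model, cfg.lvo_threshold)
        rows = master.features.loc[test_index]
        frame = clf.predict_frame(rows)
        frame.insert(0, "patient_id", rows.index)
        # baseline scale on the same rows
        sev = cascade_mod.severity_features(rows, list(assembly.ORDINAL_VARS))
        scale = cascade_mod.default_scale()
        frame["scale_result"] = [
            cascade_mod.scale_score(scale, dict(r)) for _, r in sev.iterrows()
        ]
        frame.to_csv(self.out / "cascade_predictions.csv", index=False)

    def evaluate(self) -> None:
        cfg = self.config
        master = self._load_master()
        preds = pd.read_csv(
            _require(self.out / "cascade_predictions.csv", "cascade")
        ).set_index("patient_id")
        labels = master.labels.loc[preds.index]
        seed = cfg.seed + _STAGE_SEED["evaluate"]
        report: dict[str, object] = {"config_hash": cfg.config_hash(), "n_evaluated": int(len(preds))}

        # subtype fusion performance (ischemic = positive)
        subtype_mask = labels["stroke_type"].isin(["ischemic", "hemorrhagic"])
        y_sub = (labels.loc[subtype_mask, "stroke_type"] == "ischemic").astype(int).to_numpy()
        p_sub = (preds.loc[subtype_mask, "stroke_type_call"] == "ischemic").astype(int).to_numpy()
        cm = evaluation.ConfusionMatrix.from_predictions(y_sub, p_sub)
        report["fusion"] = {
            "confusion": dataclasses.asdict(cm),
            "metrics": evaluation.confusion_metrics(cm),
        }
        if len(np.unique(y_sub)) == 2:
            report["fusion"]["auc"] = evaluation.roc_auc(
                preds.loc[subtype_mask, "p_ischemic"].to_numpy(), y_sub
            )
            acc = evaluation.bootstrap_ci(
                lambda yt, yp: float((yt == yp).mean()), p_sub, y_sub,
                n_resamples=cfg.bootstrap_resamples, seed=seed,
            )
            report["fusion"]["accuracy_ci"] = {"point": acc[0], "lower": acc[1], "upper": acc[2]}

        # LVO performance among truly ischemic rows with known LVO labels
        lvo_mask = (labels["stroke_type"] == "ischemic") & labels["lvo"].isin(["yes", "no"])
        y_lvo = (labels.loc[lvo_mask, "lvo"] == "yes").astype(int).to_numpy()
        called = preds.loc[lvo_mask]
        p_lvo_call = (called["lvo_call"] == "yes").astype(int).to_numpy()
        if len(np.unique(y_lvo)) == 2:
            cm_lvo = evaluation.ConfusionMatrix.from_predictions(y_lvo, p_lvo_call)
            report["lvo"] = {
                "confusion": dataclasses.asdict(cm_lvo),
                "metrics": evaluation.confusion_metrics(cm_lvo),
            }
            scored = called["p_lvo"].notna()
            if scored.any() and len(np.unique(y_lvo[scored.to_numpy()])) == 2:
                probs = called.loc[scored, "p_lvo"].to_numpy()
                y_scored = y_lvo[scored.to_numpy()]
                report["lvo"]["auc"] = evaluation.roc_auc(probs, y_scored)
                curve = evaluation.calibration_curve(probs, y_scored)
                report["lvo"]["calibration"] = {"bins": [list(b) for b in curve.bins]}

            # baseline scale comparison on rows where the scale is informed
            informed = called["scale_result"].isin(["positive", "negative"]).to_numpy()
            if informed.any():
                base_pred = (called.loc[informed, "scale_result"] == "positive").astype(int).to_numpy()
                comp = evaluation.population_comparison(
                    {"true-ischemic": (y_lvo[informed], p_lvo_call[informed])},
                    {"true-ischemic": (y_lvo[informed], base_pred)},
                )
                report["baseline_comparison"] = comp.to_dict(orient="records")

        # fairness by sex among LVO-labelled rows
        if "sex" in master.features.columns:
            sex = master.features.loc[preds.index, "sex"]
            ok = lvo_mask & sex.notna()
            if ok.any() and sex[ok].nunique() >= 2:
                fr = evaluation.fairness_report(
                    (preds.loc[ok, "lvo_call"] == "yes").astype(int).to_numpy(),
                    (labels.loc[ok, "lvo"] == "yes").astype(int).to_numpy(),
                    sex[ok].to_numpy(),
                )
                report["fairness_sex"] = {
                    "groups": list(fr.groups),
                    "selection_rate": list(fr.selection_rate),
                    "tpr": list(fr.tpr),
                    "fpr": list(fr.fpr),
                    "dpd": fr.dpd,
                    "eod": fr.eod,
                }
        _write_json(self.out / "report.json", report)

    # -- driver ------------------------------------------------------------

    def run(self) -> dict:
        """Execute the configured stages and write the run manifest."""
        for stage in self.stages_to_run():
            t0 = time.perf_counter()
            getattr(self, stage)()
            self.timings[stage] = round(time.perf_counter() - t0, 3)
            logger.info("stage %s done in %.2fs", stage, self.timings[stage])
        manifest = {
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "stage_seeds": {k: self.config.seed + v for k, v in _STAGE_SEED.items()},
            "stages": list(self.stages_to_run()),
            "artifacts": {
                p.name: _checksum(p)
                for p in sorted(self.out.iterdir())
                if p.suffix in (".csv", ".json") and p.name != "manifest.json"
            },
            "timings_s": self.timings,
        }
        _write_json(self.out / "manifest.json", manifest)
        return manifest

    def stages_to_run(self) -> list[str]:
        return [s for s in STAGES if s in self.config.stages]


def run(config: RunConfig) -> dict:
    """Run the configured pipeline stages; returns the manifest."""
    return PipelineRunner(config).run()
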