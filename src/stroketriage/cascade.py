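"""Decision architecture: Naive-Bayes fusion and the LVO cascade.

The two subtype specialists (an ischemic-focused and a
hemorrhagic-focused classifier) are combined by a two-feature Gaussian
Naive-Bayes rule over their positive-class probabilities, with the class
prior on ischemic chosen by grid search to balance per-class precision
and recall on an inner validation fold. Episodes fused as ischemic are
passed to the LVO model; hemorrhagic calls bypass it. A configurable
rule-based prehospital scale serves as the comparison baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import precision_score, recall_score
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB

from stroketriage.cohort import ValidationError
from stroketriage.models import TrainedModel

logger = logging.getLogger(__name__)

__all__ = [
    "NaiveBayesFusion",
    "fit_fusion",
    "fuse_predict",
    "CascadeClassifier",
    "CascadeResult",
    "cascade_predict",
    "ScaleDefinition",
    "scale_score",
    "default_scale",
    "severity_features",
]


class NaiveBayesFusion(ClassifierMixin, BaseEstimator):
    """Fuse two specialists through a Gaussian Naive-Bayes combiner.

    The combiner's two features are the specialists' positive-class
    probabilities; its class-conditional Gaussians are estimated from
    those outputs on the fusion training sample, and the prior assigned
    to the ischemic class is selected from ``prior_grid`` to maximize the
    minimum of {ischemic precision, ischemic recall, hemorrhagic
    precision, hemorrhagic recall} on an inner validation fold (ties go
    to the smaller prior). Target convention: 1 = ischemic,
    0 = hemorrhagic.
    """

    def __init__(
        self,
        ischemic_model: TrainedModel | None = None,
        hemorrhagic_model: TrainedModel | None = None,
        prior_grid: Sequence[float] = tuple(np.round(np.arange(0.05, 1.0, 0.05), 2)),
        validation_fraction: float = 0.3,
        seed: int = 0,
    ) -> None:
        self.ischemic_model = ischemic_model
        self.hemorrhagic_model = hemorrhagic_model
        self.prior_grid = prior_grid
        self.validation_fraction = validation_fraction
        self.seed = seed

    # -- internals ---------------------------------------------------------
    def _specialist_features(self, rows) -> np.ndarray:
        if self.ischemic_model is None or self.hemorrhagic_model is None:
            raise ValidationError("both specialists are required before fusion")
        return np.column_stack(
            [
                self.ischemic_model.positive_proba(rows),
                self.hemorrhagic_model.positive_proba(rows),
            ]
        )

    @staticmethod
    def _min_class_pr(y_true: np.ndarray, y_pred: np.ndarray) -> float:
        vals = [
            precision_score(y_true, y_pred, pos_label=1, zero_division=0),
            recall_score(y_true, y_pred, pos_label=1, zero_division=0),
            precision_score(y_true, y_pred, pos_label=0, zero_division=0),
            recall_score(y_true, y_pred, pos_label=0, zero_division=0),
        ]
        return float(min(vals))

    @staticmethod
    def _nb(prior: float) -> GaussianNB:
        p = float(np.clip(prior, 1e-9, 1 - 1e-9))
        return GaussianNB(priors=[1 - p, p])

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y):
        if len(self.prior_grid) == 0:
            raise ValidationError("prior grid must be non-empty")
        y = np.asarray(y).astype(int)
        feats = self._specialist_features(X)

        idx = np.arange(len(y))
        tr, va = train_test_split(
            idx, test_size=self.validation_fraction, stratify=y, random_state=self.seed
        )
        best_prior, best_score = None, -np.inf
        for prior in sorted(float(p) for p in self.prior_grid):
            nb = self._nb(prior).fit(feats[tr], y[tr])
            score = self._min_class_pr(y[va], nb.predict(feats[va]))
            if score > best_score:  # ties keep the earlier (smaller) prior
                best_prior, best_score = prior, score
        self.class_prior_ = float(best_prior)
        self.grid_score_ = float(best_score)
        # final likelihoods from the full fusion sample
        self.combiner_ = self._nb(self.class_prior_).fit(feats, y)
        self.classes_ = self.combiner_.classes_
        logger.info("fusion prior grid search: prior=%.2f (score %.3f)", best_prior, best_score)
        return self

    def predict_proba(self, X) -> np.ndarray:
        return self.combiner_.predict_proba(self._specialist_features(X))

    def predict(self, X) -> np.ndarray:
        # tie at 0.5 resolves toward ischemic (safety-first)
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def fit_fusion(
    fusion_X,
    fusion_y,
    specialists: Mapping[str, TrainedModel],
    prior_grid: Sequence[float] | None = None,
    seed: int = 0,
) -> NaiveBayesFusion:
    """Fit the fusion combiner; ``fusion_y``: 1 = ischemic, 0 = hemorrhagic."""
    for role in ("ischemic", "hemorrhagic"):
        if role not in specialists:
            raise ValidationError(f"missing specialist {role!r}")
    kwargs = {} if prior_grid is None else {"prior_grid": prior_grid}
    fusion = NaiveBayesFusion(
        ischemic_model=specialists["ischemic"],
        hemorrhagic_model=specialists["hemorrhagic"],
        seed=seed,
        **kwargs,
    )
    return fusion.fit(fusion_X, fusion_y)


def fuse_predict(fusion: NaiveBayesFusion, rows) -> tuple[np.ndarray, np.ndarray]:
    """(class call, p_ischemic) per row; call is 'ischemic' or 'hemorrhagic'."""
    p = fusion.predict_proba(rows)[:, 1]
    calls = np.where(p >= 0.5, "ischemic", "hemorrhagic")
    return calls, p


# ---------------------------------------------------------------------------
# cascade

@dataclass(frozen=True)
class CascadeResult:
    """Final triage call for one episode."""

    stroke_type_call: str  # ischemic | hemorrhagic
    p_ischemic: float
    lvo_call: str  # yes | no | not_applicable
    p_lvo: float | None


class CascadeClassifier(ClassifierMixin, BaseEstimator):
    """Three-model cascade: subtype fusion gates the LVO specialist.

    Hemorrhagic calls receive ``lvo_call='not_applicable'`` and never
    invoke the LVO model; ischemic calls are scored by the LVO model and
    thresholded (default 0.5). ``n_lvo_invocations_`` counts gated calls.
    """

    def __init__(
        self,
        fusion: NaiveBayesFusion | None = None,
        lvo_model: TrainedModel | None = None,
        lvo_threshold: float = 0.5,
    ) -> None:
        self.fusion = fusion
        self.lvo_model = lvo_model
        self.lvo_threshold = lvo_threshold

    def predict_records(self, rows) -> list[CascadeResult]:
        if self.fusion is None or self.lvo_model is None:
            raise ValidationError("cascade requires a fitted fusion and an LVO model")
        calls, p_isch = fuse_predict(self.fusion, rows)
        results: list[CascadeResult] = []
        isch_mask = calls == "ischemic"
        self.n_lvo_invocations_ = int(isch_mask.sum())
        p_lvo_all = np.full(len(calls), np.nan)
        if isch_mask.any():
            subset = rows[isch_mask] if isinstance(rows, pd.DataFrame) else np.asarray(rows)[isch_mask]
            p_lvo_all[isch_mask] = self.lvo_model.positive_proba(subset)
        for i, call in enumerate(calls):
            if call == "ischemic":
                p_lvo = float(p_lvo_all[i])
                lvo_call = "yes" if p_lvo >= self.lvo_threshold else "no"
                results.append(CascadeResult(call, float(p_isch[i]), lvo_call, p_lvo))
            else:
                results.append(CascadeResult(call, float(p_isch[i]), "not_applicable", None))
        logger.info(
            "cascade: %d rows, %d LVO-model invocations", len(calls), self.n_lvo_invocations_
        )
        return results

    def predict_frame(self, rows) -> pd.DataFrame:
        res = self.predict_records(rows)
        return pd.DataFrame(
            {
                "stroke_type_call": [r.stroke_type_call for r in res],
                "p_ischemic": [r.p_ischemic for r in res],
                "lvo_call": [r.lvo_call for r in res],
                "p_lvo": [r.p_lvo for r in res],
            },
            index=rows.index if isinstance(rows, pd.DataFrame) else None,
        )


def cascade_predict(
    fusion: NaiveBayesFusion,
    lvo_model: TrainedModel,
    rows,
    lvo_threshold: float = 0.5,
) -> list[CascadeResult]:
    """Functional wrapper over :class:`CascadeClassifier`."""
    return CascadeClassifier(fusion, lvo_model, lvo_threshold).predict_records(rows)


# ---------------------------------------------------------------------------
# rule-based prehospital scale baseline

@dataclass(frozen=True)
class ScaleDefinition:
    """Weighted-item prehospital scale with an optional age criterion.

    The score is the weighted sum of the item values; at or above
    ``threshold`` the scale is positive. ``include_age=False`` drops the
    age rule — the modification that retargets a thrombectomy-eligibility
    scale at LVO presence itself. Any required item missing makes the
    result ``missing``.
    """

    items: tuple[tuple[str, float], ...]
    threshold: float
    include_age: bool = False
    age_rule: tuple[float, float] | None = None  # (cutoff years, weight)

    def validate(self) -> None:
        if not self.items:
            raise ValidationError("scale needs at least one item")
        if not all(np.isfinite(w) for _, w in self.items):
            raise ValidationError("scale weights must be finite")


def scale_score(scale: ScaleDefinition, row: Mapping[str, object]) -> str:
    """Score one episode: 'positive', 'negative' or 'missing'."""
    scale.validate()
    total = 0.0
    for name, weight in scale.items:
        value = row.get(name)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return "missing"
        total += weight * float(value)
    if scale.include_age and scale.age_rule is not None:
        cutoff, weight = scale.age_rule
        age = row.get("age")
        if age is None or (isinstance(age, float) and np.isnan(age)):
            return "missing"
        if float(age) <= cutoff:
            total += weight
    return "positive" if total >= scale.threshold else "negative"


def severity_features(df: pd.DataFrame, ordinal_cols: Sequence[str]) -> pd.DataFrame:
    """Deficit scores (3 − ordinal code) for scale items; Not Evaluated → missing."""
    out = pd.DataFrame(index=df.index)
    for c in ordinal_cols:
        if c in df.columns:
            vals = pd.to_numeric(df[c], errors="coerce")
            vals = vals.where(vals >= 0)  # Not Evaluated code is negative
            out[f"{c}_deficit"] = 3.0 - vals
    return out


def default_scale() -> ScaleDefinition:
    """Synthetic placeholder scale over motor/facial/consciousness deficits.

    The published item content of the real prehospital scale is not
    reproduced here; this stand-in scores deficits (0 = none ... 3 =
    severe) on arm strength, facial paralysis and consciousness and is
    positive at a total of 4 or more. Configure a real
    :class:`ScaleDefinition` for any clinical use.
    """
    return ScaleDefinition(
        items=(
            ("arm_strength_deficit", 1.0),
            ("facial_paralysis_deficit", 1.0),
            ("consciousness_deficit", 1.0),
        ),
        threshold=4.0,
        include_age=False,
    )
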