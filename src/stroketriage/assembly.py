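"""Dataset assembly: preprocessing, merging, and the completeness cascade.

Covers the registry-style preprocessing chain — text-derived medication
flags, ordinal encoding of hierarchical clinical findings, duplicate
resolution, trend-to-static summarization — the merge of the clinical,
hemodynamic and hospital-history sources into a master dataset, and the
iterative completeness filter that trades variable coverage against
episode count. No step imputes feature values: missing stays missing.
"""

from __future__ import annotations

import logging
import re
import unicodedata
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from stroketriage.cohort import ORDINAL_VARS, TrendSeries, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "NOT_EVALUATED",
    "TrendSummary",
    "MasterDataset",
    "CompletenessTier",
    "derive_text_flags",
    "encode_ordinals",
    "resolve_duplicates",
    "summarize_trend",
    "summarize_trends_table",
    "merge_sources",
    "completeness_cascade",
    "build_task_matrix",
]

#: Distinct code for "Not Evaluated" ordinal entries; kept outside the
#: 0-worst .. 3-normal severity ladder so models can treat non-assessment
#: as its own state rather than a severity level.
NOT_EVALUATED = -1

#: Category labels per ordinal variable, ascending toward normal
#: (0 = worst severity ... 3 = normal).
ORDINAL_CATEGORIES: dict[str, tuple[str, ...]] = {
    "consciousness": ("comatose", "stupor", "drowsy", "conscious"),
    "orientation": ("disoriented", "oriented_one", "oriented_two", "fully_oriented"),
    "facial_paralysis": ("severe", "moderate", "mild", "none"),
    "arm_strength": ("no_movement", "some_movement", "drift", "normal"),
    "leg_strength": ("no_movement", "some_movement", "drift", "normal"),
    "sensitivity": ("severe_deficit", "moderate_deficit", "mild_deficit", "normal"),
}

TREND_STATS = ("mean", "median", "min", "max", "delta", "variation_rate")


# ---------------------------------------------------------------------------
# text normalization → flags

def _normalize_text(text: str) -> str:
    text = unicodedata.normalize("NFKD", text)
    text = "".join(c for c in text if not unicodedata.combining(c))
    text = text.upper()
    return re.sub(r"[^A-Z0-9 ]+", " ", text)


_DRUG_PATTERNS = {
    "urapidil": ("URAPIDIL",),
    "atropine": ("ATROPIN",),
    "labetalol": ("LABETALOL",),
}
_FLAG_PATTERNS = {
    "atrial_fibrillation": ("FIBRILA", "ACXFA", "AFIB"),
    "prior_stroke": ("ICTUS PREVIO", "ACV PREVIO", "PRIOR STROKE", "PREVIOUS STROKE"),
    "anticoagulant": (
        "ANTICOAGUL",
        "SINTROM",
        "ACENOCUMAROL",
        "WARFARIN",
        "APIXABAN",
        "RIVAROXABAN",
        "DABIGATRAN",
        "EDOXABAN",
        "HEPARIN",
    ),
}


def derive_text_flags(free_text_fields: Mapping[str, str]) -> dict[str, bool]:
    """Extract boolean flags from free-text EMS notes.

    Text is uppercased with accents and special characters stripped, then
    matched against substring rules. Unparseable or empty text yields
    all-false flags; never raises.
    """
    blob = " ".join(_normalize_text(str(v)) for v in free_text_fields.values() if v)
    flags = {name: any(p in blob for p in pats) for name, pats in _DRUG_PATTERNS.items()}
    flags.update({name: any(p in blob for p in pats) for name, pats in _FLAG_PATTERNS.items()})
    # any-drug: a specific drug hit or an explicit dose mention
    flags["drug_administered"] = (
        any(flags[d] for d in _DRUG_PATTERNS) or bool(re.search(r"\b\d+ ?MG\b", blob))
    )
    return flags


# ---------------------------------------------------------------------------
# ordinal encoding

def encode_ordinals(record: Mapping[str, object] | object) -> dict[str, int]:
    """Encode hierarchical clinical findings as integers ascending toward normal.

    Accepts an :class:`~stroketriage.cohort.EpisodeRecord` or a plain
    mapping of variable → category label / integer code / None. Missing
    entries map to the distinct ``NOT_EVALUATED`` code.
    """
    ordinals = getattr(record, "clinical_ordinals", record)
    out: dict[str, int] = {}
    for var in ORDINAL_VARS:
        value = ordinals.get(var) if isinstance(ordinals, Mapping) else None
        if value is None or (isinstance(value, float) and np.isnan(value)):
            out[var] = NOT_EVALUATED
            continue
        if isinstance(value, (int, np.integer)):
            code = int(value)
            if code != NOT_EVALUATED and code not in range(len(ORDINAL_CATEGORIES[var])):
                raise ValidationError(f"unknown ordinal code {code} for variable {var!r}")
            out[var] = code
            continue
        label = str(value).strip().lower().replace(" ", "_")
        cats = ORDINAL_CATEGORIES[var]
        if label not in cats:
            raise ValidationError(
                f"unknown category {value!r} for variable {var!r}; expected one of {cats}"
            )
        out[var] = cats.index(label)
    return out


# ---------------------------------------------------------------------------
# duplicate resolution

def resolve_duplicates(
    rows: pd.DataFrame,
    key: Sequence[str] = ("patient_id", "event_time"),
    text_cols: Iterable[str] = (),
    ordinal_cols: Iterable[str] = (),
    numeric_cols: Iterable[str] | None = None,
    text_sep: str = " | ",
) -> pd.DataFrame:
    """Collapse duplicate event rows to one row per event key.

    Text columns are concatenated, ordinal columns keep the most severe
    (numerically lowest under the 0-worst convention, ignoring the
    ``NOT_EVALUATED`` code unless nothing else is present), numeric
    columns keep their maximum, and rows with a missing patient id are
    dropped. Idempotent.
    """
    df = rows.dropna(subset=[key[0]]).copy()
    text_cols = [c for c in text_cols if c in df.columns]
    ordinal_cols = [c for c in ordinal_cols if c in df.columns]
    if numeric_cols is None:
        numeric_cols = [
            c
            for c in df.select_dtypes(include="number").columns
            if c not in ordinal_cols and c not in key
        ]
    numeric_cols = [c for c in numeric_cols if c in df.columns]

    def _most_severe(s: pd.Series) -> object:
        informed = s.dropna()
        informed = informed[informed != NOT_EVALUATED]
        if informed.empty:
            return NOT_EVALUATED if not s.dropna().empty else np.nan
        return informed.min()

    def _concat_text(s: pd.Series) -> object:
        parts = [str(v) for v in s.dropna() if str(v)]
        return text_sep.join(parts) if parts else np.nan

    agg: dict[str, object] = {}
    for c in df.columns:
        if c in key:
            continue
        if c in text_cols:
            agg[c] = _concat_text
        elif c in ordinal_cols:
            agg[c] = _most_severe
        elif c in numeric_cols:
            agg[c] = "max"
        else:
            agg[c] = "first"
    out = df.groupby(list(key), as_index=False, dropna=False, sort=False).agg(agg)
    return out[rows.columns.intersection(out.columns).tolist()]


# ---------------------------------------------------------------------------
# trend summarization

@dataclass(frozen=True)
class TrendSummary:
    """Static summary of one monitored vital (all in the vital's units).

    ``variation_rate`` is the net drift (last − first) / duration, in
    units per second; ``delta`` = max − min.
    """

    vital_name: str
    mean: float
    median: float
    minimum: float
    maximum: float
    delta: float
    variation_rate: float


def summarize_trend(series: TrendSeries) -> TrendSummary:
    """Exact arithmetic summaries of one trend; even-length median = midpoint."""
    v = np.asarray(series.values, dtype=float)
    if v.size == 0:
        raise ValidationError(f"empty trend series for {series.vital_name!r}")
    return TrendSummary(
        vital_name=series.vital_name,
        mean=float(np.mean(v)),
        median=float(np.median(v)),
        minimum=float(np.min(v)),
        maximum=float(np.max(v)),
        delta=float(np.max(v) - np.min(v)),
        variation_rate=float((v[-1] - v[0]) / series.duration) if series.duration > 0 else 0.0,
    )


def summarize_trends_table(long_df: pd.DataFrame, duration: int = 600) -> pd.DataFrame:
    """Wide per-episode summary of a long-format (patient_id, vital, t_seconds, value) table."""
    required = {"patient_id", "vital", "value"}
    missing = required - set(long_df.columns)
    if missing:
        raise ValidationError(f"long trend table lacks column(s) {sorted(missing)}")
    if long_df.empty:
        return pd.DataFrame(columns=["patient_id"])
    rows = []
    sort_col = "t_seconds" if "t_seconds" in long_df.columns else None
    for (pid, vital), grp in long_df.groupby(["patient_id", "vital"], sort=False):
        if sort_col:
            grp = grp.sort_values(sort_col)
        v = grp["value"].to_numpy(dtype=float)
        rows.append(
            {
                "patient_id": pid,
                f"{vital}_mean": float(np.mean(v)),
                f"{vital}_median": float(np.median(v)),
                f"{vital}_min": float(np.min(v)),
                f"{vital}_max": float(np.max(v)),
                f"{vital}_delta": float(np.max(v) - np.min(v)),
                f"{vital}_variation_rate": float((v[-1] - v[0]) / duration),
            }
        )
    wide = pd.DataFrame(rows)
    return wide.groupby("patient_id", as_index=False, sort=False).first()


# ---------------------------------------------------------------------------
# master dataset

LABEL_COLS = ("stroke_type", "lvo", "thrombolysis", "thrombectomy", "exitus")
ID_COLS = ("patient_id", "event_time")


@dataclass
class MasterDataset:
    """Merged feature matrix plus labels and per-variable metadata.

    ``features`` holds one row per retained episode (indexed by
    patient_id); ``labels`` aligns row-for-row; ``variables`` records
    each feature's kind and completeness fraction.
    """

    features: pd.DataFrame
    labels: pd.DataFrame
    variables: pd.DataFrame

    @property
    def n_episodes(self) -> int:
        return len(self.features)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)


def _infer_kind(s: pd.Series, name: str) -> str:
    if name in ORDINAL_VARS:
        return "ordinal"
    if s.dropna().isin([True, False, 0, 1]).all() and s.dropna().nunique() <= 2:
        return "flag"
    if pd.api.types.is_numeric_dtype(s):
        return "numeric"
    return "categorical"


def merge_sources(
    clinical: pd.DataFrame,
    hemodynamic: pd.DataFrame,
    histories: pd.DataFrame,
    id_col: str = "patient_id",
    time_col: str = "event_time",
    time_tolerance: str = "same_day",
) -> MasterDataset:
    """Merge the three sources into a master dataset.

    Clinical and hemodynamic features are joined per patient (long-format
    hemodynamic input is summarized first); labels come from the
    histories table. Episodes without a non-missing stroke-type label or
    without a single informed feature are dropped. Missing values are
    retained — no imputation.

    ``time_tolerance='same_day'`` keeps clinical/history pairs only when
    their timestamps fall on the same calendar day (ignored when either
    side lacks the time column).
    """
    for name, tbl in {"clinical": clinical, "hemodynamic": hemodynamic, "histories": histories}.items():
        if id_col not in tbl.columns:
            raise ValidationError(f"{name} table lacks identifier column {id_col!r}")

    if {"vital", "value"} <= set(hemodynamic.columns):
        hemodynamic = summarize_trends_table(hemodynamic)

    features = clinical.merge(hemodynamic, on=id_col, how="outer", suffixes=("", "_hemo"))
    merged = features.merge(histories, on=id_col, how="inner", suffixes=("", "_hist"))

    if (
        time_tolerance == "same_day"
        and time_col in clinical.columns
        and f"{time_col}_hist" in merged.columns
    ):
        t_clin = pd.to_datetime(merged[time_col], errors="coerce")
        t_hist = pd.to_datetime(merged[f"{time_col}_hist"], errors="coerce")
        same_day = (t_clin.dt.date == t_hist.dt.date) | t_clin.isna() | t_hist.isna()
        merged = merged[same_day]
    merged = merged.drop(columns=[c for c in merged.columns if c.endswith("_hist")])

    label_cols = [c for c in LABEL_COLS if c in merged.columns]
    feat_cols = [c for c in merged.columns if c not in label_cols and c not in ID_COLS]

    labeled = merged["stroke_type"].notna() & ~merged["stroke_type"].isin(["missing"])
    informed = merged[feat_cols].notna().any(axis=1)
    kept = merged[labeled & informed].set_index(id_col)
    logger.info(
        "merge_sources: %d rows in, %d dropped unlabeled, %d dropped featureless, %d kept",
        len(merged),
        int((~labeled).sum()),
        int((labeled & ~informed).sum()),
        len(kept),
    )
    if kept.empty:
        warnings.warn("merge produced an empty master dataset", stacklevel=2)

    features_df = kept[feat_cols]
    labels_df = kept[label_cols]
    variables = pd.DataFrame(
        {
            "name": feat_cols,
            "kind": [_infer_kind(features_df[c], c) for c in feat_cols],
            "completeness": [
                float(features_df[c].notna().mean()) if len(features_df) else 0.0
                for c in feat_cols
            ],
        }
    )
    return MasterDataset(features=features_df, labels=labels_df, variables=variables)


# ---------------------------------------------------------------------------
# completeness cascade

@dataclass(frozen=True)
class CompletenessTier:
    """One rung of the completeness cascade.

    Every retained episode is fully informed on every retained variable.
    """

    cutoff: float
    variables: tuple[str, ...]
    episodes: tuple[str, ...]

    def to_manifest(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "n_variables": len(self.variables),
            "n_episodes": len(self.episodes),
            "variables": list(self.variables),
            "episodes": list(self.episodes),
        }


DEFAULT_CUTOFFS = (1.0, 0.75, 0.5, 0.25, 0.1, 0.05)


def completeness_cascade(
    master: MasterDataset,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
) -> list[CompletenessTier]:
    """Build nested datasets by relaxing a per-variable completeness cutoff.

    For each cutoff ``c`` (strictly descending, in (0, 1]), variables with
    completeness >= c are retained, then only episodes fully informed on
    that variable set. Higher cutoffs keep fewer variables but more
    episodes; the tiers are nested accordingly.
    """
    cutoffs = list(cutoffs)
    if not cutoffs:
        raise ValidationError("cutoff list must be non-empty")
    if any(not 0.0 < c <= 1.0 for c in cutoffs):
        raise ValidationError(f"cutoffs must lie in (0, 1], got {cutoffs}")
    if any(a <= b for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValidationError(f"cutoffs must be strictly descending, got {cutoffs}")
    if cutoffs[-1] < 0.05:
        warnings.warn(
            f"cutoff {cutoffs[-1]} is below the 5% completeness floor", stacklevel=2
        )

    completeness = master.features.notna().mean(axis=0)
    tiers: list[CompletenessTier] = []
    for c in cutoffs:
        keep_vars = [v for v in master.feature_names if completeness[v] >= c]
        if keep_vars:
            full = master.features[keep_vars].notna().all(axis=1)
            episodes = tuple(str(i) for i in master.features.index[full])
        else:
            episodes = tuple(str(i) for i in master.features.index)
        tiers.append(CompletenessTier(cutoff=float(c), variables=tuple(keep_vars), episodes=episodes))
        logger.info(
            "completeness tier %.2f: %d variables, %d episodes", c, len(keep_vars), len(episodes)
        )
    return tiers


# ---------------------------------------------------------------------------
# task matrices

TASK_LABELS = {"ischemic": "stroke_type", "hemorrhagic": "stroke_type", "lvo": "lvo"}


def build_task_matrix(
    master: MasterDataset,
    task: str,
    variables: Sequence[str] | None = None,
    episodes: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Feature matrix and binary target for one classification task.

    ``ischemic`` / ``hemorrhagic``: subtype-labelled episodes only, target
    1 for the named subtype. ``lvo``: ischemic episodes with a yes/no LVO
    label, target 1 for LVO-positive.
    """
    if task not in TASK_LABELS:
        raise ValidationError(f"unknown task {task!r}; expected one of {sorted(TASK_LABELS)}")
    X = master.features
    y_raw = master.labels
    if episodes is not None:
        idx = X.index.intersection(pd.Index(episodes))
        X, y_raw = X.loc[idx], y_raw.loc[idx]
    if variables is not None:
        X = X[[v for v in variables if v in X.columns]]

    if task in ("ischemic", "hemorrhagic"):
        mask = y_raw["stroke_type"].isin(["ischemic", "hemorrhagic"])
        y = (y_raw.loc[mask, "stroke_type"] == task).astype(int)
    else:
        mask = (y_raw["stroke_type"] == "ischemic") & y_raw["lvo"].isin(["yes", "no"])
        y = (y_raw.loc[mask, "lvo"] == "yes").astype(int)
    return X.loc[mask[mask].index], y.rename(task)
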