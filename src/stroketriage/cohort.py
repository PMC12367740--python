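"""Seeded synthetic EMS stroke-code cohorts.

Emulates the statistical structure of a prehospital stroke registry:
a label mixture of hemorrhagic / ischemic / other-or-missing episodes,
roughly half of ischemic cases carrying a large vessel occlusion (LVO)
with a female excess among LVO-positives, age distributions skewed
toward the late seventies for ischemic stroke, 10-minute vital-sign
trends sampled every 30 s, ordinal neurological findings, text-derived
medication flags, and per-variable missingness (about a quarter of the
prehospital-scale entries missing by default).

Planted LVO effects — standardized mean shifts on minimum systolic
pressure, heart rate, arm strength and median SpO2 — give downstream
classifiers a recoverable signal whose size is configurable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgeModel",
    "CohortSpec",
    "EpisodeRecord",
    "TrendSeries",
    "ValidationError",
    "generate_cohort",
    "generate_trend",
    "inject_missingness",
    "cohort_tables",
    "episodes_to_frame",
    "trends_to_frame",
]


class ValidationError(ValueError):
    """Raised when a spec or argument violates a documented invariant."""


ORDINAL_VARS = (
    "consciousness",
    "orientation",
    "facial_paralysis",
    "arm_strength",
    "leg_strength",
    "sensitivity",
)
FLAG_VARS = (
    "drug_administered",
    "urapidil",
    "atropine",
    "labetalol",
    "atrial_fibrillation",
    "prior_stroke",
    "anticoagulant",
)
VITALS = ("heart_rate", "spo2", "systolic_nibp", "diastolic_nibp")

#: 0 = worst severity ... 3 = normal; a distinct "Not Evaluated" code is
#: added downstream at encoding time, never here.
ORDINAL_LEVELS = (0, 1, 2, 3)

SAMPLE_INTERVAL_S = 30
TREND_DURATION_S = 600


@dataclass(frozen=True)
class AgeModel:
    """Skew-normal age distribution for one stroke subtype (years)."""

    loc: float
    scale: float
    skew: float


@dataclass(frozen=True)
class TrendParams:
    """Population baseline and within-episode noise for one vital sign."""

    baseline_mean: float
    baseline_sd: float
    noise_sd: float
    lo: float = -np.inf
    hi: float = np.inf


def _default_age_models() -> dict[str, AgeModel]:
    # ischemic mode lands near 78 y (peak incidence reported between 75-85)
    return {
        "ischemic": AgeModel(loc=84.0, scale=12.0, skew=-4.0),
        "hemorrhagic": AgeModel(loc=78.0, scale=16.0, skew=-2.0),
        "other": AgeModel(loc=72.0, scale=16.0, skew=-1.5),
    }


def _default_effects() -> dict[str, float]:
    # standardized mean shifts, LVO-positive minus LVO-negative, among
    # ischemic episodes; signs follow the clinical picture (hypertensive,
    # tachycardic, desaturating, hemiparetic)
    return {
        "systolic_nibp": 1.0,
        "heart_rate": 1.0,
        "arm_strength": -1.0,
        "spo2": -1.0,
    }


def _default_missingness() -> dict[str, float]:
    rates: dict[str, float] = {"scale_result": 0.244}
    rates.update({v: 0.05 for v in ORDINAL_VARS})
    rates.update({v: 0.10 for v in VITALS})
    return rates


def _default_trend_params() -> dict[str, TrendParams]:
    return {
        "heart_rate": TrendParams(80.0, 15.0, 3.0, lo=20.0, hi=220.0),
        "spo2": TrendParams(96.0, 2.5, 0.8, lo=50.0, hi=100.0),
        "systolic_nibp": TrendParams(135.0, 20.0, 5.0, lo=60.0, hi=260.0),
        "diastolic_nibp": TrendParams(80.0, 12.0, 4.0, lo=30.0, hi=160.0),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Distributional targets for a synthetic cohort.

    Default label mixture matches a 2,177-record registry with 14.70%
    hemorrhagic and 61.87% ischemic episodes, 50.63% LVO among ischemic,
    and 57% of LVO-positive cases female.
    """

    n_episodes: int = 2000
    p_hemorrhagic: float = 0.1470
    p_ischemic: float = 0.6187
    p_other_or_missing_label: float = 0.2343
    p_lvo_given_ischemic: float = 0.5063
    lvo_sex_skew: float = 0.57
    p_female: float = 0.50
    age_model: Mapping[str, AgeModel] = field(default_factory=_default_age_models)
    effect_sizes: Mapping[str, float] = field(default_factory=_default_effects)
    missingness_rates: Mapping[str, float] = field(default_factory=_default_missingness)
    trend_params: Mapping[str, TrendParams] = field(default_factory=_default_trend_params)
    p_scale_positive_given_lvo: float = 0.70
    p_scale_positive_given_not_lvo: float = 0.35

    def validate(self) -> None:
        if self.n_episodes < 1:
            raise ValidationError("n_episodes must be >= 1")
        probs = {
            "p_hemorrhagic": self.p_hemorrhagic,
            "p_ischemic": self.p_ischemic,
            "p_other_or_missing_label": self.p_other_or_missing_label,
            "p_lvo_given_ischemic": self.p_lvo_given_ischemic,
            "lvo_sex_skew": self.lvo_sex_skew,
            "p_female": self.p_female,
            "p_scale_positive_given_lvo": self.p_scale_positive_given_lvo,
            "p_scale_positive_given_not_lvo": self.p_scale_positive_given_not_lvo,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {p}")
        total = self.p_hemorrhagic + self.p_ischemic + self.p_other_or_missing_label
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                "p_hemorrhagic + p_ischemic + p_other_or_missing_label must "
                f"sum to 1 (got {total})"
            )
        for name, rate in self.missingness_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValidationError(f"missingness_rates[{name!r}] must be in [0, 1]")
        for vital, tp in self.trend_params.items():
            if tp.noise_sd < 0 or tp.baseline_sd < 0:
                raise ValidationError(f"trend_params[{vital!r}] standard deviations must be >= 0")


@dataclass
class TrendSeries:
    """One vital monitored over a continuous 10-minute window, one sample every 30 s."""

    vital_name: str
    values: np.ndarray
    sample_interval: int = SAMPLE_INTERVAL_S
    duration: int = TREND_DURATION_S

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = self.duration // self.sample_interval + 1
        if len(self.values) != expected:
            raise ValidationError(
                f"trend for {self.vital_name!r} must hold {expected} samples, got {len(self.values)}"
            )

    @property
    def times(self) -> np.ndarray:
        return np.arange(0, self.duration + 1, self.sample_interval, dtype=float)


@dataclass
class EpisodeRecord:
    """One stroke-code episode: demographics, findings, trends, labels."""

    patient_id: str
    event_time: datetime
    age: float
    sex: str | None
    clinical_ordinals: dict[str, int | None]
    clinical_flags: dict[str, bool | None]
    trends: dict[str, TrendSeries]
    scale_result: str  # positive | negative | missing
    stroke_type: str  # ischemic | hemorrhagic | other | missing
    lvo: str  # yes | no | missing | not_applicable
    thrombolysis: str
    thrombectomy: str
    exitus: str


def generate_trend(
    vital_name: str,
    baseline: float,
    noise_sd: float,
    seed: int | np.random.Generator,
    lo: float = -np.inf,
    hi: float = np.inf,
) -> TrendSeries:
    """Gaussian noise around a per-episode baseline, sampled every 30 s for 10 min.

    21 samples (inclusive endpoints). ``noise_sd`` of zero yields a
    constant series at ``baseline``.
    """
    if noise_sd < 0:
        raise ValidationError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = TREND_DURATION_S // SAMPLE_INTERVAL_S + 1
    values = baseline + rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.full(n, float(baseline))
    return TrendSeries(vital_name, np.clip(values, lo, hi))


def _discretize_latent(z: float, shift: float = 0.0) -> int:
    """Map a shifted standard-normal latent onto the 0..3 severity ladder.

    Cutpoints put most probability on the normal end (code 3) so that a
    negative shift (worse function) pushes codes downward.
    """
    x = z + shift
    if x < -1.6:
        return 0
    if x < -0.9:
        return 1
    if x < -0.2:
        return 2
    return 3


def _hash_id(i: int, seed: int) -> str:
    return hashlib.sha1(f"episode-{seed}-{i}".encode()).hexdigest()[:16]


def generate_cohort(spec: CohortSpec, seed: int) -> list[EpisodeRecord]:
    """Draw a full cohort from ``spec``; identical (spec, seed) → identical cohort.

    Label mixture, LVO assignment and the sex skew among LVO-positives are
    sampled first; the planted effect sizes are then realized as mean
    shifts of the named variables between LVO classes. Missingness is
    applied last via :func:`inject_missingness` with ``spec.missingness_rates``.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    n = spec.n_episodes

    stroke_type = rng.choice(
        ["hemorrhagic", "ischemic", "other_or_missing"],
        size=n,
        p=[spec.p_hemorrhagic, spec.p_ischemic, spec.p_other_or_missing_label],
    )
    # the other-or-missing bucket splits between an explicit "other"
    # subtype and a missing label (~4% of all episodes missing, the rest other)
    p_missing_within = min(1.0, 0.175 / max(spec.p_other_or_missing_label, 1e-12))
    sex = np.where(rng.random(n) < spec.p_female, "female", "male")

    # P(LVO | ischemic, sex) from the overall rate and the female share of
    # LVO-positives: P(L|F) = p_lvo * skew / p_female (clipped)
    p_l = spec.p_lvo_given_ischemic
    p_lvo_f = np.clip(p_l * spec.lvo_sex_skew / max(spec.p_female, 1e-12), 0, 1)
    p_lvo_m = np.clip(p_l * (1 - spec.lvo_sex_skew) / max(1 - spec.p_female, 1e-12), 0, 1)

    eff = dict(spec.effect_sizes)
    records: list[EpisodeRecord] = []
    t0 = datetime(2022, 1, 1, 8, 0, 0)
    for i in range(n):
        st = stroke_type[i]
        if st == "other_or_missing":
            st = "missing" if rng.random() < p_missing_within else "other"
        if st == "ischemic":
            p_lvo_i = p_lvo_f if sex[i] == "female" else p_lvo_m
            lvo = "yes" if rng.random() < p_lvo_i else "no"
        else:
            lvo = "not_applicable"
        is_lvo = lvo == "yes"

        am = spec.age_model.get(st, spec.age_model.get("other", AgeModel(72, 16, -1.5)))
        age = float(
            np.clip(stats.skewnorm.rvs(am.skew, loc=am.loc, scale=am.scale, random_state=rng), 18, 110)
        )

        # severity latents: hemorrhagic episodes present with worse
        # consciousness; LVO shifts the motor/sensory latents
        sev_shift = -0.6 if st == "hemorrhagic" else 0.0
        ordinals: dict[str, int | None] = {}
        for var in ORDINAL_VARS:
            shift = sev_shift
            if var == "arm_strength" and is_lvo:
                shift += eff.get("arm_strength", 0.0)
            elif var in ("facial_paralysis", "leg_strength") and is_lvo:
                shift += 0.5 * eff.get("arm_strength", 0.0)
            ordinals[var] = _discretize_latent(rng.normal(), shift)

        # medication / history flags, with hypertensive-management drugs and
        # anticoagulation enriched in hemorrhagic episodes
        hem = st == "hemorrhagic"
        p_urapidil = 0.18 if hem else 0.04
        p_labetalol = 0.12 if hem else 0.03
        p_anticoag = 0.28 if hem else 0.14
        flags: dict[str, bool | None] = {
            "urapidil": bool(rng.random() < p_urapidil),
            "atropine": bool(rng.random() < 0.02),
            "labetalol": bool(rng.random() < p_labetalol),
            "atrial_fibrillation": bool(rng.random() < (0.22 if st == "ischemic" else 0.12)),
            "prior_stroke": bool(rng.random() < 0.15),
            "anticoagulant": bool(rng.random() < p_anticoag),
        }
        flags["drug_administered"] = bool(
            flags["urapidil"] or flags["atropine"] or flags["labetalol"] or rng.random() < 0.10
        )

        trends: dict[str, TrendSeries] = {}
        for vital, tp in spec.trend_params.items():
            base_shift = eff.get(vital, 0.0) * tp.baseline_sd if is_lvo else 0.0
            if vital == "systolic_nibp" and hem:
                base_shift += 0.7 * tp.baseline_sd
            baseline = rng.normal(tp.baseline_mean + base_shift, tp.baseline_sd)
            trends[vital] = generate_trend(vital, baseline, tp.noise_sd, rng, tp.lo, tp.hi)

        p_pos = spec.p_scale_positive_given_lvo if is_lvo else spec.p_scale_positive_given_not_lvo
        scale_result = "positive" if rng.random() < p_pos else "negative"

        thrombolysis = (
            ("yes" if rng.random() < 0.35 else "no") if st == "ischemic" else "no"
        )
        thrombectomy = ("yes" if rng.random() < 0.75 else "no") if is_lvo else "no"
        exitus = "yes" if rng.random() < (0.20 if hem else 0.08) else "no"

        records.append(
            EpisodeRecord(
                patient_id=_hash_id(i, seed),
                event_time=t0 + timedelta(minutes=30 * i),
                age=age,
                sex=str(sex[i]),
                clinical_ordinals=ordinals,
                clinical_flags=flags,
                trends=trends,
                scale_result=scale_result,
                stroke_type=st,
                lvo=lvo,
                thrombolysis=thrombolysis,
                thrombectomy=thrombectomy,
                exitus=exitus,
            )
        )

    return inject_missingness(records, spec.missingness_rates, seed=seed + 1)


_MASKABLE = set(ORDINAL_VARS) | set(FLAG_VARS) | set(VITALS) | {
    "scale_result",
    "age",
    "sex",
    "stroke_type",
    "lvo",
}


def inject_missingness(
    records: Sequence[EpisodeRecord],
    rates: Mapping[str, float],
    seed: int,
) -> list[EpisodeRecord]:
    """Independently mask each named variable per episode with its rate (MCAR).

    Labels (``stroke_type``, ``lvo``) are only masked if explicitly listed.
    Returns new records; inputs are not mutated.
    """
    unknown = sorted(set(rates) - _MASKABLE)
    if unknown:
        raise ValidationError(
            f"unknown variable(s) {unknown}; valid names: {sorted(_MASKABLE)}"
        )
    for name, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValidationError(f"rate for {name!r} must be in [0, 1], got {rate}")

    rng = np.random.default_rng(seed)
    out: list[EpisodeRecord] = []
    for rec in records:
        ords = dict(rec.clinical_ordinals)
        flags = dict(rec.clinical_flags)
        trends = dict(rec.trends)
        new = replace(rec, clinical_ordinals=ords, clinical_flags=flags, trends=trends)
        for name, rate in rates.items():
            if rate <= 0.0:
                continue
            if rng.random() >= rate:
                continue
            if name in ords:
                ords[name] = None
            elif name in flags:
                flags[name] = None
            elif name in trends:
                del trends[name]
            elif name == "scale_result":
                new.scale_result = "missing"
            elif name == "age":
                new.age = float("nan")
            elif name == "sex":
                new.sex = None
            elif name == "stroke_type":
                new.stroke_type = "missing"
            elif name == "lvo":
                new.lvo = "missing"
        out.append(new)
    return out


# ---------------------------------------------------------------------------
# tabular exports

def episodes_to_frame(records: Sequence[EpisodeRecord]) -> pd.DataFrame:
    """Wide clinical table, one row per episode; empty cell = missing."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "patient_id": r.patient_id,
            "event_time": r.event_time.isoformat(),
            "age": r.age,
            "sex": r.sex,
            "scale_result": None if r.scale_result == "missing" else r.scale_result,
            "stroke_type": r.stroke_type,
            "lvo": r.lvo,
            "thrombolysis": r.thrombolysis,
            "thrombectomy": r.thrombectomy,
            "exitus": r.exitus,
        }
        row.update(r.clinical_ordinals)
        row.update(r.clinical_flags)
        rows.append(row)
    return pd.DataFrame(rows)


def trends_to_frame(records: Sequence[EpisodeRecord]) -> pd.DataFrame:
    """Long-format trend export: (patient_id, vital, t_seconds, value)."""
    frames = []
    for r in records:
        for vital, series in r.trends.items():
            frames.append(
                pd.DataFrame(
                    {
                        "patient_id": r.patient_id,
                        "event_time": r.event_time.isoformat(),
                        "vital": vital,
                        "t_seconds": series.times.astype(int),
                        "value": series.values,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=["patient_id", "event_time", "vital", "t_seconds", "value"])
    return pd.concat(frames, ignore_index=True)


def cohort_tables(records: Sequence[EpisodeRecord]) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split a cohort into the three source tables the assembly stage merges.

    Returns ``(clinical, hemodynamic_long, histories)``: clinical findings,
    long-format vital trends, and the label table from hospital records.
    """
    clinical = episodes_to_frame(records).drop(
        columns=["stroke_type", "lvo", "thrombolysis", "thrombectomy", "exitus"]
    )
    hemo = trends_to_frame(records)
    histories = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "event_time": [r.event_time.isoformat() for r in records],
            "stroke_type": [r.stroke_type for r in records],
            "lvo": [r.lvo for r in records],
            "thrombolysis": [r.thrombolysis for r in records],
            "thrombectomy": [r.thrombectomy for r in records],
            "exitus": [r.exitus for r in records],
        }
    )
    return clinical, hemo, histories
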