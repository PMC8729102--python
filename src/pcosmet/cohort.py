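"""Longitudinal PCOS cohort data model, derived endocrine indices and outcome labels.

A cohort is a collection of :class:`PatientRecord` objects, one per woman, each
carrying up to three visits (baseline ``m0``, six months ``m6``, twelve months
``m12``) of anthropometric, metabolic and endocrine measurements taken under
metformin treatment, plus the disposition of the patient (completed the year of
therapy, dropped out for a given reason in a given interval, or became
pregnant).

The derived indices are the ones standard in gynaecological endocrinology:

* BMI = weight / height²  (kg/m²)
* WHR = waist / hip
* FAI = total testosterone (ng/mL) × 347 / SHBG (nmol/L), in percent
* HOMA-IR = glucose (mg/dL) × 0.05551 × insulin (μU/mL) / 22.5
* LH/FSH ratio

Therapy response is defined per outcome: a drop of at least 1 kg/m² in BMI for
overweight/obese women (BMI ≥ 25 at baseline), and a drop of at least 1
percentage point in FAI for hyperandrogenemic women (FAI ≥ 6 % at baseline).
Twelve-month labels measure *further* improvement relative to the six-month
visit.
"""

from __future__ import annotations

import io
import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_EVEN
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

__all__ = [
    "VISITS",
    "STATUSES",
    "DROPOUT_INTERVALS",
    "PatientVisit",
    "PatientRecord",
    "Cohort",
    "DerivedPanel",
    "OutcomeLabels",
    "Rate",
    "FlowReport",
    "DomainError",
    "CohortParseError",
    "compute_fai",
    "compute_homa_ir",
    "compute_bmi",
    "compute_derived",
    "label_outcomes",
    "flow_report",
    "rate",
    "read_cohort_csv",
    "write_cohort_csv",
    "baseline_frame",
]

VISITS = ("m0", "m6", "m12")
STATUSES = (
    "completed",
    "dropout_side_effects",
    "dropout_no_benefit",
    "lost_followup",
    "pregnant",
)
DROPOUT_REASONS = ("dropout_side_effects", "dropout_no_benefit", "lost_followup")
DROPOUT_INTERVALS = ("none", "m0_m6", "m6_m12")

#: Free androgen index conversion constant for T in ng/mL against SHBG in nmol/L.
FAI_FACTOR = 347.0
#: mg/dL -> mmol/L conversion for glucose in the HOMA-IR formula.
GLUCOSE_MMOL_PER_MGDL = 0.05551
HOMA_DENOMINATOR = 22.5

#: Eligibility thresholds for the two primary outcomes.
OVERWEIGHT_BMI_CUTOFF = 25.0
HYPERANDROGENEMIA_FAI_CUTOFF = 6.0
#: Minimum improvement counting as response (kg/m² for BMI, percentage points for FAI).
RESPONSE_DELTA = 1.0


class DomainError(ValueError):
    """An index was requested on physically impossible inputs."""


class CohortParseError(ValueError):
    """The cohort CSV violates the documented schema."""


# ---------------------------------------------------------------------------
# Index formulas
# ---------------------------------------------------------------------------

def compute_fai(t_ngml: float, shbg_nmoll: float) -> float:
    """Free androgen index (percent): T (ng/mL) × 347 / SHBG (nmol/L)."""
    if shbg_nmoll <= 0:
        raise DomainError(f"SHBG must be > 0 to compute FAI, got {shbg_nmoll}")
    if t_ngml < 0:
        raise DomainError(f"testosterone must be >= 0, got {t_ngml}")
    return t_ngml * FAI_FACTOR / shbg_nmoll


def compute_homa_ir(glucose_mgdl: float, insulin_uUml: float) -> float:
    """HOMA insulin-resistance index: [glucose (mg/dL) × 0.05551] × insulin / 22.5."""
    if glucose_mgdl < 0 or insulin_uUml < 0:
        raise DomainError(
            f"glucose and insulin must be >= 0, got ({glucose_mgdl}, {insulin_uUml})"
        )
    return glucose_mgdl * GLUCOSE_MMOL_PER_MGDL * insulin_uUml / HOMA_DENOMINATOR


def compute_bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index, weight in kg over squared height in metres."""
    if height_m <= 0:
        raise DomainError(f"height must be > 0 to compute BMI, got {height_m}")
    if weight_kg < 0:
        raise DomainError(f"weight must be >= 0, got {weight_kg}")
    return weight_kg / height_m**2


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

_VISIT_FIELDS = (
    "weight", "glucose", "insulin", "tg", "tc", "ldl", "hdl",
    "waist", "hip", "t", "shbg", "dheas", "a4", "fg",
    "lh", "fsh", "menses6", "afc",
)


@dataclass
class PatientVisit:
    """One assessment of one woman: all measured variables at a visit.

    Units: weight kg; glucose/tg/tc/ldl/hdl mg/dL; insulin μU/mL; waist/hip cm;
    t ng/mL; shbg nmol/L; dheas μg/dL; a4 ng/mL; lh/fsh IU/L; fg the modified
    Ferriman–Gallwey score (0–36); menses6 spontaneous menses per 6 months
    (0–6); afc antral follicle count over both ovaries; pcom polycystic ovarian
    morphology on ultrasound.
    """

    visit: str
    weight: float
    glucose: float
    insulin: float
    tg: float
    tc: float
    ldl: float
    hdl: float
    waist: float
    hip: float
    t: float
    shbg: float
    dheas: float
    a4: float
    fg: float
    lh: float
    fsh: float
    menses6: float
    afc: float
    pcom: bool

    def __post_init__(self) -> None:
        if self.visit not in VISITS:
            raise ValueError(f"unknown visit {self.visit!r}, expected one of {VISITS}")
        for name in _VISIT_FIELDS:
            value = getattr(self, name)
            if value is None or (isinstance(value, float) and math.isnan(value)):
                continue  # missing values are allowed; indices become undefined
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.menses6 is not None and not _isnan(self.menses6) and self.menses6 > 6:
            raise ValueError(f"menses6 must be <= 6, got {self.menses6}")
        if self.fg is not None and not _isnan(self.fg) and self.fg > 36:
            raise ValueError(f"Ferriman-Gallwey score must be <= 36, got {self.fg}")


def _isnan(x) -> bool:
    return isinstance(x, float) and math.isnan(x)


@dataclass
class PatientRecord:
    """A woman's full longitudinal record with disposition metadata."""

    patient_id: str
    age: float
    height: float  # metres, time-invariant
    visits: dict[str, PatientVisit] = field(default_factory=dict)
    status: str = "completed"
    dropout_interval: str = "none"
    extra: dict = field(default_factory=dict)  # unknown CSV columns, preserved

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.dropout_interval not in DROPOUT_INTERVALS:
            raise ValueError(f"unknown dropout_interval {self.dropout_interval!r}")
        if "m0" not in self.visits:
            raise ValueError(f"patient {self.patient_id}: baseline visit m0 is mandatory")
        present = [v in self.visits for v in VISITS]
        # a visit may only be present if all earlier visits are present
        if present != sorted(present, reverse=True):
            raise ValueError(
                f"patient {self.patient_id}: visits must be contiguous from m0, "
                f"got {sorted(self.visits)}"
            )
        has_m12 = "m12" in self.visits
        if self.status == "completed" and not has_m12:
            raise ValueError(
                f"patient {self.patient_id}: status 'completed' requires the m12 visit"
            )
        if self.status != "completed" and has_m12:
            raise ValueError(
                f"patient {self.patient_id}: non-completers cannot have an m12 visit"
            )
        if self.status != "completed" and self.dropout_interval == "none":
            raise ValueError(
                f"patient {self.patient_id}: non-completers need a dropout_interval"
            )

    @property
    def dropped_out(self) -> bool:
        return self.status in DROPOUT_REASONS

    def visit(self, name: str) -> Optional[PatientVisit]:
        return self.visits.get(name)


@dataclass
class Cohort:
    """The study population: an ordered collection of patient records."""

    records: list[PatientRecord]
    n_screened: Optional[int] = None  # women assessed for eligibility, if known

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def ids(self) -> list[str]:
        return [r.patient_id for r in self.records]


@dataclass
class DerivedPanel:
    """The five derived indices for one visit."""

    bmi: float
    fai: float
    homa_ir: float
    whr: float
    lh_fsh: float


@dataclass
class OutcomeLabels:
    """Per-patient eligibility and responder flags for the two primary outcomes.

    Responder flags are ``None`` (undefined) when the patient is not eligible
    for that outcome or the visit needed to measure the change is absent;
    ``True``/``False`` otherwise.  Twelve-month flags mean a *further* drop of
    at least :data:`RESPONSE_DELTA` relative to the six-month value.
    """

    bmi_eligible: bool
    fai_eligible: bool
    bmi_responder_m6: Optional[bool] = None
    bmi_responder_m12: Optional[bool] = None
    fai_responder_m6: Optional[bool] = None
    fai_responder_m12: Optional[bool] = None


# ---------------------------------------------------------------------------
# Derived panels and labels
# ---------------------------------------------------------------------------

def compute_derived(visit: PatientVisit, height: float) -> DerivedPanel:
    """All derived indices for a single visit; raises naming the offending field."""
    if height <= 0:
        raise DomainError("height must be > 0")
    if visit.hip <= 0:
        raise DomainError("hip must be > 0 to compute WHR")
    if visit.fsh <= 0:
        raise DomainError("FSH must be > 0 to compute LH/FSH")
    return DerivedPanel(
        bmi=compute_bmi(visit.weight, height),
        fai=compute_fai(visit.t, visit.shbg),
        homa_ir=compute_homa_ir(visit.glucose, visit.insulin),
        whr=visit.waist / visit.hip,
        lh_fsh=visit.lh / visit.fsh,
    )


def _safe_derived(record: PatientRecord, visit: str) -> Optional[DerivedPanel]:
    v = record.visit(visit)
    if v is None:
        return None
    try:
        return compute_derived(v, record.height)
    except (DomainError, TypeError):
        return None


def label_outcomes(
    record: PatientRecord,
    overweight_cutoff: float = OVERWEIGHT_BMI_CUTOFF,
    fai_cutoff: float = HYPERANDROGENEMIA_FAI_CUTOFF,
    delta: float = RESPONSE_DELTA,
) -> OutcomeLabels:
    """Eligibility and responder flags for one record.

    ``bmi_responder_m6`` is True when BMI(m0) − BMI(m6) ≥ ``delta``;
    ``bmi_responder_m12`` when BMI(m6) − BMI(m12) ≥ ``delta`` (further
    improvement); FAI flags analogously on the FAI scale.  A flag stays
    ``None`` when eligibility fails or a required visit/index is missing.
    """
    d0 = _safe_derived(record, "m0")
    if d0 is None:
        raise DomainError(f"patient {record.patient_id}: baseline indices undefined")
    d6 = _safe_derived(record, "m6")
    d12 = _safe_derived(record, "m12")

    bmi_eligible = d0.bmi >= overweight_cutoff
    fai_eligible = d0.fai >= fai_cutoff

    labels = OutcomeLabels(bmi_eligible=bmi_eligible, fai_eligible=fai_eligible)
    if bmi_eligible:
        if d6 is not None:
            labels.bmi_responder_m6 = (d0.bmi - d6.bmi) >= delta
            if d12 is not None:
                labels.bmi_responder_m12 = (d6.bmi - d12.bmi) >= delta
    if fai_eligible:
        if d6 is not None:
            labels.fai_responder_m6 = (d0.fai - d6.fai) >= delta
            if d12 is not None:
                labels.fai_responder_m12 = (d6.fai - d12.fai) >= delta
    return labels


# ---------------------------------------------------------------------------
# Flow-chart accounting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Rate:
    """A reported proportion: numerator, denominator and percent to 1 decimal."""

    numerator: int
    denominator: int
    percent: float

    def as_dict(self) -> dict:
        return asdict(self)


def rate(numerator: int, denominator: int) -> Rate:
    """Build a :class:`Rate` with percent = 100·num/den, 1 decimal, round-half-even."""
    if denominator <= 0:
        raise DomainError("rate denominator must be positive")
    if numerator < 0 or numerator > denominator:
        raise DomainError(f"numerator {numerator} out of [0, {denominator}]")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return Rate(numerator, denominator, float(pct.quantize(Decimal("0.1"), ROUND_HALF_EVEN)))


@dataclass
class FlowReport:
    """Counts and rates mirroring a study flow chart plus the response rates."""

    enrolled: int
    n_screened: Optional[int]
    completed_m6: int
    completed_m12: int
    dropouts: dict  # {interval: {reason: count}}
    pregnancies: dict  # {interval: count}
    eligibility_rate: Optional[Rate]
    retention_m6: Rate
    retention_m12: Rate
    side_effect_discontinuation: Rate
    other_discontinuation: Rate
    pregnancy_rate: Rate
    response_rates: dict  # {"bmi_m6": Rate, ...}

    def to_json(self, path: Optional[str | Path] = None) -> str:
        def enc(o):
            if isinstance(o, Rate):
                return o.as_dict()
            raise TypeError(type(o))

        payload = json.dumps(asdict_flow(self), indent=2, sort_keys=True, default=enc)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def asdict_flow(report: FlowReport) -> dict:
    d = asdict(report)
    return d


def flow_report(cohort: Cohort) -> FlowReport:
    """Account for every enrolled woman: completion, drop-out, pregnancy, response.

    Six-month response rates use all baseline-eligible women as denominator
    (intention-to-treat); women without the visit simply never enter the
    numerator.  Twelve-month rates count further responders over eligible women
    who reached m12.
    """
    if len(cohort) == 0:
        raise DomainError("flow_report needs a non-empty cohort")

    n = len(cohort)
    dropouts = {iv: {r: 0 for r in DROPOUT_REASONS} for iv in ("m0_m6", "m6_m12")}
    pregnancies = {"m0_m6": 0, "m6_m12": 0}
    completed_m6 = 0
    completed_m12 = 0

    num = {k: 0 for k in ("bmi_m6", "bmi_m12", "fai_m6", "fai_m12")}
    den = {k: 0 for k in ("bmi_m6", "bmi_m12", "fai_m6", "fai_m12")}

    for record in cohort:
        if record.dropped_out:
            dropouts[record.dropout_interval][record.status] += 1
        elif record.status == "pregnant":
            pregnancies[record.dropout_interval] += 1
        has_m6 = "m6" in record.visits
        has_m12 = "m12" in record.visits
        # "completed m6" = took the drug through the first interval
        if has_m6 and not (record.status == "pregnant" and record.dropout_interval == "m0_m6"):
            completed_m6 += 1
        if has_m12 and record.status == "completed":
            completed_m12 += 1

        labels = label_outcomes(record)
        if labels.bmi_eligible:
            den["bmi_m6"] += 1
            num["bmi_m6"] += bool(labels.bmi_responder_m6)
            if has_m12:
                den["bmi_m12"] += 1
                num["bmi_m12"] += bool(labels.bmi_responder_m12)
        if labels.fai_eligible:
            den["fai_m6"] += 1
            num["fai_m6"] += bool(labels.fai_responder_m6)
            if has_m12:
                den["fai_m12"] += 1
                num["fai_m12"] += bool(labels.fai_responder_m12)

    n_side = sum(dropouts[iv]["dropout_side_effects"] for iv in dropouts)
    n_other = sum(
        dropouts[iv][r] for iv in dropouts for r in ("dropout_no_benefit", "lost_followup")
    )
    n_pregnant = sum(pregnancies.values())

    response_rates = {
        k: rate(num[k], den[k]) if den[k] else None for k in num
    }
    return FlowReport(
        enrolled=n,
        n_screened=cohort.n_screened,
        completed_m6=completed_m6,
        completed_m12=completed_m12,
        dropouts=dropouts,
        pregnancies=pregnancies,
        eligibility_rate=rate(n, cohort.n_screened) if cohort.n_screened else None,
        retention_m6=rate(completed_m6, n),
        retention_m12=rate(completed_m12, n),
        side_effect_discontinuation=rate(n_side, n),
        other_discontinuation=rate(n_other, n),
        pregnancy_rate=rate(n_pregnant, n),
        response_rates=response_rates,
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "patient_id", "visit", "age", "height_m", "weight_kg", "glucose", "insulin",
    "tg", "tc", "ldl", "hdl", "waist", "hip", "t_ngml", "shbg", "dheas", "a4",
    "fg", "lh", "fsh", "menses6", "afc", "pcom", "status", "dropout_interval",
]

_CSV_TO_VISIT = {
    "weight_kg": "weight", "glucose": "glucose", "insulin": "insulin",
    "tg": "tg", "tc": "tc", "ldl": "ldl", "hdl": "hdl", "waist": "waist",
    "hip": "hip", "t_ngml": "t", "shbg": "shbg", "dheas": "dheas", "a4": "a4",
    "fg": "fg", "lh": "lh", "fsh": "fsh", "menses6": "menses6", "afc": "afc",
}


def write_cohort_csv(cohort: Cohort, path: str | Path) -> None:
    """One row per patient-visit; UTF-8, dot decimal separator."""
    rows = []
    for record in cohort:
        for visit_name in VISITS:
            v = record.visit(visit_name)
            if v is None:
                continue
            row = {
                "patient_id": record.patient_id,
                "visit": visit_name,
                "age": record.age,
                "height_m": record.height,
                "pcom": int(v.pcom),
                "status": record.status,
                "dropout_interval": record.dropout_interval,
            }
            for col, attr in _CSV_TO_VISIT.items():
                row[col] = getattr(v, attr)
            row.update(record.extra)
            rows.append(row)
    frame = pd.DataFrame(rows)
    ordered = _CSV_COLUMNS + [c for c in frame.columns if c not in _CSV_COLUMNS]
    frame[ordered].to_csv(path, index=False, encoding="utf-8")


def read_cohort_csv(path: str | Path) -> Cohort:
    """Parse the documented cohort CSV schema back into a :class:`Cohort`."""
    try:
        frame = pd.read_csv(path, encoding="utf-8")
    except pd.errors.EmptyDataError as exc:
        raise CohortParseError(f"{path}: empty file") from exc
    if frame.empty:
        raise CohortParseError(f"{path}: no data rows")
    missing = [c for c in _CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortParseError(f"{path}: missing mandatory columns {missing}")

    numeric_cols = [c for c in _CSV_COLUMNS if c not in ("patient_id", "visit", "status", "dropout_interval")]
    for col in numeric_cols:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise CohortParseError(f"{path}: non-numeric value in column {col!r} at line {line}")
        frame[col] = converted

    dup = frame.duplicated(subset=["patient_id", "visit"])
    if dup.any():
        row = int(dup.idxmax()) + 2
        raise CohortParseError(f"{path}: duplicate (patient, visit) at line {row}")

    extra_cols = [c for c in frame.columns if c not in _CSV_COLUMNS]
    records = []
    for pid, group in frame.groupby("patient_id", sort=False):
        visits = {}
        first = group.iloc[0]
        for _, row in group.iterrows():
            kwargs = {attr: row[col] for col, attr in _CSV_TO_VISIT.items()}
            visits[row["visit"]] = PatientVisit(
                visit=row["visit"], pcom=bool(row["pcom"]), **kwargs
            )
        try:
            records.append(
                PatientRecord(
                    patient_id=str(pid),
                    age=float(first["age"]),
                    height=float(first["height_m"]),
                    visits=visits,
                    status=str(first["status"]),
                    dropout_interval=str(first["dropout_interval"]),
                    extra={c: first[c] for c in extra_cols},
                )
            )
        except ValueError as exc:
            raise CohortParseError(f"{path}: {exc}") from exc
    return Cohort(records=records)


# ---------------------------------------------------------------------------
# Analysis feature table
# ---------------------------------------------------------------------------

#: Variables exposed by :func:`baseline_frame`, keyed by short analysis name.
ANALYSIS_VARIABLES = (
    "age", "weight", "bmi", "glucose", "insulin", "homa", "tg", "tc", "ldl",
    "hdl", "whr", "t", "shbg", "fai", "dheas", "a4", "fg", "lh_fsh",
    "menses6", "afc", "pcom",
)


def baseline_frame(cohort: Cohort, visit: str = "m0") -> pd.DataFrame:
    """Per-patient feature table (raw + derived) at one visit, indexed by id.

    Patients lacking the visit, or for whom an index is undefined, get NaN in
    the affected cells; downstream stages decide how to handle them.
    """
    rows = {}
    for record in cohort:
        v = record.visit(visit)
        if v is None:
            continue
        derived = _safe_derived(record, visit)
        rows[record.patient_id] = {
            "age": record.age,
            "weight": v.weight,
            "bmi": derived.bmi if derived else float("nan"),
            "glucose": v.glucose,
            "insulin": v.insulin,
            "homa": derived.homa_ir if derived else float("nan"),
            "tg": v.tg,
            "tc": v.tc,
            "ldl": v.ldl,
            "hdl": v.hdl,
            "whr": derived.whr if derived else float("nan"),
            "t": v.t,
            "shbg": v.shbg,
            "fai": derived.fai if derived else float("nan"),
            "dheas": v.dheas,
            "a4": v.a4,
            "fg": v.fg,
            "lh_fsh": derived.lh_fsh if derived else float("nan"),
            "menses6": v.menses6,
            "afc": v.afc,
            "pcom": float(v.pcom),
        }
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(ANALYSIS_VARIABLES))
    frame.index.name = "patient_id"
    return frame
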