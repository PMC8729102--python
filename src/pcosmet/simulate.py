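"""Synthetic PCOS cohort generator.

Emulates the statistical structure the downstream analysis assumes: baseline
marginals matched to the study population's published mean ± SD (skewed
hormones and lipids as moment-matched log-normals, symmetric variables as
mean-corrected truncated Gaussians), a Gaussian copula imposing a small set of
physiologically motivated correlations, treatment-effect shifts at six and
twelve months that depend on a planted logistic response model over the
dichotomized baseline, and a drop-out process driven by low baseline
testosterone (planted odds ratio for T < 0.90 ng/mL).

Every stochastic choice is keyed to ``GeneratorConfig.seed`` through
per-patient counter-derived substreams, so the first *m* patients of a run are
identical whatever the total cohort size.

The planted truth (responder indicators, drop-out latents, coefficients) is
returned as a :class:`GroundTruth` sidecar for recovery experiments; the
analysis pipeline never sees it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .cohort import Cohort, PatientRecord, PatientVisit, rate

__all__ = [
    "VariableSpec",
    "ResponseModel",
    "DropoutModel",
    "EffectSpec",
    "GeneratorConfig",
    "GroundTruth",
    "generate_baseline",
    "generate_longitudinal",
    "generate_dropout",
    "generate_cohort",
    "reference_flow_cohort",
    "BASELINE_SPEC",
    "DEFAULT_CORRELATIONS",
    "T_DROPOUT_THRESHOLD",
]

#: Baseline testosterone below this (ng/mL) carries the planted drop-out excess risk.
T_DROPOUT_THRESHOLD = 0.90


@dataclass(frozen=True)
class VariableSpec:
    """Target marginal for one drawn baseline variable."""

    mean: float
    sd: float
    median: Optional[float] = None  # published median, informational
    lower: float = 0.0
    upper: float = math.inf
    dist: str = "normal"  # "normal" | "lognormal" | "count"


# Published baseline (m0) descriptive statistics of the study population.
BASELINE_SPEC: dict[str, VariableSpec] = {
    "age": VariableSpec(28.38, 5.53, lower=18.0, upper=45.0),
    "height": VariableSpec(1.63, 0.06, lower=1.40, upper=1.90),
    "weight": VariableSpec(87.2, 18.18, median=84.0, lower=40.0),
    "glucose": VariableSpec(91.64, 9.66, median=90.0, lower=50.0),
    "insulin": VariableSpec(21.03, 11.6, median=18.0, dist="lognormal"),
    "tg": VariableSpec(121.6, 61.9, median=110.0, dist="lognormal"),
    "tc": VariableSpec(189.9, 32.5, median=185.0, lower=80.0),
    "ldl": VariableSpec(120.8, 26.8, median=120.0, lower=30.0),
    "hdl": VariableSpec(44.1, 8.9, median=43.0, lower=15.0),
    "whr": VariableSpec(0.91, 0.10, median=0.91, lower=0.60, upper=1.30),
    "hip": VariableSpec(112.0, 10.0, lower=70.0),  # not published; plausible scale
    "t": VariableSpec(0.70, 0.31, median=0.60, dist="lognormal"),
    "shbg": VariableSpec(23.1, 10.4, median=22.0, dist="lognormal"),
    "dheas": VariableSpec(291.7, 125.4, median=270.0, dist="lognormal"),
    "a4": VariableSpec(4.02, 0.65, median=4.0, lower=0.5),
    "fg": VariableSpec(12.5, 6.9, median=12.0, lower=0.0, upper=36.0, dist="count"),
    "lh_fsh": VariableSpec(1.44, 0.9, median=1.25, dist="lognormal"),
    "fsh": VariableSpec(5.5, 1.4, lower=1.0),  # not published; early-follicular scale
    "menses6": VariableSpec(2.0, 1.7, median=2.0, lower=0.0, upper=6.0, dist="count"),
    "afc": VariableSpec(41.0, 9.0, median=40.0, lower=10.0, upper=90.0, dist="count"),
}

PCOM_PREVALENCE = 0.73

#: Latent (copula) correlations among drawn variables.  T–SHBG and menses6–T
#: realize the intended associations on the derived FAI scale.
DEFAULT_CORRELATIONS: tuple[tuple[str, str, float], ...] = (
    ("weight", "insulin", 0.40),
    ("glucose", "insulin", 0.30),
    ("t", "shbg", -0.35),
    ("menses6", "t", -0.30),
    ("weight", "whr", 0.25),
    ("fg", "t", 0.30),
)


@dataclass(frozen=True)
class ResponseModel:
    """Logistic model for responder status on dichotomized baseline indicators.

    ``coefs`` maps ``(variable, side)`` to a log-odds coefficient, where
    ``side`` is ``"high"`` (above the baseline median) or ``"low"`` (at or
    below it).
    """

    intercept: float
    coefs: tuple[tuple[tuple[str, str], float], ...]


# BMI response: oligo-amenorrhea strongest, then hyperandrogenemia, hirsutism,
# insulin resistance.
BMI_RESPONSE = ResponseModel(
    intercept=-1.5,
    coefs=(
        (("menses6", "low"), 1.2),
        (("fai", "high"), 0.9),
        (("fg", "high"), 0.6),
        (("homa", "high"), 0.3),
    ),
)

# FAI response: oligo-amenorrhea, hyperandrogenemia, low DHEAS, high BMI,
# high triglycerides, low fasting glucose.
FAI_RESPONSE = ResponseModel(
    intercept=-2.25,
    coefs=(
        (("menses6", "low"), 1.2),
        (("fai", "high"), 1.0),
        (("dheas", "low"), 0.8),
        (("bmi", "high"), 0.6),
        (("tg", "high"), 0.5),
        (("glucose", "low"), 0.4),
    ),
)


@dataclass(frozen=True)
class DropoutModel:
    """Logistic drop-out risk in the low-testosterone indicator.

    ``gamma_lowt = ln(6.5)`` plants a 6.5-fold odds of discontinuation for
    women with baseline T below ``threshold``; ``gamma0`` sets the overall
    rate near the study's ≈43 % twelve-month discontinuation.
    """

    gamma0: float = -1.81
    gamma_lowt: float = math.log(6.5)
    threshold: float = T_DROPOUT_THRESHOLD
    p_first_interval: float = 21 / 46
    # reasons in study proportions: side effects 14/46, no benefit 21/46, lost 11/46
    reason_probs: tuple[float, ...] = (14 / 46, 21 / 46, 11 / 46)

    @property
    def planted_or(self) -> float:
        return math.exp(self.gamma_lowt)


@dataclass(frozen=True)
class EffectSpec:
    """Mean m0→m6 shifts; m6→m12 shifts are the same scaled by ``persistence``.

    ``bmi_drop_*`` act on weight through height²; ``t_drop``/``shbg_rise``
    apply to FAI responders (reduced testosterone, increased SHBG).
    ``trends`` are treatment effects common to everyone on the drug.
    """

    bmi_drop_responder: float = 1.7
    bmi_drop_nonresponder: float = 0.3
    bmi_noise_sd: float = 0.35
    t_drop_responder: float = 0.15
    t_drop_nonresponder: float = 0.03
    t_noise_sd: float = 0.04
    shbg_rise_responder: float = 4.5
    shbg_rise_nonresponder: float = 0.8
    shbg_noise_sd: float = 1.0
    persistence: float = 0.6
    trends: tuple[tuple[str, float, float], ...] = (
        # (variable, mean shift m0->m6, noise sd)
        ("glucose", -3.0, 3.0),
        ("insulin", -5.0, 3.0),
        ("tg", -2.0, 10.0),
        ("tc", -2.0, 8.0),
        ("ldl", -5.0, 6.0),
        ("hdl", 1.5, 2.0),
        ("menses6", 1.5, 1.0),
        ("fg", -0.5, 1.0),
        ("dheas", -12.0, 25.0),
        ("a4", -0.12, 0.20),
        ("lh", -0.5, 0.6),
        ("afc", -2.0, 2.0),
        ("waist", -1.5, 1.5),
    )


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic-cohort generator."""

    n: int = 108
    seed: int = 0
    baseline_spec: dict = field(default_factory=lambda: dict(BASELINE_SPEC))
    correlation_spec: tuple = DEFAULT_CORRELATIONS
    bmi_response: ResponseModel = BMI_RESPONSE
    fai_response: ResponseModel = FAI_RESPONSE
    dropout_model: DropoutModel = field(default_factory=DropoutModel)
    pregnancy_rate: float = 0.045  # per interval, among women still on the drug
    effect_spec: EffectSpec = field(default_factory=EffectSpec)
    pcom_prevalence: float = PCOM_PREVALENCE

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        for name, spec in self.baseline_spec.items():
            if spec.sd < 0:
                raise ValueError(f"{name}: sd must be >= 0")
        for i, j, rho in self.correlation_spec:
            if not abs(rho) < 1:
                raise ValueError(f"correlation |rho| must be < 1 for ({i}, {j})")
        if self.dropout_model.gamma_lowt < 0:
            raise ValueError("planted drop-out odds ratio must be >= 1")


@dataclass
class GroundTruth:
    """Planted latent state, stored beside the cohort for recovery tests only."""

    seed: int
    n: int
    bmi_responder: dict[str, bool] = field(default_factory=dict)
    fai_responder: dict[str, bool] = field(default_factory=dict)
    dropout: dict[str, bool] = field(default_factory=dict)
    low_t: dict[str, bool] = field(default_factory=dict)
    planted: dict = field(default_factory=dict)

    def to_json(self, path: Optional[str | Path] = None) -> str:
        payload = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload)
        return payload


# ---------------------------------------------------------------------------
# Marginals
# ---------------------------------------------------------------------------

def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of ln X for a log-normal with the requested mean and sd."""
    cv2 = (sd / mean) ** 2
    sigma2 = math.log1p(cv2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _trunc_mean(mu: float, spec: VariableSpec) -> float:
    a = (spec.lower - mu) / spec.sd
    b = (spec.upper - mu) / spec.sd if math.isfinite(spec.upper) else math.inf
    return stats.truncnorm.mean(a, b, loc=mu, scale=spec.sd)


def _discrete_trunc_mean(mu: float, spec: VariableSpec) -> float:
    """Mean of round(truncnorm) on the integer support [lower, upper]."""
    lo, hi = int(spec.lower), int(spec.upper)
    a = (spec.lower - mu) / spec.sd
    b = (spec.upper - mu) / spec.sd
    dist = stats.truncnorm(a, b, loc=mu, scale=spec.sd)
    ks = np.arange(lo, hi + 1)
    edges_lo = np.maximum(ks - 0.5, spec.lower)
    edges_hi = np.minimum(ks + 0.5, spec.upper)
    probs = dist.cdf(edges_hi) - dist.cdf(edges_lo)
    return float(np.sum(ks * probs) / np.sum(probs))


def _corrected_loc(spec: VariableSpec) -> float:
    """Underlying normal location whose truncated (and discretized) mean hits target."""
    target = spec.mean
    fn = _discrete_trunc_mean if spec.dist == "count" else _trunc_mean
    lo, hi = spec.mean - 4 * spec.sd, spec.mean + 4 * spec.sd
    try:
        return optimize.brentq(lambda m: fn(m, spec) - target, lo, hi, xtol=1e-8)
    except ValueError:
        return spec.mean  # target unreachable within bracket; fall back


def _marginal_ppf(u: np.ndarray, spec: VariableSpec, loc: float) -> np.ndarray:
    if spec.dist == "lognormal":
        mu, sigma = _lognormal_params(spec.mean, spec.sd)
        x = np.exp(mu + sigma * stats.norm.ppf(u))
        return np.clip(x, spec.lower if spec.lower > 0 else 0.0, None)
    a = (spec.lower - loc) / spec.sd
    b = (spec.upper - loc) / spec.sd if math.isfinite(spec.upper) else math.inf
    x = stats.truncnorm.ppf(u, a, b, loc=loc, scale=spec.sd)
    if spec.dist == "count":
        x = np.clip(np.rint(x), spec.lower, spec.upper)
    return x


def _correlation_matrix(variables: list[str], pairs) -> np.ndarray:
    k = len(variables)
    index = {v: i for i, v in enumerate(variables)}
    r = np.eye(k)
    for vi, vj, rho in pairs:
        if vi not in index or vj not in index:
            raise ValueError(f"correlation names unknown variable in ({vi}, {vj})")
        r[index[vi], index[vj]] = r[index[vj], index[vi]] = rho
    eigvals = np.linalg.eigvalsh(r)
    if eigvals.min() <= 1e-10:
        bad = ", ".join(f"({vi}, {vj}, {rho})" for vi, vj, rho in pairs)
        raise ValueError(
            f"correlation matrix not positive definite; check the pairs {bad}"
        )
    return r


# ---------------------------------------------------------------------------
# Baseline
# ---------------------------------------------------------------------------

def _patient_rng(seed: int, stage: int, i: int) -> np.random.Generator:
    """Counter-derived substream: stable for patient i regardless of cohort size."""
    return np.random.default_rng([seed, stage, i])


def generate_baseline(config: GeneratorConfig) -> tuple[Cohort, GroundTruth]:
    """Draw the baseline (m0-only) cohort from the copula-coupled marginals."""
    variables = list(config.baseline_spec)
    corr = _correlation_matrix(variables, config.correlation_spec)
    chol = np.linalg.cholesky(corr)
    k = len(variables)

    z = np.empty((config.n, k))
    pcom_u = np.empty(config.n)
    for i in range(config.n):
        rng = _patient_rng(config.seed, 0, i)
        z[i] = chol @ rng.standard_normal(k)
        pcom_u[i] = rng.uniform()
    u = stats.norm.cdf(z)
    u = np.clip(u, 1e-12, 1 - 1e-12)

    draws: dict[str, np.ndarray] = {}
    for j, name in enumerate(variables):
        spec = config.baseline_spec[name]
        loc = _corrected_loc(spec) if spec.dist in ("normal", "count") else spec.mean
        draws[name] = _marginal_ppf(u[:, j], spec, loc)

    records = []
    for i in range(config.n):
        pid = f"S{i:05d}"
        lh = draws["lh_fsh"][i] * draws["fsh"][i]
        visit = PatientVisit(
            visit="m0",
            weight=float(draws["weight"][i]),
            glucose=float(draws["glucose"][i]),
            insulin=float(draws["insulin"][i]),
            tg=float(draws["tg"][i]),
            tc=float(draws["tc"][i]),
            ldl=float(draws["ldl"][i]),
            hdl=float(draws["hdl"][i]),
            waist=float(draws["whr"][i] * draws["hip"][i]),
            hip=float(draws["hip"][i]),
            t=float(draws["t"][i]),
            shbg=float(draws["shbg"][i]),
            dheas=float(draws["dheas"][i]),
            a4=float(draws["a4"][i]),
            fg=float(draws["fg"][i]),
            lh=float(lh),
            fsh=float(draws["fsh"][i]),
            menses6=float(draws["menses6"][i]),
            afc=float(draws["afc"][i]),
            pcom=bool(pcom_u[i] < config.pcom_prevalence),
        )
        records.append(
            PatientRecord(
                patient_id=pid,
                age=float(draws["age"][i]),
                height=float(draws["height"][i]),
                visits={"m0": visit},
                status="lost_followup",  # placeholder until disposition is drawn
                dropout_interval="m0_m6",
            )
        )
    truth = GroundTruth(
        seed=config.seed,
        n=config.n,
        planted={
            "bmi_response": {"intercept": config.bmi_response.intercept,
                             "coefs": {f"{v}_{s}": b for (v, s), b in config.bmi_response.coefs}},
            "fai_response": {"intercept": config.fai_response.intercept,
                             "coefs": {f"{v}_{s}": b for (v, s), b in config.fai_response.coefs}},
            "dropout": {"gamma0": config.dropout_model.gamma0,
                        "gamma_lowt": config.dropout_model.gamma_lowt,
                        "odds_ratio": config.dropout_model.planted_or,
                        "threshold": config.dropout_model.threshold},
        },
    )
    return Cohort(records=records), truth


# ---------------------------------------------------------------------------
# Longitudinal follow-up
# ---------------------------------------------------------------------------

def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _baseline_indicators(cohort: Cohort) -> dict[str, dict[str, float]]:
    """Per-patient baseline analysis values for the response models."""
    from .cohort import baseline_frame

    frame = baseline_frame(cohort, "m0")
    medians = frame.median()
    out: dict[str, dict[str, float]] = {}
    for pid, row in frame.iterrows():
        out[pid] = {}
        for var in frame.columns:
            out[pid][f"{var}_high"] = float(row[var] > medians[var])
            out[pid][f"{var}_low"] = float(row[var] <= medians[var])
    return out


def _response_prob(model: ResponseModel, ind: dict[str, float]) -> float:
    eta = model.intercept
    for (var, side), beta in model.coefs:
        eta += beta * ind[f"{var}_{side}"]
    return _sigmoid(eta)


def _shift_visit(
    base: PatientVisit,
    visit_name: str,
    height: float,
    bmi_resp: bool,
    fai_resp: bool,
    effects: EffectSpec,
    scale: float,
    rng: np.random.Generator,
) -> PatientVisit:
    values = {f: getattr(base, f) for f in (
        "weight", "glucose", "insulin", "tg", "tc", "ldl", "hdl", "waist",
        "hip", "t", "shbg", "dheas", "a4", "fg", "lh", "fsh", "menses6", "afc",
    )}
    bmi_drop = effects.bmi_drop_responder if bmi_resp else effects.bmi_drop_nonresponder
    bmi_drop += rng.normal(0.0, effects.bmi_noise_sd)
    values["weight"] = max(values["weight"] - scale * bmi_drop * height**2, 35.0)

    t_drop = effects.t_drop_responder if fai_resp else effects.t_drop_nonresponder
    values["t"] = max(values["t"] - scale * (t_drop + rng.normal(0.0, effects.t_noise_sd)), 0.05)
    shbg_rise = effects.shbg_rise_responder if fai_resp else effects.shbg_rise_nonresponder
    values["shbg"] = max(values["shbg"] + scale * (shbg_rise + rng.normal(0.0, effects.shbg_noise_sd)), 2.0)

    for var, shift, noise in effects.trends:
        values[var] = values[var] + scale * (shift + rng.normal(0.0, noise))
    values["menses6"] = float(np.clip(np.rint(values["menses6"]), 0, 6))
    values["fg"] = float(np.clip(np.rint(values["fg"]), 0, 36))
    values["afc"] = float(np.clip(np.rint(values["afc"]), 3, 90))
    for name, floor in (("glucose", 40.0), ("insulin", 1.0), ("tg", 30.0),
                        ("tc", 80.0), ("ldl", 20.0), ("hdl", 15.0),
                        ("waist", 50.0), ("dheas", 20.0), ("a4", 0.3),
                        ("lh", 0.3), ("fsh", 0.5)):
        values[name] = max(values[name], floor)
    return PatientVisit(visit=visit_name, pcom=base.pcom, **values)


def generate_longitudinal(
    cohort_m0: Cohort, config: GeneratorConfig, truth: Optional[GroundTruth] = None
) -> tuple[Cohort, GroundTruth]:
    """Draw responder status and append m6/m12 visits to every patient."""
    if truth is None:
        truth = GroundTruth(seed=config.seed, n=len(cohort_m0))
    indicators = _baseline_indicators(cohort_m0)
    records = []
    for i, record in enumerate(cohort_m0):
        rng = _patient_rng(config.seed, 1, i)
        ind = indicators[record.patient_id]
        bmi_resp = rng.uniform() < _response_prob(config.bmi_response, ind)
        fai_resp = rng.uniform() < _response_prob(config.fai_response, ind)
        truth.bmi_responder[record.patient_id] = bool(bmi_resp)
        truth.fai_responder[record.patient_id] = bool(fai_resp)

        m0 = record.visits["m0"]
        m6 = _shift_visit(m0, "m6", record.height, bmi_resp, fai_resp,
                          config.effect_spec, 1.0, rng)
        m12 = _shift_visit(m6, "m12", record.height, bmi_resp, fai_resp,
                           config.effect_spec, config.effect_spec.persistence, rng)
        records.append(
            PatientRecord(
                patient_id=record.patient_id,
                age=record.age,
                height=record.height,
                visits={"m0": m0, "m6": m6, "m12": m12},
                status="completed",
                dropout_interval="none",
            )
        )
    return Cohort(records=records, n_screened=cohort_m0.n_screened), truth


# ---------------------------------------------------------------------------
# Drop-out and pregnancy
# ---------------------------------------------------------------------------

def _truncate(record: PatientRecord, status: str, interval: str) -> PatientRecord:
    keep = ["m0"] if interval == "m0_m6" else ["m0", "m6"]
    return PatientRecord(
        patient_id=record.patient_id,
        age=record.age,
        height=record.height,
        visits={k: record.visits[k] for k in keep},
        status=status,
        dropout_interval=interval,
    )


def generate_dropout(
    cohort: Cohort, config: GeneratorConfig, truth: Optional[GroundTruth] = None
) -> tuple[Cohort, GroundTruth]:
    """Apply the low-testosterone drop-out process and interval pregnancies."""
    if truth is None:
        truth = GroundTruth(seed=config.seed, n=len(cohort))
    dm = config.dropout_model
    reasons = ("dropout_side_effects", "dropout_no_benefit", "lost_followup")
    records = []
    for i, record in enumerate(cohort):
        rng = _patient_rng(config.seed, 2, i)
        low_t = record.visits["m0"].t < dm.threshold
        p_drop = _sigmoid(dm.gamma0 + dm.gamma_lowt * low_t)
        truth.low_t[record.patient_id] = bool(low_t)
        drop = rng.uniform() < p_drop
        truth.dropout[record.patient_id] = bool(drop)
        if drop:
            interval = "m0_m6" if rng.uniform() < dm.p_first_interval else "m6_m12"
            reason = reasons[rng.choice(3, p=np.asarray(dm.reason_probs))]
            records.append(_truncate(record, reason, interval))
            continue
        # pregnancy check per interval, only for women still on the drug
        if config.pregnancy_rate > 0 and rng.uniform() < config.pregnancy_rate:
            records.append(_truncate(record, "pregnant", "m0_m6"))
            continue
        if config.pregnancy_rate > 0 and rng.uniform() < config.pregnancy_rate:
            records.append(_truncate(record, "pregnant", "m6_m12"))
            continue
        records.append(record)
    return Cohort(records=records, n_screened=cohort.n_screened), truth


def generate_cohort(config: GeneratorConfig) -> tuple[Cohort, GroundTruth]:
    """Full generator: baseline → longitudinal shifts → drop-out/pregnancy."""
    cohort, truth = generate_baseline(config)
    cohort, truth = generate_longitudinal(cohort, config, truth)
    cohort, truth = generate_dropout(cohort, config, truth)
    return cohort, truth


# ---------------------------------------------------------------------------
# Deterministic flow-chart replica
# ---------------------------------------------------------------------------

def reference_flow_cohort() -> Cohort:
    """A deterministic 108-woman cohort reproducing the study's flow accounting.

    Dispositions, eligibility and response changes are planted so that every
    published flow count is met exactly: 136 screened, 108 enrolled, 21
    first-interval drop-outs (6 side effects / 11 no perceived benefit / 4
    lost), 5 first-interval pregnancies, 82 assessed at m6, 25 second-interval
    drop-outs (8/10/7), 4 second-interval pregnancies, 53 completers; 103
    overweight/obese with 54 six-month BMI responders, 89 hyperandrogenemic
    with 45 six-month FAI responders, and 22 / 24 further responders at m12.
    """
    height = 1.63
    records = []
    for i in range(1, 109):
        # disposition
        if i <= 53:
            status, interval, visits_present = "completed", "none", ("m0", "m6", "m12")
        elif i <= 57:
            status, interval, visits_present = "pregnant", "m6_m12", ("m0", "m6")
        elif i <= 65:
            status, interval, visits_present = "dropout_side_effects", "m6_m12", ("m0", "m6")
        elif i <= 75:
            status, interval, visits_present = "dropout_no_benefit", "m6_m12", ("m0", "m6")
        elif i <= 82:
            status, interval, visits_present = "lost_followup", "m6_m12", ("m0", "m6")
        elif i <= 88:
            status, interval, visits_present = "dropout_side_effects", "m0_m6", ("m0",)
        elif i <= 99:
            status, interval, visits_present = "dropout_no_benefit", "m0_m6", ("m0",)
        elif i <= 103:
            status, interval, visits_present = "lost_followup", "m0_m6", ("m0",)
        else:
            status, interval, visits_present = "pregnant", "m0_m6", ("m0",)

        bmi_eligible = i <= 103  # the 5 first-interval pregnancies are lean
        fai_eligible = not (85 <= i <= 98 or i >= 104)  # 19 normoandrogenic
        bmi0 = 32.0 if bmi_eligible else 23.0
        fai0 = 13.0 if fai_eligible else 3.0

        bmi_resp_m6 = bmi_eligible and i <= 54
        fai_resp_m6 = fai_eligible and i <= 45
        bmi_resp_m12 = i <= 22
        fai_resp_m12 = i <= 24

        def mkvisit(name: str, bmi: float, fai: float) -> PatientVisit:
            return PatientVisit(
                visit=name,
                weight=bmi * height**2,
                glucose=90.0, insulin=18.0, tg=110.0, tc=185.0, ldl=120.0,
                hdl=43.0, waist=95.0, hip=105.0,
                t=fai * 34.7 / 347.0, shbg=34.7,
                dheas=270.0, a4=4.0, fg=12.0, lh=6.9, fsh=5.5,
                menses6=2.0, afc=40.0, pcom=True,
            )

        visits = {"m0": mkvisit("m0", bmi0, fai0)}
        if "m6" in visits_present:
            bmi6 = bmi0 - (1.2 if bmi_resp_m6 else 0.4)
            fai6 = fai0 - (1.5 if fai_resp_m6 else 0.3)
            visits["m6"] = mkvisit("m6", bmi6, fai6)
            if "m12" in visits_present:
                bmi12 = bmi6 - (1.2 if bmi_resp_m12 else 0.4)
                fai12 = fai6 - (1.5 if fai_resp_m12 else 0.3)
                visits["m12"] = mkvisit("m12", bmi12, fai12)
        records.append(
            PatientRecord(
                patient_id=f"R{i:03d}",
                age=28.0,
                height=height,
                visits=visits,
                status=status,
                dropout_interval=interval,
            )
        )
    return Cohort(records=records, n_screened=136)
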