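"""End-to-end pipeline: ingest or simulate → derive → label → map → select → stats.

One call runs the whole analysis on a cohort (read from CSV or generated
synthetically), writing every artefact to a run directory:

* ``flow_report.json`` — flow-chart accounting and response rates
* ``cutoffs.csv`` — median dichotomization table
* ``scm_bmi.graphml`` / ``scm_fai.graphml`` — semantic connectivity maps
* ``pole_priorities.json`` — node orderings from the responder poles
* ``twist_results.json`` — selected features and ab/ba ROC AUC
* ``dropout_stats.json`` — logistic model, 2×2 risk, correlation, group table
* ``manifest.json`` — config hash, seed and version: identical manifest ⇒
  identical outputs.

Stages needing a minimum sample (the maps and the evolutionary selection) skip
with a warning below 20 analysable records.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    Cohort, baseline_frame, flow_report, label_outcomes, read_cohort_csv,
    write_cohort_csv,
)
from .dichotomize import (
    DEFAULT_SCM_VARIABLES, RESPONDER_NODE, compute_cutoffs, dichotomize_matrix,
)
from .autocm import build_scm
from .mlp import MLPSpec
from .simulate import GeneratorConfig, generate_cohort, T_DROPOUT_THRESHOLD
from .stats import (
    TwoByTwo, friedman, group_comparison, logistic_fit, pearson_r, two_by_two_or,
)
from .twist import GASpec, TwistSelector

__all__ = ["RunConfig", "run_pipeline", "MIN_STAGE_N"]

logger = logging.getLogger("pcosmet")

#: Below this many analysable records the SCM and selection stages skip.
MIN_STAGE_N = 20

#: Baseline covariates of the drop-out regression.
DROPOUT_COVARIATES = ("t", "shbg", "fai", "dheas", "fg", "homa", "lh_fsh", "a4", "menses6")

#: Continuous baseline features offered to the evolutionary selector.
TWIST_FEATURES = (
    "age", "bmi", "glucose", "insulin", "homa", "tg", "tc", "ldl", "hdl",
    "whr", "t", "shbg", "fai", "dheas", "a4", "fg", "lh_fsh", "menses6", "afc",
)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on."""

    output_dir: str | Path = "pcosmet_run"
    seed: int = 0
    csv_path: Optional[str | Path] = None        # exactly one input mode:
    generator: Optional[GeneratorConfig] = None  # csv_path XOR generator
    scm_variables: tuple = DEFAULT_SCM_VARIABLES
    autocm_C: Optional[float] = None
    autocm_tol: float = 1e-6
    autocm_max_epochs: int = 3000
    ga_spec: GASpec = field(default_factory=GASpec)
    mlp_spec: MLPSpec = field(default_factory=MLPSpec)
    dropout_grouping: str = "any_dropout"  # or "m12_completion"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.csv_path is None) == (self.generator is None):
            raise ValueError("exactly one of csv_path or generator must be set")

    def to_dict(self) -> dict:
        """Semantic configuration: everything except where outputs land."""
        d = dataclasses.asdict(self)
        d.pop("output_dir")
        if self.csv_path is not None:
            d["csv_path"] = str(self.csv_path)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if "generator" in raw and isinstance(raw["generator"], dict):
            raw["generator"] = GeneratorConfig(**raw["generator"])
        if "ga_spec" in raw and isinstance(raw["ga_spec"], dict):
            raw["ga_spec"] = GASpec(**raw["ga_spec"])
        if "mlp_spec" in raw and isinstance(raw["mlp_spec"], dict):
            raw["mlp_spec"] = MLPSpec(**raw["mlp_spec"])
        return cls(**raw)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                logger.error("stage %s failed: %s", name, exc)
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def _dropout_stats(cohort: Cohort, grouping: str) -> dict:
    frame = baseline_frame(cohort, "m0")
    status = {r.patient_id: r.status for r in cohort}
    dropped = pd.Series(
        {pid: status[pid] in ("dropout_side_effects", "dropout_no_benefit", "lost_followup")
         for pid in frame.index}
    )
    pregnant = pd.Series({pid: status[pid] == "pregnant" for pid in frame.index})
    if grouping == "m12_completion":
        keep = ~pregnant
    else:  # completers + pregnancies vs discontinued
        keep = pd.Series(True, index=frame.index)
    sub = frame.loc[keep]
    y = dropped.loc[keep].astype(int)

    out: dict = {"grouping": grouping, "n": int(len(sub))}

    cov = sub[list(DROPOUT_COVARIATES)].dropna()
    yv = y.loc[cov.index]
    if yv.nunique() == 2 and len(cov) > len(DROPOUT_COVARIATES) + 1:
        try:
            fit = logistic_fit(cov, yv)
            out["logistic"] = fit.to_dict()
        except ValueError as exc:
            out["logistic"] = {"error": str(exc)}
    low_t = sub["t"] < T_DROPOUT_THRESHOLD
    a = int(((low_t) & (y == 1)).sum())
    b = int(((low_t) & (y == 0)).sum())
    c = int(((~low_t) & (y == 1)).sum())
    d = int(((~low_t) & (y == 0)).sum())
    try:
        out["low_t_odds_ratio"] = two_by_two_or(TwoByTwo(a, b, c, d)).to_dict()
    except ValueError as exc:
        out["low_t_odds_ratio"] = {"error": str(exc)}
    try:
        out["t_dropout_correlation"] = pearson_r(sub["t"], y).to_dict()
    except ValueError as exc:
        out["t_dropout_correlation"] = {"error": str(exc)}
    table = group_comparison(sub, ~y.astype(bool))
    out["group_comparison"] = json.loads(table.to_json(orient="index"))

    # within-subject change across visits in completers, key indices
    completers = Cohort([r for r in cohort if r.status == "completed"])
    if len(completers) >= 2:
        frames = {v: baseline_frame(completers, v) for v in ("m0", "m6", "m12")}
        fri = {}
        for var in ("bmi", "fai", "homa"):
            m = np.column_stack([frames[v][var].to_numpy() for v in ("m0", "m6", "m12")])
            m = m[~np.isnan(m).any(axis=1)]
            if len(m) >= 2:
                fri[var] = friedman(m).to_dict()
        out["friedman_completers"] = fri
    return out


@_stage("pipeline")
def run_pipeline(config: RunConfig) -> Path:
    """Run every stage; returns the run directory."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # --- input ---------------------------------------------------------
    if config.csv_path is not None:
        cohort = read_cohort_csv(config.csv_path)
        logger.info("read cohort of %d from %s", len(cohort), config.csv_path)
    else:
        gen = dataclasses.replace(config.generator, seed=config.generator.seed or config.seed)
        cohort, truth = generate_cohort(gen)
        write_cohort_csv(cohort, out_dir / "cohort.csv")
        truth.to_json(out_dir / "ground_truth.json")
        logger.info("generated synthetic cohort of %d (seed %d)", len(cohort), gen.seed)

    # --- flow accounting ----------------------------------------------
    report = flow_report(cohort)
    report.to_json(out_dir / "flow_report.json")

    # --- dichotomization -----------------------------------------------
    frame = baseline_frame(cohort, "m0")
    cutoffs = compute_cutoffs(frame, variables=list(config.scm_variables))
    cutoffs.to_csv(out_dir / "cutoffs.csv")

    # --- semantic maps ---------------------------------------------------
    priorities = {}
    for outcome, visit in (("bmi", "m6"), ("fai", "m12")):
        try:
            matrix = dichotomize_matrix(cohort, cutoffs, outcome=outcome, visit=visit)
        except ValueError as exc:
            logger.warning("SCM %s skipped: %s", outcome, exc)
            continue
        if len(matrix) < MIN_STAGE_N:
            logger.warning(
                "SCM %s skipped: %d analysable records < %d", outcome, len(matrix), MIN_STAGE_N
            )
            continue
        scm = build_scm(
            matrix, pole=RESPONDER_NODE, C=config.autocm_C,
            max_epochs=config.autocm_max_epochs, tol=config.autocm_tol,
        )
        scm.to_graphml(out_dir / f"scm_{outcome}.graphml")
        scm.to_dot(out_dir / f"scm_{outcome}.dot")
        priorities[outcome] = json.loads(scm.priorities_json())
    (out_dir / "pole_priorities.json").write_text(
        json.dumps(priorities, indent=2, sort_keys=True)
    )

    # --- evolutionary feature selection ---------------------------------
    labels = {}
    for record in cohort:
        flag = label_outcomes(record).bmi_responder_m6
        if flag is not None:
            labels[record.patient_id] = int(flag)
    features = frame.loc[frame.index.isin(labels), list(TWIST_FEATURES)].dropna()
    y = np.array([labels[p] for p in features.index])
    if len(features) >= MIN_STAGE_N and len(np.unique(y)) == 2:
        selector = TwistSelector(
            features.to_numpy(), y, feature_names=list(features.columns),
            ga_spec=config.ga_spec, mlp_spec=config.mlp_spec,
        )
        results = selector.fit(seed=config.seed)
        results.to_json(out_dir / "twist_results.json")
        logger.info("selected features: %s", results.selected_features)
    else:
        logger.warning("selection stage skipped: %d analysable records < %d",
                       len(features), MIN_STAGE_N)

    # --- drop-out statistics ---------------------------------------------
    stats_payload = _dropout_stats(cohort, config.dropout_grouping)
    (out_dir / "dropout_stats.json").write_text(
        json.dumps(stats_payload, indent=2, sort_keys=True, default=float)
    )

    # --- manifest --------------------------------------------------------
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "n_patients": len(cohort),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return out_dir
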