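"""Median dichotomization of continuous variables into paired HIGH/LOW nodes.

The association-mapping stage works on nominal variables: each continuous
baseline variable is split at its sample median into two complementary binary
nodes (e.g. ``FAI_HIGH`` / ``FAI_LOW``), and the outcome is encoded as a
``RESPONDER`` / ``NON_RESPONDER`` node pair.  Values strictly above the median
activate the HIGH node; values at or below it activate the LOW node.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .cohort import Cohort, baseline_frame, label_outcomes

__all__ = [
    "NODE_DISPLAY_NAMES",
    "DEFAULT_SCM_VARIABLES",
    "CutoffEntry",
    "CutoffTable",
    "BinaryNodeMatrix",
    "compute_cutoffs",
    "dichotomize_matrix",
    "dichotomize_frame",
]

#: Display name of each analysis variable in node labels (field vernacular:
#: CYCL = menstrual cycles / 6 months, GLIC = fasting glucose, TRIGL =
#: triglycerides, DHEA = DHEAS).
NODE_DISPLAY_NAMES = {
    "age": "AGE", "weight": "WEIGHT", "bmi": "BMI", "glucose": "GLIC",
    "insulin": "INS", "homa": "HOMA", "tg": "TRIGL", "tc": "CHOL",
    "ldl": "LDL", "hdl": "HDL", "whr": "WHR", "t": "T", "shbg": "SHBG",
    "fai": "FAI", "dheas": "DHEA", "a4": "A4", "fg": "FG", "lh_fsh": "LHFSH",
    "menses6": "CYCL", "afc": "AFC", "pcom": "PCOM",
}

#: Variables entering the semantic connectivity maps by default: the map-
#: relevant clinical set plus hormonal/morphologic context variables.
DEFAULT_SCM_VARIABLES = (
    "menses6", "fai", "fg", "homa", "bmi", "tg", "glucose", "dheas",
    "t", "shbg", "whr", "afc",
)

RESPONDER_NODE = "RESPONDER"
NON_RESPONDER_NODE = "NON_RESPONDER"


@dataclass(frozen=True)
class CutoffEntry:
    variable: str
    cutoff: float
    high_label: str
    low_label: str
    degenerate: bool = False  # constant variable: both sides collapse


@dataclass
class CutoffTable:
    """Per-variable median cutoffs and the names of the paired nodes."""

    entries: dict[str, CutoffEntry]

    def __getitem__(self, variable: str) -> CutoffEntry:
        return self.entries[variable]

    def __contains__(self, variable: str) -> bool:
        return variable in self.entries

    def __iter__(self):
        return iter(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)

    def node_names(self) -> list[str]:
        names = []
        for e in self.entries.values():
            names.extend([e.high_label, e.low_label])
        return names

    def to_csv(self, path: str | Path) -> None:
        frame = pd.DataFrame(
            [
                {"variable": e.variable, "cutoff": e.cutoff,
                 "high_label": e.high_label, "low_label": e.low_label,
                 "degenerate": e.degenerate}
                for e in self.entries.values()
            ]
        )
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CutoffTable":
        frame = pd.read_csv(path)
        entries = {
            row.variable: CutoffEntry(
                row.variable, float(row.cutoff), row.high_label, row.low_label,
                bool(row.degenerate),
            )
            for row in frame.itertuples()
        }
        return cls(entries=entries)


class BinaryNodeMatrix:
    """Patients × nodes 0/1 matrix fed to the auto-contractive map.

    Wraps a DataFrame whose columns are the HIGH/LOW variable nodes plus the
    outcome node pair; every variable satisfies HIGH + LOW = 1 per row.
    """

    def __init__(self, frame: pd.DataFrame):
        values = frame.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("binary node matrix entries must be 0/1")
        if len(set(frame.columns)) != len(frame.columns):
            raise ValueError("node names must be unique")
        self.frame = frame.astype(int)

    @property
    def node_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=True)


def compute_cutoffs(
    baseline: pd.DataFrame,
    variables: Optional[Iterable[str]] = None,
) -> CutoffTable:
    """Median cutoff per variable (mean of central order statistics for even n).

    All-missing variables are excluded with a warning; constant variables keep
    their (constant) median but are flagged degenerate.  ``baseline`` may be a
    :class:`~pcosmet.cohort.Cohort` (its m0 feature table is used) or any
    per-patient DataFrame of variables.
    """
    if isinstance(baseline, Cohort):
        baseline = baseline_frame(baseline, "m0")
    if variables is None:
        variables = [c for c in baseline.columns if c != "pcom"]
    entries: dict[str, CutoffEntry] = {}
    for var in variables:
        if var not in baseline.columns:
            raise KeyError(f"unknown variable {var!r}")
        col = baseline[var].dropna()
        if len(col) < 2:
            warnings.warn(f"variable {var!r} has < 2 observations; excluded")
            continue
        cutoff = float(col.median())
        degenerate = col.nunique() == 1
        if degenerate:
            warnings.warn(f"variable {var!r} is constant at {cutoff}; degenerate cutoff")
        display = NODE_DISPLAY_NAMES.get(var, var.upper())
        entries[var] = CutoffEntry(
            variable=var,
            cutoff=cutoff,
            high_label=f"{display}_HIGH",
            low_label=f"{display}_LOW",
            degenerate=degenerate,
        )
    return CutoffTable(entries=entries)


def dichotomize_frame(frame: pd.DataFrame, cutoffs: CutoffTable) -> pd.DataFrame:
    """HIGH/LOW encoding of a feature frame; rows with missing values dropped."""
    variables = [e.variable for e in cutoffs]
    sub = frame[variables].dropna()
    if len(sub) < len(frame):
        dropped = sorted(set(frame.index) - set(sub.index))
        warnings.warn(f"{len(dropped)} rows with missing variables excluded: {dropped[:5]}...")
    columns = {}
    for entry in cutoffs:
        high = (sub[entry.variable] > entry.cutoff).astype(int)
        columns[entry.high_label] = high
        columns[entry.low_label] = 1 - high
    return pd.DataFrame(columns, index=sub.index)


def dichotomize_matrix(
    cohort: Cohort,
    cutoffs: CutoffTable,
    outcome: str = "bmi",
    visit: str = "m6",
) -> BinaryNodeMatrix:
    """Build the node matrix for one outcome at one visit.

    Rows are the outcome-eligible patients whose responder label at ``visit``
    is defined; the outcome node pair comes from the label.  ``outcome`` is
    ``"bmi"`` or ``"fai"``.
    """
    if outcome not in ("bmi", "fai"):
        raise ValueError("outcome must be 'bmi' or 'fai'")
    if visit not in ("m6", "m12"):
        raise ValueError("labels exist only at m6 and m12")

    labels = {}
    for record in cohort:
        lab = label_outcomes(record)
        flag = getattr(lab, f"{outcome}_responder_{visit}")
        if flag is not None:
            labels[record.patient_id] = bool(flag)
    if not labels:
        raise ValueError(f"no {outcome} labels defined at {visit}")

    frame = baseline_frame(cohort, "m0")
    frame = frame.loc[frame.index.isin(labels)]
    encoded = dichotomize_frame(frame, cutoffs)
    responder = pd.Series({pid: int(labels[pid]) for pid in encoded.index})
    encoded[RESPONDER_NODE] = responder
    encoded[NON_RESPONDER_NODE] = 1 - responder
    return BinaryNodeMatrix(encoded)
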