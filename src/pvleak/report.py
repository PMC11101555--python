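"""Regurgitant-volume conversion, severity grading and result files.

The solver predicts a steady leakage flow rate in ml/s.  Leakage only
occurs while the valve is closed, so the flow rate is converted to a
per-beat regurgitant volume (RV) using the diastolic duration
(60/heart-rate × diastolic fraction; ≈0.56 s at 70 bpm and 65%
diastole) and graded on the Kappetein scale:

    none      RV = 0 ml
    mild      0 < RV < 30 ml
    moderate  30 ≤ RV < 60 ml
    severe    RV ≥ 60 ml

The published class bounds ("30–59 ml" vs "> 60 ml") leave [59, 60) ml
unassigned; moderate is taken as [30, 60) so the scale is gapless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "LeakageReport",
    "diastolic_duration",
    "flow_to_rv",
    "classify_pvl",
    "write_report",
    "read_report",
]

SEVERITIES = ("none", "mild", "moderate", "severe")
SCHEMA_VERSION = 1

_REQUIRED_FIELDS = {
    "schema_version",
    "flow_rate_ml_s",
    "diastolic_duration_s",
    "regurgitant_volume_ml",
    "severity",
}


def diastolic_duration(heart_rate: float, diastolic_fraction: float) -> float:
    """Duration of diastole per beat: (60 / heart_rate) · fraction, seconds."""
    if heart_rate <= 0:
        raise ValueError("heart_rate must be positive")
    if not (0 < diastolic_fraction < 1):
        raise ValueError("diastolic_fraction must be strictly between 0 and 1")
    return 60.0 / heart_rate * diastolic_fraction


def flow_to_rv(Q_ml_s: float, heart_rate: float, diastolic_fraction: float) -> float:
    """Convert a diastolic leakage rate (ml/s) to regurgitant volume (ml)."""
    if Q_ml_s < 0:
        raise ValueError(
            "negative flow rate; inlet/outlet orientation is inconsistent upstream"
        )
    return Q_ml_s * diastolic_duration(heart_rate, diastolic_fraction)


def classify_pvl(rv_ml: float) -> str:
    """Kappetein severity class for a regurgitant volume in ml."""
    if rv_ml < 0:
        raise ValueError("regurgitant volume must be non-negative")
    if rv_ml == 0:
        return "none"
    if rv_ml < 30:
        return "mild"
    if rv_ml < 60:
        return "moderate"
    return "severe"


@dataclass
class LeakageReport:
    """Leakage result in clinical units plus the provenance traces."""

    flow_rate_ml_s: float
    diastolic_duration_s: float
    regurgitant_volume_ml: float
    severity: str
    scaling: dict | None = None       # ScalingReport trace (SI values)
    solver: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.severity not in SEVERITIES:
            raise ValueError(f"severity must be one of {SEVERITIES}")

    @classmethod
    def from_flow_rate(
        cls,
        Q_ml_s: float,
        heart_rate: float = 70.0,
        diastolic_fraction: float = 0.65,
        scaling: dict | None = None,
        solver: dict | None = None,
        inputs: dict | None = None,
    ) -> "LeakageReport":
        rv = flow_to_rv(Q_ml_s, heart_rate, diastolic_fraction)
        return cls(
            flow_rate_ml_s=float(Q_ml_s),
            diastolic_duration_s=diastolic_duration(heart_rate, diastolic_fraction),
            regurgitant_volume_ml=float(rv),
            severity=classify_pvl(rv),
            scaling=scaling,
            solver=dict(solver or {}),
            inputs=dict(inputs or {}),
        )

    def to_dict(self) -> dict:
        from . import __version__

        return {
            "schema_version": SCHEMA_VERSION,
            "software": {"name": "pvleak", "version": __version__},
            "units": {"flow_rate": "ml/s", "regurgitant_volume": "ml", "duration": "s"},
            "flow_rate_ml_s": self.flow_rate_ml_s,
            "diastolic_duration_s": self.diastolic_duration_s,
            "regurgitant_volume_ml": self.regurgitant_volume_ml,
            "severity": self.severity,
            "scaling": self.scaling,
            "solver": self.solver,
            "inputs": self.inputs,
        }


def write_report(report: LeakageReport, path: str | Path) -> Path:
    """Serialise a report to JSON (schema-validated on read-back)."""
    path = Path(path)
    path.write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    return path


def read_report(path: str | Path) -> LeakageReport:
    """Read and validate a report file; missing fields are named."""
    data = json.loads(Path(path).read_text())
    missing = _REQUIRED_FIELDS - data.keys()
    if missing:
        raise ValueError(f"report file is missing required field(s): {sorted(missing)}")
    if data["schema_version"] != SCHEMA_VERSION:
        raise ValueError(f"unsupported report schema version {data['schema_version']}")
    return LeakageReport(
        flow_rate_ml_s=data["flow_rate_ml_s"],
        diastolic_duration_s=data["diastolic_duration_s"],
        regurgitant_volume_ml=data["regurgitant_volume_ml"],
        severity=data["severity"],
        scaling=data.get("scaling"),
        solver=data.get("solver", {}),
        inputs=data.get("inputs", {}),
    )
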