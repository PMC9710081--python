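"""Domain record types shared across the simulator, metrics and pipeline.

All dates are integer day numbers counted from an arbitrary epoch; quarters
are fixed 90-day blocks, so no calendar arithmetic is ever needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

DRUG_CLASSES = ("lipid_lowering", "cvd", "other")

#: Hospitalisation condition categories the simulator can emit.  These are a
#: representative subset of the CVD history / outcome flag vocabulary used in
#: New Zealand CVD cohort research (HX_* = prior history, OUT_* = outcome
#: events after the index assessment).
HOSPITAL_CATEGORIES = (
    "HX_BROAD_CVD",
    "HX_ATHERO_CVD",
    "HX_MI",
    "HX_ANGINA",
    "HX_HEART_FAILURE",
    "HX_ATRIAL_FIBRILLATION",
    "OUT_BROAD_CVD",
    "OUT_MI",
    "OUT_HEART_FAILURE",
)

LAB_ANALYTES = ("HDL", "LDL", "TRI", "TCL", "TCHDL", "HBA1C", "EGFR")
CHOLESTEROL_ANALYTES = ("HDL", "LDL", "TRI", "TCL", "TCHDL")

ETHNICITIES = ("European", "Maori", "Pacific", "Asian", "Indian")
#: Labels removed by the default ethnicity exclusion filter.
EXCLUDED_ETHNICITIES = ("MELAA", "Other")


@dataclass
class PatientProfile:
    """Static per-patient record: demographics plus risk-assessment fields."""

    patient_id: str
    sex: str  # "M" or "F"
    age_at_index: int
    ethnicity: str
    nzdep: int  # deprivation quintile 1..5
    index_date: int
    death_date: Optional[int] = None
    predict_fields: dict = field(default_factory=dict)


@dataclass(frozen=True)
class DispenseEvent:
    """One community-pharmacy dispensing: the atom of adherence computation."""

    patient_id: str
    drug_code: str
    drug_class: str
    dispense_date: int
    days_supply: int

    def __post_init__(self):
        if self.days_supply <= 0:
            raise ValueError(
                f"days_supply must be positive, got {self.days_supply}"
            )
        if self.drug_class not in DRUG_CLASSES:
            raise ValueError(f"unknown drug_class {self.drug_class!r}")


@dataclass(frozen=True)
class LabResult:
    patient_id: str
    analyte: str
    date: int
    value: float

    def __post_init__(self):
        if self.analyte not in LAB_ANALYTES:
            raise ValueError(f"unknown analyte {self.analyte!r}")


@dataclass(frozen=True)
class HospitalEvent:
    patient_id: str
    admit_date: int
    discharge_date: int
    acute: bool
    categories: frozenset = frozenset()

    def __post_init__(self):
        if self.discharge_date < self.admit_date:
            raise ValueError("discharge_date earlier than admit_date")


@dataclass
class AdherencePhenotype:
    """Latent behaviour class driving a simulated dispensing trajectory.

    ``discontinue_hazard`` and ``restart_prob`` are per-quarter
    probabilities; ``stockpile_tendency`` is the probability a refill is
    collected before the previous supply runs out.
    """

    class_: str  # persistent | discontinuer | intermittent | switcher
    refill_gap_mean: float = 0.0
    discontinue_hazard: float = 0.0
    restart_prob: float = 0.0
    switch_quarter: Optional[int] = None
    stockpile_tendency: float = 0.0

    def __post_init__(self):
        for name in ("discontinue_hazard", "restart_prob", "stockpile_tendency"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.refill_gap_mean < 0:
            raise ValueError("refill_gap_mean must be >= 0")
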