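"""Cohort assembly: exclusion cascade, 90-day quarter grid, feature tensor.

The study design anchors each patient at an index (risk-assessment) date.
Observation quarter ``q`` (1..8) spans ``[index - (9-q)*90, index - (8-q)*90)``
and prediction quarter ``q`` (1..20) spans ``[index + (q-1)*90, index + q*90)``;
the index day itself belongs to prediction quarter 1.

Features fall into 8 categories — Demographic, Lipids, Lipid-lowering drugs,
CVD drugs, Other drugs, Hospitalisation, HbA1c and eGFR, and risk-assessment
(PREDICT) fields — assembled into a patients x quarters x features tensor
over the observation window, with the binary adherence label derived from
mean prediction-window class-level PDC (>= 80).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .adherence import Period, adherence_label, build_coverage, pdc, quarterly_class_pdc
from .records import (
    CHOLESTEROL_ANALYTES,
    ETHNICITIES,
    EXCLUDED_ETHNICITIES,
    HOSPITAL_CATEGORIES,
)
from .simulate import Cohort, LL_DRUGS

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class QuarterGrid:
    index_date: int
    n_obs_quarters: int = 8
    n_pred_quarters: int = 20
    quarter_length: int = 90

    def obs_period(self, q: int) -> Period:
        if not 1 <= q <= self.n_obs_quarters:
            raise ValueError(f"observation quarter {q} out of range")
        L = self.quarter_length
        n = self.n_obs_quarters
        return Period(self.index_date - (n + 1 - q) * L,
                      self.index_date - (n - q) * L)

    def pred_period(self, q: int) -> Period:
        if not 1 <= q <= self.n_pred_quarters:
            raise ValueError(f"prediction quarter {q} out of range")
        L = self.quarter_length
        return Period(self.index_date + (q - 1) * L, self.index_date + q * L)

    def observation_quarters(self) -> list[Period]:
        return [self.obs_period(q) for q in range(1, self.n_obs_quarters + 1)]

    def prediction_quarters(self) -> list[Period]:
        return [self.pred_period(q) for q in range(1, self.n_pred_quarters + 1)]

    @property
    def obs_start(self) -> int:
        return self.index_date - self.n_obs_quarters * self.quarter_length

    @property
    def pred_end(self) -> int:
        return self.index_date + self.n_pred_quarters * self.quarter_length


def assign_quarter(date: int, grid: QuarterGrid):
    """Map a day to ('obs', q) / ('pred', q) or None outside the window."""
    L = grid.quarter_length
    if grid.obs_start <= date < grid.index_date:
        return ("obs", grid.n_obs_quarters - (grid.index_date - 1 - date) // L)
    if grid.index_date <= date < grid.pred_end:
        return ("pred", 1 + (date - grid.index_date) // L)
    return None


# ---------------------------------------------------------------------------
# exclusion cascade
# ---------------------------------------------------------------------------

@dataclass
class ExclusionReport:
    rows: list = field(default_factory=list)  # (rule, removed, remaining)

    def append(self, rule: str, removed: int, remaining: int) -> None:
        self.rows.append((rule, removed, remaining))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows,
                            columns=["rule", "removed", "remaining"])


def _grid_for(profile, grid: QuarterGrid) -> QuarterGrid:
    return dataclasses.replace(grid, index_date=profile.index_date)


def _rule_index_date_range(profile, data, grid, params) -> bool:
    lo, hi = params.get("index_day_range", (0, 10**9))
    return lo <= profile.index_date <= hi


def _rule_cholesterol_complete(profile, data, grid, params) -> bool:
    g = _grid_for(profile, grid)
    obs_seen, pred_seen = set(), set()
    for r in data["labs"].get(profile.patient_id, []):
        if r.analyte not in CHOLESTEROL_ANALYTES:
            continue
        where = assign_quarter(r.date, g)
        if where is None:
            continue
        (obs_seen if where[0] == "obs" else pred_seen).add(r.analyte)
    need = set(CHOLESTEROL_ANALYTES)
    return obs_seen >= need and pred_seen >= need


def _rule_lipid_dispense(profile, data, grid, params) -> bool:
    g = _grid_for(profile, grid)
    look_ahead = params.get("look_ahead_days", 14)
    for e in data["dispenses"].get(profile.patient_id, []):
        if (e.drug_class == "lipid_lowering"
                and g.obs_start <= e.dispense_date < g.index_date + look_ahead):
            return True
    return False


def _rule_infeasible_values(profile, data, grid, params) -> bool:
    if not 0 < profile.age_at_index <= 120:
        return False
    if profile.nzdep not in range(1, 6):
        return False
    for r in data["labs"].get(profile.patient_id, []):
        if r.analyte in CHOLESTEROL_ANALYTES and r.value <= 0:
            return False
    for e in data["dispenses"].get(profile.patient_id, []):
        if e.days_supply <= 0:
            return False
    return True


def _rule_age(profile, data, grid, params) -> bool:
    return profile.age_at_index >= params.get("min_age", 18)


def _rule_ethnicity(profile, data, grid, params) -> bool:
    excluded = params.get("excluded_ethnicities", EXCLUDED_ETHNICITIES)
    return profile.ethnicity not in excluded

RULES: dict[str, Callable] = {
    "index_date_range": _rule_index_date_range,
    "cholesterol_complete": _rule_cholesterol_complete,
    "lipid_dispense": _rule_lipid_dispense,
    "infeasible_values": _rule_infeasible_values,
    "age": _rule_age,
    "ethnicity": _rule_ethnicity,
}

DEFAULT_RULES = (
    "index_date_range",
    "cholesterol_complete",
    "lipid_dispense",
    "infeasible_values",
    "age",
    "ethnicity",
)


def _index_events(cohort: Cohort) -> dict:
    data = {"dispenses": {}, "labs": {}, "hospital_events": {}}
    for e in cohort.dispenses:
        data["dispenses"].setdefault(e.patient_id, []).append(e)
    for r in cohort.labs:
        data["labs"].setdefault(r.patient_id, []).append(r)
    for h in cohort.hospital_events:
        data["hospital_events"].setdefault(h.patient_id, []).append(h)
    return data


def apply_exclusions(
    cohort: Cohort,
    grid: QuarterGrid,
    rules: Sequence[str] = DEFAULT_RULES,
    params: Optional[dict] = None,
) -> tuple[Cohort, ExclusionReport]:
    """Apply the ordered inclusion cascade; pure per-patient predicates."""
    params = params or {}
    for name in rules:
        if name not in RULES:
            raise ValueError(f"unknown exclusion rule {name!r}")
    data = _index_events(cohort)
    report = ExclusionReport()
    kept = list(cohort.profiles)
    for name in rules:
        pred = RULES[name]
        before = len(kept)
        kept = [p for p in kept if pred(p, data, grid, params)]
        report.append(name, before - len(kept), len(kept))
    ids = {p.patient_id for p in kept}
    filtered = Cohort(
        profiles=kept,
        dispenses=[e for e in cohort.dispenses if e.patient_id in ids],
        labs=[r for r in cohort.labs if r.patient_id in ids],
        hospital_events=[h for h in cohort.hospital_events if h.patient_id in ids],
        ground_truth={k: v for k, v in cohort.ground_truth.items() if k in ids},
        config=cohort.config,
        seed=cohort.seed,
    )
    return filtered, report


# ---------------------------------------------------------------------------
# feature registry and tensor
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Feature:
    name: str
    category: str
    time_varying: bool
    continuous: bool


def default_registry() -> list[Feature]:
    reg: list[Feature] = []
    add = reg.append
    # Demographic
    add(Feature("AGE", "Demographic", True, True))
    add(Feature("SEX_M", "Demographic", False, False))
    for eth in ETHNICITIES:
        add(Feature(f"ETH_{eth.upper()}", "Demographic", False, False))
    add(Feature("NZDEP", "Demographic", False, True))
    # Lipids
    for a in CHOLESTEROL_ANALYTES:
        add(Feature(a, "Lipids", True, True))
    add(Feature("TEST", "Lipids", True, False))
    add(Feature("TESTED", "Lipids", True, False))
    # Lipid-lowering drugs
    for d in LL_DRUGS:
        add(Feature(f"LL_{d}", "Lipid-lowering drugs", True, True))
    add(Feature("LL_PDC", "Lipid-lowering drugs", True, True))
    # CVD / Other drugs
    add(Feature("CVD_PDC", "CVD drugs", True, True))
    add(Feature("OTHER_PDC", "Other drugs", True, True))
    # Hospitalisation
    add(Feature("HOSP_DAYS", "Hospitalisation", True, True))
    add(Feature("ACUTE_ADM", "Hospitalisation", True, False))
    for c in HOSPITAL_CATEGORIES:
        add(Feature(c, "Hospitalisation", True, False))
    # HbA1c and eGFR
    for a in ("HBA1C", "EGFR"):
        add(Feature(a, "HbA1c and eGFR", True, True))
        add(Feature(f"TEST_{a}", "HbA1c and eGFR", True, False))
        add(Feature(f"TESTED_{a}", "HbA1c and eGFR", True, False))
    # PREDICT risk-assessment fields (one-hot for categoricals)
    add(Feature("PT_SBP", "PREDICT", False, True))
    add(Feature("PT_DBP", "PREDICT", False, True))
    for k in range(6):
        add(Feature(f"PT_SMOKING_{k}", "PREDICT", False, False))
    for k in range(4):
        add(Feature(f"PT_DIABETES_{k}", "PREDICT", False, False))
    add(Feature("PT_EN_TCHDL", "PREDICT", False, True))
    add(Feature("PT_FAMILY_HISTORY", "PREDICT", False, False))
    for k in range(5):
        add(Feature(f"PT_GEN_LIPID_{k}", "PREDICT", False, False))
    for k in range(5):
        add(Feature(f"PT_RENAL_{k}", "PREDICT", False, False))
    for k in range(3):
        add(Feature(f"PT_ATRIAL_FIBRILLATION_{k}", "PREDICT", False, False))
    add(Feature("PT_DIABETES_YR", "PREDICT", False, True))
    return reg


@dataclass
class FeatureTensor:
    patient_ids: list
    quarter_labels: list
    registry: list            # list[Feature]
    values: np.ndarray        # (n_patients, n_quarters, n_features)
    labels: np.ndarray        # (n_patients,) in {0,1}

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.registry]

    def feature_index(self, name: str) -> int:
        return self.feature_names.index(name)

    def to_dir(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for qi, qlabel in enumerate(self.quarter_labels):
            frame = pd.DataFrame(self.values[:, qi, :],
                                 columns=self.feature_names)
            frame.insert(0, "patient_id", self.patient_ids)
            frame.to_csv(outdir / f"quarter_{qlabel}.csv", index=False)
        pd.DataFrame({"patient_id": self.patient_ids,
                      "label": self.labels}).to_csv(
            outdir / "labels.csv", index=False)
        manifest = {
            "quarter_labels": list(self.quarter_labels),
            "registry": [dataclasses.asdict(f) for f in self.registry],
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_dir(cls, indir) -> "FeatureTensor":
        indir = Path(indir)
        manifest = json.loads((indir / "manifest.json").read_text())
        registry = [Feature(**d) for d in manifest["registry"]]
        qlabels = manifest["quarter_labels"]
        labels_df = pd.read_csv(indir / "labels.csv")
        patient_ids = labels_df["patient_id"].tolist()
        names = [f.name for f in registry]
        slices = []
        for qlabel in qlabels:
            frame = pd.read_csv(indir / f"quarter_{qlabel}.csv",
                                float_precision="round_trip")
            slices.append(frame[names].to_numpy(dtype=float))
        values = np.stack(slices, axis=1)
        return cls(patient_ids, qlabels, registry, values,
                   labels_df["label"].to_numpy(dtype=int))


def _locf_series(tests, quarters: list[Period]):
    """Per-quarter (value, test, tested) with last observation carried forward.

    ``tests``: sorted (day, value) pairs over the full history.  Value is 0
    before any test; the TEST/TESTED flags disambiguate true zeros.
    """
    vals, test_flag, tested_flag = [], [], []
    j = 0
    last = 0.0
    seen = False
    for qp in quarters:
        in_quarter = False
        while j < len(tests) and tests[j][0] < qp.end:
            if tests[j][0] >= qp.start:
                in_quarter = True
            last = tests[j][1]
            seen = True
            j += 1
        vals.append(last if seen else 0.0)
        test_flag.append(1.0 if in_quarter else 0.0)
        tested_flag.append(1.0 if seen else 0.0)
    return vals, test_flag, tested_flag


def build_feature_tensor(
    cohort: Cohort,
    grid: QuarterGrid,
    registry: Optional[list[Feature]] = None,
    include_carry_in: bool = True,
) -> FeatureTensor:
    """Assemble the observation-window tensor and prediction-window labels.

    Coverage for PDC features is built from each drug's full event history
    (lead-in included) and intersected with the quarters, so stockpile
    carries across window boundaries; ``include_carry_in=False`` instead
    drops events dated before the observation window.
    """
    registry = registry or default_registry()
    names = [f.name for f in registry]
    col = {n: i for i, n in enumerate(names)}
    data = _index_events(cohort)
    n = len(cohort.profiles)
    T = grid.n_obs_quarters
    values = np.zeros((n, T, len(names)))
    labels = np.zeros(n, dtype=int)
    n_dropped = 0

    for pi, p in enumerate(cohort.profiles):
        g = _grid_for(p, grid)
        obs_q = g.observation_quarters()
        pred_q = g.prediction_quarters()
        events = data["dispenses"].get(p.patient_id, [])
        if not include_carry_in:
            events = [e for e in events if e.dispense_date >= g.obs_start]
        n_dropped += sum(1 for e in events
                         if not g.obs_start - 10**6 <= e.dispense_date < g.pred_end)

        # --- dispensing-derived PDC features -------------------------
        ll = [e for e in events if e.drug_class == "lipid_lowering"]
        if ll:
            qpdc = quarterly_class_pdc(ll, obs_q + pred_q)
            for t in range(T):
                per_drug = qpdc[t].per_drug
                for d in LL_DRUGS:
                    key = f"LL_{d}"
                    if key in col:
                        values[pi, t, col[key]] = per_drug.get(d, 0.0)
                if "LL_PDC" in col:
                    values[pi, t, col["LL_PDC"]] = qpdc[t].combined
            labels[pi] = adherence_label(
                [qpdc[T + k].combined for k in range(len(pred_q))])
        for klass, key in (("cvd", "CVD_PDC"), ("other", "OTHER_PDC")):
            if key not in col:
                continue
            evs = sorted((e for e in events if e.drug_class == klass),
                         key=lambda e: e.dispense_date)
            if evs:
                cov = build_coverage(evs)
                for t, qp in enumerate(obs_q):
                    values[pi, t, col[key]] = pdc(cov, qp).pdc

        # --- labs ----------------------------------------------------
        labs = data["labs"].get(p.patient_id, [])
        chol_days = sorted({r.date for r in labs
                            if r.analyte in CHOLESTEROL_ANALYTES})
        by_analyte: dict[str, list] = {}
        for r in labs:
            by_analyte.setdefault(r.analyte, []).append((r.date, r.value))
        any_test, any_tested = None, None
        for a in CHOLESTEROL_ANALYTES:
            tests = sorted(by_analyte.get(a, []))
            vals, tflag, tdflag = _locf_series(tests, obs_q)
            if a in col:
                for t in range(T):
                    values[pi, t, col[a]] = vals[t]
            any_test = tflag if any_test is None else [
                max(x, y) for x, y in zip(any_test, tflag)]
            any_tested = tdflag if any_tested is None else [
                max(x, y) for x, y in zip(any_tested, tdflag)]
        if "TEST" in col and any_test is not None:
            for t in range(T):
                values[pi, t, col["TEST"]] = any_test[t]
                values[pi, t, col["TESTED"]] = any_tested[t]
        for a in ("HBA1C", "EGFR"):
            tests = sorted(by_analyte.get(a, []))
            vals, tflag, tdflag = _locf_series(tests, obs_q)
            for t in range(T):
                if a in col:
                    values[pi, t, col[a]] = vals[t]
                if f"TEST_{a}" in col:
                    values[pi, t, col[f"TEST_{a}"]] = tflag[t]
                if f"TESTED_{a}" in col:
                    values[pi, t, col[f"TESTED_{a}"]] = tdflag[t]
        del chol_days

        # --- hospitalisation -----------------------------------------
        for h in data["hospital_events"].get(p.patient_id, []):
            for t, qp in enumerate(obs_q):
                overlap = max(0, min(h.discharge_date + 1, qp.end)
                              - max(h.admit_date, qp.start))
                if overlap <= 0 and not qp.start <= h.admit_date < qp.end:
                    continue
                if "HOSP_DAYS" in col:
                    values[pi, t, col["HOSP_DAYS"]] += overlap
                if h.acute and "ACUTE_ADM" in col \
                        and qp.start <= h.admit_date < qp.end:
                    values[pi, t, col["ACUTE_ADM"]] = 1.0
                for c in h.categories:
                    if c in col and qp.start <= h.admit_date < qp.end:
                        values[pi, t, col[c]] = 1.0

        # --- static demographics / risk-assessment fields ------------
        for t in range(T):
            if "AGE" in col:
                # AGE advances with quarters; equals age_at_index at quarter 8
                offset_days = (t + 1 - T) * g.quarter_length
                values[pi, t, col["AGE"]] = (
                    p.age_at_index + offset_days / DAYS_PER_YEAR)
            if "SEX_M" in col:
                values[pi, t, col["SEX_M"]] = 1.0 if p.sex == "M" else 0.0
            key = f"ETH_{p.ethnicity.upper()}"
            if key in col:
                values[pi, t, col[key]] = 1.0
            if "NZDEP" in col:
                values[pi, t, col["NZDEP"]] = p.nzdep
            pf = p.predict_fields
            for name in ("PT_SBP", "PT_DBP", "PT_EN_TCHDL", "PT_DIABETES_YR",
                         "PT_FAMILY_HISTORY"):
                if name in col and name in pf:
                    values[pi, t, col[name]] = float(pf[name])
            for name, width in (("PT_SMOKING", 6), ("PT_DIABETES", 4),
                                ("PT_GEN_LIPID", 5), ("PT_RENAL", 5),
                                ("PT_ATRIAL_FIBRILLATION", 3)):
                if name in pf:
                    k = int(float(pf[name]))
                    key = f"{name}_{k}"
                    if key in col and 0 <= k < width:
                        values[pi, t, col[key]] = 1.0

    if n_dropped:
        logger.info("dropped %d events outside the window grid", n_dropped)
    qlabels = [f"obs{q}" for q in range(1, T + 1)]
    return FeatureTensor([p.patient_id for p in cohort.profiles],
                         qlabels, registry, values, labels)


# ---------------------------------------------------------------------------
# model input variants
# ---------------------------------------------------------------------------

VARIANTS = ("sequential", "flattened", "aggregated", "last_quarter")


def make_model_inputs(tensor: FeatureTensor, variant: str):
    """Model-ready inputs.

    sequential   -> (n, T, F) array for recurrent models
    flattened    -> (n, T*F) concatenation across quarters
    aggregated   -> static features at the last observation quarter, means
                    of time-varying features (AGE excepted: last-quarter value)
    last_quarter -> last observation-quarter slice only
    """
    X = tensor.values
    if variant == "sequential":
        return X.copy(), tensor.labels.copy()
    if variant == "flattened":
        return X.reshape(X.shape[0], -1).copy(), tensor.labels.copy()
    if variant == "last_quarter":
        return X[:, -1, :].copy(), tensor.labels.copy()
    if variant == "aggregated":
        out = np.empty((X.shape[0], X.shape[2]))
        for j, f in enumerate(tensor.registry):
            if f.time_varying and f.name != "AGE":
                out[:, j] = X[:, :, j].mean(axis=1)
            else:
                out[:, j] = X[:, -1, j]
        return out, tensor.labels.copy()
    raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")


class FeatureScaler:
    """Z-standardise continuous columns using training statistics only.

    Binary / one-hot columns are left untouched.  Works on 2-D and 3-D
    (sequential) inputs; the continuous mask is derived from the tensor's
    feature registry and tiled for flattened inputs.
    """

    def __init__(self, continuous_mask: np.ndarray):
        self.continuous_mask = np.asarray(continuous_mask, dtype=bool)

    @classmethod
    def for_variant(cls, tensor: FeatureTensor, variant: str) -> "FeatureScaler":
        base = np.array([f.continuous for f in tensor.registry])
        if variant == "flattened":
            base = np.tile(base, tensor.values.shape[1])
        return cls(base)

    def fit(self, X: np.ndarray) -> "FeatureScaler":
        flat = X.reshape(-1, X.shape[-1])
        m = self.continuous_mask
        self.mean_ = np.zeros(X.shape[-1])
        self.std_ = np.ones(X.shape[-1])
        self.mean_[m] = flat[:, m].mean(axis=0)
        std = flat[:, m].std(axis=0)
        self.std_[m] = np.where(std > 0, std, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.std_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)
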