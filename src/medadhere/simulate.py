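"""Seeded synthetic cohort generator for adherence prediction experiments.

Emulates the structure of linked routinely-collected CVD-management data:
per-patient pharmacy dispensing trajectories driven by latent adherence
phenotypes, quarterly lab-testing patterns, hospitalisation histories,
demographics and risk-assessment fields — arranged around an index
(risk-assessment) date that splits an observation window (default 8
ninety-day quarters) from a prediction window (default 20 quarters).

Four latent phenotypes drive dispensing behaviour:

* ``persistent`` — near-seamless refills, occasionally collected early
  (building stockpile), rarely discontinuing.
* ``discontinuer`` — two sub-modes with similar *average* observation-window
  coverage but different dynamics: a *declining* mode whose refill gaps
  escalate over the last observation quarters and who stops early in the
  prediction window, and a *steady* mode with constant moderate gaps and a
  low stopping hazard.  Future coverage therefore depends on the *shape* of
  recent history, not just its mean, so sequence order carries information.
* ``intermittent`` — alternating on/off treatment episodes.
* ``switcher`` — changes lipid-lowering drug (e.g. simvastatin to
  atorvastatin) at a switch quarter, first drug ceasing there.

Time is measured in integer days from the start of a lead-in period
(default 4 quarters before the observation window) so that carried-in
stockpile is exercised.  Identical ``(config, seed)`` pairs yield
byte-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .adherence import Period, adherence_label, quarterly_class_pdc
from .records import (
    AdherencePhenotype,
    DispenseEvent,
    ETHNICITIES,
    EXCLUDED_ETHNICITIES,
    HospitalEvent,
    LabResult,
    PatientProfile,
)

LL_DRUGS = ("SIMVASTATIN", "ATORVASTATIN")
CVD_DRUG = "METOPROLOL"
OTHER_DRUG = "METFORMIN"

#: Default phenotype mixture.  Calibrated once against the simulator's own
#: ground-truth label tally so the adherent fraction lands near the 57.6%
#: prevalence typical of large lipid-lowering cohorts; configurable.
DEFAULT_WEIGHTS = {
    "persistent": 0.28,
    "discontinuer": 0.44,
    "intermittent": 0.20,
    "switcher": 0.08,
}


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.  Defaults are the study conditions."""

    n_patients: int = 5000
    phenotype_weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    lead_in_quarters: int = 4
    n_obs_quarters: int = 8
    n_pred_quarters: int = 20
    quarter_length: int = 90
    lab_test_rate: float = 0.316      # cholesterol panel, per quarter
    hba1c_test_rate: float = 0.289
    egfr_test_rate: float = 0.372
    death_hazard: float = 0.0024      # per quarter, from the index date
    hazard_multiplier: float = 1.0    # scales discontinuation hazards
    covariate_effect: float = 0.5     # demographic tilt on phenotype odds
    hospitalisation_rate: float = 0.02  # background admissions, per quarter
    excludable_fraction: float = 0.0  # patients violating inclusion rules
    long_memory: bool = False         # plant an early-history signal (see docs)
    noise_free: bool = False          # exact 90-day refills, no hazards
    index_day_range: tuple = (0, 10**9)

    def __post_init__(self):
        total = sum(self.phenotype_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"phenotype weights must sum to 1, got {total}"
            )
        unknown = set(self.phenotype_weights) - set(DEFAULT_WEIGHTS)
        if unknown:
            raise ConfigurationError(f"unknown phenotypes {sorted(unknown)}")

    # --- derived day-grid anchors -------------------------------------
    @property
    def obs_start(self) -> int:
        return self.lead_in_quarters * self.quarter_length

    @property
    def index_day(self) -> int:
        return self.obs_start + self.n_obs_quarters * self.quarter_length

    @property
    def horizon(self) -> int:
        return self.index_day + self.n_pred_quarters * self.quarter_length

    def prediction_quarters(self) -> list[Period]:
        q = self.quarter_length
        return [
            Period(self.index_day + (k - 1) * q, self.index_day + k * q)
            for k in range(1, self.n_pred_quarters + 1)
        ]

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["index_day_range"] = list(d["index_day_range"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "index_day_range" in d:
            d["index_day_range"] = tuple(d["index_day_range"])
        return cls(**d)


@dataclass
class Cohort:
    """Bundle of the four event tables plus simulator ground truth."""

    profiles: list
    dispenses: list
    labs: list
    hospital_events: list
    ground_truth: dict = field(default_factory=dict)
    config: Optional[SimulationConfig] = None
    seed: Optional[int] = None

    def __iter__(self):
        return iter(
            (self.profiles, self.dispenses, self.labs, self.hospital_events)
        )


# ---------------------------------------------------------------------------
# phenotype parameterisation
# ---------------------------------------------------------------------------

@dataclass
class _Behaviour:
    """Realised per-patient trajectory parameters."""

    phenotype: AdherencePhenotype
    gap_sd: float = 0.0
    gap_slope: float = 0.0      # extra gap days per quarter past decline onset
    decline_onset_q: Optional[int] = None  # global quarter index
    hazard_from_day: int = 0    # discontinuation hazard active from this day
    forced_stop_day: Optional[int] = None  # long-memory planted stop


def _draw_behaviour(rng, cls: str, cfg: SimulationConfig) -> _Behaviour:
    hm = cfg.hazard_multiplier
    if cfg.noise_free:
        ph = AdherencePhenotype(class_=cls, refill_gap_mean=0.0)
        return _Behaviour(phenotype=ph)
    if cls == "persistent":
        ph = AdherencePhenotype(
            class_=cls, refill_gap_mean=2.0,
            discontinue_hazard=min(1.0, 0.004 * hm),
            restart_prob=0.6, stockpile_tendency=0.25,
        )
        return _Behaviour(ph, gap_sd=5.0, hazard_from_day=cfg.index_day)
    if cls == "discontinuer":
        if rng.random() < 0.5:  # declining sub-mode
            onset = cfg.lead_in_quarters + cfg.n_obs_quarters - 4
            ph = AdherencePhenotype(
                class_=cls, refill_gap_mean=6.0,
                discontinue_hazard=min(1.0, 0.45 * hm),
                restart_prob=0.08, stockpile_tendency=0.05,
            )
            return _Behaviour(
                ph, gap_sd=6.0, gap_slope=12.0, decline_onset_q=onset,
                hazard_from_day=cfg.index_day,
            )
        ph = AdherencePhenotype(
            class_=cls, refill_gap_mean=18.0,
            discontinue_hazard=min(1.0, 0.03 * hm),
            restart_prob=0.5, stockpile_tendency=0.1,
        )
        return _Behaviour(ph, gap_sd=8.0, hazard_from_day=cfg.index_day)
    if cls == "intermittent":
        ph = AdherencePhenotype(
            class_=cls, refill_gap_mean=10.0,
            discontinue_hazard=min(1.0, 0.30 * hm),
            restart_prob=0.45, stockpile_tendency=0.1,
        )
        return _Behaviour(ph, gap_sd=6.0, hazard_from_day=0)
    if cls == "switcher":
        n_total = cfg.lead_in_quarters + cfg.n_obs_quarters + cfg.n_pred_quarters
        lo = cfg.lead_in_quarters + 2
        hi = min(n_total - 2, cfg.lead_in_quarters + cfg.n_obs_quarters + 10)
        ph = AdherencePhenotype(
            class_=cls, refill_gap_mean=3.0,
            discontinue_hazard=min(1.0, 0.006 * hm),
            restart_prob=0.6, stockpile_tendency=0.2,
            switch_quarter=int(rng.integers(lo, hi + 1)),
        )
        return _Behaviour(ph, gap_sd=5.0, hazard_from_day=cfg.index_day)
    raise ConfigurationError(f"unknown phenotype {cls!r}")


# ---------------------------------------------------------------------------
# trajectory machinery
# ---------------------------------------------------------------------------

def _on_intervals(rng, beh: _Behaviour, cfg: SimulationConfig,
                  start_day: int, end_day: int) -> list[tuple[int, int]]:
    """On-treatment day intervals from the quarterly stop/restart chain."""
    q = cfg.quarter_length
    ph = beh.phenotype
    out = []
    t = start_day
    on = True
    while t < end_day:
        if on:
            d = t
            stop = None
            while d < end_day:
                hazard = ph.discontinue_hazard if d >= beh.hazard_from_day else 0.0
                if beh.forced_stop_day is not None and d >= beh.forced_stop_day:
                    stop = max(t, beh.forced_stop_day)
                    break
                if hazard > 0 and rng.random() < hazard:
                    stop = d + int(rng.integers(0, q))
                    break
                d += q
            seg_end = min(end_day, stop if stop is not None else end_day)
            if seg_end > t:
                out.append((t, seg_end))
            t = seg_end
            on = False
        else:
            if beh.forced_stop_day is not None and t >= beh.forced_stop_day:
                break  # planted stops never restart
            d = t
            restarted = False
            while d < end_day:
                if ph.restart_prob > 0 and rng.random() < ph.restart_prob:
                    restarted = True
                    break
                d += q
            if not restarted:
                break
            t = min(end_day, d + int(rng.integers(0, q)))
            on = True
    return out


def _refills(rng, beh: _Behaviour, cfg: SimulationConfig,
             intervals, patient_id: str) -> list[DispenseEvent]:
    """Fill each on-treatment interval with supply-90 refills and gap noise."""
    q = cfg.quarter_length
    ph = beh.phenotype
    switch_day = (
        None if ph.switch_quarter is None else ph.switch_quarter * q
    )
    events = []
    for (a, b) in intervals:
        day = a
        while day < b:
            if switch_day is None:
                drug = LL_DRUGS[0]
            else:
                drug = LL_DRUGS[0] if day < switch_day else LL_DRUGS[1]
            events.append(DispenseEvent(patient_id, drug, "lipid_lowering",
                                        int(day), 90))
            if cfg.noise_free:
                gap = 0.0
            elif rng.random() < ph.stockpile_tendency:
                gap = -float(rng.integers(5, 25))
            else:
                mean = ph.refill_gap_mean
                if (beh.decline_onset_q is not None):
                    qi = day // q
                    mean += beh.gap_slope * max(0, qi - beh.decline_onset_q + 1)
                gap = max(-5.0, rng.normal(mean, beh.gap_sd))
            # switching disrupts the refill rhythm a little
            if switch_day is not None and day < switch_day <= day + 90 + gap:
                gap += float(rng.integers(5, 20))
            day = int(round(day + 90 + gap))
    events.sort(key=lambda e: (e.drug_code, e.dispense_date))
    return events


# ---------------------------------------------------------------------------
# covariates, labs, hospitalisations
# ---------------------------------------------------------------------------

_SMOKING_P = np.array([66896, 20162, 1901, 6249, 3046, 1842], dtype=float)
_SMOKING_P /= _SMOKING_P.sum()
_DIABETES_P = np.array([64125, 1267, 32754, 1950], dtype=float)
_DIABETES_P /= _DIABETES_P.sum()
_GEN_LIPID_P = np.array([92492, 5569, 20, 499, 1516], dtype=float)
_GEN_LIPID_P /= _GEN_LIPID_P.sum()
_RENAL_P = np.array([64131, 27585, 5996, 1975, 409], dtype=float)
_RENAL_P /= _RENAL_P.sum()
_AF_P = np.array([21, 95292, 4783], dtype=float)
_AF_P /= _AF_P.sum()
_ETH_P = np.array([56641, 9977, 14878, 8971, 9629], dtype=float)
_ETH_P /= _ETH_P.sum()
_NZDEP_P = np.array([21167, 19074, 17141, 18903, 23811], dtype=float)
_NZDEP_P /= _NZDEP_P.sum()


def _draw_profile(rng, pid: str, cfg: SimulationConfig) -> PatientProfile:
    sex = "M" if rng.random() < 0.565 else "F"
    age = int(np.clip(round(rng.normal(61.8, 11.3)), 18, 95))
    ethnicity = ETHNICITIES[int(rng.choice(5, p=_ETH_P))]
    nzdep = 1 + int(rng.choice(5, p=_NZDEP_P))
    diabetes = int(rng.choice(4, p=_DIABETES_P))
    pf = {
        "PT_SBP": float(np.round(np.clip(rng.normal(132.3, 17.0), 80, 230), 1)),
        "PT_DBP": float(np.round(np.clip(rng.normal(78.7, 10.3), 40, 140), 1)),
        "PT_SMOKING": int(rng.choice(6, p=_SMOKING_P)),
        "PT_DIABETES": diabetes,
        "PT_EN_TCHDL": float(np.round(np.clip(rng.normal(3.9, 1.2), 1.0, 12.0), 2)),
        "PT_FAMILY_HISTORY": int(rng.random() < 0.2014),
        "PT_GEN_LIPID": int(rng.choice(5, p=_GEN_LIPID_P)),
        "PT_RENAL": int(rng.choice(5, p=_RENAL_P)),
        "PT_ATRIAL_FIBRILLATION": int(rng.choice(3, p=_AF_P)),
        "PT_DIABETES_YR": (
            float(np.round(np.clip(rng.normal(8.2, 7.3), 0.0, 50.0), 1))
            if diabetes > 0 else 0.0
        ),
    }
    return PatientProfile(
        patient_id=pid, sex=sex, age_at_index=age, ethnicity=ethnicity,
        nzdep=nzdep, index_date=cfg.index_day, predict_fields=pf,
    )


def _phenotype_weights_for(rng, profile: PatientProfile,
                           cfg: SimulationConfig) -> np.ndarray:
    """Tilt the phenotype mixture by demographics (mild, configurable)."""
    w = np.array([cfg.phenotype_weights.get(k, 0.0)
                  for k in DEFAULT_WEIGHTS], dtype=float)
    smoker = 1.0 if profile.predict_fields["PT_SMOKING"] >= 3 else 0.0
    z = cfg.covariate_effect * (
        0.02 * (profile.age_at_index - 62)
        - 0.30 * smoker
        - 0.10 * (profile.nzdep - 3)
    )
    tilt = np.ones(4)
    tilt[0] = np.exp(z)        # persistent
    tilt[1] = np.exp(-z)       # discontinuer
    w = w * tilt
    s = w.sum()
    return w / s if s > 0 else w


def _quarter_periods(cfg: SimulationConfig) -> list[Period]:
    q = cfg.quarter_length
    n = cfg.lead_in_quarters + cfg.n_obs_quarters + cfg.n_pred_quarters
    return [Period(k * q, (k + 1) * q) for k in range(n)]


def _on_treatment_quarters(events, cfg: SimulationConfig) -> np.ndarray:
    """Cheap per-quarter on-treatment indicator used for lab drift."""
    q = cfg.quarter_length
    n = cfg.lead_in_quarters + cfg.n_obs_quarters + cfg.n_pred_quarters
    flags = np.zeros(n, dtype=bool)
    for e in events:
        if e.drug_class != "lipid_lowering":
            continue
        lo = max(0, e.dispense_date // q)
        hi = min(n - 1, (e.dispense_date + e.days_supply) // q)
        flags[lo:hi + 1] = True
    return flags


def _simulate_labs(rng, pid: str, cfg: SimulationConfig, on_q: np.ndarray,
                   death_day: Optional[int],
                   drop_pred_panels: bool) -> list[LabResult]:
    q = cfg.quarter_length
    n = len(on_q)
    hdl0 = max(0.5, rng.normal(1.28, 0.30))
    ldl0 = max(0.8, rng.normal(3.1, 0.85))
    tri0 = max(0.4, rng.normal(1.74, 0.80))
    hba0 = max(20.0, rng.normal(48.0, 15.0))
    egfr0 = max(10.0, rng.normal(77.9, 20.0))

    panel_qs = set(np.nonzero(rng.random(n) < cfg.lab_test_rate)[0].tolist())
    # inclusion requires a full cholesterol panel in both windows
    obs_range = range(cfg.lead_in_quarters, cfg.lead_in_quarters + cfg.n_obs_quarters)
    pred_range = range(cfg.lead_in_quarters + cfg.n_obs_quarters, n)
    if not panel_qs & set(obs_range):
        panel_qs.add(int(rng.choice(list(obs_range))))
    if not panel_qs & set(pred_range):
        panel_qs.add(int(rng.choice(list(pred_range))))
    if drop_pred_panels:
        panel_qs -= set(pred_range)

    labs: list[LabResult] = []
    for k in sorted(panel_qs):
        day = int(k * q + rng.integers(0, q))
        if death_day is not None and day >= death_day:
            continue
        treat = 0.75 if on_q[k] else 1.0
        noise = rng.normal(1.0, 0.05, size=3)
        hdl = round(max(0.3, hdl0 * noise[0]), 2)
        ldl = round(max(0.3, ldl0 * treat * noise[1]), 2)
        tri = round(max(0.2, tri0 * treat * noise[2]), 2)
        tcl = round(hdl + ldl + 0.45 * tri, 2)
        labs += [
            LabResult(pid, "HDL", day, hdl),
            LabResult(pid, "LDL", day, ldl),
            LabResult(pid, "TRI", day, tri),
            LabResult(pid, "TCL", day, tcl),
            LabResult(pid, "TCHDL", day, round(tcl / hdl, 2)),
        ]
    for analyte, rate, base, sd in (
        ("HBA1C", cfg.hba1c_test_rate, hba0, 2.0),
        ("EGFR", cfg.egfr_test_rate, egfr0, 3.0),
    ):
        for k in np.nonzero(rng.random(n) < rate)[0]:
            day = int(k * q + rng.integers(0, q))
            if death_day is not None and day >= death_day:
                continue
            labs.append(LabResult(pid, analyte, day,
                                  round(max(1.0, rng.normal(base, sd)), 1)))
    labs.sort(key=lambda r: (r.date, r.analyte))
    return labs


def _simulate_hospital(rng, pid: str, cfg: SimulationConfig,
                       has_cvd_history: bool, death_day: Optional[int],
                       planted_quarter: Optional[int]) -> list[HospitalEvent]:
    q = cfg.quarter_length
    n = cfg.lead_in_quarters + cfg.n_obs_quarters + cfg.n_pred_quarters
    index_q = cfg.lead_in_quarters + cfg.n_obs_quarters
    events = []
    hits = np.nonzero(rng.random(n) < cfg.hospitalisation_rate)[0].tolist()
    if planted_quarter is not None:
        hits.append(index_q + planted_quarter - 1)
    for k in sorted(set(hits)):
        admit = int(k * q + rng.integers(0, q))
        if death_day is not None and admit >= death_day:
            continue
        los = int(rng.geometric(0.25))
        cats = set()
        if k < index_q:
            if has_cvd_history:
                cats |= {"HX_BROAD_CVD", "HX_ATHERO_CVD"}
                if rng.random() < 0.4:
                    cats.add("HX_MI")
        else:
            cats.add("OUT_BROAD_CVD")
            if rng.random() < 0.3:
                cats.add("OUT_MI")
        events.append(HospitalEvent(
            pid, admit, admit + los, acute=bool(rng.random() < 0.7),
            categories=frozenset(cats),
        ))
    return events


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig, seed: int) -> Cohort:
    """Generate a full synthetic cohort.  Deterministic in (config, seed)."""
    cfg = config
    phenos = list(DEFAULT_WEIGHTS)
    profiles, dispenses, labs, hosps = [], [], [], []
    truth = {}
    pred_quarters = cfg.prediction_quarters()

    for i in range(cfg.n_patients):
        rng = np.random.default_rng([int(seed), i])
        pid = f"P{i:06d}"
        profile = _draw_profile(rng, pid, cfg)

        excl_mode = None
        if cfg.excludable_fraction > 0 and rng.random() < cfg.excludable_fraction:
            excl_mode = ["no_dispense", "missing_chol", "underage",
                         "bad_ethnicity", "infeasible", "index_range"][
                int(rng.integers(0, 6))]
        if excl_mode == "underage":
            profile.age_at_index = int(rng.integers(14, 18))
        elif excl_mode == "bad_ethnicity":
            profile.ethnicity = EXCLUDED_ETHNICITIES[int(rng.integers(0, 2))]
        elif excl_mode == "index_range":
            profile.index_date = cfg.index_day_range[1] + cfg.index_day + 1

        w = _phenotype_weights_for(rng, profile, cfg)
        cls = phenos[int(rng.choice(4, p=w))]
        beh = _draw_behaviour(rng, cls, cfg)

        planted = None
        if cfg.long_memory and rng.random() < 0.5:
            planted = int(rng.integers(5, 11))  # prediction quarter 5..10
            if rng.random() < 0.85:
                stop_q = min(cfg.n_pred_quarters,
                             17 + int(rng.geometric(0.6)) - 1)
                beh.forced_stop_day = cfg.index_day + (stop_q - 1) * cfg.quarter_length

        # death: per-quarter hazard from the index date
        death_day = None
        if cfg.death_hazard > 0:
            for k in range(cfg.n_pred_quarters):
                if rng.random() < cfg.death_hazard:
                    death_day = int(cfg.index_day + k * cfg.quarter_length
                                    + rng.integers(0, cfg.quarter_length))
                    break
        profile.death_date = death_day

        start_day = int(rng.integers(0, cfg.obs_start)) if cfg.obs_start > 0 else 0
        end_day = cfg.horizon if death_day is None else min(cfg.horizon, death_day)
        intervals = _on_intervals(rng, beh, cfg, start_day, end_day)
        events = _refills(rng, beh, cfg, intervals, pid)
        events = [e for e in events if e.dispense_date < end_day]

        # inclusion guard: at least one lipid-lowering dispense in the
        # observation window (2-week look-ahead past the index)
        window = (cfg.obs_start, cfg.index_day + 14)
        has_obs = any(window[0] <= e.dispense_date < window[1] for e in events)
        if excl_mode == "no_dispense":
            events = []
        elif not has_obs:
            day = int(rng.integers(window[0], cfg.index_day))
            events.append(DispenseEvent(pid, LL_DRUGS[0], "lipid_lowering",
                                        day, 90))
            events.sort(key=lambda e: (e.drug_code, e.dispense_date))

        # co-medication streams (coarse persistent-style refills)
        has_cvd_history = rng.random() < 0.25
        for drug, klass, prob in ((CVD_DRUG, "cvd", 0.6 if has_cvd_history else 0.2),
                                  (OTHER_DRUG, "other", 0.35)):
            if rng.random() < prob:
                d = int(rng.integers(0, cfg.obs_start + 90))
                while d < end_day:
                    events.append(DispenseEvent(pid, drug, klass, d, 90))
                    d += 90 + int(round(max(-5.0, rng.normal(6.0, 8.0))))
        events.sort(key=lambda e: (e.drug_code, e.dispense_date))

        on_q = _on_treatment_quarters(events, cfg)
        p_labs = _simulate_labs(rng, pid, cfg, on_q, death_day,
                                drop_pred_panels=(excl_mode == "missing_chol"))
        if excl_mode == "infeasible" and p_labs:
            first = p_labs[0]
            p_labs[0] = LabResult(pid, first.analyte, first.date, -1.0)
        p_hosps = _simulate_hospital(rng, pid, cfg, has_cvd_history,
                                     death_day, planted)

        ll_events = [e for e in events if e.drug_class == "lipid_lowering"]
        if ll_events:
            qpdc = quarterly_class_pdc(ll_events, pred_quarters)
            label = adherence_label([x.combined for x in qpdc])
        else:
            label = 0
        truth[pid] = {"phenotype": cls, "label": label}

        profiles.append(profile)
        dispenses.extend(events)
        labs.extend(p_labs)
        hosps.extend(p_hosps)

    dispenses.sort(key=lambda e: (e.patient_id, e.drug_code, e.dispense_date))
    labs.sort(key=lambda r: (r.patient_id, r.date, r.analyte))
    hosps.sort(key=lambda h: (h.patient_id, h.admit_date))
    return Cohort(profiles, dispenses, labs, hosps,
                  ground_truth=truth, config=cfg, seed=seed)


def ground_truth(config: SimulationConfig, seed: int) -> dict:
    """Latent phenotype and realised adherence label per patient id."""
    return simulate_cohort(config, seed).ground_truth


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def cohort_frames(cohort: Cohort) -> dict[str, pd.DataFrame]:
    prof = pd.DataFrame([
        {
            "patient_id": p.patient_id, "sex": p.sex,
            "age_at_index": p.age_at_index, "ethnicity": p.ethnicity,
            "nzdep": p.nzdep, "index_date": p.index_date,
            "death_date": "" if p.death_date is None else p.death_date,
            **p.predict_fields,
        }
        for p in cohort.profiles
    ])
    disp = pd.DataFrame([
        {"patient_id": e.patient_id, "drug_code": e.drug_code,
         "drug_class": e.drug_class, "dispense_date": e.dispense_date,
         "days_supply": e.days_supply}
        for e in cohort.dispenses
    ])
    labs = pd.DataFrame([
        {"patient_id": r.patient_id, "analyte": r.analyte,
         "date": r.date, "value": r.value}
        for r in cohort.labs
    ])
    hosp = pd.DataFrame([
        {"patient_id": h.patient_id, "admit_date": h.admit_date,
         "discharge_date": h.discharge_date, "acute": int(h.acute),
         "categories": "|".join(sorted(h.categories))}
        for h in cohort.hospital_events
    ])
    return {"patients": prof, "dispenses": disp, "labs": labs,
            "hospitalisations": hosp}


def write_cohort(cohort: Cohort, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, frame in cohort_frames(cohort).items():
        frame.to_csv(outdir / f"{name}.csv", index=False)
    if cohort.config is not None:
        cohort.config.to_yaml(outdir / "config.yaml")
    manifest = {
        "seed": cohort.seed,
        "n_patients": len(cohort.profiles),
        "n_dispenses": len(cohort.dispenses),
        "n_labs": len(cohort.labs),
        "n_hospitalisations": len(cohort.hospital_events),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    if cohort.ground_truth:
        pd.DataFrame([
            {"patient_id": pid, **info}
            for pid, info in sorted(cohort.ground_truth.items())
        ]).to_csv(outdir / "ground_truth.csv", index=False)


def read_cohort(indir) -> Cohort:
    indir = Path(indir)
    prof_df = pd.read_csv(indir / "patients.csv",
                          keep_default_na=False, dtype={"death_date": str})
    predict_cols = [c for c in prof_df.columns if c.startswith("PT_")]
    profiles = [
        PatientProfile(
            patient_id=r["patient_id"], sex=r["sex"],
            age_at_index=int(r["age_at_index"]), ethnicity=r["ethnicity"],
            nzdep=int(r["nzdep"]), index_date=int(r["index_date"]),
            death_date=None if r["death_date"] == "" else int(float(r["death_date"])),
            predict_fields={c: r[c] for c in predict_cols},
        )
        for r in prof_df.to_dict("records")
    ]
    disp_df = pd.read_csv(indir / "dispenses.csv")
    dispenses = [
        DispenseEvent(r["patient_id"], r["drug_code"], r["drug_class"],
                      int(r["dispense_date"]), int(r["days_supply"]))
        for r in disp_df.to_dict("records")
    ]
    labs_df = pd.read_csv(indir / "labs.csv", float_precision="round_trip")
    labs = [
        LabResult(r["patient_id"], r["analyte"], int(r["date"]),
                  float(r["value"]))
        for r in labs_df.to_dict("records")
    ]
    hosp_df = pd.read_csv(indir / "hospitalisations.csv", keep_default_na=False)
    hosps = [
        HospitalEvent(r["patient_id"], int(r["admit_date"]),
                      int(r["discharge_date"]), bool(int(r["acute"])),
                      frozenset(c for c in str(r["categories"]).split("|") if c))
        for r in hosp_df.to_dict("records")
    ]
    config = None
    if (indir / "config.yaml").exists():
        config = SimulationConfig.from_yaml(indir / "config.yaml")
    seed = None
    if (indir / "manifest.json").exists():
        seed = json.loads((indir / "manifest.json").read_text()).get("seed")
    truth = {}
    if (indir / "ground_truth.csv").exists():
        gt = pd.read_csv(indir / "ground_truth.csv")
        truth = {r["patient_id"]: {"phenotype": r["phenotype"],
                                   "label": int(r["label"])}
                 for r in gt.to_dict("records")}
    return Cohort(profiles, dispenses, labs, hosps, ground_truth=truth,
                  config=config, seed=seed)
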