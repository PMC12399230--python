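"""Synthetic administrative-claims generator with ground-truth labels.

Emulates the structure of a longitudinal claims database for patients
treated for advanced non-small cell lung cancer: per-patient enrollment
spans, ICD-10-coded diagnoses on point-event medical claims, days-supply
pharmacy fills for oral agents, 21-day-cycle infusion visits for
intravenous agents, inpatient/outpatient/emergency setting flags, and
positively skewed (log-normal per event) paid amounts.

Every patient is drawn with a *scenario*: either a fully eligible
treatment history, or a decoy that violates exactly one cohort filter
(single LC diagnosis, small-cell treatment, short washout, non-advanced
disease, metastatic diagnosis without treatment, pre-approval TKI use,
other-cancer history, or early-stage surgery).  The generator records
the true line-of-therapy intervals, regimen classes, and per-filter
eligibility as a :class:`GroundTruth` object, so the cohort-selection
and line-derivation stages can be tested for exact recovery.

Oral tyrosine kinase inhibitors are emitted as 30-day-supply pharmacy
fills; platinum/chemotherapy/immunotherapy agents as outpatient medical
claims every 21 days carrying the agent keys plus an administration
procedure code.  Death is not simulated; enrollment dropout is censoring
only (an exponential tail after the last treated day).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .claims_model import (
    ClaimsDataset,
    CodeConfig,
    EGFR_TKI_AGENTS,
    OSIMERTINIB_APPROVAL_DATE,
)

DAYS_PER_MONTH = 30.4375

DATA_START = pd.Timestamp("2010-01-01")
DATA_END = pd.Timestamp("2023-01-31")

GENERATOR_CLASSES = (
    "osimertinib_mono", "osimertinib_plus_chemo", "other_egfr_tki",
    "pbc_no_io", "pbc_plus_io", "io_mono", "other_chemo",
)

#: generator regimen-class label -> line-of-therapy engine class label
REGIMEN_CLASS_MAP = {
    "osimertinib_mono": "osimertinib_based",
    "osimertinib_plus_chemo": "osimertinib_based",
    "other_egfr_tki": "other_egfr_tki",
    "pbc_no_io": "pbc_regimen",
    "pbc_plus_io": "pbc_regimen",
    "io_mono": "io_mono",
    "other_chemo": "other_chemo",
}

SELECTION_STEPS = (
    "lc_dx_2plus", "sclc_exclusion", "washout_12mo", "advanced_disease",
    "egfr_tki_post_approval", "other_cancer_prior", "lc_surgery_pre_index",
)

_CHRONIC_CODES = ("I10", "E119", "J449", "I2510", "F329")
_CHRONIC_PROBS = (0.55, 0.25, 0.35, 0.15, 0.10)
_PROVIDERS = ("acute_care_hospital", "oncologist", "radiologist",
              "general_physician", "laboratory")


class ConfigError(ValueError):
    """A simulation-config probability vector is invalid."""


def _check_mix(name: str, mix: dict[str, float]) -> None:
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"{name} probabilities sum to {total}, not 1")
    if any(p < 0 for p in mix.values()):
        raise ConfigError(f"{name} contains a negative probability")


def _default_first_line_mix() -> dict[str, float]:
    return {
        "osimertinib_mono": 0.68,
        "osimertinib_plus_chemo": 0.05,
        "other_egfr_tki": 0.05,
        "pbc_no_io": 0.14,
        "pbc_plus_io": 0.05,
        "io_mono": 0.015,
        "other_chemo": 0.015,
    }


def _default_next_line_mix() -> dict[str, dict[str, float]]:
    return {
        "osimertinib_based": {
            "osimertinib_plus_chemo": 0.06, "other_egfr_tki": 0.12,
            "pbc_no_io": 0.30, "pbc_plus_io": 0.30, "io_mono": 0.12,
            "other_chemo": 0.10,
        },
        "other_egfr_tki": {
            "osimertinib_mono": 0.65, "pbc_no_io": 0.15, "pbc_plus_io": 0.10,
            "io_mono": 0.05, "other_chemo": 0.05,
        },
        "pbc_regimen": {
            "osimertinib_mono": 0.60, "osimertinib_plus_chemo": 0.10,
            "other_egfr_tki": 0.10, "io_mono": 0.10, "other_chemo": 0.10,
        },
        "io_mono": {
            "osimertinib_mono": 0.50, "pbc_no_io": 0.30, "other_egfr_tki": 0.20,
        },
        "other_chemo": {
            "osimertinib_mono": 0.50, "pbc_no_io": 0.30, "other_egfr_tki": 0.10,
            "io_mono": 0.10,
        },
    }


def _default_durations() -> dict[str, tuple[float, float]]:
    # per-class log-normal (mu, sigma) of line duration in months
    return {
        "osimertinib_mono": (np.log(9.0), 0.7),
        "osimertinib_plus_chemo": (np.log(8.0), 0.7),
        "other_egfr_tki": (np.log(6.0), 0.7),
        "pbc_no_io": (np.log(4.0), 0.7),
        "pbc_plus_io": (np.log(5.0), 0.7),
        "io_mono": (np.log(4.0), 0.7),
        "other_chemo": (np.log(3.5), 0.7),
    }


def _default_costs() -> dict[str, tuple[float, float]]:
    # per-event log-normal (mu, sigma), 2022-USD scale
    return {
        "inpatient_day": (np.log(6500.0), 0.8),
        "outpatient_visit": (np.log(1100.0), 1.0),
        "ed_visit": (np.log(2000.0), 0.9),
        "pharmacy_fill": (np.log(15000.0), 0.25),
        "infusion_admin": (np.log(4000.0), 0.6),
        "supportive_fill": (np.log(60.0), 1.0),
    }


def _default_decoy_mix() -> dict[str, float]:
    return {
        "none": 0.66,
        "single_dx": 0.05,
        "sclc": 0.04,
        "washout": 0.05,
        "nonadvanced": 0.05,
        "met_no_treatment": 0.03,
        "pre_approval_tki": 0.04,
        "other_cancer": 0.04,
        "early_stage_surgery": 0.04,
    }


@dataclass
class SimulationConfig:
    """Generator parameters; the defaults target the magnitudes of a
    contemporary US EGFR-mutated advanced NSCLC claims cohort (mostly
    first-line osimertinib monotherapy, ~40% progression to second
    line, heavy right-skewed costs) without being calibrated to any
    particular dataset."""

    n_patients: int = 500
    seed: int = 0
    age_mean: float = 60.5
    age_sd: float = 10.0
    prob_female: float = 0.70
    plan_mix: dict[str, float] = field(default_factory=lambda: {
        "commercial": 0.68, "medicare_supplemental": 0.23, "medicaid": 0.09})
    prob_metastatic_dx_within_30d: float = 0.90
    prob_brain_metastasis: float = 0.40
    first_line_mix: dict[str, float] = field(default_factory=_default_first_line_mix)
    line_duration_months: dict[str, tuple[float, float]] = field(
        default_factory=_default_durations)
    prob_progress_to_2l: float = 0.42
    prob_progress_to_3l: float = 0.50
    second_line_mix: dict[str, dict[str, float]] = field(
        default_factory=_default_next_line_mix)
    third_line_mix: dict[str, dict[str, float]] = field(
        default_factory=_default_next_line_mix)
    outpatient_visit_rate_pppm: dict[str, float] = field(default_factory=lambda: {
        "default": 4.0, "osimertinib_mono": 3.0, "osimertinib_plus_chemo": 6.0,
        "pbc_no_io": 7.5, "pbc_plus_io": 7.0})
    inpatient_admission_rate_pppm: dict[str, float] = field(
        default_factory=lambda: {"default": 0.08})
    ed_visit_rate_pppm: dict[str, float] = field(
        default_factory=lambda: {"default": 0.12})
    baseline_outpatient_rate_pppm: float = 1.9
    baseline_inpatient_rate_pppm: float = 0.05
    baseline_ed_rate_pppm: float = 0.09
    cost_lognormal: dict[str, tuple[float, float]] = field(default_factory=_default_costs)
    enrollment_dropout_hazard: float = 0.15  # monthly; censoring tail ~ Exp(1/hazard)
    prob_non_regimen_decoy_claim: float = 0.02  # per line; breaks truth recovery
    prob_retreatment_gap: float = 0.05          # per patient; truth-consistent
    decoy_mix: dict[str, float] = field(default_factory=_default_decoy_mix)
    prob_pre1l_corticosteroid: float = 0.80
    prob_pre1l_radiotherapy: float = 0.40
    prob_pre1l_surgery_met: float = 0.18  # met-qualified patients only
    prob_split_enrollment: float = 0.10   # emit the span as two abutting rows
    data_end: pd.Timestamp = DATA_END

    def __post_init__(self) -> None:
        _check_mix("plan_mix", self.plan_mix)
        _check_mix("first_line_mix", self.first_line_mix)
        _check_mix("decoy_mix", self.decoy_mix)
        for key, mix in self.second_line_mix.items():
            _check_mix(f"second_line_mix[{key}]", mix)
        for key, mix in self.third_line_mix.items():
            _check_mix(f"third_line_mix[{key}]", mix)
        for name, (mu, sigma) in self.cost_lognormal.items():
            if sigma < 0:
                raise ConfigError(f"cost_lognormal[{name}] sigma < 0")
        for name, rates in (("outpatient", self.outpatient_visit_rate_pppm),
                            ("inpatient", self.inpatient_admission_rate_pppm),
                            ("ed", self.ed_visit_rate_pppm)):
            if any(r < 0 for r in rates.values()):
                raise ConfigError(f"{name} visit rate < 0")
        if isinstance(self.data_end, str):
            self.data_end = pd.Timestamp(self.data_end)

    def noise_free(self) -> "SimulationConfig":
        """Copy with the truth-breaking noise knob off."""
        return dataclasses.replace(self, prob_non_regimen_decoy_claim=0.0)


@dataclass
class GroundTruth:
    """True per-patient selection labels and line-of-therapy intervals."""

    patients: pd.DataFrame
    lines: pd.DataFrame

    def eligible_ids(self) -> set:
        return set(self.patients.loc[self.patients.eligible, "patient_id"])


# ---------------------------------------------------------------------------
# regimen helpers
# ---------------------------------------------------------------------------

def _regimen_agents(gen_class: str, rng: np.random.Generator) -> frozenset:
    if gen_class == "osimertinib_mono":
        return frozenset({"osimertinib"})
    if gen_class == "osimertinib_plus_chemo":
        return frozenset({"osimertinib", "carboplatin", "pemetrexed"})
    if gen_class == "other_egfr_tki":
        return frozenset({rng.choice(["erlotinib", "afatinib", "gefitinib", "dacomitinib"])})
    if gen_class == "pbc_no_io":
        return frozenset({rng.choice(["carboplatin", "cisplatin"]), "pemetrexed"})
    if gen_class == "pbc_plus_io":
        return frozenset({rng.choice(["carboplatin", "cisplatin"]),
                          "pemetrexed", "pembrolizumab"})
    if gen_class == "io_mono":
        return frozenset({rng.choice(["pembrolizumab", "nivolumab", "atezolizumab"])})
    if gen_class == "other_chemo":
        return frozenset({rng.choice(["docetaxel", "gemcitabine"])})
    raise ValueError(f"unknown generator class {gen_class!r}")


def _choice(rng: np.random.Generator, mix: dict[str, float]) -> str:
    keys = sorted(mix)
    probs = np.array([mix[k] for k in keys], dtype=float)
    return str(rng.choice(keys, p=probs / probs.sum()))


def _draw_next_regimen(rng, mix: dict[str, float], prior: frozenset):
    """Draw a next-line class whose agent set introduces a new agent."""
    for _ in range(10):
        cls = _choice(rng, mix)
        agents = _regimen_agents(cls, rng)
        if agents - prior:
            return cls, agents
    for fallback in ("docetaxel", "gemcitabine", "paclitaxel"):
        if fallback not in prior:
            return "other_chemo", frozenset({fallback})
    raise RuntimeError("could not construct a distinct next regimen")


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

class _Builder:
    """Accumulates claim rows for one generate() run."""

    def __init__(self, cfg: SimulationConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.patients: list[dict] = []
        self.enrollment: list[dict] = []
        self.medical: list[dict] = []
        self.pharmacy: list[dict] = []
        self.truth_patients: list[dict] = []
        self.truth_lines: list[dict] = []

    # -- cost draws --------------------------------------------------------
    def cost(self, key: str, n: int = 1) -> float:
        mu, sigma = self.cfg.cost_lognormal[key]
        return float(np.round(self.rng.lognormal(mu, sigma, size=n).sum(), 2))

    # -- claim emitters ----------------------------------------------------
    def visit(self, pid, date, dx, paid=None, procs=("99213",), setting="outpatient",
              end=None, provider=None):
        self.medical.append({
            "patient_id": pid,
            "service_date": date,
            "end_date": end if end is not None else date,
            "setting": setting,
            "diagnosis_codes": ";".join(dx),
            "procedure_codes": ";".join(procs),
            "provider_type": provider or self.rng.choice(_PROVIDERS),
            "paid_amount": self.cost("outpatient_visit") if paid is None else paid,
            "service_year": int(date.year),
        })

    def fill(self, pid, date, drug, days_supply, paid):
        self.pharmacy.append({
            "patient_id": pid,
            "fill_date": date,
            "drug_code": drug,
            "days_supply": int(days_supply),
            "paid_amount": paid,
            "service_year": int(date.year),
        })


def _visit_dx(b: _Builder, chronic: list[str], date, dx0, has_met30, met_date):
    """Diagnosis codes for a routine visit, principal code first."""
    rng = b.rng
    if date < dx0:
        pool = chronic if chronic else ["I10"]
        k = 1 + int(rng.random() < 0.3 and len(pool) > 1)
        return list(rng.choice(pool, size=min(k, len(pool)), replace=False))
    dx = ["C3490"]
    if has_met30 and met_date is not None and date >= met_date and rng.random() < 0.5:
        dx.append("C7800")
    if chronic and rng.random() < 0.5:
        dx.append(str(rng.choice(chronic)))
    return dx


def _emit_background_hru(b: _Builder, pid, window_start, window_end, chronic,
                         dx0, has_met30, met_date, opd_rate, ip_rate, ed_rate):
    """Poisson outpatient / inpatient / ED claims over a closed window."""
    rng = b.rng
    n_days = (window_end - window_start).days + 1
    if n_days <= 0:
        return
    months = n_days / DAYS_PER_MONTH

    def _dates(n):
        offs = rng.integers(0, n_days, size=n)
        return [window_start + pd.Timedelta(days=int(o)) for o in sorted(offs)]

    for d in _dates(rng.poisson(opd_rate * months)):
        b.visit(pid, d, _visit_dx(b, chronic, d, dx0, has_met30, met_date))
    for d in _dates(rng.poisson(ip_rate * months)):
        los = 1 + int(rng.poisson(2.0))
        discharge = min(d + pd.Timedelta(days=los - 1), window_end)
        n_los = (discharge - d).days + 1
        b.visit(pid, d, _visit_dx(b, chronic, d, dx0, has_met30, met_date),
                paid=b.cost("inpatient_day", n=n_los), procs=("99222",),
                setting="inpatient", end=discharge, provider="acute_care_hospital")
    for d in _dates(rng.poisson(ed_rate * months)):
        b.visit(pid, d, _visit_dx(b, chronic, d, dx0, has_met30, met_date),
                paid=b.cost("ed_visit"), procs=("99284",), setting="emergency",
                provider="acute_care_hospital")


def _emit_line_claims(b: _Builder, pid, agents, start, treat_end, obs_cut):
    """Treatment exposure for one line segment; returns last covered day.

    Oral TKIs: 30-day-supply fills every 30 days.  Infused agents: one
    outpatient claim per 21-day cycle carrying all infused agent keys
    plus an administration procedure code.
    """
    rng = b.rng
    exposure_end = start
    oral = sorted(a for a in agents if a in EGFR_TKI_AGENTS)
    infused = sorted(a for a in agents if a not in EGFR_TKI_AGENTS)
    for agent in oral:
        d = start
        while d <= treat_end:
            if d <= obs_cut:
                b.fill(pid, d, agent, 30, b.cost("pharmacy_fill"))
                exposure_end = max(exposure_end, d + pd.Timedelta(days=29))
            d += pd.Timedelta(days=30)
    if infused:
        d = start
        while d <= treat_end:
            if d <= obs_cut:
                b.visit(pid, d, ["C3490"], paid=b.cost("infusion_admin") * len(infused),
                        procs=tuple(infused) + ("chemo_admin",),
                        provider="oncologist")
                exposure_end = max(exposure_end, d)
            d += pd.Timedelta(days=21)
    return exposure_end


def _emit_supportive(b: _Builder, pid, gen_class, start, end):
    rng = b.rng
    days = (end - start).days + 1
    if days <= 0:
        return
    chemo = gen_class in ("pbc_no_io", "pbc_plus_io", "other_chemo",
                          "osimertinib_plus_chemo")

    def _maybe(prob, drug, supply):
        if rng.random() < prob:
            n = 1 + int(rng.poisson(1.0))
            for _ in range(n):
                off = int(rng.integers(0, days))
                b.fill(pid, start + pd.Timedelta(days=off), drug, supply,
                       b.cost("supportive_fill"))

    _maybe(0.65, str(rng.choice(["oxycodone", "morphine", "hydrocodone_acetaminophen"])), 14)
    _maybe(0.06, "albuterol", 30)
    _maybe(0.25 if chemo else 0.02, str(rng.choice(["filgrastim", "pegfilgrastim"])), 7)
    _maybe(0.01, "epoetin_alfa", 7)
    _maybe(0.30, str(rng.choice(["dexamethasone", "prednisone"])), 10)


def _plan_lines(b: _Builder, cfg: SimulationConfig, first_line_start):
    """Draw the true treatment sequence: list of (gen_class, agents, duration_days)."""
    rng = b.rng
    seq = []
    cls1 = _choice(rng, cfg.first_line_mix)
    agents1 = _regimen_agents(cls1, rng)
    seq.append([cls1, agents1])
    if rng.random() < cfg.prob_progress_to_2l:
        mix2 = cfg.second_line_mix.get(REGIMEN_CLASS_MAP[cls1])
        cls2, agents2 = _draw_next_regimen(rng, mix2, agents1)
        seq.append([cls2, agents2])
        if rng.random() < cfg.prob_progress_to_3l:
            mix3 = cfg.third_line_mix.get(REGIMEN_CLASS_MAP[cls2])
            cls3, agents3 = _draw_next_regimen(rng, mix3, agents2)
            seq.append([cls3, agents3])
    out = []
    for cls, agents in seq:
        mu, sigma = cfg.line_duration_months[cls]
        months = rng.lognormal(mu, sigma)
        days = max(22, int(round(months * DAYS_PER_MONTH)))
        out.append((cls, agents, days))
    return out


def generate(config: SimulationConfig) -> tuple[ClaimsDataset, GroundTruth]:
    """Generate a claims dataset plus ground truth; deterministic per seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    b = _Builder(cfg, rng)

    for idx in range(cfg.n_patients):
        pid = f"P{idx:05d}"
        decoy = _choice(rng, cfg.decoy_mix)
        _generate_patient(b, pid, decoy)

    patients = pd.DataFrame(b.patients, columns=["patient_id", "birth_year", "sex"])
    enrollment = pd.DataFrame(
        b.enrollment, columns=["patient_id", "start_date", "end_date", "plan_type"])
    medical = pd.DataFrame(
        b.medical,
        columns=["patient_id", "service_date", "end_date", "setting",
                 "diagnosis_codes", "procedure_codes", "provider_type",
                 "paid_amount", "service_year"])
    pharmacy = pd.DataFrame(
        b.pharmacy,
        columns=["patient_id", "fill_date", "drug_code", "days_supply",
                 "paid_amount", "service_year"])
    dataset = ClaimsDataset(patients=patients, enrollment=enrollment,
                            medical=medical, pharmacy=pharmacy)
    truth = GroundTruth(
        patients=pd.DataFrame(b.truth_patients, columns=[
            "patient_id", "decoy_type", "eligible", "excluded_at_step",
            "met_within_30d", "first_lc_dx", "first_line_start", "index_date",
            "observation_end", "n_lines", "progressed_to_2l", "progressed_to_3l"]),
        lines=pd.DataFrame(b.truth_lines, columns=[
            "patient_id", "line_number", "start", "end", "regimen",
            "regimen_class", "end_reason"]),
    )
    return dataset, truth


def _generate_patient(b: _Builder, pid: str, decoy: str) -> None:
    cfg, rng = b.cfg, b.rng

    # ---- anchor dates -----------------------------------------------------
    if decoy == "pre_approval_tki":
        dx0 = pd.Timestamp("2015-01-01") + pd.Timedelta(days=int(rng.integers(0, 540)))
    else:
        lo = (OSIMERTINIB_APPROVAL_DATE + pd.Timedelta(days=13)).value
        hi = pd.Timestamp("2022-06-30").value
        dx0 = pd.Timestamp(int(rng.integers(lo // 10**9, hi // 10**9)) * 10**9).normalize()
    washout_days = (int(rng.integers(100, 300)) if decoy == "washout"
                    else 365 + int(rng.integers(0, 1095)))
    enroll_start = dx0 - pd.Timedelta(days=washout_days)
    plan = _choice(rng, cfg.plan_mix)
    sex = "F" if rng.random() < cfg.prob_female else "M"

    first_line_start = dx0 + pd.Timedelta(days=int(rng.integers(14, 61)))
    age = max(25, min(95, int(round(rng.normal(cfg.age_mean, cfg.age_sd)))))
    birth_year = int(first_line_start.year - age)
    b.patients.append({"patient_id": pid, "birth_year": birth_year, "sex": sex})

    # chronic comorbidity pool (never malignancy codes)
    chronic = [c for c, p in zip(_CHRONIC_CODES, _CHRONIC_PROBS) if rng.random() < p]

    # metastatic qualifier
    if decoy in ("none", "sclc", "washout", "pre_approval_tki", "met_no_treatment",
                 "other_cancer"):
        has_met30 = rng.random() < cfg.prob_metastatic_dx_within_30d \
            if decoy in ("none", "other_cancer") else True
    else:
        has_met30 = False  # nonadvanced / early_stage_surgery / single_dx
    met_date = dx0 + pd.Timedelta(days=int(rng.integers(0, 31))) if has_met30 else None
    if decoy == "nonadvanced":
        met_date = dx0 + pd.Timedelta(days=int(rng.integers(31, 90)))  # too late
    brain_met = has_met30 and rng.random() < cfg.prob_brain_metastasis

    # ---- treatment plan ---------------------------------------------------
    treated = decoy in ("none", "sclc", "washout", "pre_approval_tki",
                        "other_cancer", "early_stage_surgery")
    if decoy == "sclc":
        planned = [("other_chemo", frozenset({"etoposide", "carboplatin"}),
                    max(22, int(round(rng.lognormal(np.log(4.0), 0.7) * DAYS_PER_MONTH))))]
    elif decoy == "pre_approval_tki":
        planned = [("other_egfr_tki", frozenset({"erlotinib"}),
                    max(22, int(round(rng.lognormal(np.log(8.0), 0.7) * DAYS_PER_MONTH))))]
    elif treated:
        planned = _plan_lines(b, cfg, first_line_start)
        if decoy in ("other_cancer", "early_stage_surgery") and not any(
                agents & EGFR_TKI_AGENTS for _, agents, _ in planned):
            # these decoys must survive the TKI filter to reach their own
            # exclusion step; force a TKI first line
            planned[0] = ("osimertinib_mono", frozenset({"osimertinib"}),
                          planned[0][2])
    else:
        planned = []

    # schedule segments; optionally split the last line by a >90-day gap
    segments = []  # (gen_class, agents, start, treat_end, reason_to_next)
    cursor = first_line_start
    for k, (cls, agents, days) in enumerate(planned):
        segments.append([cls, agents, cursor, cursor + pd.Timedelta(days=days - 1),
                         "new_agent"])
        cursor = cursor + pd.Timedelta(days=days)
    retreat = (treated and planned and decoy == "none"
               and rng.random() < cfg.prob_retreatment_gap)

    # ---- enrollment end / observation cut ---------------------------------
    if planned:
        last_treat_end = segments[-1][3]
    else:
        last_treat_end = dx0 + pd.Timedelta(days=int(rng.integers(60, 400)))
    tail_months = rng.exponential(1.0 / max(cfg.enrollment_dropout_hazard, 1e-9))
    tail_days = max(30, int(round(min(tail_months, 24.0) * DAYS_PER_MONTH)))

    if retreat:
        # resume the final regimen after a >90-day exposure gap; the
        # resumption date is measured past a bound on the covered days
        # (oral supply runs up to 29 days past the last fill)
        cls, agents, start, treat_end, _ = segments[-1]
        gap = int(rng.integers(91, 160))
        extra = max(22, int(round(rng.lognormal(np.log(4.0), 0.7) * DAYS_PER_MONTH)))
        oral = any(a in EGFR_TKI_AGENTS for a in agents)
        approx_exposure_end = treat_end + pd.Timedelta(days=29) if oral else treat_end
        resume = approx_exposure_end + pd.Timedelta(days=gap + 1)
        if resume + pd.Timedelta(days=extra) <= cfg.data_end - pd.Timedelta(days=10):
            segments[-1][4] = "retreatment_gap"
            segments.append([cls, agents, resume,
                             resume + pd.Timedelta(days=extra - 1), "new_agent"])
            last_treat_end = segments[-1][3]

    enroll_end = last_treat_end + pd.Timedelta(days=tail_days)
    if decoy == "pre_approval_tki":
        enroll_end = min(enroll_end, OSIMERTINIB_APPROVAL_DATE - pd.Timedelta(days=45))
    obs_cut = min(enroll_end, cfg.data_end)

    # enrollment rows (possibly split into two abutting spans)
    if rng.random() < cfg.prob_split_enrollment and enroll_end > enroll_start + pd.Timedelta(days=120):
        mid = enroll_start + pd.Timedelta(days=int(rng.integers(60, (enroll_end - enroll_start).days - 60)))
        b.enrollment.append({"patient_id": pid, "start_date": enroll_start,
                             "end_date": mid, "plan_type": plan})
        b.enrollment.append({"patient_id": pid, "start_date": mid + pd.Timedelta(days=1),
                             "end_date": enroll_end, "plan_type": plan})
    else:
        b.enrollment.append({"patient_id": pid, "start_date": enroll_start,
                             "end_date": enroll_end, "plan_type": plan})

    # ---- diagnosis claims --------------------------------------------------
    b.visit(pid, dx0, ["C3490"] + (chronic[:1] if chronic else []))
    if decoy != "single_dx":
        b.visit(pid, dx0 + pd.Timedelta(days=int(rng.integers(5, 16))), ["C3490"])
    if met_date is not None and met_date <= obs_cut:
        dx = ["C7931" if brain_met else "C7800", "C3490"]
        b.visit(pid, met_date, dx)
    if decoy == "other_cancer":
        b.visit(pid, dx0 - pd.Timedelta(days=int(rng.integers(60, min(washout_days - 5, 700)))),
                ["C61"])

    # pre-1L treatment flags
    if treated:
        if rng.random() < cfg.prob_pre1l_corticosteroid:
            for _ in range(1 + int(rng.poisson(1.0))):
                off = int(rng.integers(0, max(1, (first_line_start - dx0).days)))
                b.fill(pid, dx0 + pd.Timedelta(days=off),
                       str(rng.choice(["dexamethasone", "prednisone"])), 10,
                       b.cost("supportive_fill"))
        if rng.random() < cfg.prob_pre1l_radiotherapy and (first_line_start - dx0).days > 2:
            off = int(rng.integers(1, (first_line_start - dx0).days))
            b.visit(pid, dx0 + pd.Timedelta(days=off), ["C3490"], procs=("77412",),
                    provider="radiologist")
        wants_surgery = (decoy == "early_stage_surgery"
                         or (has_met30 and rng.random() < cfg.prob_pre1l_surgery_met))
        if wants_surgery and (first_line_start - dx0).days > 2:
            off = int(rng.integers(1, (first_line_start - dx0).days))
            b.visit(pid, dx0 + pd.Timedelta(days=off), ["C3490"], procs=("32480",),
                    provider="acute_care_hospital")

    # ---- truth lines (truncated at the observation cut) -------------------
    kept = [s for s in segments if s[2] <= obs_cut]
    truth_lines = []
    for k, (cls, agents, start, treat_end, reason) in enumerate(kept):
        if k + 1 < len(kept):
            end = kept[k + 1][2] - pd.Timedelta(days=1)
            end_reason = reason
        else:
            end = obs_cut
            end_reason = "end_of_observation"
        truth_lines.append({
            "patient_id": pid, "line_number": k + 1, "start": start,
            "end": end, "regimen": ";".join(sorted(agents)),
            "regimen_class": REGIMEN_CLASS_MAP.get(cls, "other_chemo"),
            "end_reason": end_reason,
        })

    # ---- treatment + on-treatment HRU claims ------------------------------
    opd = cfg.outpatient_visit_rate_pppm
    ipd = cfg.inpatient_admission_rate_pppm
    edr = cfg.ed_visit_rate_pppm
    for k, (cls, agents, start, treat_end, _) in enumerate(kept):
        line_end = (kept[k + 1][2] - pd.Timedelta(days=1)
                    if k + 1 < len(kept) else obs_cut)
        _emit_line_claims(b, pid, agents, start, treat_end, obs_cut)
        _emit_background_hru(
            b, pid, start, min(line_end, obs_cut), chronic, dx0, has_met30, met_date,
            opd.get(cls, opd["default"]), ipd.get(cls, ipd["default"]),
            edr.get(cls, edr["default"]))
        _emit_supportive(b, pid, cls, start, min(line_end, obs_cut))
        if rng.random() < cfg.prob_non_regimen_decoy_claim:
            span = (min(line_end, obs_cut) - start).days
            if span > 30:
                off = int(rng.integers(25, span))
                decoy_agent = "paclitaxel" if "paclitaxel" not in agents else "gemcitabine"
                b.visit(pid, start + pd.Timedelta(days=off), ["C3490"],
                        paid=b.cost("infusion_admin"),
                        procs=(decoy_agent, "chemo_admin"), provider="oncologist")

    # baseline-window background HRU (12 months before 1L)
    if treated:
        base_start = max(first_line_start - pd.Timedelta(days=365), enroll_start)
        _emit_background_hru(b, pid, base_start, first_line_start - pd.Timedelta(days=1),
                             chronic, dx0, has_met30, met_date,
                             cfg.baseline_outpatient_rate_pppm,
                             cfg.baseline_inpatient_rate_pppm,
                             cfg.baseline_ed_rate_pppm)
    elif decoy == "single_dx":
        # pre-diagnosis background only: later LC-coded visits would defeat
        # this decoy's single-diagnosis construction
        _emit_background_hru(b, pid, enroll_start + pd.Timedelta(days=30),
                             dx0 - pd.Timedelta(days=1), chronic, dx0, False, None,
                             cfg.baseline_outpatient_rate_pppm,
                             cfg.baseline_inpatient_rate_pppm, cfg.baseline_ed_rate_pppm)
    else:
        _emit_background_hru(b, pid, dx0, min(last_treat_end, obs_cut), chronic, dx0,
                             has_met30, met_date, cfg.baseline_outpatient_rate_pppm,
                             cfg.baseline_inpatient_rate_pppm, cfg.baseline_ed_rate_pppm)

    # ---- truth eligibility -------------------------------------------------
    tki_lines = [tl for tl in truth_lines
                 if set(tl["regimen"].split(";")) & EGFR_TKI_AGENTS]
    index_date = min((tl["start"] for tl in tki_lines), default=pd.NaT)
    step = None
    if decoy == "single_dx":
        step = "lc_dx_2plus"
    elif decoy == "sclc":
        step = "sclc_exclusion"
    elif decoy == "washout":
        step = "washout_12mo"
    elif decoy in ("nonadvanced", "met_no_treatment"):
        step = "advanced_disease"
    elif decoy == "pre_approval_tki":
        step = "egfr_tki_post_approval"
    elif decoy == "other_cancer":
        step = "other_cancer_prior"
    elif decoy == "early_stage_surgery":
        step = "lc_surgery_pre_index"
    elif not tki_lines or index_date < OSIMERTINIB_APPROVAL_DATE:
        step = "egfr_tki_post_approval"
    eligible = step is None

    b.truth_patients.append({
        "patient_id": pid, "decoy_type": decoy, "eligible": eligible,
        "excluded_at_step": step, "met_within_30d": bool(has_met30),
        "first_lc_dx": dx0,
        "first_line_start": truth_lines[0]["start"] if truth_lines else pd.NaT,
        "index_date": index_date if eligible else pd.NaT,
        "observation_end": obs_cut,
        "n_lines": len(truth_lines),
        "progressed_to_2l": len(truth_lines) >= 2,
        "progressed_to_3l": len(truth_lines) >= 3,
    })
    if eligible:
        b.truth_lines.extend(truth_lines)


# ---------------------------------------------------------------------------
# hand-built fixtures
# ---------------------------------------------------------------------------

FIXTURE_DATA_END = pd.Timestamp("2019-12-31")


def _fixture_scaffold(pid: str):
    """Shared scaffolding: eligible-by-construction single patient."""
    b = _Builder(SimulationConfig(n_patients=0), np.random.default_rng(0))
    dx0 = pd.Timestamp("2018-05-01")
    b.patients.append({"patient_id": pid, "birth_year": 1958, "sex": "F"})
    b.enrollment.append({"patient_id": pid, "start_date": pd.Timestamp("2017-01-01"),
                         "end_date": pd.Timestamp("2019-12-31"),
                         "plan_type": "commercial"})
    b.visit(pid, dx0, ["C3490"], paid=150.0)
    b.visit(pid, dx0 + pd.Timedelta(days=7), ["C3490"], paid=150.0)
    return b, dx0


def _fixture_dataset(b: _Builder) -> ClaimsDataset:
    return ClaimsDataset(
        patients=pd.DataFrame(b.patients),
        enrollment=pd.DataFrame(b.enrollment),
        medical=pd.DataFrame(b.medical),
        pharmacy=pd.DataFrame(b.pharmacy),
    )


def _truth(pid, lines, eligible=True, step=None, met30=True, dx0=None,
           index=None, obs_end=pd.Timestamp("2019-12-31")):
    rows = [{"patient_id": pid, "line_number": i + 1, "start": s, "end": e,
             "regimen": ";".join(sorted(reg)), "regimen_class": cls,
             "end_reason": reason}
            for i, (s, e, reg, cls, reason) in enumerate(lines)]
    pat = pd.DataFrame([{
        "patient_id": pid, "decoy_type": "fixture", "eligible": eligible,
        "excluded_at_step": step, "met_within_30d": met30, "first_lc_dx": dx0,
        "first_line_start": rows[0]["start"] if rows else pd.NaT,
        "index_date": index, "observation_end": obs_end, "n_lines": len(rows),
        "progressed_to_2l": len(rows) >= 2, "progressed_to_3l": len(rows) >= 3,
    }])
    return GroundTruth(patients=pat, lines=pd.DataFrame(rows, columns=[
        "patient_id", "line_number", "start", "end", "regimen",
        "regimen_class", "end_reason"]))


def _fx_gap(gap_days: int):
    """Oral monotherapy with an exposure gap of exactly ``gap_days``."""
    b, dx0 = _fixture_scaffold("F00001")
    b.visit("F00001", dx0 + pd.Timedelta(days=9), ["C7800", "C3490"], paid=200.0)
    start = pd.Timestamp("2018-06-01")
    b.fill("F00001", start, "osimertinib", 30, 16000.0)  # covers through 06-30
    supply_end = start + pd.Timedelta(days=29)
    resume = supply_end + pd.Timedelta(days=gap_days + 1)
    b.fill("F00001", resume, "osimertinib", 30, 16000.0)
    obs = pd.Timestamp("2019-12-31")
    if gap_days > 90:
        lines = [(start, resume - pd.Timedelta(days=1), {"osimertinib"},
                  "osimertinib_based", "retreatment_gap"),
                 (resume, obs, {"osimertinib"}, "osimertinib_based",
                  "end_of_observation")]
    else:
        lines = [(start, obs, {"osimertinib"}, "osimertinib_based",
                  "end_of_observation")]
    return _fixture_dataset(b), _truth("F00001", lines, dx0=dx0, index=start)


def _fx_window(day: int):
    """Second agent arriving on day ``day`` after line start."""
    b, dx0 = _fixture_scaffold("F00002")
    b.visit("F00002", dx0 + pd.Timedelta(days=9), ["C7800", "C3490"], paid=200.0)
    start = pd.Timestamp("2018-06-01")
    b.fill("F00002", start, "osimertinib", 30, 16000.0)
    second = start + pd.Timedelta(days=day)
    for k in range(3):
        b.visit("F00002", second + pd.Timedelta(days=21 * k), ["C3490"], paid=4000.0,
                procs=("carboplatin", "chemo_admin"), provider="oncologist")
    obs = pd.Timestamp("2019-12-31")
    if day <= 21:
        lines = [(start, obs, {"osimertinib", "carboplatin"}, "osimertinib_based",
                  "end_of_observation")]
    else:
        lines = [(start, second - pd.Timedelta(days=1), {"osimertinib"},
                  "osimertinib_based", "new_agent"),
                 (second, obs, {"carboplatin"}, "pbc_regimen",
                  "end_of_observation")]
    return _fixture_dataset(b), _truth("F00002", lines, dx0=dx0, index=start)


def _fx_combo_retreatment():
    """A platinum doublet resuming intact after a 91-day gap."""
    b, dx0 = _fixture_scaffold("F00003")
    b.visit("F00003", dx0 + pd.Timedelta(days=9), ["C7800", "C3490"], paid=200.0)
    start = pd.Timestamp("2018-06-01")
    # the fixture patient still needs a post-approval TKI to be selectable;
    # give osimertinib within the 1L window so the regimen is a combination
    b.fill("F00003", start, "osimertinib", 30, 16000.0)
    for k in range(3):
        b.visit("F00003", start + pd.Timedelta(days=21 * k), ["C3490"], paid=8000.0,
                procs=("carboplatin", "pemetrexed", "chemo_admin"),
                provider="oncologist")
    exposure_end = start + pd.Timedelta(days=42)  # last infusion day
    resume = exposure_end + pd.Timedelta(days=92)  # 91 uncovered days
    b.fill("F00003", resume, "osimertinib", 30, 16000.0)
    b.visit("F00003", resume, ["C3490"], paid=8000.0,
            procs=("carboplatin", "pemetrexed", "chemo_admin"), provider="oncologist")
    obs = pd.Timestamp("2019-12-31")
    reg = {"osimertinib", "carboplatin", "pemetrexed"}
    lines = [(start, resume - pd.Timedelta(days=1), reg, "osimertinib_based",
              "retreatment_gap"),
             (resume, obs, reg, "osimertinib_based", "end_of_observation")]
    return _fixture_dataset(b), _truth("F00003", lines, dx0=dx0, index=start)


def _fx_surgery(met_offset_days: int | None):
    """Surgery before index; metastatic diagnosis timing decides exclusion.

    met_offset_days None -> no metastatic code at all; <=30 -> exempt from
    the surgery exclusion; >30 -> excluded.
    """
    pid = "F00004"
    b, dx0 = _fixture_scaffold(pid)
    if met_offset_days is not None:
        b.visit(pid, dx0 + pd.Timedelta(days=met_offset_days), ["C7800", "C3490"],
                paid=200.0)
    b.visit(pid, dx0 + pd.Timedelta(days=12), ["C3490"], paid=9000.0,
            procs=("32480",), provider="acute_care_hospital")
    start = pd.Timestamp("2018-07-01")
    for k in range(6):
        b.fill(pid, start + pd.Timedelta(days=30 * k), "osimertinib", 30, 16000.0)
    obs = pd.Timestamp("2019-12-31")
    met30 = met_offset_days is not None and met_offset_days <= 30
    if met30:
        lines = [(start, obs, {"osimertinib"}, "osimertinib_based",
                  "end_of_observation")]
        return _fixture_dataset(b), _truth(pid, lines, dx0=dx0, index=start)
    return _fixture_dataset(b), _truth(
        pid, [], eligible=False, step="lc_surgery_pre_index", met30=False, dx0=dx0)


FIXTURES = {
    "gap90": lambda: _fx_gap(90),
    "gap91": lambda: _fx_gap(91),
    "window_day21": lambda: _fx_window(21),
    "window_day22": lambda: _fx_window(22),
    "combo_retreatment": _fx_combo_retreatment,
    "surgery_exclusion": lambda: _fx_surgery(None),
    "met_day30": lambda: _fx_surgery(30),
    "met_day31": lambda: _fx_surgery(31),
}


def make_fixture(name: str) -> tuple[ClaimsDataset, GroundTruth]:
    """Return one of the hand-constructed boundary-case datasets."""
    try:
        builder = FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}") from None
    return builder()
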