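"""Per-line healthcare resource utilization (HRU), cost aggregation, and
the Quan-mapped Charlson comorbidity index.

All utilization and costs are expressed per patient per month (PPPM),
with a month defined as 30.4375 days (365.25/12).  Paid amounts are
inflated to 2022 US dollars with a medical-care CPI deflator table
before PPPM scaling.  Cost components satisfy the additivity
invariants::

    total   = medical + pharmacy
    medical = inpatient + outpatient_total + ed_plus_other
    outpatient_total = outpatient_antineoplastic_plus_admin + outpatient_other

Emergency-department claims occurring inside an inpatient admission are
counted (days and dollars) as inpatient; ``setting="other"`` claims are
grouped with emergency-department costs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .claims_model import CodeConfig, build_admissions, code_matches, split_codes

DAYS_PER_MONTH = 30.4375
BASELINE_MONTHS = 12.0

COST_KEYS = ("total", "medical", "inpatient", "outpatient_total",
             "outpatient_antineoplastic_plus_admin", "outpatient_other",
             "ed_plus_other", "pharmacy")


def months_between(start, end) -> float:
    """Length of the closed interval [start, end] in 30.4375-day months."""
    return ((pd.Timestamp(end) - pd.Timestamp(start)).days + 1) / DAYS_PER_MONTH


def pppm(value: float, line_start, line_end) -> float:
    """Scale a count or amount to a per-patient-per-month rate."""
    m = months_between(line_start, line_end)
    if m <= 0:
        raise ValueError("line_end must be on/after line_start")
    return value / m


# ---------------------------------------------------------------------------
# CPI adjustment
# ---------------------------------------------------------------------------

@dataclass
class CPITable:
    """Map service year -> multiplier bringing costs to 2022 US dollars."""

    deflators: dict[int, float]

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.deflators.values()):
            raise ValueError("all deflators must be positive")

    def adjust(self, amount: float, service_year: int) -> float:
        try:
            return amount * self.deflators[int(service_year)]
        except KeyError:
            raise ValueError(f"no CPI deflator for year {service_year}") from None

    @classmethod
    def from_csv(cls, path: str | Path) -> "CPITable":
        df = pd.read_csv(path)
        return cls({int(r.year): float(r.deflator_to_2022) for r in df.itertuples()})

    @classmethod
    def default(cls) -> "CPITable":
        """The packaged medical-care CPI defaults (replaceable by users)."""
        with resources.files("claimlines.data").joinpath("cpi.csv").open("rb") as fh:
            df = pd.read_csv(fh)
        return cls({int(r.year): float(r.deflator_to_2022) for r in df.itertuples()})

    @classmethod
    def identity(cls, years=range(2010, 2026)) -> "CPITable":
        """All-ones table: useful when amounts are already on the 2022 scale."""
        return cls({int(y): 1.0 for y in years})


def cpi_adjust(amount: float, service_year: int, cpi_table: CPITable) -> float:
    return cpi_table.adjust(amount, service_year)


# ---------------------------------------------------------------------------
# window / line summaries
# ---------------------------------------------------------------------------

def summarize_window(med: pd.DataFrame, pha: pd.DataFrame, start, end,
                     codes: CodeConfig, cpi: CPITable,
                     months: float | None = None) -> dict:
    """All-cause HRU and CPI-adjusted PPPM costs over a closed window.

    ``med``/``pha`` are one patient's claims (they are filtered to the
    window here).  ``months`` overrides the PPPM denominator (used for
    the fixed 12-month baseline window); by default it is the window
    length in 30.4375-day months.
    """
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if months is None:
        months = months_between(start, end)
    if months <= 0:
        raise ValueError("empty summary window")

    med_w = med[(med.service_date >= start) & (med.service_date <= end)]
    pha_w = pha[(pha.fill_date >= start) & (pha.fill_date <= end)]

    def adj(rows):
        return sum(cpi.adjust(float(r.paid_amount), int(r.service_year))
                   for r in rows.itertuples())

    inp = med_w[med_w.setting == "inpatient"]
    admissions = build_admissions(inp)
    intervals = [(r.admit_date, r.discharge_date) for r in admissions.itertuples()]

    def in_admission(date):
        return any(a <= date <= d for a, d in intervals)

    ed = med_w[med_w.setting == "emergency"]
    ed_inside = ed[[in_admission(d) for d in ed.service_date]] if len(ed) else ed
    ed_outside = ed[[not in_admission(d) for d in ed.service_date]] if len(ed) else ed
    opd = med_w[med_w.setting == "outpatient"]
    other = med_w[med_w.setting == "other"]

    is_antineo = [
        any(codes.is_antineoplastic(c) or code_matches(c, codes.admin_procedure_codes)
            for c in split_codes(r.procedure_codes))
        for r in opd.itertuples()
    ]
    opd_antineo = opd[pd.Series(is_antineo, index=opd.index)] if len(opd) else opd
    opd_other = opd[~pd.Series(is_antineo, index=opd.index)] if len(opd) else opd

    inpatient_cost = adj(inp) + adj(ed_inside)
    opd_antineo_cost = adj(opd_antineo)
    opd_other_cost = adj(opd_other)
    outpatient_cost = opd_antineo_cost + opd_other_cost
    ed_other_cost = adj(ed_outside) + adj(other)
    medical_cost = inpatient_cost + outpatient_cost + ed_other_cost
    pharmacy_cost = adj(pha_w)

    n_inpatient_days = int(admissions.n_days.sum()) if len(admissions) else 0
    ed_days = len(set(ed_outside.service_date)) if len(ed_outside) else 0
    opd_days = len(set(opd.service_date)) if len(opd) else 0

    return {
        "months": months,
        "outpatient_service_days_pppm": opd_days / months,
        "inpatient_admissions_pppm": len(admissions) / months,
        "inpatient_days_pppm": n_inpatient_days / months,
        "ed_visit_days_pppm": ed_days / months,
        "any_outpatient": opd_days > 0,
        "any_inpatient": len(admissions) > 0,
        "any_ed": ed_days > 0,
        "cost_total_pppm": (medical_cost + pharmacy_cost) / months,
        "cost_medical_pppm": medical_cost / months,
        "cost_inpatient_pppm": inpatient_cost / months,
        "cost_outpatient_total_pppm": outpatient_cost / months,
        "cost_outpatient_antineoplastic_plus_admin_pppm": opd_antineo_cost / months,
        "cost_outpatient_other_pppm": opd_other_cost / months,
        "cost_ed_plus_other_pppm": ed_other_cost / months,
        "cost_pharmacy_pppm": pharmacy_cost / months,
    }


def supportive_care_flags(pha: pd.DataFrame, start, end, codes: CodeConfig) -> dict:
    """Any-claim flags for supportive-care categories inside [start, end]."""
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    pha_w = pha[(pha.fill_date >= start) & (pha.fill_date <= end)]
    drugs = set(pha_w.drug_code)
    return {
        "pain_management": bool(drugs & codes.supportive_agents("pain")),
        "respiratory_support": bool(drugs & codes.supportive_agents("respiratory")),
        "gcsf_gmcsf": bool(drugs & codes.supportive_agents("gcsf")),
        "esa": bool(drugs & codes.supportive_agents("esa")),
    }


def summarize_line(line: dict | pd.Series, med: pd.DataFrame, pha: pd.DataFrame,
                   codes: CodeConfig, cpi: CPITable) -> dict:
    """LOT summary: duration, PPPM HRU/costs, and supportive-care flags."""
    start, end = pd.Timestamp(line["start"]), pd.Timestamp(line["end"])
    out = {
        "patient_id": line["patient_id"],
        "line_number": int(line["line_number"]),
        "regimen_class": line.get("regimen_class"),
        "duration_months": months_between(start, end),
    }
    out.update(summarize_window(med, pha, start, end, codes, cpi))
    for k, v in supportive_care_flags(pha, start, end, codes).items():
        out[f"supportive_{k}"] = v
    return out


# ---------------------------------------------------------------------------
# Quan-mapped Charlson comorbidity index
# ---------------------------------------------------------------------------

@dataclass
class QuanCCIMap:
    """17 Charlson conditions with Quan ICD-9/10 prefixes and weights.

    ``hierarchy_group`` marks mutually exclusive condition pairs (mild vs
    severe liver disease, diabetes with vs without complications, any
    malignancy vs metastatic solid tumor): within a group only the
    highest-weight condition present contributes.
    """

    conditions: list[dict]

    @classmethod
    def from_csv(cls, path: str | Path) -> "QuanCCIMap":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        return cls._from_rows(rows)

    @classmethod
    def default(cls) -> "QuanCCIMap":
        ref = resources.files("claimlines.data").joinpath("quan_cci.csv")
        with ref.open("r", newline="") as fh:
            rows = list(csv.DictReader(fh))
        return cls._from_rows(rows)

    @classmethod
    def _from_rows(cls, rows) -> "QuanCCIMap":
        conditions = []
        for r in rows:
            weight = int(r["weight"])
            if weight <= 0:
                raise ValueError(f"weight must be positive: {r['condition']}")
            conditions.append({
                "condition": r["condition"],
                "prefixes": tuple(p for p in (r["icd9_prefixes"].split("|")
                                              + r["icd10_prefixes"].split("|")) if p),
                "weight": weight,
                "hierarchy_group": r["hierarchy_group"] or None,
            })
        return cls(conditions)


def quan_cci(dx_codes, cci_map: QuanCCIMap | None = None) -> int:
    """Charlson score from a bag of diagnosis codes (prefix matching).

    Monotone non-decreasing in the code bag; hierarchy rules applied per
    group (e.g. metastatic solid tumor supersedes any-malignancy).
    """
    if cci_map is None:
        cci_map = QuanCCIMap.default()
    codes_list = [str(c) for c in dx_codes]
    matched: dict[str, dict] = {}
    for cond in cci_map.conditions:
        if any(code_matches(c, cond["prefixes"]) for c in codes_list):
            matched[cond["condition"]] = cond
    # hierarchy: keep only the max-weight condition within each group
    by_group: dict[str, list[dict]] = {}
    for cond in matched.values():
        if cond["hierarchy_group"]:
            by_group.setdefault(cond["hierarchy_group"], []).append(cond)
    drop = set()
    for group, conds in by_group.items():
        best = max(conds, key=lambda c: c["weight"])
        drop.update(c["condition"] for c in conds if c is not best)
    return sum(c["weight"] for name, c in matched.items() if name not in drop)


def collect_dx_codes(med: pd.DataFrame, start, end) -> list[str]:
    """All diagnosis codes on one patient's medical claims in [start, end]."""
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    window = med[(med.service_date >= start) & (med.service_date <= end)]
    out: list[str] = []
    for joined in window.diagnosis_codes:
        out.extend(split_codes(joined))
    return out
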