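"""Claims-based proxy cohort selection for EGFR-mutated advanced NSCLC.

There is no diagnosis code for EGFR mutation or for "advanced" NSCLC in
administrative claims, so patients are selected with a proxy algorithm:

1. at least 2 lung-cancer (LC) diagnoses on distinct service dates within
   one continuous-eligibility period;
2. exclusion of small-cell LC (an SCLC agent — etoposide, irinotecan or
   topotecan — in the preliminary first-line regimen window);
3. a washout of >= 12 months of continuous eligibility before the first
   LC diagnosis (so the diagnosis is incident);
4. advanced disease: initiation of a guideline-recommended regimen, or a
   metastatic diagnosis within 30 days (inclusive) of the first LC
   diagnosis followed eventually by first-line initiation;
5. an EGFR-TKI initiation on/after the osimertinib approval date
   (2018-04-18), which defines the index date and proxies EGFR-mutated
   (Ex19del/L858R) status;
6. exclusion of any other-cancer diagnosis before the first LC diagnosis;
7. among patients without the 30-day metastatic qualifier, exclusion of
   those with LC-related surgery before the index date (early-stage
   disease treated surgically).

Patients failing a step are recorded in an ordered attrition log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .claims_model import (
    ClaimsDataset,
    CodeConfig,
    code_matches,
    normalize_enrollment,
    split_codes,
)
from .lot_engine import COMBINATION_WINDOW_DAYS, extract_episodes

DAYS_PER_MONTH = 30.4375
WASHOUT_DAYS = 365
BASELINE_DAYS = 365
METASTATIC_WINDOW_DAYS = 30  # inclusive boundary

SELECTION_STEPS = (
    "lc_dx_2plus", "sclc_exclusion", "washout_12mo", "advanced_disease",
    "egfr_tki_post_approval", "other_cancer_prior", "lc_surgery_pre_index",
)

COHORT_COLUMNS = [
    "patient_id", "first_lc_dx_date", "advanced_qualifier",
    "first_line_start_date", "index_date", "baseline_start", "baseline_end",
    "observation_end", "plan_type", "age_at_1l", "sex",
    "eligibility_start", "eligibility_end",
]


@dataclass
class AttritionLog:
    """Ordered record of cohort size before/after each selection filter."""

    steps: list[tuple[str, int, int, list]] = field(default_factory=list)

    def add(self, name: str, n_before: int, n_after: int, excluded: list) -> None:
        if n_after > n_before:
            raise ValueError("attrition must be non-increasing")
        self.steps.append((name, n_before, n_after, sorted(excluded)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s, nb, na, nb - na) for s, nb, na, _ in self.steps],
            columns=["step", "n_before", "n_after", "n_excluded"],
        )


def _merge_with_bridge(spans: pd.DataFrame, bridge_days: int) -> pd.DataFrame:
    """Normalize spans, additionally bridging uncovered gaps <= bridge_days."""
    norm = normalize_enrollment(spans)
    if bridge_days <= 0 or len(norm) <= 1:
        return norm
    rows = []
    cur = norm.iloc[0].copy()
    for _, row in norm.iloc[1:].iterrows():
        gap = (row.start_date - cur.end_date).days - 1
        if gap <= bridge_days:
            cur.end_date = max(cur.end_date, row.end_date)
        else:
            rows.append(cur)
            cur = row.copy()
    rows.append(cur)
    return pd.DataFrame(rows).reset_index(drop=True)


def _evaluate_patient(pid, demo, enr, med, pha_sub, dataset, codes: CodeConfig,
                      data_end, bridge_days):
    """Apply the selection filters in order; return (record|None, failed_step|None)."""
    approval = codes.osimertinib_approval_date

    # step 1: >=2 LC diagnoses on distinct dates within one eligibility period
    spans = _merge_with_bridge(enr, bridge_days) if len(enr) else enr
    lc_dates = sorted({
        row.service_date for row in med.itertuples()
        if any(code_matches(c, codes.lc_diagnosis_codes)
               for c in split_codes(row.diagnosis_codes))
    })
    span = None
    for s in spans.itertuples():
        in_span = [d for d in lc_dates if s.start_date <= d <= s.end_date]
        if len(in_span) >= 2:
            span = s
            first_lc_dx = in_span[0]
            break
    if span is None:
        return None, "lc_dx_2plus"
    observation_end = min(span.end_date, data_end)

    episodes = [e for e in extract_episodes(dataset, pid, codes)
                if first_lc_dx <= e.start_date <= observation_end]

    # step 2: SCLC — an SCLC agent inside the preliminary 1L regimen window
    if episodes:
        w_start = episodes[0].start_date
        w_end = w_start + pd.Timedelta(days=COMBINATION_WINDOW_DAYS)
        window_agents = {e.agent for e in episodes if e.start_date <= w_end}
        if window_agents & codes.sclc_agents:
            return None, "sclc_exclusion"

    # step 3: 12-month washout of continuous eligibility before first LC dx
    if (first_lc_dx - span.start_date).days < WASHOUT_DAYS:
        return None, "washout_12mo"

    # step 4: advanced disease (guideline 1L, or metastatic dx within 30 days
    # followed eventually by 1L initiation)
    met_window_end = first_lc_dx + pd.Timedelta(days=METASTATIC_WINDOW_DAYS)
    met_within_30d = any(
        first_lc_dx <= row.service_date <= met_window_end
        and any(code_matches(c, codes.metastatic_codes)
                for c in split_codes(row.diagnosis_codes))
        for row in med.itertuples()
    )
    if not episodes:  # neither qualifying path can complete without 1L
        return None, "advanced_disease"
    first_line_start = episodes[0].start_date

    # step 5: EGFR-TKI initiation on/after the approval date -> index date
    tki_starts = [e.start_date for e in episodes
                  if e.agent in codes.egfr_tki_agents and e.start_date >= approval]
    if not tki_starts:
        return None, "egfr_tki_post_approval"
    index_date = min(tki_starts)

    # step 6: other-cancer diagnosis before the first LC diagnosis
    for row in med.itertuples():
        if row.service_date < first_lc_dx and any(
                code_matches(c, codes.other_cancer_codes)
                for c in split_codes(row.diagnosis_codes)):
            return None, "other_cancer_prior"

    # step 7: LC-related surgery before index among non-metastatic qualifiers
    if not met_within_30d:
        for row in med.itertuples():
            if span.start_date <= row.service_date < index_date and any(
                    code_matches(c, codes.lc_surgery_procedure_codes)
                    for c in split_codes(row.procedure_codes)):
                return None, "lc_surgery_pre_index"

    birth_year = demo.get("birth_year")
    age = int(first_line_start.year - birth_year) if pd.notna(birth_year) else pd.NA
    record = {
        "patient_id": pid,
        "first_lc_dx_date": first_lc_dx,
        "advanced_qualifier": ("metastatic_dx_within_30d" if met_within_30d
                               else "regimen_initiation"),
        "first_line_start_date": first_line_start,
        "index_date": index_date,
        "baseline_start": first_line_start - pd.Timedelta(days=BASELINE_DAYS),
        "baseline_end": first_line_start - pd.Timedelta(days=1),
        "observation_end": observation_end,
        "plan_type": span.plan_type,
        "age_at_1l": age,
        "sex": demo.get("sex"),
        "eligibility_start": span.start_date,
        "eligibility_end": span.end_date,
    }
    return record, None


def select_cohort(dataset: ClaimsDataset, codes: CodeConfig,
                  data_end_date, *, eligibility_bridge_days: int = 0
                  ) -> tuple[pd.DataFrame, AttritionLog]:
    """Apply the proxy selection algorithm to every patient.

    Returns the cohort table (one row per selected patient, columns of
    :data:`COHORT_COLUMNS`) and the ordered :class:`AttritionLog`.  The
    result is invariant to the ordering of claim rows.
    ``eligibility_bridge_days`` optionally bridges short uncovered gaps
    between enrollment spans (default 0: strict continuity).
    """
    data_end = pd.Timestamp(data_end_date)
    med_by = dict(tuple(dataset.medical.groupby("patient_id", sort=True)))
    pha_by = dict(tuple(dataset.pharmacy.groupby("patient_id", sort=True)))
    enr_by = dict(tuple(dataset.enrollment.groupby("patient_id", sort=True)))
    empty_med = dataset.medical.iloc[0:0]
    empty_pha = dataset.pharmacy.iloc[0:0]
    empty_enr = dataset.enrollment.iloc[0:0]

    records, fails = [], {}
    patients = dataset.patients.sort_values("patient_id")
    for demo in patients.to_dict("records"):
        pid = demo["patient_id"]
        record, failed = _evaluate_patient(
            pid, demo,
            enr_by.get(pid, empty_enr),
            med_by.get(pid, empty_med),
            pha_by.get(pid, empty_pha),
            dataset, codes, data_end, eligibility_bridge_days)
        if failed is None:
            records.append(record)
        else:
            fails[pid] = failed

    log = AttritionLog()
    remaining = list(patients.patient_id)
    for step in SELECTION_STEPS:
        excluded = [pid for pid in remaining if fails.get(pid) == step]
        n_before = len(remaining)
        remaining = [pid for pid in remaining if fails.get(pid) != step]
        log.add(step, n_before, len(remaining), excluded)

    cohort = pd.DataFrame(records, columns=COHORT_COLUMNS)
    return cohort, log


def baseline_characteristics(record: dict | pd.Series, dataset: ClaimsDataset,
                             codes: CodeConfig) -> dict:
    """Baseline flags and timing measures for one selected patient.

    "Ever" flags cover the pre-first-line eligible period (eligibility
    start through the day before first-line initiation); "within 30
    days" flags cover the 30 days before first-line initiation,
    inclusive of the boundary day.
    """
    pid = record["patient_id"]
    t1l = pd.Timestamp(record["first_line_start_date"])
    elig_start = pd.Timestamp(record["eligibility_start"])
    pre_end = t1l - pd.Timedelta(days=1)
    recent_start = t1l - pd.Timedelta(days=30)

    med = dataset.medical[dataset.medical.patient_id == pid]
    pha = dataset.pharmacy[dataset.pharmacy.patient_id == pid]

    def _med_dates(prefixes, kind):
        out = []
        for row in med.itertuples():
            if not (elig_start <= row.service_date <= pre_end):
                continue
            joined = row.procedure_codes if kind == "proc" else row.diagnosis_codes
            if any(code_matches(c, prefixes) for c in split_codes(joined)):
                out.append(row.service_date)
        return out

    cortico_agents = codes.supportive_agents("corticosteroid")
    cortico_dates = [row.fill_date for row in pha.itertuples()
                     if row.drug_code in cortico_agents
                     and elig_start <= row.fill_date <= pre_end]
    radio_dates = _med_dates(codes.radiotherapy_procedure_codes, "proc")
    surgery_dates = _med_dates(codes.lc_surgery_procedure_codes, "proc")
    brain_dates = _med_dates(codes.brain_metastasis_codes, "dx")

    tki_dates = [row.fill_date for row in pha.itertuples()
                 if row.drug_code in codes.egfr_tki_agents]
    first_tki = min(tki_dates) if tki_dates else pd.Timestamp(record["index_date"])
    dx0 = pd.Timestamp(record["first_lc_dx_date"])

    return {
        "patient_id": pid,
        "corticosteroids_pre1l": bool(cortico_dates),
        "radiotherapy_pre1l": bool(radio_dates),
        "surgery_pre1l": bool(surgery_dates),
        "radiotherapy_30d_pre1l": any(d >= recent_start for d in radio_dates),
        "surgery_30d_pre1l": any(d >= recent_start for d in surgery_dates),
        "brain_metastasis": bool(brain_dates),
        "months_dx_to_1l": (t1l - dx0).days / DAYS_PER_MONTH,
        "months_dx_to_first_tki": (first_tki - dx0).days / DAYS_PER_MONTH,
    }
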