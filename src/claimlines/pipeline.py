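"""End-to-end convenience wrappers: cohort -> lines -> summaries -> report.

These are the functions the analysis drivers call; each stage is a thin
loop over the per-patient operations defined in the other modules.
"""

from __future__ import annotations

import pandas as pd

from .claims_model import ClaimsDataset, CodeConfig
from .cohort_selection import baseline_characteristics, select_cohort
from .lot_engine import derive_lines, extract_episodes, lines_to_frame
from .outcomes import (
    BASELINE_MONTHS,
    CPITable,
    QuanCCIMap,
    collect_dx_codes,
    quan_cci,
    summarize_line,
    summarize_window,
)


def derive_cohort_lines(dataset: ClaimsDataset, cohort: pd.DataFrame,
                        codes: CodeConfig) -> pd.DataFrame:
    """Lines of therapy for every selected patient, as one table."""
    frames = []
    for rec in cohort.to_dict("records"):
        episodes = extract_episodes(dataset, rec["patient_id"], codes)
        lines = derive_lines(episodes, rec["first_lc_dx_date"],
                             rec["observation_end"], codes)
        frames.append(lines_to_frame(lines))
    if not frames:
        return lines_to_frame([])
    return pd.concat(frames, ignore_index=True)


def summarize_cohort_lines(dataset: ClaimsDataset, lines_df: pd.DataFrame,
                           codes: CodeConfig, cpi: CPITable) -> pd.DataFrame:
    """Per patient-line LOT summaries (duration, PPPM HRU and costs)."""
    med_by = dict(tuple(dataset.medical.groupby("patient_id")))
    pha_by = dict(tuple(dataset.pharmacy.groupby("patient_id")))
    empty_med = dataset.medical.iloc[0:0]
    empty_pha = dataset.pharmacy.iloc[0:0]
    rows = []
    for line in lines_df.to_dict("records"):
        pid = line["patient_id"]
        rows.append(summarize_line(line, med_by.get(pid, empty_med),
                                   pha_by.get(pid, empty_pha), codes, cpi))
    return pd.DataFrame(rows)


def baseline_table(dataset: ClaimsDataset, cohort: pd.DataFrame,
                   codes: CodeConfig, cpi: CPITable,
                   cci_map: QuanCCIMap | None = None) -> pd.DataFrame:
    """Baseline characteristics + Quan-CCI + baseline monthly HRU/costs.

    Baseline HRU/costs use the fixed 365-day window before first-line
    initiation with a 12-month PPPM denominator.
    """
    if cci_map is None:
        cci_map = QuanCCIMap.default()
    med_by = dict(tuple(dataset.medical.groupby("patient_id")))
    pha_by = dict(tuple(dataset.pharmacy.groupby("patient_id")))
    empty_med = dataset.medical.iloc[0:0]
    empty_pha = dataset.pharmacy.iloc[0:0]
    rows = []
    for rec in cohort.to_dict("records"):
        pid = rec["patient_id"]
        med = med_by.get(pid, empty_med)
        pha = pha_by.get(pid, empty_pha)
        row = baseline_characteristics(rec, dataset, codes)
        row["quan_cci"] = quan_cci(
            collect_dx_codes(med, rec["baseline_start"], rec["baseline_end"]),
            cci_map)
        base = summarize_window(med, pha, rec["baseline_start"], rec["baseline_end"],
                                codes, cpi, months=BASELINE_MONTHS)
        for k, v in base.items():
            if k != "months":
                row[f"baseline_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(dataset: ClaimsDataset, codes: CodeConfig, cpi: CPITable,
                 data_end, *, with_baseline: bool = True):
    """Full analysis: selection, line derivation, summaries.

    Returns a dict with cohort, attrition, lines, summaries, and
    (optionally) the baseline table.
    """
    cohort, attrition = select_cohort(dataset, codes, data_end)
    lines_df = derive_cohort_lines(dataset, cohort, codes)
    summaries = summarize_cohort_lines(dataset, lines_df, codes, cpi)
    out = {"cohort": cohort, "attrition": attrition, "lines": lines_df,
           "summaries": summaries}
    if with_baseline:
        out["baseline"] = baseline_table(dataset, cohort, codes, cpi)
    return out
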