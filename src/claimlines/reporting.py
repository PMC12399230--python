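"""Descriptive reporting: table shells, sequencing summary, mean
differences with 95% confidence intervals, cost shares, and PPPY
conversions.

The study design is descriptive — no confounder adjustment and no
hypothesis testing — so the statistical surface is small: group means,
SDs and medians, and Welch (unequal-variance) intervals around mean
differences.  Groups are treated as independent even across lines of
therapy, mirroring how LOT cohorts are conventionally tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("overall", "osimertinib_monotherapy_1l", "pbc_without_io_1l")


@dataclass
class MeanDifference:
    md: float
    ci_low: float
    ci_high: float
    group_a: str = "A"
    group_b: str = "B"
    measure: str = ""

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.md <= self.ci_high):
            raise ValueError("confidence interval must bracket the mean difference")


def mean_difference_ci(values_a, values_b, alpha: float = 0.05, *,
                       quantile: str = "normal", measure: str = "",
                       group_a: str = "A", group_b: str = "B") -> MeanDifference:
    """Mean difference mean(a) - mean(b) with a Welch-type interval.

    The standard error uses unpooled variances ``sqrt(va/na + vb/nb)``.
    ``quantile="normal"`` (default) uses the normal critical value;
    ``quantile="t"`` uses a t critical value with Welch-Satterthwaite
    degrees of freedom.  Both groups need n >= 2.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    md = float(a.mean() - b.mean())
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se = float(np.sqrt(va / len(a) + vb / len(b)))
    if quantile == "normal":
        crit = float(stats.norm.ppf(1 - alpha / 2))
    elif quantile == "t":
        if se == 0:
            crit = 0.0
        else:
            df = (va / len(a) + vb / len(b)) ** 2 / (
                (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1))
            crit = float(stats.t.ppf(1 - alpha / 2, df))
    else:
        raise ValueError("quantile must be 'normal' or 't'")
    half = crit * se
    return MeanDifference(md, md - half, md + half,
                          group_a=group_a, group_b=group_b, measure=measure)


def cost_share(component_mean: float, total_mean: float) -> float:
    """Percent share of a cost component, reported to one decimal."""
    if total_mean <= 0:
        raise ValueError("total mean must be positive")
    return round(100.0 * component_mean / total_mean, 1)


def pppm_to_pppy(rate_pppm: float) -> float:
    """Per-patient-per-month rate to per-patient-per-year, one decimal."""
    if rate_pppm < 0:
        raise ValueError("rate must be nonnegative")
    return round(rate_pppm * 12.0, 1)


# ---------------------------------------------------------------------------
# grouped summaries
# ---------------------------------------------------------------------------

def group_summary(values, label: str = "") -> dict:
    """n / mean / SD / median for one measure in one group.

    SD is reported as NaN (empty cell) when n < 2.
    """
    v = np.asarray([x for x in values if pd.notna(x)], dtype=float)
    n = len(v)
    return {
        "group": label,
        "n": n,
        "mean": float(v.mean()) if n else np.nan,
        "sd": float(v.std(ddof=1)) if n >= 2 else np.nan,
        "median": float(np.median(v)) if n else np.nan,
    }


def summarize_measures(df: pd.DataFrame, measures, label: str) -> pd.DataFrame:
    rows = []
    for m in measures:
        rec = group_summary(df[m], label)
        rec["measure"] = m
        rows.append(rec)
    return pd.DataFrame(rows, columns=["group", "measure", "n", "mean", "sd", "median"])


def subgroup_ids(lines_df: pd.DataFrame, codes) -> dict[str, set]:
    """Patient-id sets for the 1L subgroups used throughout the report."""
    from .lot_engine import regimen_flags

    first = lines_df[lines_df.line_number == 1]
    osi, pbc = set(), set()
    for row in first.itertuples():
        regimen = set(row.regimen.split(";"))
        flags = regimen_flags(regimen, codes)
        if flags["osimertinib_monotherapy"]:
            osi.add(row.patient_id)
        if flags["pbc_without_io"]:
            pbc.add(row.patient_id)
    return {"overall": set(first.patient_id),
            "osimertinib_monotherapy_1l": osi,
            "pbc_without_io_1l": pbc}


MEASURE_SETS = {
    "hru": ["duration_months", "outpatient_service_days_pppm",
            "inpatient_admissions_pppm", "inpatient_days_pppm",
            "ed_visit_days_pppm"],
    "costs": ["cost_total_pppm", "cost_medical_pppm", "cost_inpatient_pppm",
              "cost_outpatient_total_pppm",
              "cost_outpatient_antineoplastic_plus_admin_pppm",
              "cost_outpatient_other_pppm", "cost_ed_plus_other_pppm",
              "cost_pharmacy_pppm"],
}

FLAG_MEASURES = ["any_outpatient", "any_inpatient", "any_ed",
                 "supportive_pain_management", "supportive_respiratory_support",
                 "supportive_gcsf_gmcsf", "supportive_esa"]


def _by_group_line(summaries: pd.DataFrame, groups: dict[str, set],
                   measures, max_depth: int = 3) -> pd.DataFrame:
    frames = []
    for gname, ids in groups.items():
        for depth in range(1, max_depth + 1):
            sub = summaries[(summaries.line_number == depth)
                            & (summaries.patient_id.isin(ids))]
            if len(sub) == 0:
                continue
            f = summarize_measures(sub, measures, gname)
            f.insert(1, "line_number", depth)
            frames.append(f)
    if not frames:
        return pd.DataFrame(columns=["group", "line_number", "measure",
                                     "n", "mean", "sd", "median"])
    return pd.concat(frames, ignore_index=True)


def _flag_table(summaries: pd.DataFrame, groups: dict[str, set],
                max_depth: int = 3) -> pd.DataFrame:
    rows = []
    for gname, ids in groups.items():
        for depth in range(1, max_depth + 1):
            sub = summaries[(summaries.line_number == depth)
                            & (summaries.patient_id.isin(ids))]
            if len(sub) == 0:
                continue
            for m in FLAG_MEASURES:
                if m not in sub:
                    continue
                n = int(len(sub))
                k = int(sub[m].sum())
                rows.append({"group": gname, "line_number": depth, "measure": m,
                             "n": k, "denominator": n,
                             "proportion_pct": round(100.0 * k / n, 1)})
    return pd.DataFrame(rows, columns=["group", "line_number", "measure", "n",
                                       "denominator", "proportion_pct"])


def _md_table(summaries: pd.DataFrame, groups: dict[str, set],
              max_depth: int = 3) -> pd.DataFrame:
    """Mean-difference tables: consecutive LOTs (overall) and the two 1L
    subgroups within each LOT, for every cost measure."""
    rows = []
    overall = groups["overall"]
    for m in MEASURE_SETS["costs"]:
        for depth in range(1, max_depth):
            a = summaries[(summaries.line_number == depth + 1)
                          & (summaries.patient_id.isin(overall))][m].dropna()
            bvals = summaries[(summaries.line_number == depth)
                              & (summaries.patient_id.isin(overall))][m].dropna()
            if len(a) >= 2 and len(bvals) >= 2:
                md = mean_difference_ci(a, bvals, measure=m,
                                        group_a=f"{depth + 1}L", group_b=f"{depth}L")
                rows.append({"comparison": f"{depth + 1}L_vs_{depth}L", "measure": m,
                             "md": md.md, "ci_low": md.ci_low, "ci_high": md.ci_high})
        for depth in range(1, max_depth + 1):
            a = summaries[(summaries.line_number == depth)
                          & summaries.patient_id.isin(groups["osimertinib_monotherapy_1l"])][m].dropna()
            bvals = summaries[(summaries.line_number == depth)
                              & summaries.patient_id.isin(groups["pbc_without_io_1l"])][m].dropna()
            if len(a) >= 2 and len(bvals) >= 2:
                md = mean_difference_ci(a, bvals, measure=m,
                                        group_a="osimertinib_mono",
                                        group_b="pbc_without_io")
                rows.append({"comparison": f"osi_vs_pbc_{depth}L", "measure": m,
                             "md": md.md, "ci_low": md.ci_low, "ci_high": md.ci_high})
    return pd.DataFrame(rows, columns=["comparison", "measure", "md",
                                       "ci_low", "ci_high"])


def build_report(cohort: pd.DataFrame, lines_df: pd.DataFrame,
                 summaries: pd.DataFrame, baseline: pd.DataFrame | None,
                 codes, out_dir: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """Assemble the report bundle (baseline, HRU, costs, sequencing).

    Every derived cell (cost shares, PPPY rates, progression percentages)
    is recomputed here from the patient-line summary table.  When
    ``out_dir`` is given each table is also written as CSV.
    """
    from .lot_engine import progression_shares, sequencing_matrix

    groups = subgroup_ids(lines_df, codes) if len(lines_df) else {
        g: set() for g in GROUPS}

    tables: dict[str, pd.DataFrame] = {}

    # baseline characteristics (Table 1 shell)
    if baseline is not None and len(baseline) and len(cohort):
        b = baseline.merge(cohort[["patient_id", "age_at_1l", "sex"]], on="patient_id")
        rows = []
        for gname, ids in groups.items():
            sub = b[b.patient_id.isin(ids)]
            if len(sub) == 0:
                continue
            rec = {"group": gname, "n": len(sub),
                   "age_mean": float(sub.age_at_1l.mean()),
                   "age_sd": float(sub.age_at_1l.std(ddof=1)) if len(sub) > 1 else np.nan,
                   "female_pct": round(100.0 * (sub.sex == "F").mean(), 1)}
            for col in ("corticosteroids_pre1l", "radiotherapy_pre1l", "surgery_pre1l",
                        "radiotherapy_30d_pre1l", "surgery_30d_pre1l",
                        "brain_metastasis"):
                rec[f"{col}_pct"] = round(100.0 * sub[col].mean(), 1)
            for col in ("months_dx_to_1l", "months_dx_to_first_tki", "quan_cci"):
                if col in sub:
                    rec[f"{col}_mean"] = float(sub[col].mean())
                    rec[f"{col}_median"] = float(sub[col].median())
            rows.append(rec)
        tables["table1_baseline"] = pd.DataFrame(rows)
    else:
        tables["table1_baseline"] = pd.DataFrame(
            columns=["group", "n", "age_mean", "age_sd", "female_pct"])

    # HRU by LOT x group (Table 2 shell) + any/supportive flags
    tables["table2_hru"] = _by_group_line(summaries, groups, MEASURE_SETS["hru"]) \
        if len(summaries) else pd.DataFrame(
            columns=["group", "line_number", "measure", "n", "mean", "sd", "median"])
    tables["table2_flags"] = _flag_table(summaries, groups) if len(summaries) \
        else pd.DataFrame(columns=["group", "line_number", "measure", "n",
                                   "denominator", "proportion_pct"])

    # costs by LOT (Tables 3-4 shells) with MD columns
    tables["table3_costs"] = _by_group_line(summaries, groups, MEASURE_SETS["costs"]) \
        if len(summaries) else pd.DataFrame(
            columns=["group", "line_number", "measure", "n", "mean", "sd", "median"])
    tables["table4_mean_differences"] = _md_table(summaries, groups) \
        if len(summaries) else pd.DataFrame(
            columns=["comparison", "measure", "md", "ci_low", "ci_high"])

    # sequencing matrix + progression shares (Figure 1 data)
    tables["sequencing"] = sequencing_matrix(lines_df) if len(lines_df) else \
        pd.DataFrame(columns=["line_number", "regimen_class", "n", "denominator",
                              "proportion_pct"])
    prog = progression_shares(lines_df) if len(lines_df) else {}
    tables["progression"] = pd.DataFrame(
        [{"transition": k, "proportion_pct": round(100.0 * v, 1)}
         for k, v in prog.items()], columns=["transition", "proportion_pct"])

    # derived: cost shares and PPPY conversions, recomputed from table cells
    shares, pppy = [], []
    t3 = tables["table3_costs"]
    t2 = tables["table2_hru"]
    for (gname, depth), sub in t3.groupby(["group", "line_number"]):
        total = sub.loc[sub.measure == "cost_total_pppm", "mean"]
        if len(total) == 0 or not np.isfinite(total.iloc[0]) or total.iloc[0] <= 0:
            continue
        for m in MEASURE_SETS["costs"][2:]:
            comp = sub.loc[sub.measure == m, "mean"]
            if len(comp):
                shares.append({"group": gname, "line_number": depth, "measure": m,
                               "share_pct": cost_share(float(comp.iloc[0]),
                                                       float(total.iloc[0]))})
    for (gname, depth), sub in t2.groupby(["group", "line_number"]):
        adm = sub.loc[sub.measure == "inpatient_admissions_pppm", "mean"]
        if len(adm) and np.isfinite(adm.iloc[0]):
            pppy.append({"group": gname, "line_number": depth,
                         "inpatient_admissions_pppy": pppm_to_pppy(float(adm.iloc[0]))})
    tables["cost_shares"] = pd.DataFrame(
        shares, columns=["group", "line_number", "measure", "share_pct"])
    tables["pppy"] = pd.DataFrame(
        pppy, columns=["group", "line_number", "inpatient_admissions_pppy"])

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
    return tables
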