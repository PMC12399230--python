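"""Line-of-therapy (LOT) derivation and regimen classification.

A line of therapy starts at the first qualifying antineoplastic claim.
Every antineoplastic agent first observed within 21 days following the
line start (inclusive: days 0..21) joins the line's regimen.  The line
ends on the earliest of

* the day prior to the initiation of an antineoplastic agent that is not
  part of the regimen (``end_reason="new_agent"``),
* the day prior to a regimen agent's resumption after a >90-day gap in
  exposure — re-treatment (``end_reason="retreatment_gap"``), or
* the end of the observation period (``end_reason="end_of_observation"``).

Exposure for oral agents runs through ``fill_date + days_supply - 1``;
for infused (medical-claim) agents the exposure day is the service date.
The gap is counted in whole uncovered days: a claim on the day
immediately after coverage ends is a 0-day gap, so a 90-day gap keeps
the line intact and a 91-day gap splits it.  Subsequent lines are built
by the same rules with their own 21-day combination window.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .claims_model import ClaimsDataset, CodeConfig, split_codes

COMBINATION_WINDOW_DAYS = 21
RETREATMENT_GAP_DAYS = 90

REGIMEN_CLASSES = (
    "osimertinib_based", "other_egfr_tki", "pbc_regimen", "io_mono",
    "other_chemo", "other",
)


@dataclass(frozen=True)
class TreatmentEpisode:
    """One exposure to one antineoplastic agent."""

    patient_id: str
    agent: str
    start_date: pd.Timestamp
    supply_end_date: pd.Timestamp
    source: str  # "pharmacy" | "medical"


@dataclass
class LineOfTherapy:
    patient_id: str
    line_number: int
    start_date: pd.Timestamp
    end_date: pd.Timestamp
    regimen: frozenset
    regimen_class: str
    end_reason: str

    @property
    def duration_days(self) -> int:
        return (self.end_date - self.start_date).days + 1


def extract_episodes(dataset: ClaimsDataset, patient_id, codes: CodeConfig) -> list[TreatmentEpisode]:
    """Build antineoplastic treatment episodes for one patient.

    Pharmacy claims contribute an episode when the drug code is an
    antineoplastic in the dictionary; medical claims contribute one
    episode per antineoplastic drug key found among their procedure
    codes (point exposure on the service date).
    """
    episodes: list[TreatmentEpisode] = []
    pha = dataset.pharmacy
    pha = pha[pha.patient_id == patient_id]
    for row in pha.itertuples():
        if codes.is_antineoplastic(row.drug_code):
            episodes.append(TreatmentEpisode(
                patient_id=patient_id,
                agent=row.drug_code,
                start_date=row.fill_date,
                supply_end_date=row.fill_date + pd.Timedelta(days=int(row.days_supply) - 1),
                source="pharmacy",
            ))
    med = dataset.medical
    med = med[med.patient_id == patient_id]
    for row in med.itertuples():
        for code in split_codes(row.procedure_codes):
            if codes.is_antineoplastic(code):
                episodes.append(TreatmentEpisode(
                    patient_id=patient_id,
                    agent=code,
                    start_date=row.service_date,
                    supply_end_date=row.service_date,
                    source="medical",
                ))
    episodes.sort(key=lambda e: (e.start_date, e.agent))
    return episodes


def derive_lines(episodes: list[TreatmentEpisode],
                 first_lc_dx_date: pd.Timestamp,
                 observation_end: pd.Timestamp,
                 codes: CodeConfig) -> list[LineOfTherapy]:
    """Derive ordered lines of therapy from one patient's episodes.

    Episodes are restricted to [first_lc_dx_date, observation_end];
    later episodes are ignored.  Same-date claims are processed as one
    batch so the result is invariant to input row order; when a batch
    contains both a new agent and a regimen agent, the new-agent rule
    takes precedence.
    """
    eps = sorted(
        (e for e in episodes
         if first_lc_dx_date <= e.start_date <= observation_end),
        key=lambda e: (e.start_date, e.agent),
    )
    if not eps:
        return []

    # group into date batches
    batches: list[tuple[pd.Timestamp, list[TreatmentEpisode]]] = []
    for e in eps:
        if batches and batches[-1][0] == e.start_date:
            batches[-1][1].append(e)
        else:
            batches.append((e.start_date, [e]))

    lines: list[LineOfTherapy] = []
    patient_id = eps[0].patient_id
    i = 0
    line_number = 1
    while i < len(batches):
        start = batches[i][0]
        window_end = start + pd.Timedelta(days=COMBINATION_WINDOW_DAYS)
        regimen: set[str] = set()
        exposure_end = start
        j = i
        end_date = None
        end_reason = None
        next_i = None
        while j < len(batches):
            date, batch = batches[j]
            if date <= window_end:
                for e in batch:
                    regimen.add(e.agent)
                    exposure_end = max(exposure_end, e.supply_end_date)
                j += 1
                continue
            agents = {e.agent for e in batch}
            if agents - regimen:
                end_date = date - pd.Timedelta(days=1)
                end_reason = "new_agent"
                next_i = j
                break
            gap_days = (date - exposure_end).days - 1
            if gap_days > RETREATMENT_GAP_DAYS:
                end_date = date - pd.Timedelta(days=1)
                end_reason = "retreatment_gap"
                next_i = j
                break
            for e in batch:
                exposure_end = max(exposure_end, e.supply_end_date)
            j += 1
        if end_date is None:
            end_date = observation_end
            end_reason = "end_of_observation"
            next_i = len(batches)
        end_date = min(end_date, observation_end)
        lines.append(LineOfTherapy(
            patient_id=patient_id,
            line_number=line_number,
            start_date=start,
            end_date=end_date,
            regimen=frozenset(regimen),
            regimen_class=classify_regimen(regimen, codes),
            end_reason=end_reason,
        ))
        line_number += 1
        i = next_i
    return lines


def classify_regimen(regimen, codes: CodeConfig) -> str:
    """Classify a regimen by agent-class precedence.

    osimertinib present -> osimertinib_based; another EGFR-TKI ->
    other_egfr_tki; a platinum agent -> pbc_regimen; immunotherapy only
    -> io_mono; any chemotherapy/other antineoplastic -> other_chemo;
    anything else -> other.
    """
    regimen = set(regimen)
    if not regimen:
        raise ValueError("empty regimen")
    classes = {codes.agent_class(a) for a in regimen}
    if "osimertinib" in regimen:
        return "osimertinib_based"
    if classes & {"egfr_tki"}:
        return "other_egfr_tki"
    if "platinum" in classes:
        return "pbc_regimen"
    if classes == {"immunotherapy"}:
        return "io_mono"
    if classes & {"nonplatinum_chemo", "other_antineoplastic"}:
        return "other_chemo"
    return "other"


def regimen_flags(regimen, codes: CodeConfig) -> dict[str, bool]:
    """Subgroup flags: exact osimertinib monotherapy and PBC with/without IO."""
    regimen = set(regimen)
    classes = {codes.agent_class(a) for a in regimen}
    is_pbc = "platinum" in classes and "osimertinib" not in regimen \
        and not (classes & {"egfr_tki"})
    has_io = "immunotherapy" in classes
    return {
        "osimertinib_monotherapy": regimen == {"osimertinib"},
        "pbc_with_io": is_pbc and has_io,
        "pbc_without_io": is_pbc and not has_io,
    }


def lines_to_frame(lines: list[LineOfTherapy]) -> pd.DataFrame:
    """Tabulate lines; regimen is ';'-joined in sorted order."""
    rows = [{
        "patient_id": ln.patient_id,
        "line_number": ln.line_number,
        "start": ln.start_date,
        "end": ln.end_date,
        "regimen": ";".join(sorted(ln.regimen)),
        "regimen_class": ln.regimen_class,
        "end_reason": ln.end_reason,
    } for ln in lines]
    return pd.DataFrame(rows, columns=["patient_id", "line_number", "start", "end",
                                       "regimen", "regimen_class", "end_reason"])


def sequencing_matrix(lines_df: pd.DataFrame, max_depth: int = 3) -> pd.DataFrame:
    """Per-depth regimen-class distribution and progression proportions.

    Denominators are the patients still treated at each depth (the
    patients with a line of that number), so each depth's proportions
    sum to 100%.
    """
    rows = []
    n_by_depth = {}
    for depth in range(1, max_depth + 1):
        sub = lines_df[lines_df.line_number == depth]
        n_depth = sub.patient_id.nunique()
        n_by_depth[depth] = n_depth
        counts = sub.groupby("regimen_class").patient_id.nunique()
        for cls, n in counts.items():
            rows.append({
                "line_number": depth,
                "regimen_class": cls,
                "n": int(n),
                "denominator": int(n_depth),
                "proportion_pct": 100.0 * n / n_depth if n_depth else 0.0,
            })
        if n_depth == 0 and depth > 1:
            continue
    out = pd.DataFrame(rows, columns=["line_number", "regimen_class", "n",
                                      "denominator", "proportion_pct"])
    return out


def progression_shares(lines_df: pd.DataFrame, max_depth: int = 3) -> dict[str, float]:
    """n(depth+1)/n(depth) progression proportions (0 when denominator is 0)."""
    out = {}
    for depth in range(1, max_depth):
        n_cur = lines_df[lines_df.line_number == depth].patient_id.nunique()
        n_next = lines_df[lines_df.line_number == depth + 1].patient_id.nunique()
        out[f"{depth}L_to_{depth + 1}L"] = (n_next / n_cur) if n_cur else 0.0
    return out
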