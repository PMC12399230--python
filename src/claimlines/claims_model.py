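"""Typed data model for administrative claims plus CSV readers/writers.

The in-memory containers are pandas DataFrames wrapped in a light
:class:`ClaimsDataset` dataclass; every downstream stage of the pipeline
(cohort selection, line-of-therapy derivation, outcome summarisation)
consumes this one container.  All calendar intervals in the package are
closed — ``[start, end]`` inclusive on both ends — matching the
"day prior to initiation" convention used for line-of-therapy ends.

On-disk schema (ISO-8601 dates, one row per claim):

* ``patients.csv``:   patient_id, birth_year, sex
* ``enrollment.csv``: patient_id, start_date, end_date, plan_type
* ``medical.csv``:    patient_id, service_date, end_date, setting,
                      dx1..dx4, proc1..proc4, provider_type, paid_amount
* ``pharmacy.csv``:   patient_id, fill_date, drug_code, days_supply,
                      paid_amount

Diagnosis and procedure codes are carried in memory as a single
``";"``-joined string column (``diagnosis_codes`` / ``procedure_codes``);
the first diagnosis code is the principal one.  Unknown extra columns in
an input CSV are ignored with a warning.  ``service_year`` is derived
from the service/fill date on read and is the key into the CPI table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

try:  # Python >= 3.11
    import tomllib
except ModuleNotFoundError:  # pragma: no cover
    tomllib = None

PLAN_TYPES = ("commercial", "medicare_supplemental", "medicaid")
SETTINGS = ("inpatient", "outpatient", "emergency", "other")

N_DX_COLS = 4
N_PROC_COLS = 4

ENROLLMENT_COLUMNS = ["patient_id", "start_date", "end_date", "plan_type"]
MEDICAL_COLUMNS = (
    ["patient_id", "service_date", "end_date", "setting"]
    + [f"dx{i}" for i in range(1, N_DX_COLS + 1)]
    + [f"proc{i}" for i in range(1, N_PROC_COLS + 1)]
    + ["provider_type", "paid_amount"]
)
PHARMACY_COLUMNS = ["patient_id", "fill_date", "drug_code", "days_supply", "paid_amount"]
PATIENT_COLUMNS = ["patient_id", "birth_year", "sex"]

ANTINEOPLASTIC_CLASSES = frozenset(
    {"egfr_tki", "platinum", "nonplatinum_chemo", "immunotherapy", "other_antineoplastic"}
)
SUPPORTIVE_CATEGORIES = ("pain", "respiratory", "gcsf", "esa", "corticosteroid")


class SchemaError(ValueError):
    """A required column is missing from an input CSV."""


@dataclass
class ValidationIssue:
    file: str
    row: int  # 0-based data-row index within the file
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    def add(self, file: str, row: int, message: str) -> None:
        self.issues.append(ValidationIssue(file, row, message))

    def __len__(self) -> int:
        return len(self.issues)

    def __bool__(self) -> bool:
        return bool(self.issues)


@dataclass
class ClaimsDataset:
    """Patients, enrollment spans, medical claims, and pharmacy claims.

    Every claim's ``patient_id`` must exist in ``patients``; all
    downstream operations are invariant to the ordering of claim rows.
    """

    patients: pd.DataFrame
    enrollment: pd.DataFrame
    medical: pd.DataFrame
    pharmacy: pd.DataFrame
    validation: ValidationReport = field(default_factory=ValidationReport)

    def __post_init__(self) -> None:
        known = set(self.patients["patient_id"])
        for name in ("enrollment", "medical", "pharmacy"):
            df = getattr(self, name)
            extra = set(df["patient_id"]) - known
            if extra:
                raise ValueError(
                    f"{name} contains patient_ids absent from patients table: "
                    f"{sorted(extra)[:5]}"
                )

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def for_patient(self, patient_id) -> "ClaimsDataset":
        return ClaimsDataset(
            patients=self.patients[self.patients.patient_id == patient_id].copy(),
            enrollment=self.enrollment[self.enrollment.patient_id == patient_id].copy(),
            medical=self.medical[self.medical.patient_id == patient_id].copy(),
            pharmacy=self.pharmacy[self.pharmacy.patient_id == patient_id].copy(),
        )


def empty_dataset() -> ClaimsDataset:
    return ClaimsDataset(
        patients=pd.DataFrame(columns=PATIENT_COLUMNS),
        enrollment=pd.DataFrame(columns=ENROLLMENT_COLUMNS),
        medical=pd.DataFrame(
            columns=["patient_id", "service_date", "end_date", "setting",
                     "diagnosis_codes", "procedure_codes", "provider_type",
                     "paid_amount", "service_year"]
        ),
        pharmacy=pd.DataFrame(
            columns=["patient_id", "fill_date", "drug_code", "days_supply",
                     "paid_amount", "service_year"]
        ),
    )


# ---------------------------------------------------------------------------
# Code-set / drug-dictionary configuration
# ---------------------------------------------------------------------------

SCLC_AGENTS = frozenset({"etoposide", "irinotecan", "topotecan"})
EGFR_TKI_AGENTS = frozenset(
    {"gefitinib", "erlotinib", "afatinib", "osimertinib", "dacomitinib"}
)
OSIMERTINIB_APPROVAL_DATE = pd.Timestamp("2018-04-18")

#: default generic-name -> agent-class dictionary.  Supportive classes use a
#: ``supportive:<category>`` label; only ANTINEOPLASTIC_CLASSES agents can
#: start or extend a line of therapy.
DEFAULT_DRUG_DICTIONARY: dict[str, str] = {
    # EGFR tyrosine kinase inhibitors (oral, 30-day fills)
    "gefitinib": "egfr_tki",
    "erlotinib": "egfr_tki",
    "afatinib": "egfr_tki",
    "osimertinib": "egfr_tki",
    "dacomitinib": "egfr_tki",
    # platinum backbone
    "carboplatin": "platinum",
    "cisplatin": "platinum",
    # non-platinum chemotherapy (includes the small-cell agents used as an
    # SCLC exclusion signal)
    "pemetrexed": "nonplatinum_chemo",
    "paclitaxel": "nonplatinum_chemo",
    "docetaxel": "nonplatinum_chemo",
    "gemcitabine": "nonplatinum_chemo",
    "etoposide": "nonplatinum_chemo",
    "irinotecan": "nonplatinum_chemo",
    "topotecan": "nonplatinum_chemo",
    # checkpoint-inhibitor immunotherapy
    "pembrolizumab": "immunotherapy",
    "nivolumab": "immunotherapy",
    "atezolizumab": "immunotherapy",
    "durvalumab": "immunotherapy",
    "ipilimumab": "immunotherapy",
    # other targeted antineoplastics
    "amivantamab": "other_antineoplastic",
    # supportive care
    "oxycodone": "supportive:pain",
    "morphine": "supportive:pain",
    "hydrocodone_acetaminophen": "supportive:pain",
    "fentanyl": "supportive:pain",
    "albuterol": "supportive:respiratory",
    "oxygen_supply": "supportive:respiratory",
    "filgrastim": "supportive:gcsf",
    "pegfilgrastim": "supportive:gcsf",
    "sargramostim": "supportive:gcsf",
    "epoetin_alfa": "supportive:esa",
    "darbepoetin_alfa": "supportive:esa",
    "dexamethasone": "supportive:corticosteroid",
    "prednisone": "supportive:corticosteroid",
    "methylprednisolone": "supportive:corticosteroid",
}


@dataclass
class CodeConfig:
    """Diagnosis/procedure code sets and the drug dictionary.

    Code matching throughout the package is by string prefix (an
    ``ICD-10 C34`` prefix matches ``C3490`` and ``C34.90`` alike after
    dot-stripping).
    """

    lc_diagnosis_codes: tuple[str, ...] = (
        # ICD-9-CM 162.2x-162.9x
        "1622", "1623", "1624", "1625", "1628", "1629",
        # ICD-10-CM C34.x
        "C34",
    )
    metastatic_codes: tuple[str, ...] = (
        "196", "197", "198", "2097",  # ICD-9
        "C77", "C78", "C79", "C7B",   # ICD-10
    )
    #: malignancies other than lung cancer / secondary (metastatic) codes —
    #: ICD-9 140-209 and ICD-10 C00-C96 minus the LC and metastatic sets.
    other_cancer_codes: tuple[str, ...] = tuple(
        [f"{n}" for n in range(140, 210)
         if n not in (162, 196, 197, 198, 209)]
        + [f"C{n:02d}" for n in range(0, 97)
           if n not in (34, 77, 78, 79)]
    )
    brain_metastasis_codes: tuple[str, ...] = ("1983", "C793")
    sclc_agents: frozenset[str] = SCLC_AGENTS
    egfr_tki_agents: frozenset[str] = EGFR_TKI_AGENTS
    drug_dictionary: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_DRUG_DICTIONARY)
    )
    lc_surgery_procedure_codes: tuple[str, ...] = ("32440", "32480", "32505")
    radiotherapy_procedure_codes: tuple[str, ...] = ("774", "7731")
    #: procedure codes flagging drug administration (chemo/IO infusion)
    admin_procedure_codes: tuple[str, ...] = ("chemo_admin", "96413", "96415")
    osimertinib_approval_date: pd.Timestamp = OSIMERTINIB_APPROVAL_DATE

    def __post_init__(self) -> None:
        if isinstance(self.osimertinib_approval_date, str):
            self.osimertinib_approval_date = pd.Timestamp(self.osimertinib_approval_date)
        classes = {}
        for drug, cls in self.drug_dictionary.items():
            classes.setdefault(cls, set()).add(drug)
        # agent classes must be disjoint by construction of a dict; check
        # the antineoplastic/supportive split is well formed instead
        for cls in classes:
            if not (cls in ANTINEOPLASTIC_CLASSES or cls.startswith("supportive:")):
                raise ValueError(f"unknown agent class {cls!r} in drug dictionary")

    # -- helpers -----------------------------------------------------------
    def agent_class(self, drug_code: str) -> str | None:
        return self.drug_dictionary.get(drug_code)

    def is_antineoplastic(self, drug_code: str) -> bool:
        return self.drug_dictionary.get(drug_code) in ANTINEOPLASTIC_CLASSES

    @property
    def antineoplastic_agents(self) -> frozenset[str]:
        return frozenset(
            d for d, c in self.drug_dictionary.items() if c in ANTINEOPLASTIC_CLASSES
        )

    def supportive_agents(self, category: str) -> frozenset[str]:
        key = f"supportive:{category}"
        return frozenset(d for d, c in self.drug_dictionary.items() if c == key)

    @classmethod
    def from_toml(cls, path: str | Path) -> "CodeConfig":
        if tomllib is None:  # pragma: no cover
            raise RuntimeError("tomllib unavailable")
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        kwargs = {}
        for key in ("lc_diagnosis_codes", "metastatic_codes", "other_cancer_codes",
                    "brain_metastasis_codes", "lc_surgery_procedure_codes",
                    "radiotherapy_procedure_codes", "admin_procedure_codes"):
            if key in raw:
                kwargs[key] = tuple(raw[key])
        for key in ("sclc_agents", "egfr_tki_agents"):
            if key in raw:
                kwargs[key] = frozenset(raw[key])
        if "drug_dictionary" in raw:
            kwargs["drug_dictionary"] = dict(raw["drug_dictionary"])
        if "osimertinib_approval_date" in raw:
            kwargs["osimertinib_approval_date"] = pd.Timestamp(raw["osimertinib_approval_date"])
        return cls(**kwargs)


def strip_dots(code: str) -> str:
    return code.replace(".", "")


def code_matches(code: str, prefixes: Iterable[str]) -> bool:
    c = strip_dots(str(code))
    return any(c.startswith(strip_dots(p)) for p in prefixes)


def split_codes(joined) -> list[str]:
    if joined is None or (isinstance(joined, float) and np.isnan(joined)) or joined == "":
        return []
    return [c for c in str(joined).split(";") if c]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _check_columns(df: pd.DataFrame, required: Sequence[str], fname: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{fname}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{fname}: ignoring unknown column(s) {extra}", stacklevel=3)


def _parse_dates(df: pd.DataFrame, cols: Sequence[str], fname: str,
                 report: ValidationReport) -> pd.DataFrame:
    bad = pd.Series(False, index=df.index)
    for col in cols:
        parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
        newly_bad = parsed.isna() & df[col].notna()
        for idx in df.index[newly_bad]:
            report.add(fname, int(idx), f"unparsable date {df.loc[idx, col]!r} in {col}")
        bad |= parsed.isna()
        df[col] = parsed
    return df[~bad].copy()


def read_dataset(enrollment_path: str | Path,
                 medical_path: str | Path,
                 pharmacy_path: str | Path,
                 patients_path: str | Path | None = None) -> ClaimsDataset:
    """Read the four-file CSV schema into a validated :class:`ClaimsDataset`.

    Rows with unparsable dates or non-positive ``days_supply`` are dropped
    and recorded (with row numbers) in ``dataset.validation``.  An empty
    file yields an empty table, not an error.  If ``patients_path`` is not
    given, the patients table is inferred from the ids present in the claim
    tables (demographics missing).
    """
    report = ValidationReport()

    def _read(path, columns):
        path = Path(path)
        if path.stat().st_size == 0:
            return pd.DataFrame(columns=columns)
        df = pd.read_csv(path, dtype={"patient_id": str})
        _check_columns(df, columns, path.name)
        return df[[c for c in columns if c in df.columns]]

    enr = _read(enrollment_path, ENROLLMENT_COLUMNS)
    med = _read(medical_path, MEDICAL_COLUMNS)
    pha = _read(pharmacy_path, PHARMACY_COLUMNS)

    enr = _parse_dates(enr, ["start_date", "end_date"], Path(enrollment_path).name, report)
    med = _parse_dates(med, ["service_date", "end_date"], Path(medical_path).name, report)
    pha = _parse_dates(pha, ["fill_date"], Path(pharmacy_path).name, report)

    # collapse dx/proc slot columns to the ";"-joined in-memory form
    def _join(df, cols):
        vals = df[cols].astype(object).where(df[cols].notna(), None)
        return [";".join(str(v) for v in row if v not in (None, "")) for row in vals.to_numpy()]

    if len(med):
        med["diagnosis_codes"] = _join(med, [f"dx{i}" for i in range(1, N_DX_COLS + 1)])
        med["procedure_codes"] = _join(med, [f"proc{i}" for i in range(1, N_PROC_COLS + 1)])
    else:
        med["diagnosis_codes"] = pd.Series(dtype=object)
        med["procedure_codes"] = pd.Series(dtype=object)
    med = med.drop(columns=[f"dx{i}" for i in range(1, N_DX_COLS + 1) if f"dx{i}" in med]
                   + [f"proc{i}" for i in range(1, N_PROC_COLS + 1) if f"proc{i}" in med])

    if len(pha):
        supply_bad = ~(pd.to_numeric(pha["days_supply"], errors="coerce") >= 1)
        for idx in pha.index[supply_bad]:
            report.add(Path(pharmacy_path).name, int(idx),
                       f"invalid days_supply {pha.loc[idx, 'days_supply']!r}")
        pha = pha[~supply_bad].copy()
        pha["days_supply"] = pha["days_supply"].astype(int)

    med["paid_amount"] = pd.to_numeric(med.get("paid_amount", 0.0), errors="coerce").fillna(0.0)
    pha["paid_amount"] = pd.to_numeric(pha.get("paid_amount", 0.0), errors="coerce").fillna(0.0)
    med["service_year"] = med["service_date"].dt.year if len(med) else pd.Series(dtype="Int64")
    pha["service_year"] = pha["fill_date"].dt.year if len(pha) else pd.Series(dtype="Int64")

    if patients_path is not None and Path(patients_path).exists() \
            and Path(patients_path).stat().st_size > 0:
        pat = pd.read_csv(patients_path, dtype={"patient_id": str})
        _check_columns(pat, PATIENT_COLUMNS, Path(patients_path).name)
        pat = pat[PATIENT_COLUMNS]
    else:
        ids = sorted(set(enr.patient_id) | set(med.patient_id) | set(pha.patient_id))
        pat = pd.DataFrame({"patient_id": ids, "birth_year": pd.NA, "sex": pd.NA})

    ds = ClaimsDataset(patients=pat, enrollment=enr.reset_index(drop=True),
                       medical=med.reset_index(drop=True),
                       pharmacy=pha.reset_index(drop=True))
    ds.validation = report
    return ds


def write_dataset(dataset: ClaimsDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset back to the documented CSV schema; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "patients": out / "patients.csv",
        "enrollment": out / "enrollment.csv",
        "medical": out / "medical.csv",
        "pharmacy": out / "pharmacy.csv",
    }
    dataset.patients.to_csv(paths["patients"], index=False)

    enr = dataset.enrollment.copy()
    for c in ("start_date", "end_date"):
        enr[c] = pd.to_datetime(enr[c]).dt.strftime("%Y-%m-%d")
    enr[ENROLLMENT_COLUMNS].to_csv(paths["enrollment"], index=False)

    med = dataset.medical.copy()
    for c in ("service_date", "end_date"):
        med[c] = pd.to_datetime(med[c]).dt.strftime("%Y-%m-%d")
    for i in range(1, N_DX_COLS + 1):
        med[f"dx{i}"] = [
            (split_codes(s)[i - 1] if len(split_codes(s)) >= i else "")
            for s in med.get("diagnosis_codes", [""] * len(med))
        ]
    for i in range(1, N_PROC_COLS + 1):
        med[f"proc{i}"] = [
            (split_codes(s)[i - 1] if len(split_codes(s)) >= i else "")
            for s in med.get("procedure_codes", [""] * len(med))
        ]
    med[MEDICAL_COLUMNS].to_csv(paths["medical"], index=False)

    pha = dataset.pharmacy.copy()
    pha["fill_date"] = pd.to_datetime(pha["fill_date"]).dt.strftime("%Y-%m-%d")
    pha[PHARMACY_COLUMNS].to_csv(paths["pharmacy"], index=False)
    return paths


def load_dataset(data_dir: str | Path) -> ClaimsDataset:
    """Read a directory written by :func:`write_dataset`."""
    d = Path(data_dir)
    return read_dataset(d / "enrollment.csv", d / "medical.csv", d / "pharmacy.csv",
                        patients_path=d / "patients.csv")


# ---------------------------------------------------------------------------
# Interval utilities
# ---------------------------------------------------------------------------

def normalize_enrollment(spans: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or adjacent enrollment spans for one patient.

    Spans are closed intervals; two spans merge when the second starts on
    or before the day after the first ends.  Output is sorted and disjoint
    and covers exactly the same calendar-day set as the input.
    """
    if len(spans) == 0:
        return spans.copy()
    s = spans.sort_values(["start_date", "end_date"]).reset_index(drop=True)
    merged = []
    cur_start, cur_end = s.loc[0, "start_date"], s.loc[0, "end_date"]
    cur_plan = s.loc[0, "plan_type"] if "plan_type" in s else None
    for _, row in s.iloc[1:].iterrows():
        if row.start_date <= cur_end + pd.Timedelta(days=1):
            cur_end = max(cur_end, row.end_date)
        else:
            merged.append((cur_start, cur_end, cur_plan))
            cur_start, cur_end = row.start_date, row.end_date
            cur_plan = row.plan_type if "plan_type" in s else None
    merged.append((cur_start, cur_end, cur_plan))
    out = pd.DataFrame(merged, columns=["start_date", "end_date", "plan_type"])
    if "patient_id" in spans:
        out.insert(0, "patient_id", spans["patient_id"].iloc[0])
    return out


def build_admissions(inpatient_claims: pd.DataFrame) -> pd.DataFrame:
    """Collapse one patient's inpatient claims into admissions.

    Claims whose closed [service_date, end_date] intervals overlap (share
    at least one day) are merged into a single admission; the admission's
    paid total is the sum over its claims and its day count is
    ``discharge - admit + 1``.
    """
    cols = ["admit_date", "discharge_date", "paid_total", "n_days"]
    if len(inpatient_claims) == 0:
        return pd.DataFrame(columns=cols)
    c = inpatient_claims.sort_values(["service_date", "end_date"]).reset_index(drop=True)
    rows = []
    a_start = c.loc[0, "service_date"]
    a_end = c.loc[0, "end_date"]
    paid = float(c.loc[0, "paid_amount"])
    for _, row in c.iloc[1:].iterrows():
        if row.service_date <= a_end:  # overlap or abutting on the same day
            a_end = max(a_end, row.end_date)
            paid += float(row.paid_amount)
        else:
            rows.append((a_start, a_end, paid, (a_end - a_start).days + 1))
            a_start, a_end, paid = row.service_date, row.end_date, float(row.paid_amount)
    rows.append((a_start, a_end, paid, (a_end - a_start).days + 1))
    return pd.DataFrame(rows, columns=cols)
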