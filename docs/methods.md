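# Methods

This note documents the models, conventions, and design choices behind
`claimlines`, and what the synthetic-data tests do and do not establish
about real claims data.

## Data model and conventions

All calendar intervals are closed (`[start, end]`, both days included).
Enrollment spans are normalized by merging overlaps and abutting spans;
"continuous eligibility" is strict by default, with an optional
`eligibility_bridge_days` parameter to bridge short uncovered gaps
(default 0, because the stricter reading is the conservative one and the
data source's enrollment files are monthly).

Diagnosis and procedure codes are matched by dot-stripped string prefix.
Drug identity is the generic-name key of a configurable drug dictionary
mapping each agent to a class (`egfr_tki`, `platinum`,
`nonplatinum_chemo`, `immunotherapy`, `other_antineoplastic`, or a
`supportive:*` category). Only antineoplastic classes can start or extend
a line of therapy; supportive agents (opioids, corticosteroids, G-CSF,
ESAs, respiratory agents) never do. Infused agents are recognised by
their agent keys among a medical claim's procedure codes together with an
administration code; a production claims feed would carry HCPCS J-codes,
which the dictionary abstracts over — users substitute their own mapping
via `CodeConfig.from_toml`.

Overlapping inpatient claims (sharing at least one calendar day) merge
into one admission; an emergency-department claim dated inside an
admission is counted as inpatient (days and dollars), not ED. Admissions
are attributed to the line containing their admitting claim's service
date. These are declared conventions — claims sources do not state them.

## Cohort selection

The proxy algorithm applies, in order: (1) ≥2 lung-cancer diagnoses on
distinct service dates within one continuous-eligibility period; (2)
exclusion of small-cell disease, operationalised as an SCLC agent
(etoposide/irinotecan/topotecan) inside the preliminary first-line
regimen window; (3) ≥365 days of eligibility before the first LC
diagnosis (washout, so the diagnosis is incident); (4) advanced disease —
a guideline-regimen first line, or a metastatic diagnosis within 30 days
(inclusive) of the first LC diagnosis followed eventually by first-line
initiation within the observation window; (5) an EGFR-TKI initiation
on/after 2018-04-18 (index date; proxy for EGFR Ex19del/L858R status);
(6) no other-cancer diagnosis before the first LC diagnosis (default
other-cancer set: ICD-9 140–209 / ICD-10 C00–C96 minus the LC and
secondary-malignancy codes; configurable); (7) among patients without the
30-day metastatic qualifier, no LC-related surgery before index
(early-stage surrogate). "Within 30 days" and "within 21 days" windows
include the boundary day; fixtures pin day 30 vs 31 and day 21 vs 22.

The requirement that the ≥2 diagnoses fall on distinct service dates is
an assumption (a single visit can emit multiple rows); it is pinned by a
fixture and easy to relax. Age is computed as first-line year minus birth
year, since claims carry birth year only.

## Line-of-therapy engine

A line starts at the first qualifying antineoplastic claim (for 1L, the
first after the first LC diagnosis). Agents first observed within 21 days
of the line start — one cycle of common regimens — join the regimen,
including agents added on day 21 itself. The line ends at the earliest
of:

- the day before initiation of an antineoplastic not in the regimen
  (`new_agent`);
- the day before a regimen agent's claim arriving after a >90-day gap in
  exposure (`retreatment_gap`), where exposure runs to the latest
  `fill_date + days_supply − 1` of the regimen's oral agents or the
  latest service date of its infused agents, and the gap is counted in
  whole uncovered days (a claim the day after coverage ends is a 0-day
  gap: a 90-day gap never splits a line, a 91-day gap always does);
- the end of observation (`end_of_observation`). A line cannot end by
  discontinuation alone: with no further antineoplastic claims it runs to
  the end of observation.

Same-date claims are processed as one batch, so results are invariant to
input row order; when a batch contains both a new agent and a regimen
agent, the new-agent rule takes precedence. The gap reference (supply end
vs claim date) matters for oral agents — measuring claim-to-claim would
make every 30-day refill cycle look like a near-gap — and supply-end is
the declared convention. The engine is verified exactly against an
independent day-by-day simulator on all fixtures and 1,000 random claim
streams per test run.

## Outcomes

PPPM rates divide by the line length in 30.4375-day months (365.25/12),
the standard average month; the baseline window uses a fixed 12-month
denominator. Costs are payer-paid amounts inflated to 2022 US dollars by
`deflator(service_year)` from a CPI table; the packaged defaults are
derived from annual medical-care CPI averages and are expected to be
replaced with the user's exact series (the table anchors at
deflator(2022) = 1). Outpatient costs are split into antineoplastic
drug + administration versus other by the drug dictionary plus an
administration-procedure list; `setting="other"` claims are grouped with
ED costs. Component additivity (total = medical + pharmacy; medical =
inpatient + outpatient + ED/other; outpatient = antineoplastic + other)
is asserted per patient-line at 1e-6 relative tolerance.

The comorbidity index uses Quan's ICD-9/10 condition mappings with the
original Charlson weights, shipped as a data file so Quan-2011 weights
can be swapped in. Prefix lists approximate a few range-defined Quan
categories; hierarchy rules (metastatic over any malignancy, severe over
mild liver disease, complicated over uncomplicated diabetes) are applied
within groups.

## Reporting

The design is descriptive: no confounder adjustment, no multiplicity
control. Mean differences carry Welch (unpooled-variance) intervals with
a normal critical value by default and a t option with Welch–Satterthwaite
degrees of freedom; LOT groups are treated as independent even though
patients overlap across lines, matching how such tables are
conventionally presented. Rounding follows table conventions: costs to
whole dollars, rates to two decimals, percentages to one.

## Synthetic data generator

The generator emits per-patient enrollment spans (occasionally split into
abutting rows to exercise normalization), ICD-10-coded point medical
claims, 30-day-supply pharmacy fills for oral TKIs, 21-day-cycle
outpatient infusion claims, Poisson background HRU (outpatient, inpatient
with length-of-stay, ED), and log-normal per-event costs whose sums
reproduce the heavy right skew (mean ≫ median) typical of claims costs.
Default parameters target the magnitudes of a contemporary US
EGFR-mutated advanced NSCLC population — ~68% 1L osimertinib monotherapy,
42% progression to 2L (50% of those to 3L), ~90% with a metastatic code
within 30 days of diagnosis, class-specific visit rates (platinum doublets
~7.5 outpatient days/month vs ~3 for oral monotherapy) — without being
calibrated to reproduce any particular published table, which would be
impossible without the proprietary source data.

Every patient carries a scenario label: fully eligible, or a decoy
violating exactly one selection filter (single diagnosis, SCLC agents,
short washout, non-advanced, metastatic-but-untreated, pre-approval TKI
only, prior other cancer, early-stage surgery). Decoys that must survive
the TKI filter to reach "their" exclusion step are forced to include a
TKI line. Ground truth records per-filter eligibility and the true line
intervals/regimens/classes, truncated at the observation cut
(min(enrollment end, data end)).

Two noise knobs exist: `prob_retreatment_gap` inserts a >90-day gap and
resumption of the final regimen (truth-consistent — the truth contains
the split), and `prob_non_regimen_decoy_claim` injects a stray
antineoplastic claim mid-line (truth-breaking by design — recovery under
it is only approximate). Dropout is censoring only — an exponential tail
(mean `1/enrollment_dropout_hazard` months, capped at 24) after the last
treated day; death is not simulated because the emulated data source
lacks mortality.

What passing the recovery tests shows: the selection and line rules are
implemented exactly as specified, because an independent construction of
histories satisfying/violating each rule is recovered without
discrepancy. What it does not show: robustness to the messiness of real
claims — reversals and adjustments, J-code granularity, interim bills,
overlapping payers, coding errors — which the generator deliberately does
not model.

## Test and acceptance problem sizes

The suite runs the exact-recovery check on a 500-patient noise-free
cohort, the parameter-recovery check on 2,000 patients, the engine-vs-
simulator comparison on 1,000 random streams, and interval coverage on
1,000 replicates of n=200 groups. For the progression-recovery check the
first-line mix is all-osimertinib and the data-end date is pushed past
every simulated timeline: with mixed first lines the TKI inclusion filter
is correlated with progression (patients on 1L chemotherapy enter the
cohort only if they progress to a TKI — the same selection artifact that
makes every 1L-chemotherapy patient in such studies a progressor), and
administrative censoring otherwise truncates late second lines; both
would bias the observed share away from the configured probability for
reasons that are properties of the study design, not of the estimator.
The acceptance script uses 600 patients under the default (mildly noisy)
configuration.

## Known limitations

- Regimen identity is exact agent-set equality at the claim level;
  maintenance phases, dose changes, and adherence are out of scope.
- The SCLC exclusion inspects the preliminary 1L window only.
- The "other costs" bucket routes `setting="other"` claims with ED; the
  underlying source's grouping is not published.
- The shipped drug dictionary covers the named agents plus common
  partners; it stands in for a full guideline regimen list, which users
  should supply for production use.
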