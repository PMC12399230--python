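"""Independent oracles used by the test suite.

These deliberately re-derive expected results by different means than
the library (literal day-by-day simulation, explicit rule tables,
day-set unions) so that agreement is evidence, not tautology.
"""

import numpy as np
import pandas as pd

from claimlines.lot_engine import TreatmentEpisode

ONE_DAY = pd.Timedelta(days=1)


def brute_force_lines(episodes, first_dx, obs_end):
    """Literal day-by-day application of the three line-ending rules.

    Returns [(start, end, frozenset(regimen), end_reason), ...].
    """
    eps = [e for e in episodes if first_dx <= e.start_date <= obs_end]
    claims = {}
    for e in eps:
        claims.setdefault(e.start_date, []).append(e)
    if not claims:
        return []
    dates = sorted(claims)
    lines = []
    t = dates[0]
    while t is not None:
        start = t
        window_end = start + pd.Timedelta(days=21)
        regimen, exposure = set(), start
        for d in dates:
            if start <= d <= window_end:
                for e in claims[d]:
                    regimen.add(e.agent)
                    exposure = max(exposure, e.supply_end_date)
        end = reason = t_next = None
        d = window_end + ONE_DAY
        while d <= obs_end:
            if d in claims:
                agents = {e.agent for e in claims[d]}
                if agents - regimen:
                    end, reason, t_next = d - ONE_DAY, "new_agent", d
                    break
                if (d - exposure).days - 1 > 90:
                    end, reason, t_next = d - ONE_DAY, "retreatment_gap", d
                    break
                for e in claims[d]:
                    exposure = max(exposure, e.supply_end_date)
            d += ONE_DAY
        if end is None:
            end, reason = obs_end, "end_of_observation"
        lines.append((start, min(end, obs_end), frozenset(regimen), reason))
        t = t_next
    return lines


AGENT_POOL = ("osimertinib", "erlotinib", "carboplatin", "pemetrexed",
              "pembrolizumab", "docetaxel")


def random_episode_stream(rng: np.random.Generator, max_claims: int = 20):
    """A random small antineoplastic claim stream for oracle comparison."""
    t0 = pd.Timestamp("2019-01-01")
    horizon = int(rng.integers(120, 420))
    n = int(rng.integers(1, max_claims + 1))
    episodes = []
    for _ in range(n):
        off = int(rng.integers(0, horizon))
        supply = int(rng.choice([1, 7, 14, 30]))
        agent = str(rng.choice(AGENT_POOL))
        start = t0 + pd.Timedelta(days=off)
        episodes.append(TreatmentEpisode(
            "PX", agent, start, start + pd.Timedelta(days=supply - 1), "pharmacy"))
    obs_end = t0 + pd.Timedelta(days=horizon + int(rng.integers(0, 120)))
    return episodes, t0, obs_end


# explicit rule table for regimen classification
_TKI = {"gefitinib", "erlotinib", "afatinib", "osimertinib", "dacomitinib"}
_PLATINUM = {"carboplatin", "cisplatin"}
_IO = {"pembrolizumab", "nivolumab", "atezolizumab", "durvalumab", "ipilimumab"}
_CHEMO = {"pemetrexed", "paclitaxel", "docetaxel", "gemcitabine", "etoposide",
          "irinotecan", "topotecan", "amivantamab"}


def rule_table_class(regimen) -> str:
    r = set(regimen)
    if "osimertinib" in r:
        return "osimertinib_based"
    if r & _TKI:
        return "other_egfr_tki"
    if r & _PLATINUM:
        return "pbc_regimen"
    if r and r <= _IO:
        return "io_mono"
    if r & _CHEMO:
        return "other_chemo"
    return "other"


def day_set(intervals) -> set:
    """All covered days of a list of closed (start, end) intervals."""
    out = set()
    for s, e in intervals:
        d = s
        while d <= e:
            out.add(d)
            d += ONE_DAY
    return out


def quan_oracle(dx_codes, csv_path) -> int:
    """Condition-by-condition enumeration straight off the mapping file."""
    table = pd.read_csv(csv_path)
    stripped = [str(c).replace(".", "") for c in dx_codes]
    hits = []
    for row in table.itertuples():
        prefixes = [p for p in (str(row.icd9_prefixes).split("|")
                                + str(row.icd10_prefixes).split("|"))
                    if p and p != "nan"]
        if any(code.startswith(p.replace(".", "")) for code in stripped
               for p in prefixes):
            group = row.hierarchy_group if isinstance(row.hierarchy_group, str) else None
            hits.append((row.condition, int(row.weight), group))
    total = 0
    for name, weight, group in hits:
        if group is not None:
            best = max(w for _, w, g in hits if g == group)
            if weight < best:
                continue
        total += weight
    return total
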