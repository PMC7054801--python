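"""Eligibility, follow-up cohort construction, person-time, incidence, and
nested case-control sampling.

Follow-up runs from baseline (2010-01-01) to the earliest of PD diagnosis,
death, first excluded-diagnosis date, or administrative end of follow-up
(2014-12-31).  Ties are broken with precedence
``censored_excluded_dx > pd > death > admin_end``; in particular a PD code
on the date of death counts as a PD event.  Follow-up years are exact day
counts divided by 365.25.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .claims_data import STUDY_YEARS

__all__ = [
    "BASELINE",
    "FOLLOW_UP_END",
    "EVENT_TYPES",
    "EligibilityDecision",
    "assess_eligibility",
    "assess_eligibility_frame",
    "build_cohort",
    "person_years",
    "incidence_rate",
    "sample_nested_case_control",
]

BASELINE = pd.Timestamp("2010-01-01")
FOLLOW_UP_END = pd.Timestamp("2014-12-31")
EVENT_TYPES = ("pd", "death", "censored_excluded_dx", "admin_end")

#: Minimum age at the eligibility evaluation date: 66 years, 11 months,
#: guaranteeing at least two full claim-years of look-back.
MIN_AGE_YEARS = 66 + 11 / 12
#: Beneficiaries aged <=90 are eligible; the 91st birthday disqualifies.
MAX_AGE_EXCLUSIVE = 91.0
DAYS_PER_YEAR = 365.25


class CohortError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class EligibilityDecision:
    beneficiary_id: str
    eligible: bool
    reasons: tuple[str, ...]


def _age_years(birth: pd.Series | pd.Timestamp, at: pd.Timestamp):
    birth = pd.to_datetime(birth)
    if isinstance(birth, pd.Timestamp):
        return (at - birth).days / DAYS_PER_YEAR
    return (at - birth).dt.days / DAYS_PER_YEAR


def assess_eligibility_frame(
    base: pd.DataFrame,
    pd_statuses: pd.DataFrame,
    reference_year: int = 2009,
) -> pd.DataFrame:
    """Vectorized eligibility over a base file.

    Age is evaluated at December 31 of ``reference_year``: eligible ages
    span [66 years 11 months, 91 years).  Further requirements: U.S.
    residence, Part A/B coverage with no non-Medicare coverage in the
    reference year, alive at the start of follow-up (January 1 of the
    following year), and no PD diagnosis on or before baseline.

    Returns the base frame's ids with ``eligible`` and a semicolon-joined
    ``reasons`` column.
    """
    if reference_year not in STUDY_YEARS:
        raise CohortError(
            f"no coverage data for reference year {reference_year}; have {STUDY_YEARS}"
        )
    eval_date = pd.Timestamp(reference_year, 12, 31)
    baseline = pd.Timestamp(reference_year + 1, 1, 1)
    age = _age_years(base["birth_date"], eval_date)

    status = pd_statuses.set_index("beneficiary_id")
    dx = pd.to_datetime(
        status["diagnosis_date"].reindex(base["beneficiary_id"]).to_numpy()
    )
    prior_pd = pd.Series(dx <= baseline, index=base.index).fillna(False)

    death = pd.to_datetime(base["death_date"])
    reasons = {
        "under_age": age < MIN_AGE_YEARS,
        "over_age": age >= MAX_AGE_EXCLUSIVE,
        "not_us_resident": ~base["us_residence"].astype(bool),
        "no_part_ab": ~base[f"part_ab_{reference_year}"].astype(bool),
        "non_medicare_coverage": base[f"non_medicare_{reference_year}"].astype(bool),
        "not_alive_at_baseline": death.notna() & (death < baseline),
        "prior_pd": prior_pd,
    }
    reason_df = pd.DataFrame(reasons)
    eligible = ~reason_df.any(axis=1)
    joined = reason_df.apply(lambda r: ";".join(reason_df.columns[r.to_numpy()]), axis=1)
    return pd.DataFrame(
        {
            "beneficiary_id": base["beneficiary_id"],
            "eligible": eligible,
            "reasons": joined,
            "baseline_age": _age_years(base["birth_date"], baseline),
        }
    )


def assess_eligibility(beneficiary, pd_status, reference_year: int = 2009) -> EligibilityDecision:
    """Single-record eligibility decision (see :func:`assess_eligibility_frame`)."""
    cov_years = set(beneficiary.part_ab_coverage) & set(beneficiary.non_medicare_coverage)
    if reference_year not in cov_years:
        raise CohortError(f"missing coverage data for reference year {reference_year}")
    eval_date = pd.Timestamp(reference_year, 12, 31)
    baseline = pd.Timestamp(reference_year + 1, 1, 1)
    age = _age_years(pd.Timestamp(beneficiary.birth_date), eval_date)
    reasons = []
    if age < MIN_AGE_YEARS:
        reasons.append("under_age")
    if age >= MAX_AGE_EXCLUSIVE:
        reasons.append("over_age")
    if not beneficiary.us_residence:
        reasons.append("not_us_resident")
    if not beneficiary.part_ab_coverage[reference_year]:
        reasons.append("no_part_ab")
    if beneficiary.non_medicare_coverage[reference_year]:
        reasons.append("non_medicare_coverage")
    if beneficiary.death_date is not None and pd.Timestamp(beneficiary.death_date) < baseline:
        reasons.append("not_alive_at_baseline")
    if (
        pd_status is not None
        and pd_status.diagnosis_date is not None
        and pd.Timestamp(pd_status.diagnosis_date) <= baseline
    ):
        reasons.append("prior_pd")
    return EligibilityDecision(beneficiary.beneficiary_id, not reasons, tuple(reasons))


def build_cohort(
    base: pd.DataFrame,
    pd_statuses: pd.DataFrame,
    entry: pd.Timestamp = BASELINE,
    end: pd.Timestamp = FOLLOW_UP_END,
) -> pd.DataFrame:
    """Follow-up rows for the (already eligibility-screened) beneficiaries.

    Exit is the earliest of PD diagnosis (cases only), death, first
    excluded-diagnosis date, and the administrative end; the event label
    records which minimum applied under the documented tie precedence.
    """
    status = pd_statuses.set_index("beneficiary_id")
    ids = base["beneficiary_id"]
    dx = pd.to_datetime(pd.Series(
        status["diagnosis_date"].reindex(ids).to_numpy(), index=base.index))
    is_case = pd.Series(
        status["is_case"].reindex(ids, fill_value=False).to_numpy(), index=base.index
    ).astype(bool)
    dx = dx.where(is_case)
    excl = pd.to_datetime(pd.Series(
        status["first_exclusion_date"].reindex(ids).to_numpy(), index=base.index))
    death = pd.to_datetime(base["death_date"]).reset_index(drop=True)
    death.index = base.index

    if (dx.notna() & (dx <= entry)).any():
        bad = ids[(dx.notna() & (dx <= entry)).to_numpy()].tolist()
        raise CohortError(
            f"PD diagnosis on or before cohort entry for supposedly eligible "
            f"beneficiaries: {bad[:5]}"
        )

    admin = pd.Series(end, index=base.index)
    # Candidates in tie-precedence order: excluded dx > pd > death > admin.
    cand = pd.DataFrame({
        "censored_excluded_dx": excl.clip(lower=entry),
        "pd": dx,
        "death": death,
        "admin_end": admin,
    })
    exit_date = cand.min(axis=1)
    event = cand.le(exit_date, axis=0).idxmax(axis=1)

    follow_up = (exit_date - entry).dt.days / DAYS_PER_YEAR
    out = pd.DataFrame(
        {
            "beneficiary_id": ids.to_numpy(),
            "entry_date": entry,
            "exit_date": exit_date,
            "event": event,
            "baseline_age": _age_years(base["birth_date"], entry).to_numpy(),
            "follow_up_years": follow_up,
        }
    )
    if (out["exit_date"] < out["entry_date"]).any():
        raise CohortError("exit_date precedes entry_date")
    return out


def person_years(cohort: pd.DataFrame) -> float:
    """Total person-years at risk: the sum of per-row follow-up years."""
    return float(cohort["follow_up_years"].sum())


def incidence_rate(n_events: int, person_years: float) -> float:
    """Incidence per 100,000 person-years: ``1e5 * n_events / person_years``."""
    if person_years <= 0:
        raise CohortError("person_years must be positive")
    if n_events < 0:
        raise CohortError("n_events must be non-negative")
    return 1e5 * n_events / person_years


def sample_nested_case_control(cohort: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Incidence-density nested case-control sample from a cohort.

    Every PD event becomes a case with its diagnosis date as reference
    date.  Every noncase is assigned a random reference date drawn from
    the empirical distribution of case diagnosis dates (uniform over
    follow-up when the cohort has no cases); noncases who did not survive
    at risk to their assigned date are dropped, so all controls were alive
    and uncensored at their reference date.  Reproducible for fixed seed.
    """
    rng = np.random.default_rng(seed)
    cohort = cohort.sort_values("beneficiary_id", kind="mergesort").reset_index(drop=True)
    is_case = cohort["event"] == "pd"
    cases = cohort[is_case]
    noncases = cohort[~is_case]

    if len(cases):
        ref = pd.to_datetime(
            rng.choice(pd.to_datetime(cases["exit_date"]).to_numpy(), size=len(noncases))
        )
    else:
        entry = pd.to_datetime(noncases["entry_date"]).to_numpy()
        span_days = (FOLLOW_UP_END - BASELINE).days
        offs = rng.integers(1, span_days + 1, size=len(noncases))
        ref = pd.to_datetime(entry) + pd.to_timedelta(offs, unit="D")

    surv = pd.to_datetime(noncases["exit_date"]).to_numpy() >= ref.to_numpy()
    controls = pd.DataFrame(
        {
            "beneficiary_id": noncases["beneficiary_id"].to_numpy()[surv],
            "is_case": False,
            "reference_date": ref[surv],
        }
    )
    case_rows = pd.DataFrame(
        {
            "beneficiary_id": cases["beneficiary_id"].to_numpy(),
            "is_case": True,
            "reference_date": pd.to_datetime(cases["exit_date"]).to_numpy(),
        }
    )
    out = pd.concat([case_rows, controls], ignore_index=True)
    return out.sort_values(["is_case", "beneficiary_id"], ascending=[False, True],
                           kind="mergesort").reset_index(drop=True)
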