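"""Rule-based Parkinson disease case ascertainment from claims.

A beneficiary is a PD case when they carry at least one ICD-9 332 / 332.0
diagnosis code and none of the disqualifying patterns:

* Lewy body dementia (ICD-9 331.82);
* other extrapyramidal disease / abnormal movement disorders (ICD-9 333
  or 333.0);
* probable typographic error: nonpyogenic meningitis (ICD-9 322 or 322.0)
  anywhere in the record without a diagnostic lumbar puncture (CPT 62270).

The diagnosis date is the earliest PD code; the neurologist flag records
whether any PD code came from a neurologist.  Exclusion codes anywhere in
the record (any date) disqualify the case label; the survival stage
separately censors at the first excluded-diagnosis date, for which
``first_exclusion_date`` is exported.
"""

from __future__ import annotations

import dataclasses
import datetime

import numpy as np
import pandas as pd

from .claims_data import NEUROLOGY_SPECIALTY

__all__ = [
    "PD_CODES",
    "LEWY_BODY_CODES",
    "EXTRAPYRAMIDAL_CODES",
    "MENINGITIS_CODES",
    "LUMBAR_PUNCTURE_CPT",
    "EXCLUSION_REASONS",
    "QUALITY_MODES",
    "PDStatus",
    "classify_pd",
    "ascertain_all",
    "case_quality_filter",
]

PD_CODES = frozenset({"332", "3320"})
LEWY_BODY_CODES = frozenset({"33182"})
EXTRAPYRAMIDAL_CODES = frozenset({"333", "3330"})
MENINGITIS_CODES = frozenset({"322", "3220"})
LUMBAR_PUNCTURE_CPT = "62270"

EXCLUSION_REASONS = ("none", "lewy_body", "extrapyramidal", "typographic_error")
QUALITY_MODES = ("any", "neurologist", "two_codes")


@dataclasses.dataclass(frozen=True)
class PDStatus:
    """Ascertainment outcome for one beneficiary."""

    beneficiary_id: str
    is_case: bool
    diagnosis_date: datetime.date | None
    n_pd_codes: int
    neurologist_flag: bool
    exclusion_reason: str
    first_exclusion_date: datetime.date | None = None

    def __post_init__(self) -> None:
        if self.is_case and (self.diagnosis_date is None or self.n_pd_codes < 1):
            raise ValueError("a case must have a diagnosis date and >=1 PD code")
        if self.exclusion_reason != "none" and self.is_case:
            raise ValueError("an excluded beneficiary cannot be a case")


def _exclusion(dx_codes: set[str], cpt_codes: set[str]) -> str:
    """Exclusion reason from code sets; precedence lewy > extrapyramidal > typo."""
    if dx_codes & LEWY_BODY_CODES:
        return "lewy_body"
    if dx_codes & EXTRAPYRAMIDAL_CODES:
        return "extrapyramidal"
    if (dx_codes & MENINGITIS_CODES) and LUMBAR_PUNCTURE_CPT not in cpt_codes:
        return "typographic_error"
    return "none"


def classify_pd(events: pd.DataFrame, beneficiary_id: str | None = None) -> PDStatus:
    """Classify one beneficiary's claims; order-invariant in the events.

    ``events`` must hold claims of a single beneficiary with normalized
    codes.  An empty frame is a valid non-case.
    """
    if len(events) and beneficiary_id is None:
        ids = events["beneficiary_id"].unique()
        if len(ids) > 1:
            raise ValueError(f"events span multiple beneficiaries: {ids[:3]}")
        beneficiary_id = ids[0]
    beneficiary_id = beneficiary_id or ""
    if len(events) == 0:
        return PDStatus(beneficiary_id, False, None, 0, False, "none", None)

    is_dx = events["code_system"] == "ICD9_DX"
    dx_codes = set(events.loc[is_dx, "code"])
    cpt_codes = set(events.loc[events["code_system"] == "CPT", "code"])
    pd_mask = is_dx & events["code"].isin(PD_CODES)
    n_pd = int(pd_mask.sum())

    reason = _exclusion(dx_codes, cpt_codes)

    excl_mask = is_dx & events["code"].isin(
        LEWY_BODY_CODES | EXTRAPYRAMIDAL_CODES
        | (MENINGITIS_CODES if reason == "typographic_error" else frozenset())
    )
    first_excl = (
        pd.to_datetime(events.loc[excl_mask, "service_date"]).min()
        if reason != "none"
        else None
    )

    if n_pd == 0 or reason != "none":
        return PDStatus(
            beneficiary_id, False, None, n_pd, False, reason,
            None if first_excl is None or pd.isna(first_excl) else first_excl.date(),
        )

    pd_events = events.loc[pd_mask]
    dx_date = pd.to_datetime(pd_events["service_date"]).min().date()
    neuro = bool(
        pd_events["provider_specialty"].fillna("").eq(NEUROLOGY_SPECIALTY).any()
    )
    return PDStatus(beneficiary_id, True, dx_date, n_pd, neuro, "none", None)


def ascertain_all(claims: pd.DataFrame, beneficiary_ids=None) -> pd.DataFrame:
    """Vectorized ascertainment over a full claims table.

    Returns one row per beneficiary (all of ``beneficiary_ids`` when given,
    else every id appearing in ``claims``) with columns ``beneficiary_id,
    is_case, diagnosis_date, n_pd_codes, neurologist_flag,
    exclusion_reason, first_exclusion_date``.
    """
    c = claims
    is_dx = (c["code_system"] == "ICD9_DX").to_numpy()
    code = c["code"].to_numpy()
    bene = c["beneficiary_id"].to_numpy()
    dates = pd.to_datetime(c["service_date"]).to_numpy()

    def _agg_any(mask: np.ndarray) -> pd.Series:
        return pd.Series(mask, index=bene).groupby(level=0).any()

    pd_mask = is_dx & np.isin(code, list(PD_CODES))
    lewy = _agg_any(is_dx & np.isin(code, list(LEWY_BODY_CODES)))
    extrap = _agg_any(is_dx & np.isin(code, list(EXTRAPYRAMIDAL_CODES)))
    mening = _agg_any(is_dx & np.isin(code, list(MENINGITIS_CODES)))
    lp = _agg_any((~is_dx) & (c["code_system"] == "CPT").to_numpy() & (code == LUMBAR_PUNCTURE_CPT))

    index = (
        pd.Index(sorted(set(beneficiary_ids)), name="beneficiary_id")
        if beneficiary_ids is not None
        else lewy.index.union(pd.Index(np.unique(bene)))
    )
    lewy = lewy.reindex(index, fill_value=False)
    extrap = extrap.reindex(index, fill_value=False)
    typo = (mening.reindex(index, fill_value=False)
            & ~lp.reindex(index, fill_value=False))

    reason = pd.Series("none", index=index, dtype=object)
    reason[typo] = "typographic_error"
    reason[extrap.reindex(index, fill_value=False)] = "extrapyramidal"
    reason[lewy] = "lewy_body"

    n_pd = (
        pd.Series(pd_mask.astype(np.int64), index=bene)
        .groupby(level=0).sum().reindex(index, fill_value=0)
    )
    pd_dates = pd.Series(dates, index=bene).where(pd.Series(pd_mask, index=bene))
    first_pd = pd_dates.groupby(level=0).min().reindex(index)

    neuro_mask = pd_mask & c["provider_specialty"].fillna("").eq(NEUROLOGY_SPECIALTY).to_numpy()
    neuro = _agg_any(neuro_mask).reindex(index, fill_value=False)

    excl_code_mask = is_dx & (
        np.isin(code, list(LEWY_BODY_CODES | EXTRAPYRAMIDAL_CODES))
        | (np.isin(code, list(MENINGITIS_CODES))
           & typo.reindex(pd.Index(bene)).fillna(False).to_numpy())
    )
    first_excl = (
        pd.Series(dates, index=bene)
        .where(pd.Series(excl_code_mask, index=bene))
        .groupby(level=0).min().reindex(index)
    )
    first_excl[reason == "none"] = pd.NaT

    is_case = (n_pd >= 1) & (reason == "none")
    out = pd.DataFrame(
        {
            "is_case": is_case,
            "diagnosis_date": first_pd.where(is_case),
            "n_pd_codes": n_pd,
            "neurologist_flag": neuro & is_case,
            "exclusion_reason": reason,
            "first_exclusion_date": first_excl,
        },
        index=index,
    ).reset_index()
    return out


def case_quality_filter(statuses: pd.DataFrame, mode: str = "any") -> pd.DataFrame:
    """Restrict the ascertained cases by case-quality criterion.

    ``any`` keeps all cases; ``neurologist`` keeps cases with >=1 PD code
    from a neurologist; ``two_codes`` keeps cases with >=2 PD codes.
    Non-cases never pass.
    """
    if mode not in QUALITY_MODES:
        raise ValueError(f"unknown quality mode {mode!r}; expected one of {QUALITY_MODES}")
    cases = statuses[statuses["is_case"]]
    if mode == "neurologist":
        cases = cases[cases["neurologist_flag"]]
    elif mode == "two_codes":
        cases = cases[cases["n_pd_codes"] >= 2]
    return cases.reset_index(drop=True)
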