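"""Predictor computation from claims within an observation window.

Predictors mirror the code-based risk model: two linear age splines with a
knot at 85, sex, race/ethnicity (7 categories, white reference, "unknown"
folded into Pacific Islander / other), a predicted probability of ever
smoking, the count of unique ICD-9 diagnosis codes, and a binary indicator
per configured (code, code_system) pair.

Windows are half-open ``(start, end]``: a claim contributes iff
``start < service_date <= end``.  The unlagged configuration ends the
window at each person's reference date; the lagged configuration ends it
at 2009-12-31 regardless of reference date, so only pre-baseline codes
contribute.  PD-definition codes (ICD-9 332/332.0) define the outcome
label and are excluded from every predictor, including the unique-code
count.

Smoking rule: anyone with a tobacco-specific code in the window gets
probability 1.0; everyone else gets the inverse logit of a configurable
logistic smoking model evaluated on their demographics and code
indicators.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .ascertainment import PD_CODES
from .claims_data import CodeList
from .scoring import (
    CoefficientSet,
    DEMOGRAPHIC_TERMS,
    ScoringError,
    linear_predictor_frame,
    predicted_probability,
)

__all__ = [
    "CLAIMS_START",
    "LAG_END",
    "DEFAULT_TOBACCO_CODES",
    "Window",
    "reference_window",
    "lagged_window",
    "age_splines",
    "smoking_probability",
    "smoking_index",
    "count_unique_dx",
    "extract_features",
    "score_sample",
]

CLAIMS_START = pd.Timestamp("2004-01-01")
LAG_END = pd.Timestamp("2009-12-31")
DAYS_PER_YEAR = 365.25

#: Tobacco-specific codes forcing smoking probability to 1.0 (ICD-9
#: V15.82 history of tobacco use; 305.1 tobacco use disorder and children).
DEFAULT_TOBACCO_CODES = CodeList(
    [
        ("V1582", "ICD9_DX", "history of tobacco use"),
        ("3051", "ICD9_DX", "tobacco use disorder"),
        ("30510", "ICD9_DX", "tobacco use disorder, unspecified"),
        ("30511", "ICD9_DX", "tobacco use disorder, continuous"),
        ("30512", "ICD9_DX", "tobacco use disorder, episodic"),
        ("30513", "ICD9_DX", "tobacco use disorder, in remission"),
    ],
    label="tobacco-specific codes",
)

RACE_TERM = {
    "white": None,  # reference
    "black": "race:black",
    "asian": "race:asian",
    "hispanic": "race:hispanic",
    "native_american": "race:native_american",
    "pacific_islander_other": "race:pacific_islander_other",
    "unknown": "race:pacific_islander_other",  # folded
}


@dataclasses.dataclass(frozen=True)
class Window:
    """Half-open observation window ``(start_exclusive, end_inclusive]``."""

    start_exclusive: pd.Timestamp
    end_inclusive: pd.Timestamp

    def __post_init__(self) -> None:
        if self.end_inclusive <= self.start_exclusive:
            raise ValueError("window end must be after start")

    def contains(self, dates) -> np.ndarray:
        d = pd.to_datetime(dates)
        return ((d > self.start_exclusive) & (d <= self.end_inclusive))


def reference_window(reference_date) -> Window:
    """Unlagged window: all claims history up to the reference date."""
    return Window(CLAIMS_START - pd.Timedelta(days=1), pd.Timestamp(reference_date))


def lagged_window() -> Window:
    """Lagged window: claims recorded before baseline (2004-2009)."""
    return Window(CLAIMS_START - pd.Timedelta(days=1), LAG_END)


def age_splines(age: float) -> tuple[float, float]:
    """Two linear age splines with a knot at 85; they sum to age."""
    if not age > 0:
        raise ValueError(f"age must be positive, got {age}")
    return min(age, 85.0), max(age - 85.0, 0.0)


def smoking_index(probability: float, n_unique_dx_codes: int) -> float:
    """Ever-smoking probability divided by the unique diagnosis-code count
    (divisor 1 for people with no diagnosis codes)."""
    if not 0.0 <= probability <= 1.0:
        raise ValueError("probability must lie in [0, 1]")
    return probability / max(int(n_unique_dx_codes), 1)


def _drop_pd_codes(events: pd.DataFrame) -> pd.DataFrame:
    mask = (events["code_system"] == "ICD9_DX") & events["code"].isin(PD_CODES)
    return events[~mask]


def count_unique_dx(events: pd.DataFrame, window: Window | None = None) -> int:
    """Number of distinct normalized ICD-9 diagnosis codes in the window
    (procedure codes and PD-definition codes excluded)."""
    ev = _drop_pd_codes(events)
    ev = ev[ev["code_system"] == "ICD9_DX"]
    if window is not None and len(ev):
        ev = ev[window.contains(ev["service_date"])]
    return int(ev["code"].nunique())


def _demographics(sex: str, race: str, age: float) -> dict[str, float]:
    s1, s2 = age_splines(age)
    feats = {
        "age_spline_1": s1,
        "age_spline_2": s2,
        "female": 1.0 if sex == "female" else 0.0,
        "race:black": 0.0,
        "race:asian": 0.0,
        "race:hispanic": 0.0,
        "race:native_american": 0.0,
        "race:pacific_islander_other": 0.0,
    }
    term = RACE_TERM[race]
    if term is not None:
        feats[term] = 1.0
    return feats


def smoking_probability(
    events: pd.DataFrame,
    smoking_model: CoefficientSet,
    demographics: dict[str, float] | None = None,
    tobacco_codes: CodeList = DEFAULT_TOBACCO_CODES,
    window: Window | None = None,
) -> float:
    """Predicted probability of ever smoking for one beneficiary.

    Returns 1.0 when any tobacco-specific code falls in the window;
    otherwise the inverse logit of the smoking model's linear predictor
    over demographics and code indicators.
    """
    ev = events
    if window is not None and len(ev):
        ev = ev[window.contains(ev["service_date"])]
    dx = ev[ev["code_system"] == "ICD9_DX"]
    if any((c, "ICD9_DX") in tobacco_codes for c in dx["code"].unique()):
        return 1.0
    feats = dict(demographics or {})
    present = set(ev["code"] + ":" + ev["code_system"])
    for term in smoking_model.terms:
        if term not in DEMOGRAPHIC_TERMS:
            feats[term] = 1.0 if term in present else 0.0
        elif term not in feats:
            raise ScoringError(
                f"smoking model needs demographic term {term!r} but none was supplied"
            )
    lp = smoking_model.constant + sum(
        beta * feats[t] for t, beta in smoking_model.terms.items()
    )
    return float(predicted_probability(lp))


def extract_features(
    beneficiary,
    events: pd.DataFrame,
    window: Window,
    code_list: CodeList,
    smoking_model: CoefficientSet,
    age_at: pd.Timestamp,
    tobacco_codes: CodeList = DEFAULT_TOBACCO_CODES,
) -> pd.Series:
    """Full feature vector for one beneficiary as a term-indexed Series.

    ``beneficiary`` is any object with ``birth_date``, ``sex`` and
    ``race_ethnicity`` attributes (a BeneficiaryRecord or base-file row).
    Only events with ``start < service_date <= end`` contribute;
    deterministic and invariant to event ordering/duplication.
    """
    if len(code_list) == 0:
        raise ScoringError("code_list is empty")
    age = (pd.Timestamp(age_at) - pd.Timestamp(beneficiary.birth_date)).days / DAYS_PER_YEAR
    feats = _demographics(beneficiary.sex, beneficiary.race_ethnicity, age)

    ev = events[window.contains(events["service_date"])] if len(events) else events
    ev = _drop_pd_codes(ev)

    feats["smoking_probability"] = smoking_probability(
        ev, smoking_model, demographics=feats, tobacco_codes=tobacco_codes
    )
    feats["n_unique_dx_codes"] = float(count_unique_dx(ev))
    present = set(ev["code"] + ":" + ev["code_system"]) if len(ev) else set()
    for term in code_list.term_keys():
        feats[term] = 1.0 if term in present else 0.0
    return pd.Series(feats, dtype=float)


# ---------------------------------------------------------------------------
# Vectorized scoring over a sample (no dense code-indicator matrix)


def _window_filter(
    claims: pd.DataFrame, sample: pd.DataFrame, window_mode: str
) -> pd.DataFrame:
    """Claims of sampled beneficiaries restricted to each person's window."""
    merged = claims.merge(
        sample[["beneficiary_id", "reference_date"]], on="beneficiary_id", how="inner"
    )
    sd = pd.to_datetime(merged["service_date"])
    start = CLAIMS_START - pd.Timedelta(days=1)
    if window_mode == "lagged":
        keep = (sd > start) & (sd <= LAG_END)
    elif window_mode == "to_reference":
        keep = (sd > start) & (sd <= pd.to_datetime(merged["reference_date"]))
    else:
        raise ScoringError(f"unknown window mode {window_mode!r}")
    return merged[keep.to_numpy()]


def _presence_contribution(
    inwin: pd.DataFrame, coeffs: CoefficientSet, index: pd.Index
) -> pd.Series:
    """Sum of coefficients of distinct in-window code terms per beneficiary."""
    code_terms = coeffs.code_terms()
    if not code_terms:
        return pd.Series(0.0, index=index)
    term = inwin["code"] + ":" + inwin["code_system"]
    hit = inwin.loc[term.isin(code_terms).to_numpy(), ["beneficiary_id"]].assign(
        term=term[term.isin(code_terms)]
    )
    hit = hit.drop_duplicates()
    beta = hit["term"].map({t: b for t, b in coeffs.terms.items()})
    return (
        beta.groupby(hit["beneficiary_id"].to_numpy()).sum()
        .reindex(index, fill_value=0.0)
    )


def score_sample(
    base: pd.DataFrame,
    claims: pd.DataFrame,
    sample: pd.DataFrame,
    coeffs: CoefficientSet,
    smoking_model: CoefficientSet,
    window_mode: str = "to_reference",
    age_at: str = "reference",
    tobacco_codes: CodeList = DEFAULT_TOBACCO_CODES,
) -> pd.DataFrame:
    """Score every row of ``sample`` (beneficiary_id, reference_date).

    Equivalent to :func:`extract_features` + the exact dot product for
    each beneficiary, implemented with grouped set arithmetic so large
    samples never materialize a dense indicator matrix.  ``age_at``
    selects the age used in the splines: at the per-person reference date
    (nested case-control convention) or at the 2010-01-01 baseline
    (cohort convention).

    Returns a frame indexed like ``sample`` with ``linear_predictor``,
    ``probability``, ``smoking_probability`` and ``n_unique_dx_codes``.
    """
    sample = sample.reset_index(drop=True)
    demo = base.set_index("beneficiary_id").loc[
        sample["beneficiary_id"], ["birth_date", "sex", "race_ethnicity"]
    ]
    if age_at == "reference":
        at = pd.to_datetime(sample["reference_date"]).to_numpy()
    elif age_at == "baseline":
        at = np.full(len(sample), pd.Timestamp("2010-01-01").to_datetime64())
    else:
        raise ScoringError(f"unknown age_at {age_at!r}")
    age = (at - pd.to_datetime(demo["birth_date"]).to_numpy()).astype(
        "timedelta64[D]"
    ).astype(float) / DAYS_PER_YEAR

    design = pd.DataFrame(index=sample.index)
    design["age_spline_1"] = np.minimum(age, 85.0)
    design["age_spline_2"] = np.maximum(age - 85.0, 0.0)
    design["female"] = (demo["sex"].to_numpy() == "female").astype(float)
    race = demo["race_ethnicity"].to_numpy()
    for cat in ("black", "asian", "hispanic", "native_american"):
        design[f"race:{cat}"] = (race == cat).astype(float)
    design["race:pacific_islander_other"] = (
        (race == "pacific_islander_other") | (race == "unknown")
    ).astype(float)

    inwin = _drop_pd_codes(_window_filter(claims, sample, window_mode))
    bene_index = pd.Index(sample["beneficiary_id"], name="beneficiary_id")

    dx = inwin[inwin["code_system"] == "ICD9_DX"]
    n_unique = (
        dx.drop_duplicates(["beneficiary_id", "code"])
        .groupby("beneficiary_id").size()
        .reindex(bene_index, fill_value=0)
    )
    tobacco_dx = set(tobacco_codes.codes_for("ICD9_DX"))
    has_tobacco = (
        dx.loc[dx["code"].isin(tobacco_dx), "beneficiary_id"]
        .drop_duplicates()
    )
    tobacco_mask = bene_index.isin(has_tobacco)

    aux = design.assign(n_unique_dx_codes=n_unique.to_numpy(dtype=float))
    smoke_demo = CoefficientSet(
        smoking_model.constant,
        {t: b for t, b in smoking_model.terms.items() if t in DEMOGRAPHIC_TERMS},
    )
    smoke_lp = (
        linear_predictor_frame(aux, smoke_demo)
        + _presence_contribution(inwin, smoking_model, bene_index).to_numpy()
    )
    smoking = predicted_probability(smoke_lp.to_numpy())
    smoking = np.where(tobacco_mask, 1.0, smoking)

    design["smoking_probability"] = smoking
    design["n_unique_dx_codes"] = n_unique.to_numpy(dtype=float)

    demo_terms = [t for t in coeffs.terms if t in DEMOGRAPHIC_TERMS]
    lp = linear_predictor_frame(
        design, CoefficientSet(coeffs.constant, {t: coeffs.terms[t] for t in demo_terms})
    ).to_numpy() + _presence_contribution(inwin, coeffs, bene_index).to_numpy()

    return pd.DataFrame(
        {
            "beneficiary_id": sample["beneficiary_id"].to_numpy(),
            "reference_date": pd.to_datetime(sample["reference_date"]).to_numpy(),
            "linear_predictor": lp,
            "probability": predicted_probability(lp),
            "smoking_probability": smoking,
            "n_unique_dx_codes": n_unique.to_numpy(),
        },
        index=sample.index,
    )
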