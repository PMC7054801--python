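"""Synthetic Medicare-like population and claims generator.

The generator emulates the structure of the study population so that
every downstream stage — ascertainment, cohort construction, nested
case-control sampling, scoring, and validation — can be exercised with a
known ground truth:

* beneficiaries aged 66y11m-90 at the 2010-01-01 baseline, with a
  realistic sex/race mix and age-increasing Gompertz death hazard;
* a latent PD process: time to diagnosis is exponential at a configurable
  population rate (default 461 per 100,000 person-years), modulated by
  age; the latent onset precedes diagnosis by a uniform prodromal delay;
* per-beneficiary code streams: independent Poisson emission over a
  synthetic code vocabulary, with positively weighted signal codes
  emitted at an exponentially inflated rate between latent onset and
  diagnosis, a 332.0 diagnosis code stream from diagnosis onward (some
  from a neurologist), tobacco-specific codes among ever smokers, and
  rare ascertainment-exclusion codes (331.82, 333.0, 322.0 +/- CPT 62270);
* death truncates all emission.

Coefficient sets shipped or built here are synthetic stand-ins: the
original model's published coefficients are consumed as configuration by
the pipeline, and none are reproduced here.  Per-code prevalences are
order-of-magnitude placeholders, not calibrated Medicare marginals.

Ground truth records each person's latent onset/diagnosis dates, smoking
status, and the true-model linear predictor at baseline computed by an
independent in-module route (plain numpy set arithmetic), so that
pipeline-recovered metrics can be checked against an oracle.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .claims_data import CLAIM_SOURCES, RACE_CATEGORIES, STUDY_YEARS
from .scoring import CoefficientSet, DEMOGRAPHIC_TERMS

__all__ = [
    "GompertzHazard",
    "SimulationConfig",
    "synthetic_full_coefficients",
    "synthetic_smoking_model",
    "generate_population",
    "inject_edge_cases",
]

BASELINE = pd.Timestamp("2010-01-01")
HORIZON_END = pd.Timestamp("2014-12-31")
CLAIMS_START = pd.Timestamp("2004-01-01")
DAYS_PER_YEAR = 365.25

EPOCH = np.datetime64("1970-01-01")
_D = lambda ts: (np.datetime64(ts, "D") - EPOCH).astype(np.int64)  # noqa: E731
BASELINE_D = _D("2010-01-01")
END_D = _D("2014-12-31")
START_D = _D("2004-01-01")


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Mortality


@dataclasses.dataclass(frozen=True)
class GompertzHazard:
    """Age-dependent annual death hazard h(age) = rate_at_75 * exp(slope*(age-75))."""

    rate_at_75: float = 0.042
    log_slope: float = 0.09

    def rate(self, age):
        return self.rate_at_75 * np.exp(self.log_slope * (np.asarray(age, float) - 75.0))

    def draw_times(self, rng: np.random.Generator, age0: np.ndarray) -> np.ndarray:
        """Years from baseline to death, by inverse transform."""
        a0 = self.rate(age0)
        b = self.log_slope
        e = rng.exponential(size=a0.shape)
        return np.log1p(b * e / a0) / b

    def expected_person_years(self, age0: np.ndarray, horizon: float) -> np.ndarray:
        """E[min(T_death, horizon)] per person, by quadrature of survival."""
        t = np.linspace(0.0, horizon, 51)
        a0 = self.rate(age0)[:, None]
        b = self.log_slope
        surv = np.exp(-(a0 / b) * np.expm1(b * t[None, :]))
        return np.trapezoid(surv, t, axis=1)


# ---------------------------------------------------------------------------
# Synthetic stand-in models (coefficients and vocabulary)

# Clinically motivated core codes of the stand-in model: prodromal PD
# symptoms/markers (positive) and smoking/cardiovascular/cancer/preventive
# care (negative), mirroring the qualitative shape of code-based PD models.
_CORE_MODEL_CODES = [
    # code, system, label, coefficient
    ("5640", "ICD9_DX", "constipation, unspecified", 0.65),
    ("564", "ICD9_DX", "constipation (3-digit)", 0.45),
    ("56400", "ICD9_DX", "constipation, unspecified (5-digit)", 0.50),
    ("56401", "ICD9_DX", "slow transit constipation", 0.55),
    ("56402", "ICD9_DX", "outlet dysfunction constipation", 0.50),
    ("56409", "ICD9_DX", "other constipation", 0.45),
    ("32742", "ICD9_DX", "REM sleep behavior disorder", 1.60),
    ("7811", "ICD9_DX", "disturbance of smell and taste", 1.10),
    ("7810", "ICD9_DX", "abnormal involuntary movements", 1.30),
    ("7812", "ICD9_DX", "abnormality of gait", 0.95),
    ("7813", "ICD9_DX", "lack of coordination", 0.85),
    ("7807", "ICD9_DX", "malaise and fatigue", 0.40),
    ("78079", "ICD9_DX", "other malaise and fatigue", 0.35),
    ("78052", "ICD9_DX", "insomnia, unspecified", 0.35),
    ("E8889", "ICD9_DX", "unspecified fall", 0.55),
    ("311", "ICD9_DX", "depressive disorder NEC", 0.45),
    ("30000", "ICD9_DX", "anxiety state, unspecified", 0.30),
    ("5990", "ICD9_DX", "urinary tract infection", 0.30),
    ("78841", "ICD9_DX", "urinary frequency", 0.35),
    ("70551", "CPT", "MRI brain without contrast", 0.80),
    ("70450", "CPT", "CT head without contrast", 0.60),
    ("82607", "CPT", "vitamin B-12 assay", 0.45),
    ("84443", "CPT", "TSH assay", 0.25),
    ("95860", "CPT", "needle electromyography", 0.50),
    ("E0100", "HCPCS", "cane", 0.55),
    ("E0143", "HCPCS", "walker", 0.70),
    ("K0001", "HCPCS", "standard wheelchair", 0.60),
    ("A0428", "HCPCS", "ambulance, basic life support", 0.35),
    ("E0260", "HCPCS", "hospital bed", 0.40),
    ("496", "ICD9_DX", "chronic airway obstruction (COPD)", -0.40),
    ("49121", "ICD9_DX", "obstructive chronic bronchitis w/ exacerbation", -0.35),
    ("1629", "ICD9_DX", "malignant neoplasm of lung", -0.50),
    ("41401", "ICD9_DX", "coronary atherosclerosis", -0.20),
    ("V700", "ICD9_DX", "routine general medical examination", -0.25),
    ("90658", "CPT", "influenza vaccine", -0.20),
    ("99397", "CPT", "preventive visit, 65+", -0.25),
    ("G0008", "HCPCS", "influenza vaccine administration", -0.25),
    ("G0121", "HCPCS", "screening colonoscopy", -0.20),
]

_DEMOGRAPHIC_BETAS = {
    "age_spline_1": 0.09,
    "age_spline_2": -0.05,
    "female": -0.35,
    "race:black": -0.45,
    "race:asian": 0.05,
    "race:hispanic": 0.15,
    "race:native_american": 0.10,
    "race:pacific_islander_other": -0.40,
    "smoking_probability": -0.45,
    "n_unique_dx_codes": 0.02,
}

#: ICD-9 prefixes never used for generated filler codes (reserved for the
#: case definition, its exclusions, and the basic-model/tobacco codes).
_RESERVED_DX_PREFIXES = ("331", "332", "333", "322", "564", "305", "V15", "327", "781")

# Codes emitted at triple rate by ever smokers (smoking-model signal).
_SMOKING_ASSOC = [("496", "ICD9_DX"), ("49121", "ICD9_DX"), ("1629", "ICD9_DX"),
                  ("41401", "ICD9_DX")]
_TOBACCO_EMITTED = [("V1582", "ICD9_DX"), ("3051", "ICD9_DX")]


def _filler_codes(rng: np.random.Generator, n: int, system: str) -> list[str]:
    out: set[str] = set()
    while len(out) < n:
        if system == "ICD9_DX":
            code = str(rng.integers(10000, 100000))
            if code.startswith(tuple(p for p in _RESERVED_DX_PREFIXES if not p.startswith("V"))):
                continue
        elif system == "CPT":
            code = str(rng.integers(10000, 100000))
        else:  # HCPCS: letter + 4 digits
            code = "AEGJKL"[int(rng.integers(0, 6))] + f"{int(rng.integers(0, 10000)):04d}"
        out.add(code)
    return sorted(out)


def synthetic_full_coefficients(
    n_codes: int = 536, n_hcpcs: int = 54, constant: float = -11.5
) -> tuple[CoefficientSet, pd.DataFrame]:
    """Deterministic synthetic stand-in for the full code-based risk model.

    Returns the coefficient set (``n_codes`` code terms of which
    ``n_hcpcs`` are HCPCS, plus demographics/smoking/unique-count and a
    constant) and a code-list frame (code, code_system, label).  This is
    a constructed stand-in with the published model's *shape*, not its
    values.
    """
    rng = np.random.default_rng(20200221)  # fixed: the stand-in is a constant artifact
    core = list(_CORE_MODEL_CODES)
    n_core_hcpcs = sum(1 for _, s, _, _ in core if s == "HCPCS")
    n_fill = n_codes - len(core)
    n_fill_hcpcs = n_hcpcs - n_core_hcpcs
    if n_fill < 0 or n_fill_hcpcs < 0:
        raise ConfigError("n_codes/n_hcpcs too small for the core code set")
    n_fill_cpt = max(int(round(0.18 * n_fill)) - 0, 0)
    n_fill_dx = n_fill - n_fill_hcpcs - n_fill_cpt

    terms = dict(_DEMOGRAPHIC_BETAS)
    rows = []
    for code, system, label, beta in core:
        terms[f"{code}:{system}"] = beta
        rows.append((code, system, label))
    existing = {(c, s) for c, s, _ in rows}
    for system, count in (("ICD9_DX", n_fill_dx), ("CPT", n_fill_cpt), ("HCPCS", n_fill_hcpcs)):
        for code in _filler_codes(rng, count, system):
            if (code, system) in existing:
                continue
            beta = float(rng.normal(0.0, 0.12))
            terms[f"{code}:{system}"] = beta
            rows.append((code, system, f"synthetic filler ({system})"))
    coeffs = CoefficientSet(
        constant=constant,
        terms=terms,
        label="synthetic full model (stand-in)",
        provenance="synthetic_full_coefficients()",
    )
    code_list = pd.DataFrame(rows, columns=["code", "code_system", "label"])
    return coeffs, code_list


def synthetic_smoking_model() -> CoefficientSet:
    """Synthetic stand-in logistic model for ever-smoking probability."""
    return CoefficientSet(
        constant=-0.3,
        terms={
            "female": -0.5,
            "496:ICD9_DX": 0.9,
            "49121:ICD9_DX": 0.8,
            "1629:ICD9_DX": 0.9,
            "41401:ICD9_DX": 0.25,
        },
        label="synthetic smoking model (stand-in)",
        provenance="synthetic_smoking_model()",
    )


# ---------------------------------------------------------------------------
# Configuration

DEFAULT_AGE_WEIGHTS: dict[int, float] = {
    66: 0.010, 67: 0.055, 68: 0.055, 69: 0.055,
    **{a: 0.0638 for a in range(70, 75)},
    **{a: 0.0466 for a in range(75, 80)},
    **{a: 0.0350 for a in range(80, 85)},
    **{a: 0.0180 for a in range(85, 91)},
}

DEFAULT_RACE_WEIGHTS: dict[str, float] = {
    "white": 0.8615, "black": 0.0750, "asian": 0.0226, "hispanic": 0.0188,
    "native_american": 0.0040, "pacific_islander_other": 0.0165, "unknown": 0.0016,
}


@dataclasses.dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic population.

    Defaults follow the validated study's structure where stated (PD
    incidence 461 per 100,000 person-years; 66y11m-90 age window; up to a
    five-year prodromal enrichment window) and documented realistic
    placeholders elsewhere.
    """

    n_beneficiaries: int = 10_000
    seed: int = 0
    age_distribution: Mapping[int, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_AGE_WEIGHTS))
    sex_ratio_female: float = 0.577
    race_weights: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_RACE_WEIGHTS))
    annual_pd_incidence: float = 0.00461
    pd_age_log_hr: float = 0.05
    annual_death_hazard: GompertzHazard = dataclasses.field(default_factory=GompertzHazard)
    background_code_rate: float = 5.0
    prodromal_window_years: float = 5.0
    signal_enrichment: float = 1.75
    signal_coefficients: CoefficientSet | None = None
    ever_smoker_prevalence: float = 0.5
    tobacco_code_prevalence: float = 0.35
    smoker_code_multiplier: float = 3.0
    pd_repeat_code_rate: float = 0.5
    neurologist_code_prob: float = 0.15
    exclusion_rates: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {
            "lewy_body": 0.002, "extrapyramidal": 0.002,
            "meningitis": 0.002, "lp_given_meningitis": 0.5,
        })
    vocabulary_model_codes: int = 150
    vocabulary_noise_codes: int = 40

    def __post_init__(self) -> None:
        if self.n_beneficiaries <= 0:
            raise ConfigError("n_beneficiaries must be positive")
        for name in ("annual_pd_incidence", "background_code_rate",
                     "prodromal_window_years", "pd_repeat_code_rate",
                     "signal_enrichment"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("sex_ratio_female", "ever_smoker_prevalence",
                     "tobacco_code_prevalence", "neurologist_code_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        for weights, what in ((self.age_distribution, "age_distribution"),
                              (self.race_weights, "race_weights")):
            total = float(sum(weights.values()))
            if total <= 0 or any(w < 0 for w in weights.values()):
                raise ConfigError(f"{what} weights must be non-negative with positive sum")
        if set(self.race_weights) - set(RACE_CATEGORIES):
            raise ConfigError("race_weights has unknown categories")

    def resolved_coefficients(self) -> CoefficientSet:
        if self.signal_coefficients is not None:
            return self.signal_coefficients
        coeffs, _ = synthetic_full_coefficients()
        return coeffs


# ---------------------------------------------------------------------------
# Generation


def _emission_vocabulary(config: SimulationConfig, coeffs: CoefficientSet) -> pd.DataFrame:
    """Emission vocabulary: core model codes, a filler-model sample, and
    non-model noise codes, with Zipf-ish weights."""
    rng = np.random.default_rng(983_241)  # vocabulary is a fixed artifact
    rows = [(c, s) for c, s, _, _ in _CORE_MODEL_CODES]
    model_terms = [t for t in coeffs.code_terms()]
    core_set = set(f"{c}:{s}" for c, s in rows)
    other_model = [t for t in model_terms if t not in core_set]
    take = other_model[: max(config.vocabulary_model_codes - len(rows), 0)]
    rows += [tuple(t.rsplit(":", 1)) for t in take]
    for code in _filler_codes(rng, config.vocabulary_noise_codes, "ICD9_DX"):
        if f"{code}:ICD9_DX" not in coeffs.terms:
            rows.append((code, "ICD9_DX"))

    vocab = pd.DataFrame(rows, columns=["code", "code_system"]).drop_duplicates()
    w = rng.lognormal(mean=0.0, sigma=1.0, size=len(vocab))
    vocab["weight"] = w / w.sum()
    term = vocab["code"] + ":" + vocab["code_system"]
    beta = term.map(coeffs.terms).fillna(0.0)
    vocab["enrich_mult"] = np.exp(
        config.signal_enrichment * np.maximum(beta.to_numpy(), 0.0)
    )
    vocab["smoker_mult"] = np.where(
        term.isin([f"{c}:{s}" for c, s in _SMOKING_ASSOC]),
        config.smoker_code_multiplier, 1.0,
    )
    return vocab.reset_index(drop=True)


def _make_claims(
    bene_ids: np.ndarray,
    code: np.ndarray,
    system: np.ndarray,
    day: np.ndarray,
    specialty: np.ndarray | None,
    rng: np.random.Generator,
) -> pd.DataFrame:
    source = np.asarray(CLAIM_SOURCES)[
        rng.choice(len(CLAIM_SOURCES), size=day.size,
                   p=[0.55, 0.20, 0.08, 0.05, 0.07, 0.05])
    ]
    return pd.DataFrame(
        {
            "beneficiary_id": bene_ids,
            "service_date": (EPOCH + day.astype("timedelta64[D]")),
            "code": code,
            "code_system": system,
            "claim_source": source,
            "provider_specialty": specialty if specialty is not None
            else np.full(day.size, np.nan, dtype=object),
        }
    )


def _uniform_days(rng, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Uniform integer day in [lo, hi] (inclusive), elementwise."""
    span = np.maximum(hi - lo, 0) + 1
    return lo + (rng.random(lo.size) * span).astype(np.int64)


def generate_population(config: SimulationConfig):
    """Simulate (base, claims, ground_truth) tables.

    Reproducible for a fixed config seed; beneficiaries satisfy baseline
    eligibility by construction.  See the module docstring for the model.
    """
    n = config.n_beneficiaries
    coeffs = config.resolved_coefficients()
    ss = np.random.SeedSequence(config.seed)
    r_demo, r_death, r_onset, r_codes, r_dates, r_pd, r_misc = (
        np.random.default_rng(s) for s in ss.spawn(7)
    )

    ids = np.array([f"B{i:07d}" for i in range(n)])

    # demographics ---------------------------------------------------------
    ages_int = np.array(sorted(config.age_distribution))
    w = np.array([config.age_distribution[a] for a in ages_int], float)
    band = ages_int[r_demo.choice(ages_int.size, size=n, p=w / w.sum())]
    frac = r_demo.random(n)
    age0 = np.where(band == 66, 66 + 11 / 12 + frac * (1 / 12), band + frac)
    birth_day = BASELINE_D - np.round(age0 * DAYS_PER_YEAR).astype(np.int64)

    sex = np.where(r_demo.random(n) < config.sex_ratio_female, "female", "male")
    races = np.array(sorted(config.race_weights))
    rw = np.array([config.race_weights[r] for r in races], float)
    race = races[r_demo.choice(races.size, size=n, p=rw / rw.sum())]
    smoker = r_demo.random(n) < config.ever_smoker_prevalence

    # death ----------------------------------------------------------------
    t_death = config.annual_death_hazard.draw_times(r_death, age0)
    death_day = BASELINE_D + np.round(t_death * DAYS_PER_YEAR).astype(np.int64)
    horizon_years = (END_D - BASELINE_D) / DAYS_PER_YEAR
    died_in_study = death_day <= END_D
    end_day = np.minimum(death_day, END_D)

    # latent PD process ----------------------------------------------------
    mult = np.exp(config.pd_age_log_hr * (age0 - age0.mean()))
    epy = config.annual_death_hazard.expected_person_years(age0, horizon_years)
    norm = epy.sum() / (epy * mult).sum() if config.annual_pd_incidence > 0 else 1.0
    lam = config.annual_pd_incidence * mult * norm
    with np.errstate(divide="ignore"):
        t_pd = np.where(lam > 0, r_onset.exponential(size=n) / np.maximum(lam, 1e-300), np.inf)
    # cap far-future times so day arithmetic stays within datetime range
    t_pd_capped = np.minimum(t_pd, 200.0)
    dx_day_sched = BASELINE_D + np.round(t_pd_capped * DAYS_PER_YEAR).astype(np.int64)
    diagnosed = (t_pd <= t_pd_capped) & (dx_day_sched <= end_day)
    delay_days = np.round(
        r_onset.random(n) * config.prodromal_window_years * DAYS_PER_YEAR
    ).astype(np.int64)
    onset_day = dx_day_sched - np.maximum(delay_days, 1)

    # emission periods -----------------------------------------------------
    start_day = np.maximum(START_D, birth_day + np.round(65 * DAYS_PER_YEAR).astype(np.int64))
    active_years = np.maximum(end_day - start_day, 0) / DAYS_PER_YEAR

    vocab = _emission_vocabulary(config, coeffs)
    wv = vocab["weight"].to_numpy()
    smoker_mult = vocab["smoker_mult"].to_numpy()
    enrich = vocab["enrich_mult"].to_numpy()

    lam_codes = config.background_code_rate * np.outer(active_years, wv)
    lam_codes[smoker] *= smoker_mult[None, :]
    counts = r_codes.poisson(lam_codes)
    bi, ci = np.nonzero(counts)
    reps = counts[bi, ci]
    ev_bene = np.repeat(bi, reps)
    ev_code = np.repeat(ci, reps)
    ev_day = _uniform_days(
        r_dates, start_day[ev_bene], np.maximum(end_day[ev_bene] - 1, start_day[ev_bene])
    )
    frames = [
        _make_claims(
            ids[ev_bene], vocab["code"].to_numpy()[ev_code],
            vocab["code_system"].to_numpy()[ev_code], ev_day, None, r_misc,
        )
    ]

    # prodromal enrichment -------------------------------------------------
    win_lo = np.maximum(onset_day, start_day)
    win_hi = np.minimum(np.minimum(dx_day_sched, end_day), END_D)
    has_win = win_hi > win_lo
    if has_win.any() and (enrich > 1).any():
        idx = np.flatnonzero(has_win)
        win_years = (win_hi[idx] - win_lo[idx]) / DAYS_PER_YEAR
        sig = np.flatnonzero(enrich > 1.0)
        extra_lam = (
            config.background_code_rate
            * np.outer(win_years, wv[sig] * (enrich[sig] - 1.0))
        )
        extra_lam[smoker[idx]] *= smoker_mult[sig][None, :]
        ecounts = r_codes.poisson(extra_lam)
        bi2, ci2 = np.nonzero(ecounts)
        reps2 = ecounts[bi2, ci2]
        gb = np.repeat(idx[bi2], reps2)
        gc = np.repeat(sig[ci2], reps2)
        gday = _uniform_days(r_dates, win_lo[gb], np.maximum(win_hi[gb] - 1, win_lo[gb]))
        frames.append(
            _make_claims(
                ids[gb], vocab["code"].to_numpy()[gc],
                vocab["code_system"].to_numpy()[gc], gday, None, r_misc,
            )
        )

    # PD diagnosis codes ---------------------------------------------------
    dxi = np.flatnonzero(diagnosed)
    if dxi.size:
        remain_years = (end_day[dxi] - dx_day_sched[dxi]) / DAYS_PER_YEAR
        extra = r_pd.poisson(config.pd_repeat_code_rate * remain_years)
        pd_bene = np.concatenate([dxi, np.repeat(dxi, extra)])
        first_day = dx_day_sched[dxi]
        extra_day = _uniform_days(
            r_pd, np.repeat(dx_day_sched[dxi], extra), np.repeat(end_day[dxi], extra)
        )
        pd_day = np.concatenate([first_day, extra_day])
        neuro = r_pd.random(pd_bene.size) < config.neurologist_code_prob
        specialty = np.where(neuro, "neurology", None).astype(object)
        frames.append(
            _make_claims(
                ids[pd_bene], np.full(pd_bene.size, "3320"),
                np.full(pd_bene.size, "ICD9_DX"), pd_day, specialty, r_misc,
            )
        )

    # tobacco-specific codes ----------------------------------------------
    tob = smoker & (r_misc.random(n) < config.tobacco_code_prevalence)
    ti = np.flatnonzero(tob)
    if ti.size:
        which = r_misc.integers(0, len(_TOBACCO_EMITTED), size=ti.size)
        tcodes = np.array([c for c, _ in _TOBACCO_EMITTED])[which]
        tday = _uniform_days(r_misc, start_day[ti], np.maximum(end_day[ti] - 1, start_day[ti]))
        frames.append(
            _make_claims(ids[ti], tcodes, np.full(ti.size, "ICD9_DX"), tday, None, r_misc)
        )

    # rare exclusion codes -------------------------------------------------
    er = config.exclusion_rates
    for code, key in (("33182", "lewy_body"), ("3330", "extrapyramidal"),
                      ("3220", "meningitis")):
        hit = np.flatnonzero(r_misc.random(n) < float(er.get(key, 0.0)))
        if hit.size == 0:
            continue
        day = _uniform_days(r_misc, start_day[hit], np.maximum(end_day[hit] - 1, start_day[hit]))
        frames.append(
            _make_claims(ids[hit], np.full(hit.size, code),
                         np.full(hit.size, "ICD9_DX"), day, None, r_misc)
        )
        if code == "3220":
            lp_hit = hit[r_misc.random(hit.size) < float(er.get("lp_given_meningitis", 0.0))]
            if lp_hit.size:
                lp_day = _uniform_days(
                    r_misc, start_day[lp_hit],
                    np.maximum(end_day[lp_hit] - 1, start_day[lp_hit]),
                )
                frames.append(
                    _make_claims(ids[lp_hit], np.full(lp_hit.size, "62270"),
                                 np.full(lp_hit.size, "CPT"), lp_day, None, r_misc)
                )

    claims = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["beneficiary_id", "service_date"], kind="mergesort")
        .reset_index(drop=True)
    )

    base = pd.DataFrame({
        "beneficiary_id": ids,
        "birth_date": EPOCH + birth_day.astype("timedelta64[D]"),
        "sex": sex,
        "race_ethnicity": race,
        "death_date": pd.Series(EPOCH + death_day.astype("timedelta64[D]")).where(
            pd.Series(died_in_study)),
    })
    for y in STUDY_YEARS:
        base[f"part_ab_{y}"] = True
        base[f"non_medicare_{y}"] = False
    base["us_residence"] = True
    base["birth_date"] = pd.to_datetime(base["birth_date"]).astype("datetime64[ns]")
    base["death_date"] = pd.to_datetime(base["death_date"]).astype("datetime64[ns]")
    claims["service_date"] = pd.to_datetime(claims["service_date"]).astype("datetime64[ns]")

    truth = pd.DataFrame({
        "beneficiary_id": ids,
        "ever_smoker": smoker,
        "onset_date": pd.Series(EPOCH + onset_day.astype("timedelta64[D]")).where(
            pd.Series(diagnosed | (has_win & (onset_day <= END_D)))),
        "diagnosis_date": pd.Series(EPOCH + dx_day_sched.astype("timedelta64[D]")).where(
            pd.Series(diagnosed)),
    })
    truth["onset_date"] = pd.to_datetime(truth["onset_date"]).astype("datetime64[ns]")
    truth["diagnosis_date"] = pd.to_datetime(truth["diagnosis_date"]).astype("datetime64[ns]")
    truth["true_lp_baseline"] = _true_baseline_lp(
        base, claims, coeffs, synthetic_smoking_model()
    )
    return base, claims, truth


# ---------------------------------------------------------------------------
# Independent ground-truth linear predictor (oracle route)


def _true_baseline_lp(
    base: pd.DataFrame,
    claims: pd.DataFrame,
    coeffs: CoefficientSet,
    smoking_model: CoefficientSet,
) -> np.ndarray:
    """Baseline (2004-2009 window) linear predictor by direct set arithmetic.

    Deliberately independent of the predictors/scoring modules: indicator
    resolution uses integer-coded (beneficiary, term) pairs and numpy
    scatter-adds rather than the pipeline's merge-based path, so it can
    serve as an oracle for pipeline-recovered scores.
    """
    ids = base["beneficiary_id"].to_numpy()
    id_pos = {b: i for i, b in enumerate(ids)}
    n = len(ids)

    day = pd.to_datetime(claims["service_date"]).to_numpy().astype("datetime64[D]")
    inwin = (day >= np.datetime64("2004-01-01")) & (day <= np.datetime64("2009-12-31"))
    code = claims["code"].to_numpy()[inwin]
    system = claims["code_system"].to_numpy()[inwin]
    bene = np.array(
        [id_pos[b] for b in claims["beneficiary_id"].to_numpy()[inwin]], dtype=np.int64
    )

    not_pd = ~((system == "ICD9_DX") & np.isin(code, ["332", "3320"]))
    code, system, bene = code[not_pd], system[not_pd], bene[not_pd]
    term = np.char.add(np.char.add(code.astype(str), ":"), system.astype(str))

    # unique dx codes per beneficiary
    is_dx = system == "ICD9_DX"
    dx_key = bene[is_dx] * (1 << 32) + pd.factorize(code[is_dx])[0]
    uniq_dx = np.unique(dx_key)
    n_unique = np.bincount((uniq_dx >> 32).astype(np.int64), minlength=n).astype(float)

    # distinct (beneficiary, term) pairs -> coefficient scatter-add
    if term.size:
        term_codes, term_idx = np.unique(term, return_inverse=True)
        pair = bene * len(term_codes) + term_idx
        upair = np.unique(pair)
        u_bene = (upair // len(term_codes)).astype(np.int64)
        u_term_idx = (upair % len(term_codes)).astype(np.int64)
    else:
        term_codes = np.array([], dtype=str)
        u_bene = np.array([], dtype=np.int64)
        u_term_idx = np.array([], dtype=np.int64)

    def scatter(model: CoefficientSet) -> np.ndarray:
        beta_by_code = np.array(
            [model.terms.get(t, 0.0) for t in term_codes], dtype=float
        )
        out = np.zeros(n)
        if u_bene.size:
            np.add.at(out, u_bene, beta_by_code[u_term_idx])
        return out

    age = (np.datetime64("2010-01-01") - pd.to_datetime(base["birth_date"]).to_numpy()
           .astype("datetime64[D]")).astype(float) / DAYS_PER_YEAR
    s1 = np.minimum(age, 85.0)
    s2 = np.maximum(age - 85.0, 0.0)
    female = (base["sex"].to_numpy() == "female").astype(float)
    race = base["race_ethnicity"].to_numpy()
    demo = {
        "age_spline_1": s1, "age_spline_2": s2, "female": female,
        "race:black": (race == "black").astype(float),
        "race:asian": (race == "asian").astype(float),
        "race:hispanic": (race == "hispanic").astype(float),
        "race:native_american": (race == "native_american").astype(float),
        "race:pacific_islander_other": ((race == "pacific_islander_other")
                                        | (race == "unknown")).astype(float),
    }

    tobacco = {"V1582", "3051", "30510", "30511", "30512", "30513"}
    tob_mask = np.zeros(n, dtype=bool)
    tob_by_code = np.isin(term_codes, [f"{c}:ICD9_DX" for c in tobacco])
    if u_bene.size:
        tob_mask[u_bene[tob_by_code[u_term_idx]]] = True
    smoke_lp = smoking_model.constant + scatter(smoking_model)
    for t, b in smoking_model.terms.items():
        if t in demo:
            smoke_lp += b * demo[t]
    smoking = np.where(tob_mask, 1.0, expit(smoke_lp))

    lp = coeffs.constant + scatter(coeffs)
    for t, b in coeffs.terms.items():
        if t in demo:
            lp += b * demo[t]
    lp += coeffs.terms.get("smoking_probability", 0.0) * smoking
    lp += coeffs.terms.get("n_unique_dx_codes", 0.0) * n_unique
    return lp


# ---------------------------------------------------------------------------
# Edge-case fixtures


_EDGE_KINDS = ("lewy_body", "extrapyramidal", "typographic", "dead_before_baseline",
               "over_age")


def inject_edge_cases(population, kinds: Sequence[str] = _EDGE_KINDS):
    """Append deterministic pathological fixtures to a generated population.

    Each kind adds one beneficiary: a 332+331.82 carrier (Lewy-body
    exclusion), a 332+333 carrier (extrapyramidal exclusion), a 332+322
    carrier without CPT 62270 (typographic-error rule), one dying before
    baseline, and one aged 91.  An empty ``kinds`` returns the population
    unchanged.
    """
    base, claims, truth = population
    kinds = tuple(kinds)
    unknown = set(kinds) - set(_EDGE_KINDS)
    if unknown:
        raise ConfigError(f"unknown edge-case kind(s): {sorted(unknown)}")
    if not kinds:
        return base, claims, truth

    base_rows, claim_rows = [], []

    def add_bene(bid, birth, death=None):
        row = {
            "beneficiary_id": bid, "birth_date": pd.Timestamp(birth),
            "sex": "male", "race_ethnicity": "white",
            "death_date": pd.Timestamp(death) if death else pd.NaT,
            "us_residence": True,
        }
        for y in STUDY_YEARS:
            row[f"part_ab_{y}"] = True
            row[f"non_medicare_{y}"] = False
        base_rows.append(row)

    def add_claim(bid, date, code, system="ICD9_DX"):
        claim_rows.append({
            "beneficiary_id": bid, "service_date": pd.Timestamp(date),
            "code": code, "code_system": system, "claim_source": "carrier",
            "provider_specialty": np.nan,
        })

    if "lewy_body" in kinds:
        add_bene("EDGE_LEWY", "1935-06-01")
        add_claim("EDGE_LEWY", "2012-03-01", "3320")
        add_claim("EDGE_LEWY", "2012-09-01", "33182")
    if "extrapyramidal" in kinds:
        add_bene("EDGE_EXTRAP", "1935-06-01")
        add_claim("EDGE_EXTRAP", "2012-03-01", "3320")
        add_claim("EDGE_EXTRAP", "2011-05-01", "333")
    if "typographic" in kinds:
        add_bene("EDGE_TYPO", "1935-06-01")
        add_claim("EDGE_TYPO", "2012-03-01", "332")
        add_claim("EDGE_TYPO", "2012-03-01", "322")
    if "dead_before_baseline" in kinds:
        add_bene("EDGE_DEAD", "1935-06-01", death="2009-12-15")
    if "over_age" in kinds:
        add_bene("EDGE_OVERAGE", "1918-06-01")

    base2 = pd.concat([base, pd.DataFrame(base_rows)[base.columns]], ignore_index=True)
    claims2 = pd.concat([claims, pd.DataFrame(claim_rows)[claims.columns]],
                        ignore_index=True)
    claims2 = claims2.sort_values(["beneficiary_id", "service_date"],
                                  kind="mergesort").reset_index(drop=True)
    truth2 = truth.copy()
    return base2, claims2, truth2
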