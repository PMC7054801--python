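"""End-to-end orchestration: simulate/ingest -> ascertain -> cohort ->
score -> validate -> survival, as a configured, seeded, logged run.

Every stage is a pure function of its inputs and the configuration, so a
rerun with the same config and seed produces byte-identical reports.  The
manifest records the seed, a configuration hash, library versions, and
record counts after every filter.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ascertainment import ascertain_all, case_quality_filter, QUALITY_MODES
from .claims_data import read_base_file, read_claims, write_base_file, write_claims
from .cohort import (
    assess_eligibility_frame,
    build_cohort,
    incidence_rate,
    person_years,
    sample_nested_case_control,
)
from .metrics import descriptive_table, validation_report
from .predictors import score_sample, DAYS_PER_YEAR
from .scoring import CoefficientSet, build_model_variant, MODEL_VARIANTS
from .survival import cox_fit, decile_assign
from .synthetic_data import (
    SimulationConfig,
    generate_population,
    synthetic_full_coefficients,
    synthetic_smoking_model,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("claimscreen")


class PipelineError(RuntimeError):
    pass


@dataclasses.dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Either provide ``base_path``/``claims_path`` or leave them unset to
    simulate ``n_beneficiaries`` synthetic beneficiaries with the run
    seed.
    """

    out_dir: str = "claimscreen_run"
    seed: int = 0
    n_beneficiaries: int = 10_000
    base_path: str | None = None
    claims_path: str | None = None
    coefficients_path: str | None = None
    smoking_model_path: str | None = None
    window_mode: str = "to_reference"   # or "lagged"
    model_variant: str = "full"
    quality_mode: str = "any"
    hcpcs_excluded: bool = False
    write_data: bool = False

    def __post_init__(self) -> None:
        if self.window_mode not in ("to_reference", "lagged"):
            raise PipelineError(f"unknown window_mode {self.window_mode!r}")
        if self.model_variant not in MODEL_VARIANTS:
            raise PipelineError(f"unknown model_variant {self.model_variant!r}")
        if self.quality_mode not in QUALITY_MODES:
            raise PipelineError(f"unknown quality_mode {self.quality_mode!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as err:
                raise PipelineError(f"stage '{name}' failed: {err}") from err
        return wrapped
    return deco


def _load_models(config: RunConfig):
    if config.coefficients_path:
        coeffs = CoefficientSet.from_csv(config.coefficients_path)
    else:
        coeffs, _ = synthetic_full_coefficients()
    if config.smoking_model_path:
        smoking = CoefficientSet.from_csv(config.smoking_model_path)
    else:
        smoking = synthetic_smoking_model()
    return coeffs, smoking


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a result dict and writes reports.

    Result keys: ``cohort``, ``case_control``, ``scores``, ``validation``
    (ValidationReport), ``survival`` (SurvivalReport), ``table1``,
    ``incidence_per_100k``, ``person_years``, ``manifest``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    # -- data --------------------------------------------------------------
    if config.base_path and config.claims_path:
        base = _stage("read_base")(read_base_file)(config.base_path)
        claims = _stage("read_claims")(read_claims)(config.claims_path)
        truth = None
    else:
        sim = SimulationConfig(n_beneficiaries=config.n_beneficiaries, seed=config.seed)
        base, claims, truth = _stage("simulate")(generate_population)(sim)
        if config.write_data:
            write_base_file(base, out / "base.csv")
            write_claims(claims, out / "claims.csv")
    counts["beneficiaries"] = len(base)
    counts["claims"] = len(claims)
    log.info("data: %d beneficiaries, %d claims", len(base), len(claims))

    coeffs_full, smoking = _load_models(config)
    coeffs = build_model_variant(
        config.model_variant, coeffs_full, hcpcs_excluded=config.hcpcs_excluded
    )

    # -- ascertainment -----------------------------------------------------
    statuses = _stage("ascertain")(ascertain_all)(claims, base["beneficiary_id"])
    counts["ascertained_cases"] = int(statuses["is_case"].sum())

    # -- eligibility + cohort ---------------------------------------------
    elig = _stage("eligibility")(assess_eligibility_frame)(base, statuses, 2009)
    eligible = base[elig["eligible"].to_numpy()].reset_index(drop=True)
    counts["eligible"] = len(eligible)
    cohort = _stage("cohort")(build_cohort)(eligible, statuses)
    counts["cohort"] = len(cohort)
    py = person_years(cohort)
    n_pd = int((cohort["event"] == "pd").sum())
    counts["incident_pd"] = n_pd
    inc = incidence_rate(n_pd, py) if py > 0 else float("nan")
    log.info("cohort: %d rows, %.0f person-years, %d PD events (%.0f/100k py)",
             len(cohort), py, n_pd, inc)

    # -- nested case-control ----------------------------------------------
    ncc_seed = int((config.seed * 1_000_003 + 7) % (2**31))
    sample = _stage("case_control")(sample_nested_case_control)(cohort, ncc_seed)
    if config.quality_mode != "any":
        status_cases = case_quality_filter(statuses, config.quality_mode)
        keep_case = sample["beneficiary_id"].isin(status_cases["beneficiary_id"])
        sample = sample[~sample["is_case"] | keep_case].reset_index(drop=True)
    counts["ncc_cases"] = int(sample["is_case"].sum())
    counts["ncc_controls"] = int((~sample["is_case"]).sum())

    # -- scoring -----------------------------------------------------------
    scores = _stage("score")(score_sample)(
        base, claims, sample, coeffs, smoking,
        window_mode=config.window_mode, age_at="reference",
    )
    scores["is_case"] = sample["is_case"].to_numpy()

    # -- validation metrics ------------------------------------------------
    p_case = scores.loc[scores["is_case"], "probability"]
    p_ctrl = scores.loc[~scores["is_case"], "probability"]
    report = _stage("validate")(validation_report)(
        p_case, p_ctrl,
        label=f"{config.model_variant}/{config.window_mode}"
              f"{'/hcpcs_excluded' if config.hcpcs_excluded else ''}"
              f"/{config.quality_mode}",
    )

    # descriptive table ----------------------------------------------------
    demo = base.set_index("beneficiary_id").loc[
        sample["beneficiary_id"], ["birth_date", "sex", "race_ethnicity"]
    ].reset_index()
    age = (
        pd.to_datetime(sample["reference_date"]).to_numpy()
        - pd.to_datetime(demo["birth_date"]).to_numpy()
    ).astype("timedelta64[D]").astype(float) / DAYS_PER_YEAR
    tbl_input = pd.DataFrame({
        "is_case": sample["is_case"].to_numpy(),
        "age": age,
        "sex": demo["sex"].to_numpy(),
        "race_ethnicity": demo["race_ethnicity"].to_numpy(),
        "smoking_index": scores["smoking_probability"].to_numpy()
        / np.maximum(scores["n_unique_dx_codes"].to_numpy(), 1),
    })
    table1 = _stage("table1")(descriptive_table)(tbl_input)

    # -- survival ----------------------------------------------------------
    baseline_sample = cohort[["beneficiary_id"]].assign(
        reference_date=pd.Timestamp("2010-01-01")
    )
    baseline_scores = _stage("baseline_score")(score_sample)(
        base, claims, baseline_sample, coeffs, smoking,
        window_mode="lagged", age_at="baseline",
    )
    deciles, edges = _stage("deciles")(decile_assign)(
        baseline_scores["probability"].to_numpy()
    )
    surv = _stage("survival")(cox_fit)(cohort, deciles, edges)

    # -- outputs -----------------------------------------------------------
    cohort_out = cohort.copy()
    for col in ("entry_date", "exit_date"):
        cohort_out[col] = pd.to_datetime(cohort_out[col]).dt.strftime("%Y-%m-%d")
    cohort_out.to_csv(out / "cohort.csv", index=False)
    sample_out = sample.copy()
    sample_out["reference_date"] = pd.to_datetime(
        sample_out["reference_date"]).dt.strftime("%Y-%m-%d")
    sample_out.to_csv(out / "case_control.csv", index=False)
    scores.drop(columns=["reference_date"]).to_csv(out / "scores.csv", index=False)
    report.to_json(out / "validation.json")
    surv.to_json(out / "survival.json")
    table1.to_csv(out / "table1.csv", index=False)

    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "package": "claimscreen",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "counts": counts,
        "person_years": py,
        "incidence_per_100k": inc,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {
        "base": base,
        "claims": claims,
        "truth": truth,
        "statuses": statuses,
        "cohort": cohort,
        "case_control": sample,
        "scores": scores,
        "baseline_scores": baseline_scores,
        "validation": report,
        "survival": surv,
        "table1": table1,
        "person_years": py,
        "incidence_per_100k": inc,
        "manifest": manifest,
    }
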