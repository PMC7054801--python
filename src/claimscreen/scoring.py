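"""Risk scoring: coefficient sets, linear predictors, and model variants.

A :class:`CoefficientSet` holds the constant and named term coefficients of
a logistic risk model.  Term keys are either demographic/summary names
(``age_spline_1``, ``female``, ``race:black``, ``smoking_probability``,
``n_unique_dx_codes``) or ``"{code}:{system}"`` pairs for binary code
indicators.  Scoring is an exact dot product plus the constant; the
predicted probability is the inverse logit of the linear predictor.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "DEMOGRAPHIC_TERMS",
    "BASIC_MODEL_CODES",
    "MODEL_VARIANTS",
    "CoefficientSet",
    "RiskScore",
    "linear_predictor",
    "linear_predictor_frame",
    "predicted_probability",
    "build_model_variant",
]

#: Demographic / summary term names recognized in coefficient files.
DEMOGRAPHIC_TERMS = (
    "age_spline_1",
    "age_spline_2",
    "female",
    "race:black",
    "race:asian",
    "race:hispanic",
    "race:native_american",
    "race:pacific_islander_other",
    "smoking_probability",
    "n_unique_dx_codes",
)

#: Code terms of the simpler comparison model: constipation (ICD-9 564
#: family), REM sleep behavior disorder (327.42), anosmia/hyposmia (781.1).
BASIC_MODEL_CODES = (
    "564:ICD9_DX",
    "5640:ICD9_DX",
    "56400:ICD9_DX",
    "56401:ICD9_DX",
    "56402:ICD9_DX",
    "56409:ICD9_DX",
    "32742:ICD9_DX",
    "7811:ICD9_DX",
)

MODEL_VARIANTS = ("full", "basic", "basic_plus_codes_count", "age_only")


class ScoringError(ValueError):
    """A coefficient term cannot be resolved, or configuration is invalid."""


@dataclasses.dataclass(frozen=True)
class RiskScore:
    """A scored individual: linear predictor and its inverse-logit."""

    linear_predictor: float
    probability: float


@dataclasses.dataclass
class CoefficientSet:
    """Named model terms with coefficients plus a constant.

    Parameters
    ----------
    constant : float
        The model intercept, added once to every linear predictor.
    terms : dict
        Mapping from term key to coefficient.  Keys are unique by
        construction of the dict.
    label, provenance : str
        Free-text metadata carried through reports.
    """

    constant: float
    terms: dict[str, float]
    label: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.constant):
            raise ScoringError("constant term must be finite")
        self.terms = {str(k): float(v) for k, v in self.terms.items()}

    def __len__(self) -> int:
        return len(self.terms)

    def code_terms(self) -> list[str]:
        return [t for t in self.terms if t not in DEMOGRAPHIC_TERMS]

    def hcpcs_terms(self) -> list[str]:
        return [t for t in self.terms if t.endswith(":HCPCS")]

    def restricted(self, keep: Iterable[str], label: str = "") -> "CoefficientSet":
        """A copy keeping only the requested terms (constant retained)."""
        keep = set(keep)
        return CoefficientSet(
            constant=self.constant,
            terms={t: b for t, b in self.terms.items() if t in keep},
            label=label or self.label,
            provenance=self.provenance,
        )

    def with_zeroed(self, zero: Iterable[str], label: str = "") -> "CoefficientSet":
        """A copy with the named terms' contributions forced to zero."""
        zero = set(zero)
        return CoefficientSet(
            constant=self.constant,
            terms={t: (0.0 if t in zero else b) for t, b in self.terms.items()},
            label=label or self.label,
            provenance=self.provenance,
        )

    def scaled(self, factor: float, label: str = "") -> "CoefficientSet":
        """A copy with every non-constant coefficient multiplied by ``factor``."""
        return CoefficientSet(
            constant=self.constant,
            terms={t: factor * b for t, b in self.terms.items()},
            label=label or self.label,
            provenance=self.provenance,
        )

    # -- CSV round trip (columns: term, code_system, coefficient) ----------

    @classmethod
    def from_csv(cls, path, label: str = "") -> "CoefficientSet":
        from .claims_data import CODE_SYSTEMS, SchemaError, normalize_code

        df = pd.read_csv(
            Path(path), dtype={"term": str, "code_system": str},
            float_precision="round_trip",
        )
        for col in ("term", "code_system", "coefficient"):
            if col not in df.columns:
                raise SchemaError(f"{path}: missing mandatory column '{col}'")
        constant = None
        terms: dict[str, float] = {}
        for row in df.itertuples(index=False):
            system = str(row.code_system)
            if row.term == "constant":
                if constant is not None:
                    raise ScoringError(f"{path}: constant term appears twice")
                constant = float(row.coefficient)
            elif system == "demographic":
                terms[str(row.term)] = float(row.coefficient)
            elif system in CODE_SYSTEMS:
                key = f"{normalize_code(row.term, system)}:{system}"
                terms[key] = float(row.coefficient)
            else:
                raise SchemaError(f"{path}: unknown code_system {system!r}")
        if constant is None:
            raise ScoringError(f"{path}: coefficient file has no constant term")
        return cls(constant=constant, terms=terms, label=label or str(path),
                   provenance=str(path))

    def to_csv(self, path) -> None:
        rows = [("constant", "demographic", self.constant)]
        for term, beta in sorted(self.terms.items()):
            if term in DEMOGRAPHIC_TERMS:
                rows.append((term, "demographic", beta))
            else:
                code, system = term.rsplit(":", 1)
                rows.append((code, system, beta))
        pd.DataFrame(rows, columns=["term", "code_system", "coefficient"]).to_csv(
            path, index=False
        )


def linear_predictor(features: Mapping[str, float], coeffs: CoefficientSet) -> float:
    """``constant + sum(coefficient * feature)`` with exact dot-product semantics.

    Every coefficient term must be resolvable against the feature mapping;
    a missing feature raises :class:`ScoringError` naming the term rather
    than silently contributing zero.
    """
    missing = [t for t in coeffs.terms if t not in features]
    if missing:
        raise ScoringError(f"unresolvable coefficient term(s): {sorted(missing)[:8]}")
    return float(coeffs.constant) + float(
        sum(beta * float(features[t]) for t, beta in coeffs.terms.items())
    )


def linear_predictor_frame(design: pd.DataFrame, coeffs: CoefficientSet) -> pd.Series:
    """Vectorized linear predictor over a design matrix (rows = people)."""
    missing = [t for t in coeffs.terms if t not in design.columns]
    if missing:
        raise ScoringError(f"unresolvable coefficient term(s): {sorted(missing)[:8]}")
    if not coeffs.terms:
        return pd.Series(coeffs.constant, index=design.index, dtype=float)
    terms = list(coeffs.terms)
    beta = np.array([coeffs.terms[t] for t in terms], dtype=float)
    lp = design[terms].to_numpy(dtype=float) @ beta + coeffs.constant
    return pd.Series(lp, index=design.index)


def predicted_probability(lp):
    """Inverse-logit of a finite linear predictor; saturates without error.

    Accepts a scalar or array; raises for non-finite input.
    """
    arr = np.asarray(lp, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ScoringError("linear predictor must be finite")
    out = expit(arr)
    return float(out) if np.isscalar(lp) or arr.ndim == 0 else out


def score(features: Mapping[str, float], coeffs: CoefficientSet) -> RiskScore:
    lp = linear_predictor(features, coeffs)
    return RiskScore(linear_predictor=lp, probability=predicted_probability(lp))


def build_model_variant(
    variant: str,
    base_coeffs: CoefficientSet,
    hcpcs_excluded: bool = False,
) -> CoefficientSet:
    """Derive a comparison model from the full coefficient set.

    ``full``
        All terms (536 code indicators + demographics + smoking + the
        unique-diagnosis-code count in the shipped stand-in).
    ``basic``
        Demographics + smoking + the constipation / REM sleep behavior
        disorder / anosmia-hyposmia code indicators, without the
        unique-code count.
    ``basic_plus_codes_count``
        ``basic`` plus the unique-code count.
    ``age_only``
        The two age-spline terms and the constant.

    ``hcpcs_excluded`` zeroes the contribution of every HCPCS code term
    (their value is assumed zero), modelling transport to claims systems
    without HCPCS coding.
    """
    if variant not in MODEL_VARIANTS:
        raise ScoringError(
            f"unknown model variant {variant!r}; expected one of {MODEL_VARIANTS}"
        )
    if variant == "full":
        out = CoefficientSet(
            base_coeffs.constant, dict(base_coeffs.terms),
            label="full", provenance=base_coeffs.provenance,
        )
    elif variant == "age_only":
        keep = {"age_spline_1", "age_spline_2"}
        _require_terms(base_coeffs, keep, variant)
        out = base_coeffs.restricted(keep, label="age_only")
    else:
        keep = {t for t in DEMOGRAPHIC_TERMS if t != "n_unique_dx_codes"}
        keep |= set(BASIC_MODEL_CODES) & set(base_coeffs.terms)
        if variant == "basic_plus_codes_count":
            keep.add("n_unique_dx_codes")
        _require_terms(
            base_coeffs, {"age_spline_1", "age_spline_2"}, variant
        )
        out = base_coeffs.restricted(keep, label=variant)
    if hcpcs_excluded:
        out = out.with_zeroed(out.hcpcs_terms(), label=out.label + "+hcpcs_excluded")
    return out


def _require_terms(coeffs: CoefficientSet, needed: set[str], variant: str) -> None:
    missing = needed - set(coeffs.terms)
    if missing:
        raise ScoringError(
            f"base coefficients missing term(s) {sorted(missing)} for variant {variant!r}"
        )
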