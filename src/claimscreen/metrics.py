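"""Validation metrics on the nested case-control sample.

AUC is the concordance probability P(score_case > score_control) with
ties counted 1/2, identical to Mann-Whitney U / (n1*n0); its confidence
interval uses the DeLong placement-variance method.  The operating point
is the threshold that balances sensitivity and specificity (not the one
maximizing accuracy, since non-cases dominate).  Crude odds ratios come
from the closed-form 2x2 table with Woolf (log-scale) intervals; mutually
adjusted odds ratios come from a maximum-likelihood logistic fit.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "ValidationReport",
    "ContingencyTable2x2",
    "auc",
    "balanced_cutpoint",
    "classification_at",
    "mean_prob_difference",
    "odds_ratio",
    "fit_multivariable_logistic",
    "validation_report",
    "descriptive_table",
]


class MetricsError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class ContingencyTable2x2:
    """Exposure-by-outcome counts: a/b exposed/unexposed cases, c/d
    exposed/unexposed controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise MetricsError("contingency counts must be non-negative")


@dataclasses.dataclass
class ValidationReport:
    """Discrimination summary of a scored case-control sample."""

    auc: float
    auc_ci: tuple[float, float]
    cutpoint: float
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    accuracy: float
    mean_prob_difference: float
    n_cases: int
    n_controls: int
    label: str = ""

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["auc_ci"] = list(d["auc_ci"])
        d["sensitivity_ci"] = list(d["sensitivity_ci"])
        d["specificity_ci"] = list(d["specificity_ci"])
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def summary(self) -> str:
        lines = [
            f"Validation report{f' [{self.label}]' if self.label else ''}",
            f"  cases / controls       {self.n_cases:>8,} / {self.n_controls:,}",
            f"  AUC                    {100 * self.auc:6.1f}%  "
            f"(95% CI {100 * self.auc_ci[0]:.1f}%-{100 * self.auc_ci[1]:.1f}%)",
            f"  balanced cut point     {self.cutpoint:8.5f}",
            f"  sensitivity            {100 * self.sensitivity:6.1f}%  "
            f"(95% CI {100 * self.sensitivity_ci[0]:.1f}%-{100 * self.sensitivity_ci[1]:.1f}%)",
            f"  specificity            {100 * self.specificity:6.1f}%  "
            f"(95% CI {100 * self.specificity_ci[0]:.1f}%-{100 * self.specificity_ci[1]:.1f}%)",
            f"  accuracy               {100 * self.accuracy:6.1f}%",
            f"  mean prob. difference  {self.mean_prob_difference:8.4f}",
        ]
        return "\n".join(lines)


def _as_groups(scores_cases, scores_controls):
    x = np.asarray(scores_cases, dtype=float)
    y = np.asarray(scores_controls, dtype=float)
    if x.size == 0 or y.size == 0:
        raise MetricsError("both case and control score groups must be non-empty")
    return x, y


def _midrank_placements(x: np.ndarray, y: np.ndarray):
    """DeLong placement values V10 (cases) and V01 (controls)."""
    m, n = x.size, y.size
    combined = np.concatenate([x, y])
    r = scipy.stats.rankdata(combined)
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    v10 = (r[:m] - rx) / n          # per-case fraction of controls beaten
    v01 = 1.0 - (r[m:] - ry) / m    # per-control fraction of cases beating it... inverted below
    return v10, v01


def auc(scores_cases, scores_controls, alpha: float = 0.05):
    """Concordance AUC with a DeLong confidence interval.

    Returns ``(auc, (low, high))``; the CI is clipped to [0, 1] and
    degenerates to the point estimate when the DeLong variance is zero
    (perfect separation).
    """
    x, y = _as_groups(scores_cases, scores_controls)
    v10, v01 = _midrank_placements(x, y)
    a = float(v10.mean())
    # v01 as computed above equals P(case > this control) (ties 1/2)
    s10 = v10.var(ddof=1) if x.size > 1 else 0.0
    s01 = v01.var(ddof=1) if y.size > 1 else 0.0
    var = s10 / x.size + s01 / y.size
    z = scipy.stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    return a, (max(a - half, 0.0), min(a + half, 1.0))


def mean_prob_difference(scores_cases, scores_controls) -> float:
    """Difference in mean predicted probability, cases minus controls."""
    x, y = _as_groups(scores_cases, scores_controls)
    return float(x.mean() - y.mean())


def _sens_spec(threshold: float, x: np.ndarray, y: np.ndarray):
    sens = float((x >= threshold).mean())
    spec = float((y < threshold).mean())
    return sens, spec


def balanced_cutpoint(scores_cases, scores_controls) -> float:
    """Threshold minimizing |sensitivity - specificity|.

    Candidates are midpoints of adjacent distinct pooled scores plus one
    sentinel below the minimum and one above the maximum (scores >=
    threshold classify positive).  Ties in balance are broken by larger
    sensitivity + specificity, then by the smaller threshold.
    """
    x, y = _as_groups(scores_cases, scores_controls)
    distinct = np.unique(np.concatenate([x, y]))
    candidates = np.concatenate(
        [[distinct[0] - 1.0], (distinct[:-1] + distinct[1:]) / 2.0, [distinct[-1] + 1.0]]
    )
    best = None
    for t in candidates:
        sens, spec = _sens_spec(t, x, y)
        key = (abs(sens - spec), -(sens + spec), t)
        if best is None or key < best[0]:
            best = (key, t)
    return float(best[1])


def classification_at(threshold: float, scores_cases, scores_controls, alpha=0.05):
    """Sensitivity, specificity and accuracy at a threshold, with Wilson CIs.

    Returns ``(sensitivity, specificity, accuracy, sens_ci, spec_ci)``;
    scores >= threshold classify positive.
    """
    if not np.isfinite(threshold):
        raise MetricsError("threshold must be finite")
    x, y = _as_groups(scores_cases, scores_controls)
    tp = int((x >= threshold).sum())
    tn = int((y < threshold).sum())
    sens = tp / x.size
    spec = tn / y.size
    accuracy = (tp + tn) / (x.size + y.size)
    sens_ci = proportion_confint(tp, x.size, alpha=alpha, method="wilson")
    spec_ci = proportion_confint(tn, y.size, alpha=alpha, method="wilson")
    return sens, spec, accuracy, tuple(map(float, sens_ci)), tuple(map(float, spec_ci))


def validation_report(scores_cases, scores_controls, label: str = "") -> ValidationReport:
    """Full discrimination report at the balanced cut point."""
    x, y = _as_groups(scores_cases, scores_controls)
    a, ci = auc(x, y)
    t = balanced_cutpoint(x, y)
    sens, spec, acc, sens_ci, spec_ci = classification_at(t, x, y)
    return ValidationReport(
        auc=a, auc_ci=ci, cutpoint=t,
        sensitivity=sens, sensitivity_ci=sens_ci,
        specificity=spec, specificity_ci=spec_ci,
        accuracy=acc,
        mean_prob_difference=mean_prob_difference(x, y),
        n_cases=int(x.size), n_controls=int(y.size), label=label,
    )


def odds_ratio(table: ContingencyTable2x2, alpha: float = 0.05):
    """Crude odds ratio (a*d)/(b*c) with a Woolf log-scale CI.

    With any zero cell the point estimate may still be defined (when
    b*c > 0) but the CI is returned as (nan, nan); no continuity
    correction is applied.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if b * c == 0:
        raise MetricsError("odds ratio undefined: zero unexposed-case or exposed-control cell")
    point = (a * d) / (b * c)
    if min(a, b, c, d) == 0:
        return point, (float("nan"), float("nan"))
    z = scipy.stats.norm.ppf(1 - alpha / 2)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(point) - z * se), np.exp(np.log(point) + z * se)
    return float(point), (float(lo), float(hi))


def fit_multivariable_logistic(design: pd.DataFrame, labels, alpha: float = 0.05):
    """Maximum-likelihood logistic regression for mutually adjusted ORs.

    ``design`` holds one column per covariate (an intercept is added);
    ``labels`` is the binary outcome.  Returns a DataFrame indexed by
    term with ``coef``, ``se``, ``or``, ``ci_low``, ``ci_high``.  Raises
    :class:`MetricsError` on rank deficiency or separation.
    """
    X = pd.DataFrame(design).astype(float)
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise MetricsError("labels must be binary")
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        raise MetricsError(
            "design matrix is rank deficient (constant or collinear covariate)"
        )
    try:
        fit = sm.Logit(y, Xc).fit(method="newton", tol=1e-8, maxiter=100, disp=0)
    except (PerfectSeparationError, np.linalg.LinAlgError) as err:
        raise MetricsError(f"logistic fit failed (separation?): {err}") from err
    if not fit.mle_retvals.get("converged", True):
        raise MetricsError("logistic fit did not converge (possible separation)")
    ci = fit.conf_int(alpha=alpha)
    out = pd.DataFrame(
        {
            "coef": fit.params,
            "se": fit.bse,
            "or": np.exp(fit.params),
            "ci_low": np.exp(ci[0]),
            "ci_high": np.exp(ci[1]),
        }
    )
    return out


# ---------------------------------------------------------------------------
# Descriptive case/control table


AGE_BANDS = ((66, 70), (70, 75), (75, 80), (80, 85), (85, 91))


def descriptive_table(sample: pd.DataFrame) -> pd.DataFrame:
    """Case/control counts and crude + adjusted ORs by characteristic.

    ``sample`` needs ``is_case``, ``age``, ``sex``, ``race_ethnicity``
    and ``smoking_index``.  Rows: age bands (66-69 reference), female
    (male reference), race categories (white reference; unknown folded
    into Pacific Islander / other), and smoking index >= sample median.
    """
    s = sample.copy()
    s["race_ethnicity"] = s["race_ethnicity"].replace(
        {"unknown": "pacific_islander_other"}
    )
    median_idx = float(s["smoking_index"].median())
    s["smoking_hi"] = s["smoking_index"] >= median_idx

    design = pd.DataFrame(index=s.index)
    rows = []

    def add_row(label, exposed_mask, reference_mask, colname):
        a = int((exposed_mask & s["is_case"]).sum())
        b = int((reference_mask & s["is_case"]).sum())
        c = int((exposed_mask & ~s["is_case"]).sum())
        d = int((reference_mask & ~s["is_case"]).sum())
        try:
            point, (lo, hi) = odds_ratio(ContingencyTable2x2(a, b, c, d))
        except MetricsError:
            point, lo, hi = float("nan"), float("nan"), float("nan")
        rows.append(
            {"characteristic": label, "cases": a, "controls": c,
             "or": point, "ci_low": lo, "ci_high": hi}
        )
        if colname is not None:
            design[colname] = exposed_mask.astype(float)

    age_ref = (s["age"] >= 66) & (s["age"] < 70)
    for lo_a, hi_a in AGE_BANDS[1:]:
        mask = (s["age"] >= lo_a) & (s["age"] < hi_a)
        add_row(f"age_{lo_a}_{hi_a - 1}", mask, age_ref, f"age_{lo_a}_{hi_a - 1}")
    add_row("female", s["sex"] == "female", s["sex"] == "male", "female")
    race_ref = s["race_ethnicity"] == "white"
    for cat in ("black", "pacific_islander_other", "asian", "hispanic", "native_american"):
        add_row(cat, s["race_ethnicity"] == cat, race_ref, f"race_{cat}")
    add_row("smoking_index_ge_median", s["smoking_hi"], ~s["smoking_hi"], "smoking_hi")

    table = pd.DataFrame(rows)
    try:
        adj = fit_multivariable_logistic(design, s["is_case"].astype(float))
        adj = adj.drop(index="const")
        mapping = dict(zip(design.columns, adj.index))
        table["adj_or"] = [
            adj.loc[mapping[c], "or"] if c in mapping else np.nan
            for c in list(design.columns)
        ]
        table["adj_ci_low"] = [adj.loc[mapping[c], "ci_low"] for c in design.columns]
        table["adj_ci_high"] = [adj.loc[mapping[c], "ci_high"] for c in design.columns]
    except MetricsError:
        table["adj_or"] = np.nan
        table["adj_ci_low"] = np.nan
        table["adj_ci_high"] = np.nan
    return table
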