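"""Baseline-probability deciles and Cox proportional-hazards analysis.

The cohort's baseline predicted probabilities are cut at their 10%-90%
sample quantiles into deciles; time to PD diagnosis is modelled with a Cox
proportional-hazards regression on nine decile indicators (decile 1 is the
reference, hazard ratio 1 by definition).  Death, censoring at the first
excluded diagnosis, and administrative end of follow-up are treated as
right-censoring.  Ties are handled with the Efron approximation; the
proportional-hazards assumption is tested with scaled Schoenfeld
residuals against ranked time.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import proportional_hazard_test

__all__ = [
    "SurvivalReport",
    "decile_assign",
    "cox_fit",
    "fit_grouped_cox",
    "schoenfeld_test",
]


class SurvivalError(ValueError):
    pass


@dataclasses.dataclass
class SurvivalReport:
    """Cox decile analysis results.

    ``hr_by_decile`` maps decile label (1-10) to ``(hr, lo, hi)``;
    decile 1 is the reference with HR exactly 1.  ``unstable`` lists
    deciles whose CI is untrustworthy (no events).
    """

    decile_edges: list[float]
    hr_by_decile: dict[int, tuple[float, float, float]]
    n_events_by_decile: dict[int, int]
    global_p: float
    ph_test_p: float
    unstable: list[int]

    def to_dict(self) -> dict:
        return {
            "decile_edges": list(map(float, self.decile_edges)),
            "hr_by_decile": {str(k): list(map(float, v)) for k, v in self.hr_by_decile.items()},
            "n_events_by_decile": {str(k): int(v) for k, v in self.n_events_by_decile.items()},
            "global_p": float(self.global_p),
            "ph_test_p": float(self.ph_test_p),
            "unstable": list(self.unstable),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def summary(self) -> str:
        lines = ["Cox decile analysis (decile 1 = reference)"]
        for k in sorted(self.hr_by_decile):
            hr, lo, hi = self.hr_by_decile[k]
            star = "  [unstable]" if k in self.unstable else ""
            lines.append(
                f"  decile {k:>2}: HR {hr:7.2f} (95% CI {lo:6.2f}-{hi:6.2f}),"
                f" events {self.n_events_by_decile.get(k, 0):>5}{star}"
            )
        lines.append(f"  global LR p = {self.global_p:.3g}")
        lines.append(f"  Schoenfeld PH test p = {self.ph_test_p:.3g}")
        return "\n".join(lines)


def decile_assign(values):
    """Assign decile labels 1-10 by the 10%..90% sample quantiles.

    Returns ``(labels, edges)`` where ``edges`` are the nine interior
    quantiles and label ``k`` means ``edges[k-2] < value <= edges[k-1]``
    (ties share the lower decile of their value).  Requires at least 10
    distinct values.
    """
    v = np.asarray(values, dtype=float)
    if np.unique(v).size < 10:
        raise SurvivalError(
            f"need >=10 distinct values to form deciles, got {np.unique(v).size}"
        )
    edges = np.quantile(v, np.arange(1, 10) / 10.0)
    labels = 1 + np.searchsorted(edges, v, side="left")
    return labels.astype(int), edges


def fit_grouped_cox(durations, events, groups, reference=None, alpha=0.05):
    """Cox PH fit on group indicators relative to a reference group.

    Returns ``(hr_table, fitter, df)``: hr_table maps group label to
    ``(hr, lo, hi, n_events, unstable)``; the reference group has HR 1.
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    if events.sum() == 0:
        raise SurvivalError("no events; Cox model is not estimable")
    labels = np.unique(groups)
    if reference is None:
        reference = labels[0]

    df = pd.DataFrame({"T": durations, "E": events.astype(int)})
    cols = []
    for g in labels:
        if g == reference:
            continue
        col = f"g_{g}"
        df[col] = (groups == g).astype(float)
        cols.append((g, col))

    cph = CoxPHFitter(alpha=alpha)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="T", event_col="E")

    events_by_group = {
        g: int(events[groups == g].sum()) for g in labels
    }
    ci = cph.confidence_intervals_
    table = {reference: (1.0, 1.0, 1.0, events_by_group[reference], False)}
    with np.errstate(over="ignore"):
        exp_ci = np.exp(np.clip(ci.to_numpy(dtype=float), -700, 700))
    for g, col in cols:
        hr = float(np.exp(cph.params_[col]))
        lo, hi = (float(v) for v in exp_ci[list(ci.index).index(col)])
        unstable = events_by_group[g] == 0 or not np.isfinite(
            cph.standard_errors_[col]
        ) or cph.standard_errors_[col] > 50
        table[g] = (hr, lo, hi, events_by_group[g], bool(unstable))
    return table, cph, df


def cox_fit(cohort: pd.DataFrame, deciles, edges=None) -> SurvivalReport:
    """Decile-indicator Cox model for time to PD on a cohort table.

    ``cohort`` needs ``follow_up_years`` and ``event`` (event type
    strings; ``pd`` is the event, all else right-censoring); ``deciles``
    are the per-row labels from :func:`decile_assign`.
    """
    durations = cohort["follow_up_years"].to_numpy(dtype=float)
    # zero-length follow-up breaks partial likelihood ordering; nudge by half a day
    durations = np.maximum(durations, 0.5 / 365.25)
    events = (cohort["event"] == "pd").to_numpy()
    table, cph, df = fit_grouped_cox(durations, events, np.asarray(deciles), reference=1)

    lr = cph.log_likelihood_ratio_test()
    ph_p = schoenfeld_test(cph, df)
    return SurvivalReport(
        decile_edges=[] if edges is None else list(map(float, edges)),
        hr_by_decile={int(g): (v[0], v[1], v[2]) for g, v in table.items()},
        n_events_by_decile={int(g): v[3] for g, v in table.items()},
        global_p=float(lr.p_value),
        ph_test_p=float(ph_p),
        unstable=sorted(int(g) for g, v in table.items() if v[4]),
    )


def schoenfeld_test(fitter: CoxPHFitter, df: pd.DataFrame) -> float:
    """Proportional-hazards p-value from scaled Schoenfeld residuals.

    Score test of zero slope of the scaled residuals against ranked event
    time, per covariate.  For a single covariate this is the usual
    Schoenfeld test; with several covariates the reported global p is the
    Bonferroni-adjusted minimum (conservative).
    """
    if df["E"].sum() == 0:
        raise SurvivalError("no events; Schoenfeld test undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = proportional_hazard_test(fitter, df, time_transform="rank")
    pvals = np.atleast_1d(np.asarray(res.summary["p"], dtype=float))
    return float(min(1.0, np.nanmin(pvals) * pvals.size))
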