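"""Feature extraction: splines, smoking rule, code indicators, windows."""

import numpy as np
import pandas as pd
import pytest

from claimscreen.claims_data import CodeList
from claimscreen.predictors import (
    Window,
    age_splines,
    count_unique_dx,
    extract_features,
    lagged_window,
    reference_window,
    score_sample,
    smoking_index,
    smoking_probability,
)
from claimscreen.scoring import CoefficientSet, linear_predictor
from claimscreen.synthetic_data import synthetic_full_coefficients, synthetic_smoking_model
from conftest import make_claims


@pytest.mark.parametrize("age, expected", [(70, (70, 0)), (85, (85, 0)), (90, (85, 5))])
def test_age_splines_knot_at_85(age, expected):
    assert age_splines(age) == expected
    assert sum(age_splines(age)) == age


def test_age_splines_reject_nonpositive_age():
    with pytest.raises(ValueError):
        age_splines(0)


class TestSmokingProbability:
    def test_tobacco_specific_code_forces_certainty(self):
        events = make_claims([("B1", "2008-01-01", "V15.82", "ICD9_DX")])
        events["code"] = "V1582"  # make_claims doesn't normalize
        model = CoefficientSet(constant=-5.0, terms={})
        assert smoking_probability(events, model) == 1.0

    def test_constant_zero_model_gives_half(self):
        model = CoefficientSet(constant=0.0, terms={})
        assert smoking_probability(make_claims([]), model) == 0.5

    def test_single_indicator_matches_hand_computed_logistic(self):
        model = CoefficientSet(constant=-0.7, terms={"496:ICD9_DX": 1.1})
        events = make_claims([("B1", "2008-01-01", "496", "ICD9_DX")])
        expected = 1.0 / (1.0 + np.exp(-(-0.7 + 1.1)))
        assert smoking_probability(events, model) == pytest.approx(expected, abs=1e-12)
        assert smoking_probability(make_claims([]), model) == pytest.approx(
            1.0 / (1.0 + np.exp(0.7)), abs=1e-12
        )


@pytest.mark.parametrize(
    "prob, n, expected", [(0.6, 3, 0.2), (0.8, 0, 0.8), (0.0, 7, 0.0)]
)
def test_smoking_index_divides_by_at_least_one(prob, n, expected):
    assert smoking_index(prob, n) == pytest.approx(expected)


def test_count_unique_dx_distinct_diagnosis_codes_only():
    events = make_claims([
        ("B1", "2008-01-01", "4019", "ICD9_DX"),
        ("B1", "2008-02-01", "4019", "ICD9_DX"),
        ("B1", "2008-03-01", "5640", "ICD9_DX"),
        ("B1", "2008-04-01", "70551", "CPT"),
    ])
    assert count_unique_dx(events) == 2
    assert count_unique_dx(make_claims([("B1", "2008-04-01", "70551", "CPT")])) == 0
    assert count_unique_dx(make_claims([])) == 0


def test_pd_definition_codes_never_enter_predictors():
    events = make_claims([("B1", "2008-01-01", "3320", "ICD9_DX")])
    assert count_unique_dx(events) == 0


class TestExtractFeatures:
    bene = pd.Series({
        "birth_date": pd.Timestamp("1938-06-15"), "sex": "female",
        "race_ethnicity": "black",
    })
    code_list = CodeList([("5640", "ICD9_DX", "constipation"), ("70551", "CPT", "mri")])
    smoking = CoefficientSet(constant=-0.5, terms={})

    def _features(self, events, window):
        return extract_features(
            self.bene, events, window, self.code_list, self.smoking,
            age_at=pd.Timestamp("2012-06-01"),
        )

    def test_window_membership_controls_indicators(self):
        events = make_claims([("B1", "2010-06-01", "5640", "ICD9_DX")])
        lag = self._features(events, lagged_window())
        unlag = self._features(events, reference_window("2010-12-31"))
        assert lag["5640:ICD9_DX"] == 0.0 and lag["n_unique_dx_codes"] == 0.0
        assert unlag["5640:ICD9_DX"] == 1.0 and unlag["n_unique_dx_codes"] == 1.0

    def test_empty_record_gives_zero_indicators(self):
        f = self._features(make_claims([]), lagged_window())
        assert f["5640:ICD9_DX"] == 0.0 and f["70551:CPT"] == 0.0
        assert f["n_unique_dx_codes"] == 0.0
        assert f["female"] == 1.0 and f["race:black"] == 1.0

    def test_enlarging_window_never_drops_indicators(self):
        rng = np.random.default_rng(5)
        dates = pd.Timestamp("2004-06-01") + pd.to_timedelta(
            rng.integers(0, 3650, 30), unit="D")
        codes = rng.choice(["5640", "4019", "70551"], 30)
        systems = np.where(codes == "70551", "CPT", "ICD9_DX")
        events = make_claims(list(zip(["B1"] * 30, dates, codes, systems)))
        small = self._features(events, reference_window("2008-12-31"))
        big = self._features(events, reference_window("2012-12-31"))
        ind = [k for k in small.index if ":" in k and not k.startswith("race")]
        assert (big[ind] >= small[ind]).all()
        assert big["n_unique_dx_codes"] >= small["n_unique_dx_codes"]

    def test_invariant_to_event_order_and_duplication(self):
        events = make_claims([
            ("B1", "2008-01-01", "5640", "ICD9_DX"),
            ("B1", "2009-01-01", "70551", "CPT"),
        ])
        doubled = pd.concat([events, events.iloc[::-1]], ignore_index=True)
        f1 = self._features(events, lagged_window())
        f2 = self._features(doubled, lagged_window())
        pd.testing.assert_series_equal(f1, f2)


def test_bulk_scoring_matches_per_person_route(small_population):
    """The merge-based bulk scorer equals feature extraction + dot product."""
    base, claims, _ = small_population
    coeffs, code_frame = synthetic_full_coefficients()
    code_list = CodeList(
        list(code_frame.itertuples(index=False, name=None)), label="model codes"
    )
    smoking = synthetic_smoking_model()
    rng = np.random.default_rng(0)
    ids = rng.choice(base["beneficiary_id"], size=80, replace=False)
    refs = pd.Timestamp("2010-01-01") + pd.to_timedelta(
        rng.integers(30, 1800, size=80), unit="D")
    sample = pd.DataFrame({"beneficiary_id": ids, "reference_date": refs})

    for mode in ("to_reference", "lagged"):
        bulk = score_sample(base, claims, sample, coeffs, smoking, window_mode=mode)
        indexed = base.set_index("beneficiary_id")
        by_bene = dict(tuple(claims.groupby("beneficiary_id")))
        for i, (bid, ref) in enumerate(zip(ids, refs)):
            window = lagged_window() if mode == "lagged" else reference_window(ref)
            events = by_bene.get(bid, claims.iloc[0:0])
            feats = extract_features(
                indexed.loc[bid], events, window, code_list, smoking, age_at=ref
            )
            lp = linear_predictor(feats, coeffs)
            assert bulk["linear_predictor"].iloc[i] == pytest.approx(lp, abs=1e-9)
            assert bulk["smoking_probability"].iloc[i] == pytest.approx(
                feats["smoking_probability"], abs=1e-12)
            assert bulk["n_unique_dx_codes"].iloc[i] == feats["n_unique_dx_codes"]
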