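"""Biomarker pipeline: eligibility, imputation, elimination projection,
increment, sub-sample selection and the PM-equivalent conversion."""

from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shsexposure.cotinine import (
    CotinineRecord,
    RosettaParams,
    TKParams,
    cohort_summaries,
    cotinine_delta,
    delta_to_pm_equivalent,
    eligibility_filter,
    estimate_exposures,
    impute_cotinine_lod,
    predict_post_shift,
    select_subsample,
)

T0 = datetime(2016, 11, 7, 7, 30)


def _rec(pid="W1", pre=0.4, post=0.5, hours=8.0, **kw):
    pre_cens = pre is None
    post_cens = post is None
    return CotinineRecord(
        participant_id=pid,
        prison_id=kw.pop("prison", "P1"),
        pre_time=T0,
        post_time=T0 + timedelta(hours=hours),
        pre_value=pre,
        post_value=post,
        pre_censored=pre_cens,
        post_censored=post_cens,
        **kw,
    )


class TestEligibility:
    def test_empty_input(self):
        kept, tallies = eligibility_filter([])
        assert kept == [] and sum(tallies.values()) == 0

    def test_each_rule_tallied(self):
        records = [
            _rec("ok"),
            _rec("smoker", smoker=True),
            _rec("cohab", smoking_cohabitant=True),
            _rec("novalid", valid_post=False),
            _rec("heavy", pre=6.0, post=7.0),
        ]
        kept, tallies = eligibility_filter(records)
        assert [r.participant_id for r in kept] == ["ok"]
        assert tallies == {"questionnaire": 2, "invalid_sample": 1, "over_cutoff": 1}

    def test_boundary_value_retained(self):
        # the smoker rule is strictly "> 5 ng/ml": equality stays in
        kept, _ = eligibility_filter([_rec(post=5.0)])
        assert len(kept) == 1

    def test_non_increasing_times_invalid(self):
        rec = _rec(hours=-1.0)
        kept, tallies = eligibility_filter([rec])
        assert not kept and tallies["invalid_sample"] == 1

    @given(
        st.lists(
            st.tuples(st.booleans(), st.booleans(), st.floats(0.1, 10.0)),
            max_size=40,
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_tallies_partition_input(self, specs):
        records = [
            _rec(f"W{i}", pre=v, post=v, smoker=s, valid_pre=ok)
            for i, (s, ok, v) in enumerate(specs)
        ]
        kept, tallies = eligibility_filter(records)
        assert len(kept) + sum(tallies.values()) == len(records)


class TestImputation:
    def test_censored_to_half_lod(self):
        assert impute_cotinine_lod([None])[0] == pytest.approx(0.05)

    def test_detect_unchanged(self):
        assert impute_cotinine_lod([0.155])[0] == 0.155

    def test_cohort_counts(self):
        values = [None] * 139 + [0.2] * 268
        out = impute_cotinine_lod(values)
        assert int((out == 0.05).sum()) == 139


class TestElimination:
    def test_zero_elapsed_identity(self):
        assert predict_post_shift(0.7, 0.0, TKParams()) == 0.7

    def test_one_half_life(self):
        assert predict_post_shift(1.0, 16.0, TKParams(half_life=16.0)) == pytest.approx(0.5)

    def test_closed_form_eight_hours(self):
        # 0.4 × 2^(−8/16) = 0.4/√2
        assert predict_post_shift(0.4, 8.0, TKParams(half_life=16.0)) == pytest.approx(
            0.4 * 2 ** -0.5
        )

    def test_negative_elapsed_rejected(self):
        with pytest.raises(ValueError):
            predict_post_shift(0.4, -1.0, TKParams())

    @given(
        st.floats(0.01, 5.0),
        st.floats(0.0, 24.0),
        st.floats(0.0, 24.0),
    )
    @settings(deadline=None, max_examples=100)
    def test_semigroup_property(self, pre, t1, t2):
        tk = TKParams()
        direct = predict_post_shift(pre, t1 + t2, tk)
        staged = predict_post_shift(predict_post_shift(pre, t1, tk), t2, tk)
        assert staged == pytest.approx(direct, rel=1e-12)


class TestDelta:
    @pytest.mark.parametrize(
        "measured,predicted,expected",
        [(0.5, 0.362, 0.138), (0.3, 0.3, 0.0), (0.1, 0.975, -0.875)],
    )
    def test_sign_preserving_subtraction(self, measured, predicted, expected):
        assert cotinine_delta(measured, predicted) == pytest.approx(expected)


class TestSubsample:
    def test_censored_pre_excluded(self):
        est = estimate_exposures([_rec(pre=None, post=0.5)], TKParams())
        assert select_subsample(est) == []

    def test_predicted_below_lod_excluded(self):
        # pre 0.11 over a long gap decays below the 0.1 ng/ml LOD
        est = estimate_exposures([_rec(pre=0.11, post=0.5, hours=16.0)], TKParams())
        assert est[0].predicted_post < 0.1
        assert select_subsample(est) == []

    def test_qualifying_record_kept_with_delta(self):
        est = estimate_exposures([_rec(pre=0.4, post=0.5, hours=8.0)], TKParams())
        sub = select_subsample(est)
        assert len(sub) == 1
        assert sub[0].delta == pytest.approx(0.5 - 0.4 * 2**-0.5)

    def test_constructed_cohort_of_149_qualifiers(self):
        # 149 workers with pre well above LOD, plus censored-pre and
        # short-projection workers that the selection rules must reject
        records = (
            [_rec(f"q{i}", pre=0.4, post=0.5) for i in range(149)]
            + [_rec(f"c{i}", pre=None, post=0.5) for i in range(30)]
            + [_rec(f"l{i}", pre=0.11, post=0.2, hours=16.0) for i in range(20)]
        )
        sub = select_subsample(estimate_exposures(records, TKParams()))
        assert len(sub) == 149


class TestPMEquivalent:
    def test_zero_delta_zero_pm(self):
        assert delta_to_pm_equivalent(0.0, 8.0, RosettaParams()) == 0.0

    def test_linearity(self):
        r = RosettaParams()
        one = delta_to_pm_equivalent(0.1, 8.0, r)
        assert delta_to_pm_equivalent(0.2, 8.0, r) == pytest.approx(2 * one)

    def test_cohort_median_increment_maps_to_survey_estimate(self):
        r = RosettaParams()
        pm = delta_to_pm_equivalent(0.138, r.representative_shift_h, r)
        assert pm == pytest.approx(24.8, rel=0.05)

    def test_nonpositive_elapsed_rejected(self):
        with pytest.raises(ValueError):
            delta_to_pm_equivalent(0.1, 0.0, RosettaParams())


class TestCohortSummaries:
    def test_all_censored_prison_median_is_half_lod(self):
        records = [_rec(f"W{i}", pre=0.2, post=None) for i in range(5)]
        table, _ = cohort_summaries(records)
        assert table.iloc[0]["median"] == pytest.approx(0.05)

    def test_singleton_prison_quantiles_collapse(self):
        table, _ = cohort_summaries([_rec(post=0.2)])
        row = table.iloc[0]
        assert row["p25"] == row["median"] == row["p75"] == 0.2

    def test_gm_gsd_recovered_at_cohort_size(self):
        rng = np.random.default_rng(7)
        vals = rng.lognormal(np.log(0.145), np.log(2.48), 407)
        records = [_rec(f"W{i}", pre=0.2, post=float(v)) for i, v in enumerate(vals)]
        _, (gm, gsd) = cohort_summaries(records)
        assert gm == pytest.approx(0.145, rel=0.15)
        assert gsd == pytest.approx(2.48, rel=0.15)
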