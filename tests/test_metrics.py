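"""Search-report metrics: Inf, %dH(DV), dBIC/dAIC, G^2, %Correct, %Cover."""

import numpy as np
import pytest
from scipy import stats

import rascube as rc
from rascube.metrics import (
    MetricRow,
    information_captured,
    information_criteria,
    lr_significance,
    pct_correct,
    pct_cover,
    pct_delta_h_dv,
)

from conftest import make_dataset, random_dataset

ABCD = ("A", "B", "C", "Z")


@pytest.fixture
def fits(abcz):
    def fit(name):
        return rc.RAModel(abcz, name).fit(tol=1e-10, max_iter=50000)

    return fit


@pytest.fixture
def bottom(fits):
    return fits("IV:Z")


class TestInformation:
    def test_bottom_is_zero(self, abcz, fits, bottom):
        assert information_captured(abcz, bottom, bottom) == pytest.approx(0.0, abs=1e-9)

    def test_saturated_is_one(self, abcz, fits, bottom):
        top = fits("IV:ABCZ")
        assert information_captured(abcz, top, bottom) == pytest.approx(1.0, abs=1e-9)

    def test_monotone_under_nesting(self, abcz, fits, bottom):
        chain = ["IV:Z", "IV:CZ", "IV:BCZ", "IV:ABCZ"]
        vals = [information_captured(abcz, fits(nm), bottom) for nm in chain]
        assert all(a <= b + 1e-9 for a, b in zip(vals, vals[1:]))
        assert all(-1e-9 <= v <= 1 + 1e-9 for v in vals)

    def test_hand_value_single_relation(self, abcz, fits, bottom):
        """Inf = [H(Z) - H_q(Z|C)] / [H(Z) - H(Z|ABC)] for IV:CZ."""
        res = fits("IV:CZ")
        p_full = abcz.project_counts(list(ABCD)) / abcz.n
        p_z = abcz.project_counts(["Z"]) / abcz.n
        p_cz = abcz.project_counts(["C", "Z"]) / abcz.n
        h_z = rc.entropy(p_z)
        h_z_c = rc.entropy(p_cz) - rc.entropy(p_cz.sum(axis=1))
        h_z_abc = rc.entropy(p_full) - rc.entropy(p_full.sum(axis=3))
        expected = (h_z - h_z_c) / (h_z - h_z_abc)
        assert information_captured(abcz, res, bottom) == pytest.approx(expected, abs=1e-8)

    def test_degenerate_denominator_warns(self):
        # DV independent of the IVs and deterministic given them is impossible;
        # instead: IVs carry no DV information (H(Z)=H(Z|A)): A independent of Z
        ds = make_dataset({(0, 0): 1, (0, 1): 1, (1, 0): 1, (1, 1): 1}, (2, 2))
        bot = rc.RAModel(ds, "IV:Z").fit()
        top = rc.RAModel(ds, "IV:AZ").fit()
        with pytest.warns(RuntimeWarning, match="no DV information"):
            v = information_captured(ds, top, bot)
        assert v in (0.0, 1.0)


class TestPctDeltaH:
    def test_bottom_is_zero(self, abcz, bottom):
        assert pct_delta_h_dv(abcz, bottom) == pytest.approx(0.0, abs=1e-7)

    def test_hand_value(self, abcz, fits):
        res = fits("IV:CZ")
        p_cz = abcz.project_counts(["C", "Z"]) / abcz.n
        h_z = rc.entropy(p_cz.sum(axis=0))
        h_z_c = rc.entropy(p_cz) - rc.entropy(p_cz.sum(axis=1))
        assert pct_delta_h_dv(abcz, res) == pytest.approx(
            100.0 * (h_z - h_z_c) / h_z, abs=1e-8
        )

    def test_zero_entropy_dv_raises(self):
        ds = make_dataset({(0, 0): 2, (1, 0): 3}, (2, 2))
        res = rc.RAModel(ds, "IV:Z").fit()
        with pytest.raises(ValueError, match="zero entropy"):
            pct_delta_h_dv(ds, res)


class TestInformationCriteria:
    def test_bottom_vs_itself_zero(self, abcz, bottom):
        dbic, daic = information_criteria(abcz, bottom, bottom)
        assert dbic == pytest.approx(0.0, abs=1e-8)
        assert daic == pytest.approx(0.0, abs=1e-8)

    def test_hand_values_saturated(self, abcz, fits, bottom):
        top = fits("IV:ABCZ")
        dll = top.cond_loglik - bottom.cond_loglik
        ddf = top.df - bottom.df
        n = abcz.n
        dbic, daic = information_criteria(abcz, top, bottom)
        assert ddf == 7  # 15 - 8 for four binary variables
        assert dbic == pytest.approx(2 * dll - np.log(n) * ddf)
        assert daic == pytest.approx(2 * dll - 2 * ddf)

    def test_aic_bic_gap(self, abcz, fits, bottom):
        res = fits("IV:AZ:BZ")
        dbic, daic = information_criteria(abcz, res, bottom)
        ddf = res.df - bottom.df
        assert daic - dbic == pytest.approx((np.log(abcz.n) - 2.0) * ddf)


class TestSignificance:
    def test_self_comparison_p_one(self, abcz, bottom):
        assert lr_significance(abcz, bottom, bottom) == 1.0

    def test_matches_scipy_g2(self, rng):
        """G^2 p-value for IV:AZ vs bottom equals the classical likelihood-
        ratio test of independence on the A-x-Z contingency table."""
        ds = random_dataset(rng, (2, 3))
        res = rc.RAModel(ds, "IV:AZ").fit(tol=1e-12, max_iter=50000)
        bot = rc.RAModel(ds, "IV:Z").fit(tol=1e-12, max_iter=50000)
        p = lr_significance(ds, res, bot)
        table = ds.project_counts(["A", "Z"])
        g2, p_ref, dof, _ = stats.chi2_contingency(
            table, correction=False, lambda_="log-likelihood"
        )
        assert dof == res.df - bot.df
        assert p == pytest.approx(p_ref, rel=1e-6)

    def test_non_nested_raises(self, abcz, fits):
        a = fits("IV:AZ")
        b = fits("IV:BZ")
        with pytest.raises(ValueError, match="not nested"):
            lr_significance(abcz, a, b)

    def test_nested_chain_ordering(self, abcz, fits, bottom):
        """p against bottom from a bigger model uses the summed G^2."""
        mid = fits("IV:CZ")
        top = fits("IV:BCZ")
        p_top = lr_significance(abcz, top, bottom)
        g2 = 2 * (top.cond_loglik - bottom.cond_loglik)
        assert p_top == pytest.approx(
            float(stats.chi2.sf(g2, top.df - bottom.df)), rel=1e-9
        )
        # mid is nested in top
        assert 0 <= lr_significance(abcz, top, mid) <= 1


class TestPctCorrect:
    def test_deterministic_relation_is_100(self):
        ds = make_dataset({(0, 0): 5, (1, 1): 7}, (2, 2))
        res = rc.RAModel(ds, "IV:AZ").fit()
        assert pct_correct(res) == pytest.approx(100.0)

    def test_hand_value(self):
        # A=0: Z=0 in 3 of 4; A=1: Z=1 in 5 of 6 -> (3+5)/10 correct
        ds = make_dataset({(0, 0): 3, (0, 1): 1, (1, 0): 1, (1, 1): 5}, (2, 2))
        res = rc.RAModel(ds, "IV:AZ").fit()
        assert pct_correct(res) == pytest.approx(80.0)

    def test_tie_goes_to_lowest_state(self):
        ds = make_dataset({(0, 0): 2, (0, 1): 2, (1, 1): 4}, (2, 2))
        res = rc.RAModel(ds, "IV:AZ").fit()
        preds = res.predict()
        assert int(preds.loc[preds["observed"] == 0].iloc[0]["predicted"]) == 0

    def test_bottom_predicts_marginal_mode(self):
        ds = make_dataset({(0, 0): 2, (0, 1): 3, (1, 0): 1, (1, 1): 4}, (2, 2))
        res = rc.RAModel(ds, "IV:Z").fit()
        assert pct_correct(res) == pytest.approx(70.0)  # mode Z=1, 7 of 10

    def test_unseen_state_falls_back_to_marginal(self):
        train = make_dataset({(0, 0): 6, (0, 1): 1, (1, 1): 3}, (2, 2))
        res = rc.RAModel(train, "IV:AZ").fit()
        # training marginal mode is Z=0 (7 vs 3)... but A=1 seen -> use cond.
        # craft an unseen composite state with a 3-state IV
        train3 = make_dataset({(0, 0): 6, (0, 1): 1, (1, 1): 3}, (3, 2))
        res3 = rc.RAModel(train3, "IV:AZ").fit()
        test3 = make_dataset({(2, 0): 4, (2, 1): 1}, (3, 2))
        # A=2 unseen -> fallback = train marginal argmax = Z0 -> 4 of 5 correct
        assert pct_correct(res3, test3) == pytest.approx(80.0)
        assert pct_correct(res) == pytest.approx(90.0)

    def test_eval_on_test_data(self, abcz, rng):
        res = rc.RAModel(abcz, "IV:ABCZ").fit()
        test = random_dataset(rng, (2, 2, 2, 2))
        v = pct_correct(res, test)
        assert 0 <= v <= 100


class TestPctCover:
    def test_bottom_always_full(self, abcz):
        assert pct_cover(abcz, rc.ModelStructure.bottom(ABCD, "Z")) == 100.0

    def test_full_product_observed(self, abcz):
        st_ = rc.parse_model("IV:ABCZ", ABCD, "Z")
        assert pct_cover(abcz, st_) == pytest.approx(100.0)  # zero-free fixture

    def test_partial_cover(self):
        ds = make_dataset({(0, 0, 0): 1, (1, 1, 1): 1, (0, 1, 0): 2}, (2, 2, 2))
        st_ = rc.parse_model("IV:ABZ", ds.names, "Z")
        # observed AB combos: (0,0), (1,1), (0,1) -> 3 of 4
        assert pct_cover(ds, st_) == pytest.approx(75.0)

    def test_accepts_fit_results(self, abcz):
        res = rc.RAModel(abcz, "IV:CZ").fit()
        assert pct_cover(abcz, res) == pytest.approx(100.0)


class TestMetricRow:
    def kwargs(self, **over):
        base = dict(
            name="IV:Z",
            level=0,
            inf=0.0,
            pct_dh_dv=0.0,
            delta_bic=0.0,
            delta_aic=0.0,
            pct_correct_train=50.0,
            pct_cover=100.0,
        )
        base.update(over)
        return base

    def test_valid(self):
        MetricRow(**self.kwargs())

    @pytest.mark.parametrize(
        "field,value",
        [("inf", 1.5), ("inf", -0.2), ("pct_correct_train", 120.0), ("pct_cover", -5.0)],
    )
    def test_out_of_range_rejected(self, field, value):
        with pytest.raises(ValueError):
            MetricRow(**self.kwargs(**{field: value}))
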