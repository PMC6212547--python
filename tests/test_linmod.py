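"""Moderated linear model: OLS, shrinkage, contrasts, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from parasnail import (
    ArrayLinearModel,
    estimate_variance_prior,
    fit_row_models,
    squeeze_variances,
)
from parasnail.linmod import ContrastError, trigamma_inverse
from tests.conftest import make_sample_design


def two_group_design():
    return make_sample_design(2, localities=("Burela", "Roncudo", "Silleiro"))


def simulate_null_matrix(sample_design, n_rows, d0, s0sq, seed):
    """Rows drawn under the moderation prior with no group effects."""
    rng = np.random.default_rng(seed)
    cols = list(sample_design.sample_ids)
    sigma = np.sqrt(s0sq * d0 / rng.chisquare(d0, size=n_rows))
    values = rng.normal(size=(n_rows, len(cols))) * sigma[:, None]
    return pd.DataFrame(values, index=[f"r{i}" for i in range(n_rows)], columns=cols)


class TestOLS:
    def test_perfect_two_group_difference(self):
        sd = two_group_design()
        cols = list(sd.sample_ids)
        values = pd.DataFrame([[0.0] * len(cols)], index=["g"], columns=cols)
        crab_burela = sd.subset(ecotype="crab", locality="Burela").sample_ids
        values.loc["g", list(crab_burela)] = 1.0
        res = fit_row_models(values, sd, "ecotype_within_locality")
        assert res.coef.loc["g", "ecotype@Burela"] == pytest.approx(1.0)
        assert res.sigma2.loc["g"] == pytest.approx(0.0)

    def test_residual_df_accounting(self):
        """22 samples across 6 cells leave 16 residual df."""
        sd = make_sample_design(4)
        table = sd.table.drop(index=[0, 5]).reset_index(drop=True)
        from parasnail import SampleDesign

        sd22 = SampleDesign(table)
        rng = np.random.default_rng(0)
        values = pd.DataFrame(
            rng.normal(size=(10, 22)), index=[f"g{i}" for i in range(10)],
            columns=list(sd22.sample_ids),
        )
        res = fit_row_models(values, sd22, "ecotype_within_locality")
        assert res.df_residual == 16

    def test_sample_order_invariance(self):
        sd = two_group_design()
        rng = np.random.default_rng(1)
        cols = list(sd.sample_ids)
        values = pd.DataFrame(rng.normal(size=(20, len(cols))), columns=cols)
        res1 = ArrayLinearModel(values, sd).fit()
        perm = rng.permutation(len(cols))
        res2 = ArrayLinearModel(values.iloc[:, perm], sd).fit()
        pd.testing.assert_frame_equal(res1.pvalues, res2.pvalues)

    def test_single_replicate_group_rejected(self):
        sd = two_group_design()
        from parasnail import SampleDesign

        table = sd.table.drop(index=[0]).reset_index(drop=True)
        sd_bad = SampleDesign(table)
        values = pd.DataFrame(
            np.zeros((3, len(sd_bad.sample_ids))), columns=list(sd_bad.sample_ids)
        )
        with pytest.raises(ContrastError, match="fewer than 2"):
            ArrayLinearModel(values, sd_bad)


class TestModeration:
    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma

        for y in (1e-5, 0.01, 0.5, 2.0, 100.0):
            x = trigamma_inverse(y)
            assert polygamma(1, x) == pytest.approx(y, rel=1e-6)

    def test_d0_zero_gives_ordinary_t(self):
        sd = two_group_design()
        rng = np.random.default_rng(2)
        cols = list(sd.sample_ids)
        values = pd.DataFrame(rng.normal(size=(30, len(cols))), columns=cols)
        res = fit_row_models(values, sd, "ecotype_within_locality")  # d0 = 0
        # ordinary t from first principles for one row/locality
        crab = list(sd.subset(ecotype="crab", locality="Burela").sample_ids)
        wave = list(sd.subset(ecotype="wave", locality="Burela").sample_ids)
        row = values.iloc[0]
        est = row[crab].mean() - row[wave].mean()
        t_expected = est / np.sqrt(res.sigma2.iloc[0] * (1 / len(crab) + 1 / len(wave)))
        assert res.tstats.iloc[0]["ecotype@Burela"] == pytest.approx(t_expected)

    def test_identical_variances_hit_infinite_prior_branch(self):
        s2 = np.full(50, 0.3)
        d0, s0sq = estimate_variance_prior(s2, df=10)
        assert np.isinf(d0)
        assert s0sq == pytest.approx(0.3)
        np.testing.assert_allclose(squeeze_variances(s2, 10, d0, s0sq), 0.3)

    def test_posterior_variance_between_prior_and_observed(self):
        rng = np.random.default_rng(3)
        s2 = rng.chisquare(8, size=200) / 8 * 0.05
        d0, s0sq = estimate_variance_prior(s2, df=8)
        post = squeeze_variances(s2, 8, d0, s0sq)
        lo = np.minimum(s2, s0sq)
        hi = np.maximum(s2, s0sq)
        assert ((post >= lo - 1e-12) & (post <= hi + 1e-12)).all()

    def test_posterior_variance_monotone_in_s2(self):
        s2 = np.linspace(0.001, 1.0, 100)
        post = squeeze_variances(s2, 10, 4.0, 0.05)
        assert (np.diff(post) > 0).all()

    def test_hyperparameter_recovery_within_15_percent(self):
        """Method of moments on 5000 rows simulated from the prior."""
        rng = np.random.default_rng(4)
        d0_true, s0sq_true, d = 4.0, 0.05, 16
        sigma2 = s0sq_true * d0_true / rng.chisquare(d0_true, size=5000)
        s2 = sigma2 * rng.chisquare(d, size=5000) / d
        d0, s0sq = estimate_variance_prior(s2, df=d)
        assert d0 == pytest.approx(d0_true, rel=0.15)
        assert s0sq == pytest.approx(s0sq_true, rel=0.15)


class TestContrasts:
    def test_zero_estimate_gives_p_one(self):
        sd = two_group_design()
        cols = list(sd.sample_ids)
        rng = np.random.default_rng(5)
        noise = rng.normal(size=len(cols))
        # same values in both ecotypes within each locality -> zero contrasts
        values = pd.DataFrame([noise], index=["g"], columns=cols)
        meta = sd.table.set_index("sample_id")
        for loc in ("Burela", "Roncudo", "Silleiro"):
            ids = meta.index[(meta["locality"] == loc)]
            values.loc["g", ids] = float(rng.normal())
        res = ArrayLinearModel(pd.concat([values] * 3 + [pd.DataFrame(
            rng.normal(size=(5, len(cols))), columns=cols)]), sd).fit()
        assert res.pvalues.iloc[0]["ecotype@Burela"] == pytest.approx(1.0)

    def test_huge_effect_gives_tiny_p(self):
        sd = two_group_design()
        cols = list(sd.sample_ids)
        rng = np.random.default_rng(6)
        values = pd.DataFrame(rng.normal(size=(20, len(cols))), columns=cols)
        crab = [c for c in cols if "_crab_" in c]
        values.loc[0, crab] += 100.0
        res = ArrayLinearModel(values, sd, analysis="factorial_interaction").fit()
        assert res.pvalues.loc[0, "ecotype"] < 1e-10

    def test_factorial_contrast_names(self):
        sd = two_group_design()
        cols = list(sd.sample_ids)
        values = pd.DataFrame(np.random.default_rng(7).normal(size=(5, len(cols))), columns=cols)
        res = ArrayLinearModel(values, sd, analysis="factorial_interaction").fit()
        assert list(res.pvalues.columns) == ["ecotype", "locality", "interaction"]
        res2 = ArrayLinearModel(values, sd, analysis="locality_within_ecotype").fit()
        assert set(res2.pvalues.columns) == {"locality@crab", "locality@wave"}

    def test_unknown_analysis_rejected(self):
        sd = two_group_design()
        values = pd.DataFrame(np.zeros((2, len(sd.sample_ids))), columns=list(sd.sample_ids))
        with pytest.raises(ContrastError, match="unknown analysis"):
            ArrayLinearModel(values, sd, analysis="bogus")

    def test_shift_invariance_of_pvalues(self):
        sd = two_group_design()
        cols = list(sd.sample_ids)
        values = pd.DataFrame(np.random.default_rng(8).normal(size=(15, len(cols))), columns=cols)
        res1 = ArrayLinearModel(values, sd).fit()
        res2 = ArrayLinearModel(values + 5.0, sd).fit()
        pd.testing.assert_frame_equal(res1.pvalues, res2.pvalues)


class TestCalibration:
    def test_null_moderated_t_uniform_and_nominal_rate(self):
        """Under the moderation prior the moderated t p-values are uniform."""
        sd = make_sample_design(4)
        values = simulate_null_matrix(sd, 10_000, d0=4.0, s0sq=0.05, seed=9)
        res = ArrayLinearModel(values, sd).fit()
        p = res.pvalues.to_numpy().ravel()
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01
        rate = (res.pvalues["ecotype@Burela"] <= 0.05).mean()
        assert 0.04 <= rate <= 0.06

    def test_summary_mentions_analysis_and_prior(self):
        sd = two_group_design()
        values = pd.DataFrame(
            np.random.default_rng(10).normal(size=(50, len(sd.sample_ids))),
            columns=list(sd.sample_ids),
        )
        res = ArrayLinearModel(values, sd).fit()
        text = res.summary()
        assert "ecotype_within_locality" in text
        assert "prior df" in text
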