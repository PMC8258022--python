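"""Product-of-coefficients mediation, bootstrap inference and the
counterfactual cross-check."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_null_mediation_frame
from upfmed.association import FitResult, fit_ols
from upfmed.mediation import (
    MediationModel,
    UnsupportedModelError,
    acme_counterfactual,
    acme_product,
)


def _fake_fit(label, **params):
    s = pd.Series(params)
    return FitResult(params=s, bse=s * 0, pvalues=s * 0, nobs=100,
                     model_label=label, formula="")


class TestProductFormula:
    def test_published_coefficient_pair(self):
        med = _fake_fit("m", nova4_pct=-0.197)
        out = _fake_fit("y", nova4_pct=0.001, dash=-0.008)
        acme, ade, total = acme_product(med, out)
        assert acme == pytest.approx(0.001576, abs=1e-12)
        assert ade == pytest.approx(0.001)
        assert total == pytest.approx(0.002576, abs=1e-12)

    def test_zero_mediator_coefficient_nulls_the_acme(self):
        med = _fake_fit("m", nova4_pct=-0.197)
        out = _fake_fit("y", nova4_pct=0.004, dash=0.0)
        acme, ade, total = acme_product(med, out)
        assert acme == 0.0
        assert total == ade

    def test_product_of_two_negatives_is_positive(self):
        med = _fake_fit("m", nova4_pct=-0.3)
        out = _fake_fit("y", nova4_pct=0.0, dash=-0.5)
        acme, _, _ = acme_product(med, out)
        assert acme > 0

    def test_missing_term_error_names_the_term(self):
        med = _fake_fit("m", other=-0.3)
        out = _fake_fit("y", nova4_pct=0.0, dash=-0.5)
        with pytest.raises(KeyError, match="nova4_pct"):
            acme_product(med, out)


class TestCounterfactualRoute:
    @staticmethod
    def _fits(df):
        med = fit_ols("m ~ x + c", df, label="med")
        out = fit_ols("y ~ x + m + c", df, label="out")
        return med, out

    def test_equals_product_formula_for_linear_models(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"x": rng.standard_normal(200),
                           "c": rng.standard_normal(200)})
        df["m"] = -0.4 * df["x"] + 0.2 * df["c"] + rng.standard_normal(200)
        df["y"] = 0.1 * df["x"] - 0.3 * df["m"] + rng.standard_normal(200)
        med, out = self._fits(df)
        acme, _, _ = acme_product(med, out, "x", "m")
        cf = acme_counterfactual(med, out, df, "x", "m")
        assert cf == pytest.approx(acme, abs=1e-10)

    def test_zero_b_gives_zero_counterfactual_effect(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"x": rng.standard_normal(100),
                           "c": rng.standard_normal(100)})
        df["m"] = 0.5 * df["x"] + rng.standard_normal(100)
        df["y"] = df["c"] * 0.2 + 1.0  # y ignores m entirely up to noise-free fit
        med = fit_ols("m ~ x + c", df, label="med")
        out = fit_ols("y ~ x + m + c", df, label="out")
        cf = acme_counterfactual(med, out, df, "x", "m")
        assert cf == pytest.approx(out.params["m"] * med.params["x"], abs=1e-10)

    def test_six_row_dataset_matches_explicit_enumeration(self):
        df = pd.DataFrame({
            "x": [0.0, 1.0, 2.0, 3.0, 4.0, 5.0],
            "c": [1.0, 0.0, 1.0, 0.0, 1.0, 0.0],
            "m": [2.0, 1.5, 3.0, 2.0, 4.5, 3.0],
            "y": [1.0, 1.2, 0.8, 1.5, 0.7, 1.4],
        })
        med, out = self._fits(df)
        # brute-force: per-row predicted outcome difference
        bm, bo = med.params, out.params
        diffs = []
        for _, r in df.iterrows():
            m0 = bm["Intercept"] + bm["x"] * r["x"] + bm["c"] * r["c"]
            m1 = bm["Intercept"] + bm["x"] * (r["x"] + 1) + bm["c"] * r["c"]
            y0 = bo["Intercept"] + bo["x"] * r["x"] + bo["m"] * m0 + bo["c"] * r["c"]
            y1 = bo["Intercept"] + bo["x"] * r["x"] + bo["m"] * m1 + bo["c"] * r["c"]
            diffs.append(y1 - y0)
        cf = acme_counterfactual(med, out, df, "x", "m")
        assert cf == pytest.approx(np.mean(diffs), abs=1e-10)

    def test_nonlinear_fit_rejected(self):
        med = _fake_fit("not_ols", x=1.0)
        out = _fake_fit("also_not", x=0.1, m=0.2)
        with pytest.raises(UnsupportedModelError):
            acme_counterfactual(med, out, pd.DataFrame(), "x", "m")


class TestBootstrap:
    @staticmethod
    def _frame(n=400, seed=8):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({"x": rng.standard_normal(n),
                           "c": rng.standard_normal(n)})
        df["m"] = -0.5 * df["x"] + rng.standard_normal(n)
        df["y"] = 0.1 * df["x"] - 0.4 * df["m"] + rng.standard_normal(n)
        return df

    def test_decomposition_holds_in_every_replicate(self):
        model = MediationModel(self._frame(), exposure="x", mediator="m",
                               outcome="y", covariates=("c",))
        res = model.fit(sims=200, seed=1)
        d = res.boot_draws
        assert np.abs(d["total"] - (d["acme"] + d["ade"])).max() < 1e-12
        assert res.total_effect == pytest.approx(res.acme + res.ade, abs=1e-12)

    def test_seed_determinism(self):
        df = self._frame()
        kw = dict(exposure="x", mediator="m", outcome="y", covariates=("c",))
        r1 = MediationModel(df, **kw).fit(sims=150, seed=42)
        r2 = MediationModel(df, **kw).fit(sims=150, seed=42)
        assert r1.conf_ints.equals(r2.conf_ints)
        assert (r1.boot_draws == r2.boot_draws).all().all()
        assert r1.pvalues == r2.pvalues

    def test_single_replicate_gives_degenerate_ci(self):
        model = MediationModel(self._frame(), exposure="x", mediator="m",
                               outcome="y", covariates=("c",))
        res = model.fit(sims=1, seed=3)
        lo, hi = res.conf_ints.loc["acme"]
        assert lo == hi == res.boot_draws["acme"].iloc[0]

    def test_point_estimate_matches_product_on_full_sample(self):
        df = self._frame()
        model = MediationModel(df, exposure="x", mediator="m", outcome="y",
                               covariates=("c",))
        res = model.fit(sims=50, seed=2)
        acme, ade, total = acme_product(res.mediator_fit, res.outcome_fit, "x", "m")
        assert res.acme == pytest.approx(acme, abs=1e-14)
        assert res.ade == pytest.approx(ade, abs=1e-14)

    def test_proportion_mediated_undefined_on_sign_clash(self):
        # positive indirect path, strongly negative direct path: the ACME
        # and the total effect are guaranteed opposite signs
        rng = np.random.default_rng(11)
        n = 500
        x = rng.standard_normal(n)
        m = 0.5 * x + 0.1 * rng.standard_normal(n)
        y = -0.5 * x + 0.3 * m + 0.1 * rng.standard_normal(n)
        df = pd.DataFrame({"x": x, "m": m, "y": y})
        model = MediationModel(df, exposure="x", mediator="m", outcome="y",
                               covariates=())
        with pytest.warns(UserWarning, match="proportion mediated"):
            res = model.fit(sims=20, seed=5)
        assert np.sign(res.acme) != np.sign(res.total_effect)
        assert np.isnan(res.proportion_mediated)

    def test_summary_reports_estimates_and_floor(self):
        res = MediationModel(self._frame(), exposure="x", mediator="m",
                             outcome="y", covariates=("c",)).fit(sims=99, seed=1)
        text = res.summary()
        assert "ACME" in text and "bootstrap" in text
        assert f"{2/100:.4g}" in text  # p floor 2/(sims+1)

    def test_bca_interval_available_and_ordered(self):
        res = MediationModel(self._frame(n=150), exposure="x", mediator="m",
                             outcome="y", covariates=("c",)).fit(
            sims=200, seed=4, ci_method="bca")
        lo, hi = res.conf_ints.loc["acme"]
        assert lo < res.acme < hi
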