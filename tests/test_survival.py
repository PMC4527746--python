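"""Cox screen: design encoding, partial-likelihood fits, LRT, q-values."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from helpers import make_callset, newton_cox_beta, qvalues_stepwise
from lohcna.errors import ConfigError, DegenerateDesignError, UsageError
from lohcna.survival import (bonferroni_threshold, encode_design, fit_cox,
                             lrt, null_log_partial_likelihood, qvalues, screen)


def small_design(n=60, seed=0, beta=0.0):
    """Unique-time dataset with one binary covariate of true log-HR beta."""
    rng = np.random.default_rng(seed)
    x = (rng.random(n) < 0.5).astype(float)
    time = rng.exponential(1.0, n) / np.exp(beta * x)
    event = np.ones(n, dtype=int)
    event[rng.random(n) < 0.2] = 0
    return pd.DataFrame({"x": x, "time": time, "event": event})


class TestEncodeDesign:
    def build(self, loh_status, cna_class):
        loh = pd.DataFrame([[loh_status]], index=["p0"], columns=["s0"])
        cna = pd.DataFrame([[cna_class]], index=["p0"], columns=["s0"])
        cs = make_callset(loh, cna)
        clinical = pd.DataFrame(
            {"sex": [1], "age": [60.0], "smoking": ["never"], "alcohol": ["no"],
             "stage": ["II"], "site": ["oral_cavity"], "nodal": [0],
             "time_months": [30.0], "event": ["other_death"]},
            index=["s0"])
        return encode_design(cs, clinical, "p0")

    @pytest.mark.parametrize("loh_status, cna_class, expected", [
        ("L", "GAIN", (1.0, 1.0, 1.0)),
        ("R", "NEUTRAL", (0.0, 0.0, 0.0)),
        ("L", "LOSS", (-1.0, 1.0, -1.0)),
        ("N", "GAIN", (1.0, 0.0, 0.0)),
    ])
    def test_ternary_coding(self, loh_status, cna_class, expected):
        d = self.build(loh_status, cna_class)
        assert (d.loc["s0", "cna"], d.loc["s0", "loh"], d.loc["s0", "cna_loh"]) == expected

    def test_other_death_censored_at_death_time(self):
        d = self.build("R", "NEUTRAL")
        assert d.loc["s0", "time"] == 30.0 and d.loc["s0", "event"] == 0

    def test_missing_clinical_sample_rejected(self):
        loh = pd.DataFrame([["L", "R"]], index=["p0"], columns=["s0", "s1"])
        cna = pd.DataFrame([["GAIN", "NEUTRAL"]], index=["p0"], columns=["s0", "s1"])
        cs = make_callset(loh, cna)
        clinical = pd.DataFrame({"sex": [1], "age": [60.0], "smoking": ["never"],
                                 "time_months": [10.0], "event": ["censored"]},
                                index=["s0"])
        with pytest.raises(ConfigError, match="s1"):
            encode_design(cs, clinical, "p0")


class TestFitCox:
    def test_beta_matches_independent_newton_maximization(self):
        d = small_design(n=80, seed=1, beta=0.8)
        fit = fit_cox(d, ("x",))
        oracle = newton_cox_beta(d[["x"]].to_numpy(), d["time"].to_numpy(),
                                 d["event"].to_numpy())
        assert fit.params["x"] == pytest.approx(oracle[0], abs=1e-4)

    def test_constant_covariate_rejected(self):
        d = small_design()
        d["x"] = 1.0
        with pytest.raises(DegenerateDesignError, match="constant"):
            fit_cox(d, ("x",))

    def test_null_model_log_partial_likelihood(self):
        d = small_design(n=40, seed=2)
        fit0 = fit_cox(d, ())
        # cross-check against lifelines' null log-likelihood via a zero-effect LRT
        fit1 = fit_cox(d, ("x",))
        stat, p = lrt(fit1, fit0, df=1)
        assert stat >= 0 and 0 < p <= 1
        # Efron at beta=0, no ties: -sum log(riskset size) over events
        t, e = d["time"].to_numpy(), d["event"].to_numpy()
        expected = -sum(np.log((t >= ti).sum()) for ti in t[e == 1])
        assert null_log_partial_likelihood(t, e) == pytest.approx(expected)

    def test_null_beta_small_and_wald_p_uniformish(self):
        """beta=0 data: estimates near zero, Wald p approximately uniform."""
        rng = np.random.default_rng(3)
        ps, betas = [], []
        for _ in range(120):
            n = 100
            x = (rng.random(n) < 0.5).astype(float)
            d = pd.DataFrame({"x": x, "time": rng.exponential(1.0, n),
                              "event": np.ones(n, dtype=int)})
            fit = fit_cox(d, ("x",))
            se = np.sqrt(fit.cov.loc["x", "x"])
            from scipy.stats import norm
            ps.append(2 * norm.sf(abs(fit.params["x"] / se)))
            betas.append(fit.params["x"])
        assert abs(np.mean(betas)) < 0.1
        frac = np.mean(np.array(ps) < 0.1)
        assert abs(frac - 0.1) < 3 * np.sqrt(0.1 * 0.9 / len(ps))


class TestLRT:
    def test_identical_fits_give_p_one(self):
        d = small_design(n=50, seed=4)
        fit = fit_cox(d, ("x",))
        stat, p = lrt(fit, fit, df=1)
        assert stat == 0.0 and p == 1.0

    def test_chi_square_tail(self):
        d = small_design(n=50, seed=5)
        f1, f0 = fit_cox(d, ("x",)), fit_cox(d, ())
        f1 = type(f1)(f1.terms, f1.params, f1.cov, f0.log_likelihood + 1.92,
                      f1.n_events, True)
        stat, p = lrt(f1, f0, df=1)
        assert stat == pytest.approx(3.84)
        assert p == pytest.approx(0.05, abs=5e-4)

    def test_non_nested_rejected(self):
        d = small_design(n=50, seed=6)
        d["y"] = 1 - d["x"] + np.random.default_rng(0).normal(0, .1, len(d))
        fx, fy = fit_cox(d, ("x",)), fit_cox(d, ("y",))
        with pytest.raises(UsageError, match="nested"):
            lrt(fx, fy)


class TestQValues:
    def test_all_ones(self):
        assert (qvalues([1.0, 1.0, 1.0]) == 1.0).all()

    def test_single_p_with_pi0_one(self):
        assert qvalues([0.04])[0] == pytest.approx(0.04)

    def test_matches_stepwise_recomputation(self):
        rng = np.random.default_rng(8)
        p = rng.random(1000)
        np.testing.assert_allclose(qvalues(p), qvalues_stepwise(p), rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            qvalues([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_p(self, ps):
        p = np.array(ps)
        q = qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestScreen:
    @staticmethod
    @pytest.fixture(scope="class")
    def crafted():
        """40 samples; probe pA has LOH in 5 samples (retained at the strict
        'fewer than 5' boundary), pB in 4 (excluded)."""
        rng = np.random.default_rng(12)
        samples = [f"s{i}" for i in range(40)]
        loh = np.full((2, 40), "R", dtype="<U1")
        loh[0, :5] = "L"
        loh[1, :4] = "L"
        classes = np.full((2, 40), "NEUTRAL", dtype=object)
        classes[:, 2:12] = "GAIN"   # overlaps 3 of the LOH samples at pA
        probes = pd.Index(["pA", "pB"], name="probe")
        cs = make_callset(pd.DataFrame(loh, index=probes, columns=samples),
                          pd.DataFrame(classes, index=probes, columns=samples))
        clinical = pd.DataFrame({
            "sex": rng.integers(0, 2, 40), "age": rng.normal(60, 8, 40),
            "smoking": rng.choice(["never", "former", "current"], 40),
            "alcohol": "no", "stage": "II", "site": "oral_cavity", "nodal": 0,
            "time_months": rng.exponential(50, 40).round(2) + 1,
            "event": rng.choice(["OSCC_death", "censored"], 40, p=[0.6, 0.4]),
        }, index=samples)
        return cs, clinical

    def test_min_loh_sample_filter_boundary(self, crafted):
        cs, clinical = crafted
        result = screen(cs, clinical, min_loh_samples=5)
        assert "pA" in result.index and "pB" not in result.index

    def test_bonferroni_and_qvalue_columns(self, crafted):
        cs, clinical = crafted
        result = screen(cs, clinical, min_loh_samples=5)
        assert result["bonferroni_threshold"].iloc[0] == pytest.approx(0.05 / len(result))
        assert ((result["q_all"] >= 0) & (result["q_all"] <= 1)).all()

    def test_bonferroni_printed_precision(self):
        assert f"{bonferroni_threshold(66875):.3g}" == "7.48e-07"

    def test_stratum_sign_recovery(self):
        """Opposite-sign interaction: hazard up with LOH, down without."""
        from lohcna.pipeline import call_cohort
        from lohcna.scenarios import EFFECT_PROBE, opposite_sign_interaction_config
        from lohcna.synthetic import generate_cohort
        cohort = generate_cohort(opposite_sign_interaction_config(seed=42))
        callset, _ = call_cohort(cohort)
        row = screen(callset, cohort.clinical, probes=[EFFECT_PROBE]).loc[EFFECT_PROBE]
        assert row["sign_no_loh"] == "-" and row["sign_loh"] == "+"
        assert row["beta_cna_loh_stratum"] == pytest.approx(
            row["beta_cna"] + row["beta_interaction"])
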