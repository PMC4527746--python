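"""Clustering, Fisher exact enumeration, log-rank and adjusted Cox association."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from helpers import fisher_2x2_enumeration, make_callset
from lohcna.cluster import (cluster_covariate_cox, cluster_samples,
                            compare_mortality, fisher_exact,
                            fisher_exact_table, logrank_two_group)
from lohcna.errors import DegenerateDesignError, UsageError
from lohcna.pipeline import call_cohort
from lohcna.scenarios import planted_cluster_config
from lohcna.synthetic import generate_cohort


class TestClustering:
    def test_planted_two_block_recovery(self):
        """23 samples share an amplified region, 52 do not; zero noise ->
        the exact 23/52 split."""
        cohort = generate_cohort(planted_cluster_config(seed=5, cn_noise_sd=0.0))
        callset, _ = call_cohort(cohort)
        res = cluster_samples(callset, "cna")
        truth = cohort.truth.cluster
        agree = (res.labels == truth).mean()
        assert agree in (0.0, 1.0)  # identical up to label swap
        assert sorted(res.labels.value_counts().tolist()) == [23, 52]

    def test_permutation_invariance(self):
        cohort = generate_cohort(planted_cluster_config(seed=6))
        callset, _ = call_cohort(cohort)
        res = cluster_samples(callset, "cna")
        perm = list(reversed(callset.samples))
        callset2 = make_callset(callset.loh[perm], callset.cna.classes[perm],
                                delta_df=callset.cna.delta[perm],
                                annotation=callset.annotation)
        res2 = cluster_samples(callset2, "cna")
        a = res.labels.loc[callset.samples].to_numpy()
        b = res2.labels.loc[callset.samples].to_numpy()
        assert ((a == b).all() or (a == 3 - b).all())

    def test_hand_worked_complete_linkage(self):
        """Samples at 1-D positions 0, 1, 10, 12: merges at heights 1, 2, 12."""
        probes = pd.Index(["p0"], name="probe")
        samples = ["a", "b", "c", "d"]
        delta = pd.DataFrame([[0.0, 1.0, 10.0, 12.0]], index=probes, columns=samples)
        loh = pd.DataFrame([["R"] * 4], index=probes, columns=samples)
        classes = pd.DataFrame([["NEUTRAL"] * 4], index=probes, columns=samples)
        cs = make_callset(loh, classes, delta_df=delta)
        res = cluster_samples(cs, "cna")
        np.testing.assert_allclose(sorted(res.linkage_matrix[:, 2]), [1.0, 2.0, 12.0])
        assert res.labels["a"] == res.labels["b"]
        assert res.labels["c"] == res.labels["d"]
        assert res.labels["a"] != res.labels["c"]

    def test_identical_samples_degenerate(self):
        probes = pd.Index(["p0", "p1"], name="probe")
        samples = list("abcd")
        loh = pd.DataFrame([["L"] * 4] * 2, index=probes, columns=samples)
        classes = pd.DataFrame([["NEUTRAL"] * 4] * 2, index=probes, columns=samples)
        res = cluster_samples(make_callset(loh, classes), "loh")
        assert res.degenerate


class TestFisherExact:
    def test_no_association_table(self):
        assert fisher_exact_table([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        for table in ([[5, 1], [1, 5]], [[8, 2], [3, 7]], [[10, 0], [5, 5]]):
            p = fisher_exact_table(table)
            assert p == pytest.approx(fisher_2x2_enumeration(table), rel=1e-9)
            assert p == pytest.approx(scipy_fisher(table).pvalue, rel=1e-7)

    def test_identical_rows_2x3(self):
        assert fisher_exact_table([[2, 3, 4], [2, 3, 4]]) == pytest.approx(1.0)

    def test_probability_conservation(self):
        # with the observed table at the distribution's mode, every table
        # satisfies P <= P_obs, so the enumeration must sum to exactly 1
        assert fisher_exact_table([[6, 4], [6, 4]]) == pytest.approx(1.0, abs=1e-10)
        assert fisher_exact_table([[4, 4, 4], [4, 4, 4]]) == pytest.approx(1.0, abs=1e-10)

    def test_large_table_requires_monte_carlo(self):
        big = [[4000, 3000], [2000, 1000]]
        with pytest.raises(UsageError, match="monte_carlo"):
            fisher_exact_table(big)
        p_mc = fisher_exact_table(big, monte_carlo=True, n_draws=2000, seed=1)
        assert 0 < p_mc <= 1

    def test_labels_interface(self):
        labels = pd.Series([1, 1, 1, 2, 2, 2], index=list("abcdef"))
        cov = pd.Series(["x", "x", "x", "y", "y", "y"], index=list("abcdef"))
        p, table = fisher_exact(labels, cov)
        assert table.shape == (2, 2)
        assert p == pytest.approx(scipy_fisher(table.to_numpy()).pvalue, rel=1e-7)


class TestLogRank:
    # 6 patients, 4 events; O/E/V computed by hand from the risk table
    TIME = np.array([1.0, 3.0, 5.0, 2.0, 4.0, 6.0])
    EVENT = np.array([1, 1, 0, 1, 1, 0])
    GROUP = np.array([1, 1, 1, 2, 2, 2])

    def test_hand_worked_risk_table(self):
        o1, e1, v, stat, p = logrank_two_group(self.TIME, self.EVENT, self.GROUP)
        assert o1 == pytest.approx(2.0)
        assert e1 == pytest.approx(0.5 + 0.4 + 0.5 + 1 / 3)
        assert v == pytest.approx(0.25 + 0.24 + 0.25 + 2 / 9)
        assert stat == pytest.approx((2 - (0.5 + 0.4 + 0.5 + 1 / 3)) ** 2
                                     / (0.25 + 0.24 + 0.25 + 2 / 9))

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test
        rng = np.random.default_rng(3)
        time = rng.exponential(10, 40)
        event = (rng.random(40) < 0.7).astype(int)
        group = np.repeat([1, 2], 20)
        *_, stat, p = logrank_two_group(time, event, group)
        ref = logrank_test(time[group == 1], time[group == 2],
                           event[group == 1], event[group == 2])
        assert stat == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_label_swap_invariance(self):
        *_, stat1, p1 = logrank_two_group(self.TIME, self.EVENT, self.GROUP)
        *_, stat2, p2 = logrank_two_group(self.TIME, self.EVENT, 3 - self.GROUP)
        assert stat1 == pytest.approx(stat2) and p1 == pytest.approx(p2)

    def test_identical_groups_give_p_one(self):
        time = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        event = np.array([1, 1, 0, 1, 1, 0])
        group = np.array([1, 1, 1, 2, 2, 2])
        *_, stat, p = logrank_two_group(time, event, group)
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)


class TestCompareMortality:
    def make_clinical(self, time, event_label, samples):
        return pd.DataFrame({
            "sex": 1, "age": 60.0, "smoking": "never", "alcohol": "no",
            "stage": "II", "site": "oral_cavity", "nodal": 0,
            "time_months": time, "event": event_label}, index=samples)

    def test_identical_patterns_p_one(self):
        samples = list("abcdef")
        clin = self.make_clinical([1, 2, 3, 1, 2, 3],
                                  ["OSCC_death"] * 2 + ["censored"]
                                  + ["OSCC_death"] * 2 + ["censored"], samples)
        labels = pd.Series([1, 1, 1, 2, 2, 2], index=samples)
        comp = compare_mortality(labels, clin)
        assert comp.statistic == pytest.approx(0.0) and comp.p_value == 1.0

    def test_no_events_warns_p_one(self):
        samples = list("abcd")
        clin = self.make_clinical([5, 6, 7, 8], ["censored"] * 4, samples)
        comp = compare_mortality(pd.Series([1, 1, 2, 2], index=samples), clin)
        assert comp.p_value == 1.0

    def test_competing_deaths_censored_in_curves(self):
        samples = list("abcd")
        clin = self.make_clinical([5, 6, 7, 8],
                                  ["OSCC_death", "other_death", "censored",
                                   "OSCC_death"], samples)
        comp = compare_mortality(pd.Series([1, 1, 2, 2], index=samples), clin)
        assert comp.n_events.sum() == 2  # other_death does not count
        for curve in comp.curves.values():
            assert (curve["cumulative_incidence"].diff().dropna() >= -1e-12).all()

    def test_planted_cluster_effect_detected(self):
        """Hazard linked to the planted cluster: log-rank p < 0.05 in the
        majority of replicates."""
        hits = 0
        for seed in range(7):
            cohort = generate_cohort(planted_cluster_config(
                seed=seed, n_samples=150, carrier_fraction=0.45,
                beta_cluster=1.3))
            truth = cohort.truth.cluster
            comp = compare_mortality(truth, cohort.clinical)
            hits += comp.p_value < 0.05
        assert hits >= 4


class TestClusterCovariateCox:
    def test_null_label_p_roughly_uniform(self):
        rng = np.random.default_rng(9)
        ps = []
        for seed in range(60):
            cohort = generate_cohort(planted_cluster_config(seed=100 + seed,
                                                            n_samples=60))
            labels = pd.Series(rng.choice([1, 2], 60),
                               index=cohort.clinical.index)
            if labels.nunique() < 2:
                continue
            _, p = cluster_covariate_cox(labels, cohort.clinical)
            ps.append(p)
        frac = np.mean(np.array(ps) < 0.1)
        assert abs(frac - 0.1) < 3 * np.sqrt(0.1 * 0.9 / len(ps))

    def test_duplicated_adjuster_degenerate(self):
        cohort = generate_cohort(planted_cluster_config(seed=8))
        clin = cohort.clinical.copy()
        labels = pd.Series(np.where(clin["sex"] == 1, 1, 2), index=clin.index)
        with pytest.raises(DegenerateDesignError):
            cluster_covariate_cox(labels, clin, adjusters=("sex",))

    def test_no_adjusters_matches_single_covariate_lrt(self):
        from lohcna.survival import fit_cox, lrt, encode_clinical
        cohort = generate_cohort(planted_cluster_config(seed=10))
        labels = cohort.truth.cluster
        stat, p = cluster_covariate_cox(labels, cohort.clinical)
        enc = encode_clinical(cohort.clinical)
        df = enc[["time", "event"]].copy()
        df["cluster"] = (labels == labels.iloc[0]).astype(float).to_numpy()
        stat2, p2 = lrt(fit_cox(df, ("cluster",)), fit_cox(df, ()), df=1)
        assert stat == pytest.approx(stat2) and p == pytest.approx(p2)
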