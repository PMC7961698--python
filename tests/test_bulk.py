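"""Bulk scoring, progressive six-cluster stratification and survival."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import crcprograms as c


class TestScoreBulk:
    def test_constant_expression_gives_constant_score(self):
        expr = pd.DataFrame(
            np.full((4, 6), 2.5), columns=[f"g{i}" for i in range(6)]
        )
        scores = c.score_bulk(expr, {"s": ["g0", "g1", "g2"]})
        assert (scores["s"] == 2.5).all()

    def test_two_gene_mean(self):
        expr = pd.DataFrame({"g0": [1.0], "g1": [3.0]})
        scores = c.score_bulk(expr, {"s": ["g0", "g1"]})
        assert scores.loc[0, "s"] == 2.0

    def test_missing_signature_rejected_and_missingness_recorded(self):
        expr = pd.DataFrame({"g0": [1.0, 2.0], "g1": [3.0, 4.0]})
        with pytest.raises(ValueError, match="absent"):
            c.score_bulk(expr, {"s": ["x", "y"]})
        with pytest.raises(ValueError, match="present"):
            c.score_bulk(expr, {"s": ["g0", "x", "y", "z"]})
        ok = c.score_bulk(expr, {"s": ["g0", "g1", "x"]}, min_present=0.5)
        assert ok.attrs["missing"]["s"] == pytest.approx(1 / 3)

    def test_scores_recover_planted_shifts(self):
        sigs, eff, hrs = c.default_bulk_archetypes(shift=2.0)
        coh = c.generate_bulk_cohort(240, sigs, eff, hrs, seed=9, noise_sd=0.5)
        scores = c.score_bulk(coh.expression, sigs)
        tol = 3 * 0.5 / np.sqrt(40)  # noise SD / sqrt(signature size)
        for cl, shifts in eff.items():
            sub = scores[(coh.cluster == cl).to_numpy()]
            for sig, shift in shifts.items():
                assert sub[sig].mean() == pytest.approx(5.0 + shift, abs=tol)


class TestProgressiveCluster:
    def test_zero_noise_exact_recovery(self):
        sigs, eff, hrs = c.default_bulk_archetypes()
        coh = c.generate_bulk_cohort(90, sigs, eff, hrs, seed=1, noise_sd=1e-9)
        scores = c.score_bulk(coh.expression, sigs)
        out = c.progressive_cluster(scores)
        assert (out.labels == coh.cluster).all()

    def test_sample_order_invariance(self):
        sigs, eff, hrs = c.default_bulk_archetypes()
        coh = c.generate_bulk_cohort(120, sigs, eff, hrs, seed=2, noise_sd=0.5)
        scores = c.score_bulk(coh.expression, sigs)
        a = c.progressive_cluster(scores).labels
        perm = scores.sample(frac=1.0, random_state=0)
        b = c.progressive_cluster(perm).labels
        assert (a.loc[scores.index] == b.loc[scores.index]).all()

    def test_duplicated_samples_get_identical_labels(self):
        sigs, eff, hrs = c.default_bulk_archetypes()
        coh = c.generate_bulk_cohort(60, sigs, eff, hrs, seed=3, noise_sd=0.3)
        scores = c.score_bulk(coh.expression, sigs)
        dup = pd.concat([scores, scores.set_axis([f"{i}_d" for i in scores.index])])
        labels = c.progressive_cluster(dup).labels
        for s in scores.index:
            assert labels[s] == labels[f"{s}_d"]

    def test_missing_signature_column_rejected(self):
        with pytest.raises(KeyError, match="missing signatures"):
            c.progressive_cluster(pd.DataFrame({"stem": [1.0, 2.0]}))

    def test_too_few_samples_rejected(self):
        sigs, eff, hrs = c.default_bulk_archetypes()
        coh = c.generate_bulk_cohort(6, sigs, eff, hrs, seed=4, noise_sd=0.1)
        scores = c.score_bulk(coh.expression, sigs).iloc[:1]
        with pytest.raises(ValueError, match="sample"):
            c.progressive_cluster(scores)


class TestKmLogrank:
    def test_identical_groups_statistic_zero(self):
        surv = pd.DataFrame(
            {"time": [5.0, 8, 12, 20], "event": [1, 1, 0, 1]}, index=list("abcd")
        )
        both = pd.concat([surv, surv.set_axis(list("wxyz"))])
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=both.index)
        res = c.km_logrank(groups, both)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_against_hand_computed_expected_events(self):
        # Independent oracle: the log-rank O-E table computed directly on a
        # 6-subject two-group example, all events observed.
        times = np.array([1.0, 2, 3, 4, 5, 6])
        groups = np.array(["A", "A", "A", "B", "B", "B"])
        at_risk = {"A": 3, "B": 3}
        o_minus_e, var = 0.0, 0.0
        for t in times:
            n = at_risk["A"] + at_risk["B"]
            e_a = at_risk["A"] / n
            d_a = 1.0 if groups[times == t][0] == "A" else 0.0
            o_minus_e += d_a - e_a
            if n > 1:
                var += at_risk["A"] * at_risk["B"] * (n - 1) / (n**2 * (n - 1))
            at_risk[groups[times == t][0]] -= 1
        expected_chi2 = o_minus_e**2 / var

        surv = pd.DataFrame({"time": times, "event": np.ones(6, dtype=int)},
                            index=[f"s{i}" for i in range(6)])
        res = c.km_logrank(pd.Series(groups, index=surv.index), surv)
        assert res.statistic == pytest.approx(expected_chi2, rel=1e-6)

    def test_merged_contrast_via_group_map(self):
        sigs, eff, hrs = c.default_bulk_archetypes()
        coh = c.generate_bulk_cohort(300, sigs, eff, hrs, seed=5)
        gm = {cl: ("poor" if cl in ("cl4", "cl5", "cl6") else "good")
              for cl in c.bulk.CLUSTER_LABELS}
        res = c.km_logrank(coh.cluster, coh.survival, group_map=gm)
        assert res.df == 1
        assert res.p_value < 0.05

    def test_single_group_rejected(self):
        surv = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 1]}, index=["a", "b"])
        with pytest.raises(ValueError, match="2 groups"):
            c.km_logrank(pd.Series(["A", "A"], index=["a", "b"]), surv)

    def test_km_reduces_to_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 40)
        surv = pd.DataFrame({"time": t, "event": 1}, index=[f"s{i}" for i in range(40)])
        groups = pd.Series(["A"] * 20 + ["B"] * 20, index=surv.index)
        res = c.km_logrank(groups, surv)
        km_a = res.curves["A"].iloc[:, 0]
        ta = np.sort(t[:20])
        for i, tt in enumerate(ta):
            assert km_a.loc[tt] == pytest.approx(1 - (i + 1) / 20, abs=1e-9)

    def test_logrank_p_agrees_with_permutation_null(self):
        rng = np.random.default_rng(1)
        surv = pd.DataFrame(
            {"time": rng.exponential(10, 24), "event": 1},
            index=[f"s{i}" for i in range(24)],
        )
        groups = pd.Series(["A"] * 12 + ["B"] * 12, index=surv.index)
        obs = c.km_logrank(groups, surv).statistic
        perm_stats = []
        for _ in range(1000):
            shuffled = pd.Series(rng.permutation(groups.to_numpy()), index=surv.index)
            perm_stats.append(c.km_logrank(shuffled, surv).statistic)
        p_perm = float(np.mean(np.asarray(perm_stats) >= obs))
        p_chi2 = c.km_logrank(groups, surv).p_value
        assert abs(p_perm - p_chi2) < 0.05


class TestCoxComparison:
    def test_constant_covariate_dropped_with_warning(self):
        sigs, eff, hrs = c.default_bulk_archetypes()
        coh = c.generate_bulk_cohort(150, sigs, eff, hrs, seed=6)
        covs = pd.DataFrame({"const": 1.0}, index=coh.survival.index)
        with pytest.warns(UserWarning, match="constant"):
            with_const = c.cox_model_comparison(coh.survival, covs, coh.cluster)
        without = c.cox_model_comparison(coh.survival, None, coh.cluster)
        assert with_const.ll_full == pytest.approx(without.ll_full, rel=1e-9)
        assert with_const.dropped_covariates == ["const"]

    def test_null_lr_p_uniform(self):
        # Cluster labels independent of hazard: LR p over 200 replicates is
        # uniform (KS not rejected at alpha = 0.01).
        sigs = {"stem": [f"S{i}" for i in range(10)]}
        eff = {cl: {"stem": 0.0} for cl in ("a", "b", "c")}
        hrs = {cl: 1.0 for cl in ("a", "b", "c")}
        pvals = []
        for rep in range(200):
            coh = c.generate_bulk_cohort(90, sigs, eff, hrs, seed=40_000 + rep)
            pvals.append(c.cox_model_comparison(coh.survival, None, coh.cluster).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_hazard_detected(self):
        # Cluster hazard ratio 2.5 at n = 300: LR p < 0.05 in >= 90% of reps.
        sigs = {"stem": [f"S{i}" for i in range(10)]}
        eff = {"a": {"stem": 0.0}, "b": {"stem": 0.0}}
        hits = 0
        for rep in range(30):
            coh = c.generate_bulk_cohort(
                300, sigs, eff, {"a": 1.0, "b": 2.5}, seed=50_000 + rep
            )
            hits += c.cox_model_comparison(coh.survival, None, coh.cluster).p_value < 0.05
        assert hits >= 27
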