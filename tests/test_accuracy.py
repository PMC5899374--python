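import numpy as np
import pandas as pd
import pytest

import sucroscreen as ss
from sucroscreen.accuracy import DegenerateResampleError

from _oracles import brute_force_auc, brute_force_roc_points


def _dataset(values45, labels, values90=None, two_occasions=False):
    """Small hand-built dataset: one (or two) record(s) per foal."""
    values90 = values90 if values90 is not None else values45
    records = []
    for i, (v45, v90, lab) in enumerate(zip(values45, values90, labels)):
        records.append(ss.FoalRecord(
            foal_id=f"F{i:03d}", occasion="pre", sucrose45=float(v45),
            sucrose90=float(v90), gl=int(lab), gdl=0, sql=0, csl=0))
        if two_occasions:
            records.append(ss.FoalRecord(
                foal_id=f"F{i:03d}", occasion="post", sucrose45=float(v45) + 1,
                sucrose90=float(v90) + 1, gl=int(lab), gdl=0, sql=0, csl=0))
    return ss.StudyDataset(tuple(records))


class TestDichotomize:
    @pytest.mark.parametrize("value, cutoff, expected",
                             [(35.4, 24, 1), (24.0, 24, 1), (10.0, 24, 0)])
    def test_threshold_convention(self, value, cutoff, expected):
        assert ss.dichotomize(value, cutoff) == expected

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            ss.dichotomize(0.0, 24)


class TestSpearman:
    def test_identity_and_antitone(self):
        x = [1.0, 5.0, 2.0, 9.0]
        assert ss.spearman_rho(x, x) == pytest.approx(1.0)
        assert ss.spearman_rho(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_hand_value(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with d = (2, -1, -1) wait -- ranks
        # x=(1,2,3) has ranks (1,2,3); y=(3,1,2) has ranks (3,1,2);
        # d = (-2, 1, 1), sum d^2 = 6 -> 1 - 36/24 = -0.5
        assert ss.spearman_rho([1, 2, 3], [3, 1, 2]) == pytest.approx(-0.5)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ss.spearman_rho([1, 2], [1, 2])
        with pytest.raises(ValueError):
            ss.spearman_rho([1, 2, 3], [2, 2, 2])


class TestEmpiricalROC:
    def test_perfect_separation(self):
        curve = ss.empirical_roc([1, 2, 3, 4], [0, 0, 1, 1])
        pts = set(zip(curve.one_minus_specificity, curve.sensitivity))
        assert {(0.0, 0.0), (0.0, 1.0), (1.0, 1.0)} <= pts

    def test_uninformative_all_equal(self):
        curve = ss.empirical_roc([5, 5, 5, 5], [0, 1, 0, 1])
        assert len(curve) == 2  # +inf endpoint and the single value
        assert curve.sensitivity.tolist() == [0.0, 1.0]
        assert curve.one_minus_specificity.tolist() == [0.0, 1.0]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ss.empirical_roc([1, 2, 3], [1, 1, 1])

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = rng.integers(4, 15)
            values = rng.integers(1, 8, size=n).astype(float)
            labels = np.zeros(n, int)
            labels[: n // 2] = 1
            rng.shuffle(labels)
            if labels.min() == labels.max():
                continue
            curve = ss.empirical_roc(values, labels)
            expected = brute_force_roc_points(values, labels)
            got = list(zip(curve.thresholds, curve.sensitivity,
                           curve.one_minus_specificity))
            assert got == pytest.approx(expected)


class TestAUC:
    @pytest.mark.parametrize("values, labels, expected", [
        ([1, 2, 3, 4], [0, 0, 1, 1], 1.0),
        ([1, 3, 2, 4], [1, 1, 0, 0], 0.25),
        ([5, 5, 5, 5], [0, 1, 0, 1], 0.5),
    ])
    def test_examples(self, values, labels, expected):
        assert ss.auc_point(values, labels) == pytest.approx(expected)

    def test_equals_trapezoid_and_brute_force(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            n = int(rng.integers(4, 20))
            values = rng.integers(1, 10, size=n).astype(float)
            labels = (rng.random(n) < 0.5).astype(int)
            if labels.min() == labels.max():
                continue
            auc = ss.auc_point(values, labels)
            assert auc == pytest.approx(brute_force_auc(values, labels))
            assert auc == pytest.approx(
                ss.empirical_roc(values, labels).trapezoidal_area())

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        values = rng.lognormal(3, 0.5, size=40)
        labels = (rng.random(40) < 0.4).astype(int)
        base = ss.auc_point(values, labels)
        assert ss.auc_point(np.log(values), labels) == pytest.approx(base)
        assert ss.auc_point(values**3, labels) == pytest.approx(base)


class TestClusterBootstrapAUC:
    def test_point_equals_full_sample_statistic(self, small_cohort):
        df = small_cohort.to_frame()
        expected = ss.auc_point(df["sucrose45_umol_l"], df["gl"])
        res = ss.cluster_bootstrap_auc(small_cohort, "gl", 45, n_boot=200, seed=1)
        assert res.point == pytest.approx(expected)
        assert res.ci[0] <= res.point <= res.ci[1]

    def test_no_bootstrap_requested(self, small_cohort):
        res = ss.cluster_bootstrap_auc(small_cohort, "gl", 45, n_boot=0, seed=1)
        assert res.ci is None

    def test_perfect_separation(self):
        ds = _dataset([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        res = ss.cluster_bootstrap_auc(ds, "gl", 45, n_boot=100, seed=2)
        assert res.point == 1.0
        assert res.ci[1] == 1.0

    def test_ci_narrows_with_sample_size(self):
        wide = ss.cluster_bootstrap_auc(
            ss.simulate_cohort(ss.SimulationConfig(n_foals=45, seed=8)),
            "gl", 45, n_boot=300, seed=3)
        narrow = ss.cluster_bootstrap_auc(
            ss.simulate_cohort(ss.SimulationConfig(n_foals=450, seed=8)),
            "gl", 45, n_boot=300, seed=3)
        assert (narrow.ci[1] - narrow.ci[0]) < (wide.ci[1] - wide.ci[0])

    def test_deterministic(self, small_cohort):
        a = ss.cluster_bootstrap_auc(small_cohort, "gl", 45, n_boot=100, seed=9)
        b = ss.cluster_bootstrap_auc(small_cohort, "gl", 45, n_boot=100, seed=9)
        assert a == b


class TestCompareAUC:
    def test_identical_tests(self):
        ds = _dataset([1, 2, 3, 10, 11, 4], [0, 0, 0, 1, 1, 1])
        res = ss.compare_auc(ds, "gl", n_boot=100, seed=1)
        assert res.delta == 0.0
        assert res.p_value == 1.0

    def test_antisymmetry(self, small_cohort):
        res = ss.compare_auc(small_cohort, "gl", n_boot=0, seed=1)
        df = small_cohort.to_frame().rename(columns={
            "sucrose45_umol_l": "sucrose90_umol_l",
            "sucrose90_umol_l": "sucrose45_umol_l"})
        swapped = ss.compare_auc(ss.StudyDataset.from_frame(df), "gl",
                                 n_boot=0, seed=1)
        assert swapped.delta == pytest.approx(-res.delta)

    def test_signal_versus_noise_excludes_zero(self):
        rng = np.random.default_rng(6)
        labels = np.repeat([0, 1], 20)
        v45 = np.where(labels == 1, 50.0, 10.0) + rng.random(40)
        v90 = rng.uniform(5, 60, size=40)
        ds = _dataset(v45, labels, values90=v90)
        res = ss.compare_auc(ds, "gl", n_boot=400, seed=7)
        assert res.ci[0] > 0
        assert res.p_value < 0.05


class TestYouden:
    @pytest.mark.parametrize("se, sp, expected",
                             [(1, 1, 1.0), (0.5, 0.5, 0.0), (0.89, 0.65, 0.54)])
    def test_index(self, se, sp, expected):
        assert ss.youden(se, sp) == pytest.approx(expected)

    @pytest.mark.parametrize("se, sp, expected",
                             [(1, 1, 1.0), (0, 0, -1.0), (0.89, 0.65, 0.6192)])
    def test_weighted_index(self, se, sp, expected):
        assert ss.weighted_youden(se, sp) == pytest.approx(expected)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            ss.youden(1.2, 0.5)
        with pytest.raises(ValueError):
            ss.weighted_youden(0.5, -0.1)


class TestSelectCutoff:
    def test_perfect_separation(self):
        curve = ss.empirical_roc([1, 2, 10, 11], [0, 0, 1, 1])
        perf = ss.select_cutoff(curve, "youden")
        assert perf.cutoff == 10
        assert perf.youden == pytest.approx(1.0)

    def test_tie_broken_toward_lower_threshold(self):
        # thresholds 10 and 20 both give Youden 0.5; lower must win
        curve = ss.empirical_roc([1, 5, 10, 20], [0, 0, 1, 1])
        sub = ss.select_cutoff(curve, "youden")
        assert sub.cutoff == 10

    def test_matches_exhaustive_search(self, small_cohort):
        df = small_cohort.to_frame()
        values = df["sucrose45_umol_l"].to_numpy()
        labels = df["gl"].to_numpy()
        curve = ss.empirical_roc(values, labels)
        perf = ss.select_cutoff(curve, "youden")
        best = max(
            ((t, np.mean(values[labels == 1] >= t)
              + np.mean(values[labels == 0] < t) - 1)
             for t in np.unique(values)),
            key=lambda p: (p[1], -p[0]),
        )
        assert perf.cutoff == pytest.approx(best[0])
        assert perf.youden == pytest.approx(best[1])

    def test_manual_max_se(self):
        curve = ss.empirical_roc([1, 2, 3, 10, 11], [0, 0, 1, 1, 1])
        perf = ss.select_cutoff(curve, "manual_max_se")
        assert perf.sensitivity == 1.0
        assert perf.specificity > 0
        assert perf.cutoff == 3  # largest threshold with Se = 1 and Sp > 0

    def test_degenerate_curve(self):
        curve = ss.ROCCurve(np.array([np.inf]), np.array([0.0]), np.array([0.0]))
        with pytest.raises(ValueError):
            ss.select_cutoff(curve)


class TestSeSpAtCutoff:
    def test_hand_counted_toy_table(self):
        values = [30, 40, 25, 10, 20, 50, 12, 24, 8, 30]
        labels = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        ds = _dataset(values, labels)
        perf = ss.se_sp_at_cutoff(ds, "gl", 45, cutoff=24, n_boot=0)
        # diseased {30, 40, 25, 10, 20}: >= 24 are 30, 40, 25
        assert perf.sensitivity == pytest.approx(3 / 5)
        # healthy {50, 12, 24, 8, 30}: below 24 are only 12 and 8
        assert perf.specificity == pytest.approx(2 / 5)

    def test_cutoff_below_all_values(self):
        ds = _dataset([10, 20, 30, 40], [0, 0, 1, 1])
        perf = ss.se_sp_at_cutoff(ds, "gl", 45, cutoff=1.0, n_boot=0)
        assert perf.sensitivity == 1.0
        assert perf.specificity == 0.0

    def test_perfect_separation_at_cutoff(self):
        ds = _dataset([1, 2, 30, 40], [0, 0, 1, 1])
        perf = ss.se_sp_at_cutoff(ds, "gl", 45, cutoff=25, n_boot=100, seed=1)
        assert perf.sensitivity == 1.0 and perf.specificity == 1.0
        assert perf.se_ci == (1.0, 1.0)


class TestPrevalence:
    def test_trivial_proportions(self):
        ds = _dataset([10, 20, 30, 40], [1, 0, 0, 0])
        est, _ = ss.prevalence(ds, "gl", "pre", n_boot=50, seed=1)
        assert est == pytest.approx(0.25)
        all_pos = _dataset([10, 20], [1, 1])
        est, _ = ss.prevalence(all_pos, "gl", "pre", n_boot=0)
        assert est == 1.0

    def test_missing_occasion(self):
        ds = _dataset([10, 20, 30], [1, 0, 1])
        with pytest.raises(ValueError):
            ss.prevalence(ds, "gl", "post")

    def test_default_cohort_recovers_configured_prevalence(self, big_cohort):
        est, ci = ss.prevalence(big_cohort, "gl", "pre", n_boot=200, seed=4)
        # endoscopy-observed prevalence: pi*se + (1-pi)*(1-sp)
        expected = 0.21 * 0.81 + 0.79 * 0.01
        assert est == pytest.approx(expected, abs=0.03)
        assert ci[0] <= est <= ci[1]


class TestPairedPrevalence:
    def test_no_discordant_pairs(self):
        ds = _dataset([10, 20], [1, 0], two_occasions=True)
        stat, p = ss.paired_prevalence_test(ds, "gl")
        assert (stat, p) == (0, 1.0)

    def test_one_directional_discordance(self):
        records = []
        for i in range(10):
            records.append(ss.FoalRecord(f"F{i}", "pre", 10, 10, 0, 0, 0, 0))
            records.append(ss.FoalRecord(f"F{i}", "post", 10, 10, 1, 0, 0, 0))
        stat, p = ss.paired_prevalence_test(ss.StudyDataset(tuple(records)), "gl")
        assert stat == 10
        assert p == pytest.approx(2 * 0.5**10)

    def test_symmetric_discordance(self):
        records = []
        for i in range(10):
            pre, post = (0, 1) if i < 5 else (1, 0)
            records.append(ss.FoalRecord(f"F{i}", "pre", 10, 10, pre, 0, 0, 0))
            records.append(ss.FoalRecord(f"F{i}", "post", 10, 10, post, 0, 0, 0))
        _, p = ss.paired_prevalence_test(ss.StudyDataset(tuple(records)), "gl")
        assert p == pytest.approx(1.0)

    def test_matches_statsmodels_exact(self):
        from statsmodels.stats.contingency_tables import mcnemar

        rng = np.random.default_rng(12)
        for _ in range(10):
            n = 30
            pre = (rng.random(n) < 0.4).astype(int)
            post = (rng.random(n) < 0.7).astype(int)
            records = []
            for i in range(n):
                records.append(ss.FoalRecord(f"F{i}", "pre", 10, 10,
                                             int(pre[i]), 0, 0, 0))
                records.append(ss.FoalRecord(f"F{i}", "post", 10, 10,
                                             int(post[i]), 0, 0, 0))
            ds = ss.StudyDataset(tuple(records))
            table = np.array([
                [np.sum((pre == 1) & (post == 1)), np.sum((pre == 1) & (post == 0))],
                [np.sum((pre == 0) & (post == 1)), np.sum((pre == 0) & (post == 0))],
            ])
            expected = mcnemar(table, exact=True).pvalue
            _, p = ss.paired_prevalence_test(ds, "gl")
            assert p == pytest.approx(expected, abs=1e-10)


class TestIncidence:
    def test_direct_arithmetic(self):
        records = []
        for i in range(10):
            post = 1 if i < 6 else 0
            records.append(ss.FoalRecord(f"F{i}", "pre", 10, 10, 0, 0, 0, 0))
            records.append(ss.FoalRecord(f"F{i}", "post", 10, 10, post, 0, 0, 0))
        ds = ss.StudyDataset(tuple(records))
        assert ss.incidence_rate(ds, "gl", weeks_between=2) == pytest.approx(0.30)

    def test_no_new_cases(self):
        ds = _dataset([10, 20], [0, 0], two_occasions=True)
        assert ss.incidence_rate(ds, "gl", weeks_between=3) == 0.0

    def test_generator_closed_form(self):
        """With a perfect endoscope the rate matches
        (prev_post - prev_pre) / ((1 - prev_pre) * weeks)."""
        cfg = ss.SimulationConfig(n_foals=3000, endo_se=1.0, endo_sp=1.0, seed=21)
        ds = ss.simulate_cohort(cfg)
        expected = (0.98 - 0.21) / (0.79 * 3.0)
        assert ss.incidence_rate(ds, "gl", 3.0) == pytest.approx(expected,
                                                                 abs=0.02)


class TestCohenKappa:
    def test_identical_raters(self):
        res = ss.cohen_kappa([0, 1, 0, 1], [0, 1, 0, 1])
        assert res.percent_agreement == 1.0
        assert res.kappa == pytest.approx(1.0)

    def test_hand_arithmetic_2x2(self):
        r1 = [1] * 50 + [0] * 50
        r2 = [1] * 40 + [0] * 10 + [1] * 10 + [0] * 40
        res = ss.cohen_kappa(r1, r2)
        assert res.percent_agreement == pytest.approx(0.8)
        assert res.kappa == pytest.approx(0.6)

    def test_balanced_complement(self):
        r1 = [0, 0, 1, 1]
        res = ss.cohen_kappa(r1, [1 - v for v in r1])
        assert res.kappa == pytest.approx(-1.0)

    def test_symmetry_and_sklearn_oracle(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(31)
        for _ in range(10):
            a = (rng.random(50) < 0.5).astype(int)
            b = (rng.random(50) < 0.6).astype(int)
            if a.min() == a.max() and b.min() == b.max():
                continue
            res = ss.cohen_kappa(a, b)
            assert res.kappa == pytest.approx(ss.cohen_kappa(b, a).kappa)
            assert res.kappa == pytest.approx(cohen_kappa_score(a, b))

    def test_undefined_flagged(self):
        with pytest.raises(ValueError, match="undefined"):
            ss.cohen_kappa([1, 1, 1], [1, 1, 1])
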