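"""ROC AUC, DeLong, Bonferroni, bootstrap and KS machinery."""

from itertools import combinations

import numpy as np
import pytest

from medadhere.evaluation import (
    ScoredTestSet,
    bonferroni_threshold,
    bootstrap_auc,
    compare_models,
    delong_test,
    ks_two_sample,
    roc_auc,
)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_four_point_hand_case(self):
        # enumerate the 4 positive-negative pairs: 3 concordant, 1 discordant
        assert roc_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(10, 80))
            scores = rng.normal(size=n).round(1)  # induce ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12)

    def test_negation_complements(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            scores = rng.normal(size=30).round(1)
            labels = rng.integers(0, 2, size=30)
            if labels.min() == labels.max():
                continue
            assert roc_auc(scores, labels) + roc_auc(-scores, labels) == \
                pytest.approx(1.0, abs=1e-12)


def jackknife_delong_variance(a, b, labels):
    """Independent oracle: grouped delete-one jackknife of the AUC difference."""
    a, b, labels = map(np.asarray, (a, b, labels))

    def diff(mask):
        return roc_auc(a[mask], labels[mask]) - roc_auc(b[mask], labels[mask])

    var = 0.0
    for cls in (0, 1):
        idx = np.nonzero(labels == cls)[0]
        k = len(idx)
        loo = []
        for i in idx:
            mask = np.ones(len(labels), dtype=bool)
            mask[i] = False
            loo.append(diff(mask))
        loo = np.array(loo)
        var += (k - 1) / k * ((loo - loo.mean()) ** 2).sum()
    return var


class TestDeLong:
    LABELS = np.array([1, 1, 1, 1, 0, 0, 0, 0])
    A = np.array([0.9, 0.7, 0.6, 0.3, 0.8, 0.4, 0.2, 0.1])
    B = np.array([0.8, 0.6, 0.5, 0.4, 0.7, 0.5, 0.3, 0.2])

    def test_self_comparison(self):
        res = delong_test(self.A, self.A, self.LABELS)
        assert res.z == 0.0 and res.p == 1.0

    def test_swap_negates_z_same_p(self):
        r1 = delong_test(self.A, self.B, self.LABELS)
        r2 = delong_test(self.B, self.A, self.LABELS)
        assert r1.z == pytest.approx(-r2.z)
        assert r1.p == pytest.approx(r2.p)
        assert (r1.auc_a, r1.auc_b) == (r2.auc_b, r2.auc_a)

    def test_variance_matches_jackknife_oracle(self):
        res = delong_test(self.A, self.B, self.LABELS)
        var_oracle = jackknife_delong_variance(self.A, self.B, self.LABELS)
        var_impl = ((res.auc_a - res.auc_b) / res.z) ** 2
        assert var_impl == pytest.approx(var_oracle, abs=1e-8)

    def test_variance_matches_jackknife_on_random_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n = int(rng.integers(8, 30))
            labels = np.array([1, 0] * (n // 2))
            a = rng.normal(size=len(labels))
            b = a + rng.normal(scale=0.5, size=len(labels))
            res = delong_test(a, b, labels)
            if res.z == 0.0 or res.degenerate:
                continue
            var_impl = ((res.auc_a - res.auc_b) / res.z) ** 2
            assert var_impl == pytest.approx(
                jackknife_delong_variance(a, b, labels), rel=1e-8)

    def test_invariant_to_monotone_transform(self):
        r1 = delong_test(self.A, self.B, self.LABELS)
        r2 = delong_test(np.exp(3 * self.A), np.exp(3 * self.B), self.LABELS)
        assert r1.z == pytest.approx(r2.z, abs=1e-12)
        assert r1.p == pytest.approx(r2.p, abs=1e-12)

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            labels = rng.integers(0, 2, size=20)
            if labels.min() == labels.max():
                continue
            res = delong_test(rng.normal(size=20), rng.normal(size=20),
                              labels)
            assert 0.0 <= res.p <= 1.0

    def test_degenerate_flagged(self):
        labels = np.array([1, 1, 0, 0])
        a = np.array([1.0, 1.0, 0.0, 0.0])   # perfect, no variability
        b = np.array([0.0, 0.0, 1.0, 1.0])   # perfectly wrong
        res = delong_test(a, b, labels)
        assert res.degenerate


class TestBonferroni:
    def test_nine_models(self):
        m, thr = bonferroni_threshold(0.05, 9)
        assert m == 36
        assert thr == pytest.approx(0.00139, abs=5e-6)

    def test_six_models(self):
        m, thr = bonferroni_threshold(0.05, 6)
        assert m == 15
        assert thr == pytest.approx(3.333e-3, abs=5e-7)

    def test_two_models(self):
        assert bonferroni_threshold(0.05, 2) == (1, 0.05)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 1)


class TestKS:
    def test_identical_samples(self):
        x = np.arange(10.0)
        d, p = ks_two_sample(x, x)
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        d, _ = ks_two_sample([1.0, 2.0, 3.0], [10.0, 11.0])
        assert d == 1.0

    def test_brute_force_ecdf_oracle(self):
        x = np.array([0.1, 0.4, 0.6, 0.8, 0.9])
        y = np.array([0.2, 0.3, 0.5, 0.7, 0.95])
        grid = np.concatenate([x, y])
        ecdf = lambda s, t: np.mean(s <= t)
        d_oracle = max(abs(ecdf(x, t) - ecdf(y, t)) for t in grid)
        d, _ = ks_two_sample(x, y)
        assert d == pytest.approx(d_oracle, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


def _scored(seed=0, n=120):
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 2, size=n)
    strong = labels + rng.normal(scale=0.6, size=n)
    weak = labels + rng.normal(scale=2.0, size=n)
    return ScoredTestSet(labels=labels,
                         scores={"strong": strong, "weak": weak})


class TestBootstrap:
    def test_seeded_reproducibility(self):
        scored = _scored()
        r1 = bootstrap_auc(scored, n_reps=50, seed=9)
        r2 = bootstrap_auc(scored, n_reps=50, seed=9)
        for name in scored.scores:
            np.testing.assert_array_equal(r1.auc_samples[name],
                                          r2.auc_samples[name])

    def test_samples_bounded_and_centered(self):
        scored = _scored()
        res = bootstrap_auc(scored, n_reps=400, seed=1)
        point = roc_auc(scored.scores["strong"], scored.labels)
        s = res.auc_samples["strong"]
        assert np.all((0 <= s) & (s <= 1))
        assert abs(s.mean() - point) < 2 * s.std()

    def test_degenerate_two_patient_set_redraws_to_original(self):
        scored = ScoredTestSet(labels=np.array([1, 0]),
                               scores={"m": np.array([0.9, 0.1])})
        res = bootstrap_auc(scored, n_reps=1, seed=0)
        # the only two-class resample of size 2 is the original set
        assert res.auc_samples["m"][0] == roc_auc([0.9, 0.1], [1, 0])

    def test_ks_pairs_present(self):
        scored = _scored()
        res = bootstrap_auc(scored, n_reps=60, seed=2)
        assert set(res.ks_p) == set(combinations(sorted(scored.scores), 2))


class TestCompareModels:
    def test_report_structure(self):
        scored = _scored(n=300)
        report = compare_models(scored, alpha=0.05)
        assert report.m == 1
        assert report.bonferroni_threshold == 0.05
        assert set(report.auc) == {"strong", "weak"}
        assert report.auc["strong"] > report.auc["weak"]
        key = ("strong", "weak")
        assert 0 <= report.p_values[key] <= 1
        d = report.to_json_dict()
        assert "strong|weak" in d["p_values"]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ScoredTestSet(labels=np.ones(5, dtype=int),
                          scores={"m": np.zeros(5)})
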