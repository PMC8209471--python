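"""Feature fusion, Fisher ranking, LOOCV SVM, permutation and rank statistics."""

import numpy as np
import pytest

from connfuse import (
    ChannelMontage, PDCMatrix, PLIMatrix, ValidationError,
    build_feature_table, compare_selected_features, fisher_score, loocv_svm,
    modified_permutation_test, read_feature_table,
    select_and_classify_combined, select_and_classify_single,
    write_feature_table,
)


def _montage(n):
    return ChannelMontage(tuple(f"c{i}" for i in range(n)))


def _matrices(n_channels, n_subjects, seed=0):
    rng = np.random.default_rng(seed)
    plis, pdcs = [], []
    for _ in range(n_subjects):
        u = np.triu(rng.uniform(0, 1, (n_channels, n_channels)), 1)
        plis.append(PLIMatrix(values=u + u.T, band=(4, 7), window=(0.1, 0.6),
                              montage=_montage(n_channels)))
        d = rng.uniform(0, 1, (n_channels, n_channels))
        np.fill_diagonal(d, 0)
        pdcs.append(PDCMatrix(values=d, band=(4, 7), montage=_montage(n_channels)))
    return plis, pdcs


def _gaussian_table(n_per_group, n_features, informative=(), shift=3.0, seed=0):
    """Noise features; listed columns get a group mean shift."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    values = rng.standard_normal((n, n_features))
    labels = np.array(["SZ"] * n_per_group + ["HC"] * n_per_group)
    for j in informative:
        values[:n_per_group, j] += shift
    return values, labels


class TestBuildFeatureTable:
    def test_twenty_channels_give_570_columns(self):
        plis, pdcs = _matrices(20, 4)
        t = build_feature_table(plis, pdcs, ["SZ", "SZ", "HC", "HC"])
        assert t.values.shape == (4, 570)

    def test_three_channels_give_nine_columns(self):
        plis, pdcs = _matrices(3, 4)
        t = build_feature_table(plis, pdcs, ["SZ", "SZ", "HC", "HC"])
        assert t.values.shape == (4, 9)

    def test_column_zero_is_first_upper_triangle_pli(self):
        plis, pdcs = _matrices(3, 2)
        t = build_feature_table(plis, pdcs, ["SZ", "HC"])
        assert t.descriptors[0] == ("PLI", "c0", "c1")
        assert t.values[0, 0] == plis[0].values[0, 1]
        assert t.descriptors[3][0] == "PDC"

    def test_tsv_round_trip(self, tmp_path):
        plis, pdcs = _matrices(4, 3)
        t = build_feature_table(plis, pdcs, ["SZ", "HC", "HC"], ["a", "b", "c"])
        write_feature_table(t, tmp_path / "ft.tsv")
        back = read_feature_table(tmp_path / "ft.tsv")
        assert np.allclose(back.values, t.values)
        assert back.descriptors == t.descriptors
        assert back.subject_ids == ["a", "b", "c"]


class TestFisherScore:
    def test_equal_means_score_zero(self):
        values = np.array([[1.0], [1.0], [1.0], [1.0]])
        r = fisher_score(values + [[0.1], [-0.1], [0.1], [-0.1]],
                         np.array(["a", "a", "b", "b"]))
        assert r.scores[0] == 0.0

    def test_textbook_value(self):
        # mu1 = 0, mu2 = 2, unit class variances -> F = 4 / 2 = 2
        rng = np.random.default_rng(0)
        a = rng.standard_normal(3000)
        b = rng.standard_normal(3000) + 2.0
        values = np.concatenate([a, b])[:, None]
        labels = np.array(["x"] * 3000 + ["y"] * 3000)
        assert fisher_score(values, labels).scores[0] == pytest.approx(2.0, rel=0.1)

    def test_scale_invariance(self):
        values, labels = _gaussian_table(8, 5, informative=(1,))
        s1 = fisher_score(values, labels).scores
        s2 = fisher_score(values * 37.5, labels).scores
        assert np.allclose(s1, s2)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            fisher_score(np.zeros((4, 2)), np.array(["a"] * 4))

    def test_ties_broken_by_index(self):
        values = np.zeros((4, 3))
        r = fisher_score(values, np.array(["a", "a", "b", "b"]))
        assert list(r.order) == [0, 1, 2]


class TestLoocvSvm:
    def test_separable_data_perfect(self):
        values, labels = _gaussian_table(20, 3, informative=(0,), shift=10.0)
        r = loocv_svm(values, labels, "SZ")
        assert r.acc == 100.0 and r.auc == 1.0

    def test_chance_level_on_permuted_labels(self):
        rng = np.random.default_rng(1)
        values, labels = _gaussian_table(10, 3, informative=(0,), shift=5.0)
        accs = []
        for _ in range(50):
            accs.append(loocv_svm(values, rng.permutation(labels), "SZ").acc)
        se = 100 * 0.5 / np.sqrt(len(accs) * 20)
        # permuted labels should hover around 50%; allow wide slack since
        # LOOCV on permuted labels is anti-correlated across folds
        assert abs(np.mean(accs) - 50.0) < 10.0

    def test_confusion_arithmetic(self):
        # force one positive mistake: move one SZ subject into HC territory
        values, labels = _gaussian_table(6, 2, informative=(0,), shift=8.0)
        values[0, 0] -= 16.0  # this SZ subject looks like an HC
        r = loocv_svm(values, labels, "SZ")
        assert r.sen == pytest.approx(100.0 * 5 / 6)
        assert r.spe == 100.0
        assert r.acc == pytest.approx(100.0 * 11 / 12)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValidationError):
            loocv_svm(np.zeros((3, 2)), np.array(["a", "a", "b"]), "a")

    def test_deterministic(self):
        values, labels = _gaussian_table(8, 4, informative=(0,), shift=2.0)
        r1 = loocv_svm(values, labels, "SZ")
        r2 = loocv_svm(values, labels, "SZ")
        assert r1.acc == r2.acc and np.array_equal(r1.decision_values,
                                                   r2.decision_values)


def _planted_table(seed=0, n_per_group=12):
    """570-feature-like table with one informative PLI and one PDC column."""
    rng = np.random.default_rng(seed)
    plis, pdcs = _matrices(5, 2 * n_per_group, seed=seed)
    labels = ["SZ"] * n_per_group + ["HC"] * n_per_group
    t = build_feature_table(plis, pdcs, labels)
    # plant effects: one undirected (col 2) and one directed feature
    pdc_cols = t.columns_of("PDC")
    t.values[:n_per_group, 2] += 2.0
    t.values[:n_per_group, pdc_cols[5]] += 2.0
    return t, 2, int(pdc_cols[5])


class TestSelectionStrategies:
    def test_single_recovers_planted_feature(self):
        t, pli_col, _ = _planted_table()
        best = select_and_classify_single(t, "PLI", n_max=5)
        assert best.n_features <= 3
        assert t.descriptors[pli_col] in best.selected

    def test_nmax_one_single_evaluation(self):
        t, _, _ = _planted_table()
        best = select_and_classify_single(t, "PLI", n_max=1)
        assert best.n_features == 1

    def test_combined_recovers_both_planted(self):
        t, pli_col, pdc_col = _planted_table()
        best = select_and_classify_combined(t, l_max=4)
        assert t.descriptors[pli_col] in best.selected
        assert t.descriptors[pdc_col] in best.selected

    def test_combined_lmax_two_single_split(self):
        t, _, _ = _planted_table()
        best = select_and_classify_combined(t, l_max=2)
        assert best.n_features == 2 and best.split == (1, 1)

    def test_combined_at_least_single_on_planted_data(self):
        t, _, _ = _planted_table(seed=3)
        fc = select_and_classify_single(t, "PLI", n_max=4)
        ec = select_and_classify_single(t, "PDC", n_max=4)
        comb = select_and_classify_combined(t, l_max=4)
        assert comb.acc >= fc.acc and comb.acc >= ec.acc

    def test_full_data_ranking_mode(self):
        t, pli_col, _ = _planted_table(seed=5)
        best = select_and_classify_single(t, "PLI", n_max=3,
                                          rank_on_full_data=True)
        assert t.descriptors[pli_col] in best.selected

    def test_within_fold_ranking_never_sees_held_out(self, monkeypatch):
        # instrumentation: every ranking call inside the LOOCV must see
        # exactly n-1 subjects (the training fold), never all n
        import connfuse.classify as cl

        calls = []
        orig = cl.fisher_score

        def spy(values, labels):
            calls.append(values.shape[0])
            return orig(values, labels)

        monkeypatch.setattr(cl, "fisher_score", spy)
        t, _, _ = _planted_table(seed=9)
        cl.select_and_classify_single(t, "PLI", n_max=2)
        n = t.values.shape[0]
        assert calls.count(n - 1) == 2 * n  # n folds for each of N = 1, 2
        assert calls.count(n) == 2  # one full-data call per N, reporting only

    def test_strategy_is_deterministic(self):
        t, _, _ = _planted_table(seed=7)
        b1 = select_and_classify_combined(t, l_max=3)
        b2 = select_and_classify_combined(t, l_max=3)
        assert (b1.acc, b1.split, b1.selected) == (b2.acc, b2.split, b2.selected)


class TestModifiedPermutationTest:
    def test_separable_data_small_p(self):
        # many subjects per feature dimension: 24 points in 2-D are almost
        # never linearly separable by chance after column shuffling
        # (Cover's bound ~ 2 sum_{k<=2} C(23,k) / 2^24 ~ 3e-5 per perm)
        values, labels = _gaussian_table(12, 2, informative=(0, 1), shift=6.0)
        r = modified_permutation_test(values, labels, "SZ", n_perm=500, seed=0)
        assert r.observed_acc == 100.0
        assert r.p_value <= 0.002

    def test_p_value_convention(self):
        values, labels = _gaussian_table(6, 2, seed=2)
        r = modified_permutation_test(values, labels, "SZ", n_perm=100, seed=1)
        count = int(np.sum(r.null_accs >= r.observed_acc))
        assert r.p_value == (1 + count) / 101

    def test_low_n_perm_rejected(self):
        values, labels = _gaussian_table(6, 2)
        with pytest.raises(ValidationError):
            modified_permutation_test(values, labels, "SZ", n_perm=50)


class TestCompareSelectedFeatures:
    def test_planted_shift_detected_with_direction(self):
        values, labels = _gaussian_table(15, 4, informative=(1,), shift=3.0,
                                         seed=4)
        res = compare_selected_features(values, labels, 0.05,
                                        group_order=("SZ", "HC"))
        assert res[1].p_fdr < 0.05 and res[1].direction == "up"
        assert res[0].p_fdr > 0.05

    def test_constant_feature_p_one(self):
        values, labels = _gaussian_table(5, 2)
        values[:, 0] = 3.14
        res = compare_selected_features(values, labels, 0.05)
        assert res[0].p_raw == 1.0

    def test_bh_arithmetic(self):
        # BH on (0.01, 0.02, 0.9) at q = 0.05 rejects the first two
        from statsmodels.stats.multitest import multipletests

        reject, p_adj, _, _ = multipletests([0.01, 0.02, 0.9], alpha=0.05,
                                            method="fdr_bh")
        assert list(reject) == [True, True, False]
        assert np.allclose(p_adj, [0.03, 0.03, 0.9])
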