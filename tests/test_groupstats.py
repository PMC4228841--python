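import itertools

import numpy as np
import pandas as pd
import pytest

from sppa3.groupstats import (
    BONFERRONI_P,
    GROUP_TESTS,
    TIER_BONFERRONI,
    TIER_HIGHLY,
    TIER_NS,
    TIER_SIGNIFICANT,
    CohortFeatures,
    best_index_search,
    bonferroni_threshold,
    count_significant,
    group_test,
    loocv_discriminant,
    mann_whitney_u,
    roc_summary,
    screen_cubelets,
    tier_of,
)


def permutation_pvalue(a, b):
    """Full enumeration of the two-sided rank-sum null over all C(n,|a|) splits."""
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    ranks = pooled.argsort().argsort() + 1  # no ties by construction

    def ustat(idx):
        r = ranks[list(idx)].sum()
        return r - na * (na + 1) / 2

    observed = ustat(range(na))
    mu = na * (len(b)) / 2
    dev = abs(observed - mu)
    hits = sum(
        abs(ustat(comb) - mu) >= dev - 1e-12
        for comb in itertools.combinations(range(n), na)
    )
    from math import comb as ncomb

    return hits / ncomb(n, na)


class TestMannWhitney:
    def test_identical_samples_give_p_one(self, rng):
        a = rng.uniform(size=10)
        assert mann_whitney_u(a, a.copy()) > 0.99

    def test_matches_full_permutation_enumeration(self):
        a, b = np.array([1.0, 2, 3]), np.array([4.0, 5, 6])
        assert mann_whitney_u(a, b) == pytest.approx(permutation_pvalue(a, b))
        assert mann_whitney_u(a, b) == pytest.approx(0.1)

    def test_matches_enumeration_on_random_tie_free_samples(self, rng):
        for _ in range(5):
            a = rng.permutation(100)[:5].astype(float)
            b = (rng.permutation(100)[:6] + 0.5).astype(float)
            assert mann_whitney_u(a, b) == pytest.approx(permutation_pvalue(a, b))

    def test_all_tied_zero_samples(self):
        p = mann_whitney_u(np.zeros(4), np.zeros(4))
        assert p == 1.0
        assert tier_of(p) == TIER_NS

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            mann_whitney_u(np.array([]), np.array([1.0]))


class TestTiers:
    def test_threshold_arithmetic(self):
        assert tier_of(0.2) == TIER_NS
        assert tier_of(0.03) == TIER_SIGNIFICANT
        assert tier_of(0.009) == TIER_HIGHLY
        assert tier_of(0.000001) == TIER_BONFERRONI

    def test_bonferroni_constant_reproduced_by_rounding(self):
        # 0.05/1728 = 2.89e-5 → one significant figure → 3e-5
        assert bonferroni_threshold(1728) == BONFERRONI_P

    def test_group_test_definitions(self):
        assert group_test("VIII").group_a == frozenset({"CH", "PIH"})
        assert group_test("VIII").group_b == frozenset({"PE"})
        assert group_test("IX").group_a == frozenset({"PREG", "CH", "PIH"})
        assert group_test("X").group_b == frozenset({"CH", "PIH", "PE"})
        assert len(GROUP_TESTS) == 10


def make_cohort(frame_a, frame_b, label_a="PREG", label_b="PE", name="fs"):
    na, nb = len(frame_a), len(frame_b)
    subjects = [f"A{i}" for i in range(na)] + [f"B{i}" for i in range(nb)]
    cohort = CohortFeatures(subjects=subjects, labels=[label_a] * na + [label_b] * nb)
    frame = pd.DataFrame(
        np.vstack([frame_a, frame_b]),
        index=subjects,
        columns=[f"c{j}" for j in range(frame_a.shape[1])],
    )
    cohort.add_table(name, frame)
    return cohort


class TestScreening:
    def test_null_false_positive_rate_is_calibrated(self, rng):
        cohort = make_cohort(
            rng.uniform(size=(12, 1728)), rng.uniform(size=(12, 1728))
        )
        sr = screen_cubelets(cohort, group_test("IV"), "fs")
        frac = (sr.pvalues < 0.01).mean()
        assert frac <= 0.03
        assert count_significant(sr, TIER_HIGHLY) == (sr.pvalues < 0.01).sum()

    def test_injected_effect_dominates_smallest_pvalues(self, rng):
        a = rng.uniform(size=(12, 200))
        b = rng.uniform(size=(12, 200))
        b[:, 40:50] += 2.0  # shifted block
        cohort = make_cohort(a, b)
        sr = screen_cubelets(cohort, group_test("IV"), "fs")
        top10 = set(sr.pvalues.nsmallest(10).index)
        assert top10 == {f"c{j}" for j in range(40, 50)}

    def test_single_cubelet_composes_scalar_test(self, rng):
        a = rng.uniform(size=(5, 1))
        b = rng.uniform(size=(6, 1)) + 0.3
        cohort = make_cohort(a, b)
        sr = screen_cubelets(cohort, group_test("IV"), "fs")
        assert sr.pvalues.iloc[0] == pytest.approx(
            mann_whitney_u(a[:, 0], b[:, 0])
        )

    def test_vectorised_and_scalar_paths_agree(self, rng):
        a = rng.uniform(size=(10, 40))
        b = rng.uniform(size=(10, 40))
        a[:, 0] = b[:, 0] = 0.0  # an all-tied (empty-cubelet) column
        cohort = make_cohort(a, b)
        sr = screen_cubelets(cohort, group_test("IV"), "fs")  # fast path (n>8... not)
        expected = [mann_whitney_u(a[:, j], b[:, j]) for j in range(40)]
        np.testing.assert_allclose(sr.pvalues.to_numpy(), expected, rtol=1e-9)
        assert sr.pvalues.iloc[0] == 1.0

    def test_empty_group_errors_naming_test(self, rng):
        cohort = make_cohort(rng.uniform(size=(5, 4)), rng.uniform(size=(5, 4)))
        with pytest.raises(ValueError, match="VIII"):
            screen_cubelets(cohort, group_test("VIII"), "fs")

    def test_viii_equals_ix_without_preg_subjects(self, rng):
        a = rng.uniform(size=(8, 30))
        b = rng.uniform(size=(8, 30)) + 0.2
        cohort = make_cohort(a, b, label_a="CH", label_b="PE")
        p8 = screen_cubelets(cohort, group_test("VIII"), "fs").pvalues
        p9 = screen_cubelets(cohort, group_test("IX"), "fs").pvalues
        np.testing.assert_array_equal(p8.to_numpy(), p9.to_numpy())

    def test_count_matches_filter_oracle(self, rng):
        cohort = make_cohort(
            rng.uniform(size=(10, 100)), rng.uniform(size=(10, 100)) + 0.25
        )
        sr = screen_cubelets(cohort, group_test("IV"), "fs")
        for tier, thr in [
            (TIER_SIGNIFICANT, 0.05),
            (TIER_HIGHLY, 0.01),
            (TIER_BONFERRONI, BONFERRONI_P),
        ]:
            assert count_significant(sr, tier) == sum(
                p < thr for p in sr.pvalues
            )
        # the Bonferroni-tier set is nested in the highly-tier set
        assert count_significant(sr, TIER_BONFERRONI) <= count_significant(
            sr, TIER_HIGHLY
        )


class TestDiscriminant:
    def test_perfect_separation_gives_auc_100(self, rng):
        x = np.concatenate([rng.uniform(0, 1, 8), rng.uniform(2, 3, 8)])
        y = np.repeat([0, 1], 8)
        ev = loocv_discriminant(x, y)
        assert ev.auc == 100.0
        assert ev.sens == 100.0 and ev.spec == 100.0

    def test_permuted_labels_give_chance_auc(self, rng):
        x = rng.normal(size=24)
        y = np.repeat([0, 1], 12)
        aucs = []
        for _ in range(200):
            aucs.append(loocv_discriminant(x, rng.permutation(y)).auc)
        assert np.mean(aucs) == pytest.approx(50.0, abs=3.0)

    def test_pair_beats_both_marginals_on_diagonal_geometry(self, rng):
        # class means offset along the diagonal with overlapping marginals:
        # only the 2D discriminant separates well
        n = 30
        common = rng.normal(size=(2 * n,))
        noise = rng.normal(scale=0.15, size=(2 * n, 2))
        x = np.column_stack([common, -common]) + noise
        x[n:] += [0.55, 0.55]
        y = np.repeat([0, 1], n)
        auc_pair = loocv_discriminant(x, y).auc
        auc_1 = loocv_discriminant(x[:, 0], y).auc
        auc_2 = loocv_discriminant(x[:, 1], y).auc
        assert auc_pair > max(auc_1, auc_2)

    def test_label_reversal_maps_auc_to_complement(self, rng):
        # for a fixed score vector, flipping the labels mirrors the ROC
        x = rng.normal(size=20) + np.repeat([0.0, 1.0], 10)
        y = np.repeat([0, 1], 10)
        _, _, a1, _, _ = roc_summary(x, y)
        _, _, a2, _, _ = roc_summary(x, 1 - y)
        assert a1 + a2 == pytest.approx(100.0, abs=1e-9)
        # the refit LOOCV discriminant re-orients toward the positive class,
        # so its AUC is invariant under relabelling (scores negate exactly)
        e1, e2 = loocv_discriminant(x, y), loocv_discriminant(x, 1 - y)
        np.testing.assert_allclose(e1.loocv_scores, -e2.loocv_scores, atol=1e-12)
        assert e1.auc == pytest.approx(e2.auc, abs=1e-9)

    def test_auc_invariant_under_monotone_score_transform(self, rng):
        scores = rng.normal(size=30)
        y = rng.integers(0, 2, 30)
        y[:3], y[-3:] = 0, 1
        _, _, auc1, _, _ = roc_summary(scores, y)
        _, _, auc2, _, _ = roc_summary(np.exp(scores / 2), y)
        assert auc1 == pytest.approx(auc2, abs=1e-12)

    def test_singular_covariance_falls_back_to_diagonal(self, rng, caplog):
        x = np.column_stack([rng.normal(size=12), np.zeros(12)])
        x[6:, 0] += 3.0
        y = np.repeat([0, 1], 6)
        with caplog.at_level("WARNING"):
            ev = loocv_discriminant(x, y)
        assert ev.auc == 100.0
        assert any("singular" in r.message for r in caplog.records)

    def test_fewer_than_three_per_class_rejected(self, rng):
        with pytest.raises(ValueError):
            loocv_discriminant(rng.normal(size=5), np.array([0, 0, 1, 1, 1]))


class TestBestIndexSearch:
    def _cohort_with_signal(self, rng, n_cols=6, strong_col=0):
        a = rng.uniform(size=(10, n_cols)) * 0.05
        b = rng.uniform(size=(10, n_cols)) * 0.05
        b[:, strong_col] += 1.0  # perfectly separating index
        b[:, 1] += 0.04  # weaker effect
        return make_cohort(a, b)

    def test_single_candidate_matches_direct_evaluation(self, rng):
        cohort = self._cohort_with_signal(rng)
        test = group_test("IV")
        sr = screen_cubelets(cohort, test, "fs")
        # keep only the strongest candidate
        strongest = sr.pvalues.nsmallest(1)
        from sppa3.groupstats import ScreeningResult

        sr1 = ScreeningResult(test=test, feature_set="fs", pvalues=strongest)
        ranked = best_index_search(cohort, test, {"fs": sr1})
        assert len(ranked) == 1
        direct = loocv_discriminant(
            cohort.tables["fs"][strongest.index[0]].to_numpy(),
            np.repeat([0, 1], 10),
        )
        assert ranked[0].auc == direct.auc

    def test_perfect_separator_ranks_first(self, rng):
        cohort = self._cohort_with_signal(rng, strong_col=3)
        test = group_test("IV")
        sr = screen_cubelets(cohort, test, "fs")
        ranked = best_index_search(cohort, test, {"fs": sr})
        assert ranked[0].index_labels == ("c3",)
        assert ranked[0].auc == 100.0

    def test_ranking_equals_exhaustive_reevaluation(self, rng):
        cohort = self._cohort_with_signal(rng)
        test = group_test("IV")
        sr = screen_cubelets(cohort, test, "fs")
        ranked = best_index_search(cohort, test, {"fs": sr})
        y = np.repeat([0, 1], 10)
        oracle = []
        for lab in sr.candidates():
            ev = loocv_discriminant(cohort.tables["fs"][lab].to_numpy(), y)
            oracle.append((-ev.auc, -(ev.sens + ev.spec), (lab,)))
        oracle.sort()
        assert [e.index_labels for e in ranked] == [key[2] for key in oracle]

    def test_pair_search_mixes_univariate_and_multivariate(self, rng):
        cohort = self._cohort_with_signal(rng)
        uni = pd.DataFrame(
            rng.uniform(size=(20, 3)),
            index=cohort.subjects,
            columns=["u0", "u1", "u2"],
        )
        uni.iloc[10:, 1] += 1.0
        cohort.add_table("uni", uni, variant="univariate")
        test = group_test("IV")
        screenings = {
            "fs": screen_cubelets(cohort, test, "fs"),
            "uni": screen_cubelets(cohort, test, "uni"),
        }
        ranked = best_index_search(cohort, test, screenings, max_pair=True)
        pairs = [e for e in ranked if len(e.indices) == 2]
        assert pairs
        for e in pairs:
            variants = {cohort.variants[fs] for fs, _ in e.indices}
            assert variants == {"univariate", "multivariate"}

    def test_no_surviving_candidate_returns_empty(self, rng):
        a = rng.uniform(size=(6, 4))
        cohort = make_cohort(a, a.copy())
        test = group_test("IV")
        sr = screen_cubelets(cohort, test, "fs")
        ranked = best_index_search(cohort, test, {"fs": sr})
        assert ranked == []
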