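"""Cross-validation plans, stability and discrimination metrics against
independent brute-force oracles, the Brier decomposition identity, and the
two-stage configuration rule."""

import itertools

import numpy as np
import pandas as pd
import pytest

from moepheno.selection import (
    BrierDecomposition,
    GridResult,
    adjusted_rand_index,
    auprc,
    auroc,
    brier_decomposition,
    cluster_size_check,
    logistic_baseline,
    make_fold_plan,
    mean_pairwise_ari,
    select_configuration,
)


# --- independent oracles ---------------------------------------------------


def ari_bruteforce(a, b):
    """ARI from raw pair counting: classify every unordered item pair as
    together/apart in each partition, then chance-correct the Rand index
    using the permutation-model expectation from the contingency table."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    pairs = list(itertools.combinations(range(n), 2))
    same_a = np.array([a[i] == a[j] for i, j in pairs])
    same_b = np.array([b[i] == b[j] for i, j in pairs])
    n11 = (same_a & same_b).sum()
    n_pairs = len(pairs)
    sum_a = sum(c * (c - 1) / 2 for c in np.bincount(a))
    sum_b = sum(c * (c - 1) / 2 for c in np.bincount(b))
    index = n11
    expected = sum_a * sum_b / n_pairs
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (index - expected) / (max_index - expected)


def auroc_bruteforce(y, s):
    """AUROC as the fraction of (positive, negative) pairs ranked correctly,
    ties counting half."""
    y, s = np.asarray(y), np.asarray(s)
    pos, neg = s[y == 1], s[y == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def all_partitions(items):
    """Every set partition, as label vectors."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        k = max(part, default=-1) + 1
        for target in range(k + 1):
            yield [target] + part


# --- fold plans ------------------------------------------------------------


class TestFoldPlan:
    def test_five_equal_test_sets(self):
        y = np.tile([0, 0, 0, 1], 25)
        plan = make_fold_plan(100, seed=1, y=y)
        assert [len(t) for t in plan.test_folds] == [20] * 5
        together = np.sort(np.concatenate(plan.test_folds))
        np.testing.assert_array_equal(together, np.arange(100))

    def test_stratification_preserves_prevalence(self):
        rng = np.random.default_rng(0)
        y = (rng.random(1000) < 0.25).astype(int)
        plan = make_fold_plan(1000, seed=3, y=y)
        for t in plan.test_folds:
            assert y[t].mean() == pytest.approx(y.mean(), abs=0.02)

    def test_inner_validation_disjoint(self):
        y = np.tile([0, 1], 50)
        plan = make_fold_plan(100, seed=2, y=y)
        for f in range(5):
            assert not set(plan.train_idx[f]) & set(plan.val_idx[f])
            assert not set(plan.train_idx[f]) & set(plan.test_folds[f])
            assert not set(plan.val_idx[f]) & set(plan.test_folds[f])

    def test_deterministic(self):
        y = np.tile([0, 1], 30)
        a = make_fold_plan(60, seed=7, y=y)
        b = make_fold_plan(60, seed=7, y=y)
        for f in range(5):
            np.testing.assert_array_equal(a.test_folds[f], b.test_folds[f])
            np.testing.assert_array_equal(a.train_idx[f], b.train_idx[f])

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            make_fold_plan(5, seed=0)


# --- ARI -------------------------------------------------------------------


class TestAdjustedRandIndex:
    def test_identical_partitions_give_one(self):
        assert adjusted_rand_index([0, 0, 1, 1, 2], [0, 0, 1, 1, 2]) == pytest.approx(1.0)

    def test_label_permutation_invariance(self):
        assert adjusted_rand_index([0, 0, 1, 1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_matches_bruteforce_on_all_small_partitions(self):
        """Exhaustive check against pair counting over every pair of
        partitions of 5 items, plus random partitions of 8."""
        parts5 = [np.array(p) for p in all_partitions(list(range(5)))]
        for a, b in itertools.combinations(parts5, 2):
            assert adjusted_rand_index(a, b) == pytest.approx(ari_bruteforce(a, b), abs=1e-12)
        rng = np.random.default_rng(1)
        for _ in range(200):
            a, b = rng.integers(0, 3, 8), rng.integers(0, 4, 8)
            if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
                continue
            assert adjusted_rand_index(a, b) == pytest.approx(ari_bruteforce(a, b), abs=1e-12)

    def test_bounded_above_by_one(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            a, b = rng.integers(0, 4, 20), rng.integers(0, 4, 20)
            assert adjusted_rand_index(a, b) <= 1.0 + 1e-12

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            adjusted_rand_index([0, 1], [0, 1, 2])


class TestMeanPairwiseAri:
    def test_identical_partitions(self):
        parts = [[0, 0, 1, 1, 2]] * 5
        mean, pairs = mean_pairwise_ari(parts)
        assert mean == pytest.approx(1.0)
        assert len(pairs) == 10

    def test_singular_partition_pairs_score_zero(self):
        good = [0, 0, 1, 1]
        parts = [good, good, good, good, [0, 0, 0, 0]]
        mean, pairs = mean_pairwise_ari(parts)
        # 6 good pairs at ARI 1, 4 singular pairs at 0
        assert mean == pytest.approx(6 / 10)
        assert sum(p == 0.0 for p in pairs) == 4

    def test_independent_partitions_near_zero(self):
        rng = np.random.default_rng(3)
        parts = [rng.integers(0, 3, 1000) for _ in range(5)]
        mean, _ = mean_pairwise_ari(parts)
        assert mean == pytest.approx(0.0, abs=0.02)

    def test_needs_two_partitions(self):
        with pytest.raises(ValueError):
            mean_pairwise_ari([[0, 1]])


# --- AUROC / AUPRC ---------------------------------------------------------


class TestDiscrimination:
    def test_perfect_separation(self):
        assert auroc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == pytest.approx(1.0)

    def test_chance_level(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 4000)
        s = rng.random(4000)
        assert auroc(y, s) == pytest.approx(0.5, abs=0.03)

    def test_worked_example_by_pair_counting(self):
        y, s = [0, 1, 1, 0], [0.1, 0.9, 0.4, 0.5]
        assert auroc(y, s) == pytest.approx(auroc_bruteforce(y, s))
        assert auroc(y, s) == pytest.approx(0.75)

    def test_matches_bruteforce_with_ties(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            y = rng.integers(0, 2, 50)
            if len(np.unique(y)) < 2:
                continue
            s = rng.integers(0, 5, 50) / 4  # many ties
            assert auroc(y, s) == pytest.approx(auroc_bruteforce(y, s), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([1, 1, 1], [0.1, 0.2, 0.3])
        with pytest.raises(ValueError):
            auprc([0, 0], [0.1, 0.2])

    def test_auprc_perfect_and_bounds(self):
        assert auprc([0, 1], [0.1, 0.9]) == pytest.approx(1.0)
        rng = np.random.default_rng(7)
        y, s = rng.integers(0, 2, 200), rng.random(200)
        assert 0.0 <= auprc(y, s) <= 1.0


# --- Brier decomposition ---------------------------------------------------


class TestBrierDecomposition:
    def test_perfect_sharp_forecast(self):
        y = np.array([0, 1, 1, 0, 1])
        bd = brier_decomposition(y, y.astype(float))
        assert bd.reliability == pytest.approx(0.0, abs=1e-12)
        assert bd.resolution == pytest.approx(bd.uncertainty, abs=1e-12)

    def test_climatology_forecast(self):
        y = np.array([0, 1, 0, 1, 0, 0, 1, 0])
        p = np.full(8, y.mean())
        bd = brier_decomposition(y, p)
        assert bd.resolution == pytest.approx(0.0, abs=1e-12)
        assert bd.reliability == pytest.approx(0.0, abs=1e-12)

    def test_uncertainty_is_event_rate_variance(self):
        rng = np.random.default_rng(8)
        y = (rng.random(10_000) < 0.257).astype(int)
        bd = brier_decomposition(y, rng.random(10_000))
        ybar = y.mean()
        assert bd.uncertainty == pytest.approx(ybar * (1 - ybar), abs=1e-12)
        # at the cohort event rate 0.257 exactly: 0.257 * 0.743
        assert 0.257 * (1 - 0.257) == pytest.approx(0.190951, abs=5e-7)

    def test_identity_under_bin_mean_forecasts(self):
        """reliability - resolution + uncertainty == Brier score exactly when
        each forecast is replaced by its bin's mean forecast."""
        rng = np.random.default_rng(9)
        p = rng.random(500)
        y = (rng.random(500) < p).astype(int)
        bins = np.clip((p * 10).astype(int), 0, 9)
        p_binned = p.copy()
        for b in range(10):
            sel = bins == b
            if sel.any():
                p_binned[sel] = p[sel].mean()
        bd = brier_decomposition(y, p_binned)
        assert bd.reliability - bd.resolution + bd.uncertainty == pytest.approx(
            bd.brier, abs=1e-9
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            brier_decomposition([], [])


# --- configuration rule ----------------------------------------------------


def _grid_from_rows(rows):
    df = pd.DataFrame(rows)
    df["ci_low"] = df["mean"] - df["ci"]
    df["ci_high"] = df["mean"] + df["ci"]
    return GridResult(table=df, l2_grid=tuple(sorted(df.l2.unique())),
                      k_grid=tuple(sorted(df.K.unique())), seed=0)


class TestSelectConfiguration:
    def test_dominant_cell_wins(self):
        rows = []
        for l2 in (0.01, 0.1):
            for K in (2, 3):
                best = l2 == 0.01 and K == 3
                rows.append({"metric": "ari", "l2": l2, "K": K,
                             "mean": 0.9 if best else 0.2, "ci": 0.01})
                rows.append({"metric": "auroc", "l2": l2, "K": K,
                             "mean": 0.85 if best else 0.7, "ci": 0.01})
        assert select_configuration(_grid_from_rows(rows)) == (3, 0.01)

    def test_ari_tie_broken_by_auroc(self):
        rows = []
        for l2, au in [(0.01, 0.80), (0.05, 0.86)]:
            rows.append({"metric": "ari", "l2": l2, "K": 3, "mean": 0.6, "ci": 0.05})
            rows.append({"metric": "auroc", "l2": l2, "K": 3, "mean": au, "ci": 0.01})
        assert select_configuration(_grid_from_rows(rows)) == (3, 0.05)

    def test_full_tie_prefers_smaller_penalty(self):
        rows = []
        for l2 in (0.004, 0.01):
            rows.append({"metric": "ari", "l2": l2, "K": 4, "mean": 0.6, "ci": 0.02})
            rows.append({"metric": "auroc", "l2": l2, "K": 4, "mean": 0.8, "ci": 0.01})
        assert select_configuration(_grid_from_rows(rows)) == (4, 0.004)


class TestClusterSizeCheck:
    def test_small_cluster_fails_both(self):
        df = cluster_size_check([0] * 100 + [1] * 9, [0.9, 0.1])
        assert df.passes.tolist() == [True, False]
        assert not df.size_ok[1] and not df.weight_ok[1]

    def test_balanced_clusters_pass(self):
        df = cluster_size_check([0, 1, 2] * 10, [1 / 3] * 3)
        assert df.passes.all()

    def test_five_expert_share_profile(self):
        """With weight shares (0.770, 0.122, 0.085, 0.021, 0.0009) exactly the
        last two clusters fail the 10% weight criterion, and 0.085 < 0.10
        fails too — matching a five-expert fit whose top three experts carry
        ~97.7% of the vote."""
        shares = [0.770, 0.122, 0.085, 0.021, 0.0009]
        labels = sum(([k] * 100 for k in range(5)), [])  # equal sizes: size check passes
        df = cluster_size_check(labels, shares)
        assert df.weight_ok.tolist() == [True, True, False, False, False]
        assert df.size_ok.all()


def test_logistic_baseline_extremes(tiny_schema):
    from moepheno.schema import CohortTable

    rng = np.random.default_rng(10)
    n = 400
    x = rng.normal(size=n)
    y = (x > 0).astype(int)
    df = pd.DataFrame({"age": x, "flag": (x > 0).astype(float), "dose": rng.normal(size=n),
                       "device": rng.integers(0, 2, n).astype(float)})
    separable = CohortTable(features=df, outcome=y, schema=tiny_schema)
    aucs = logistic_baseline(separable, seed=1)
    assert min(aucs) > 0.99

    y2 = rng.integers(0, 2, n)
    noise = CohortTable(features=df.sample(frac=1.0, random_state=1).reset_index(drop=True),
                        outcome=y2, schema=tiny_schema)
    aucs2 = logistic_baseline(noise, seed=1)
    assert np.mean(aucs2) == pytest.approx(0.5, abs=0.1)
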