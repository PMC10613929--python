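"""Cross-validated model selection for the mixture of experts.

Implements five-fold stratified cross-validation with an inner 20%
validation split, discrimination metrics (AUROC, AUPRC), the Brier score
decomposition (uncertainty / resolution / reliability), cluster-stability
scoring by mean pairwise adjusted Rand index across folds (with any pair
involving a single-cluster "singular" partition contributing 0), a
(lambda, K) hyperparameter grid search, and the two-stage stability-then-
discrimination configuration choice: first shortlist L2 penalties whose best
stability is statistically indistinguishable from the global best and pick
the consensus expert count, then break remaining ties by AUROC.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import adjusted_rand_score, average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .moe import MoEConfig, assign_clusters, build_moe, predict_table, train_moe
from .schema import CohortTable

__all__ = [
    "DEFAULT_L2_GRID",
    "DEFAULT_K_GRID",
    "FoldPlan",
    "BrierDecomposition",
    "GridResult",
    "make_fold_plan",
    "adjusted_rand_index",
    "mean_pairwise_ari",
    "auroc",
    "auprc",
    "brier_decomposition",
    "run_grid",
    "select_configuration",
    "cluster_size_check",
    "logistic_baseline",
]

#: default L2-penalty search grid
DEFAULT_L2_GRID = (0.001, 0.002, 0.004, 0.006, 0.008, 0.01, 0.05, 0.1)
#: default expert-count search grid (capped at 10 experts)
DEFAULT_K_GRID = tuple(range(2, 11))


@dataclass
class FoldPlan:
    """Outer test folds plus, per fold, an inner train/validation split of the
    remaining data (validation fraction 0.20), all stratified on outcome."""

    test_folds: list[np.ndarray]
    train_idx: list[np.ndarray]
    val_idx: list[np.ndarray]
    seed: int

    @property
    def n_folds(self) -> int:
        return len(self.test_folds)


def make_fold_plan(n: int, seed: int, y: Optional[np.ndarray] = None, n_folds: int = 5,
                   val_frac: float = 0.2) -> FoldPlan:
    """Stratified outer folds with inner validation splits, reproducible by seed.

    ``y`` is the binary outcome used for stratification; omitting it produces
    unstratified folds.  Raises if any fold ends up with a single outcome
    class (metrics would be undefined).
    """
    if n < 10:
        raise ValueError("need at least 10 rows to build a fold plan")
    idx = np.arange(n)
    if y is None:
        y = np.zeros(n)
        splits = np.array_split(np.random.default_rng(seed).permutation(idx), n_folds)
        folds = [np.sort(s) for s in splits]
    else:
        y = np.asarray(y)
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = [test for _, test in skf.split(idx, y)]
    test_folds, train_idx, val_idx = [], [], []
    for i, test in enumerate(folds):
        rest = np.setdiff1d(idx, test)
        strat = y[rest] if len(np.unique(y[rest])) > 1 else None
        tr, va = train_test_split(rest, test_size=val_frac, random_state=seed + i, stratify=strat)
        if len(np.unique(y)) > 1 and (len(np.unique(y[test])) < 2 or len(np.unique(y[tr])) < 2
                                      or len(np.unique(y[va])) < 2):
            raise ValueError(f"fold {i} has a single outcome class; metrics undefined")
        test_folds.append(np.sort(test))
        train_idx.append(np.sort(tr))
        val_idx.append(np.sort(va))
    return FoldPlan(test_folds=test_folds, train_idx=train_idx, val_idx=val_idx, seed=seed)


# --- metrics ---------------------------------------------------------------


def adjusted_rand_index(labels_a: Sequence[int], labels_b: Sequence[int]) -> float:
    """Chance-corrected partition agreement (permutation model); 1 for
    identical partitions up to relabeling, ~0 for independent ones."""
    a, b = np.asarray(labels_a), np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    if a.size < 2:
        raise ValueError("need at least two items")
    return float(adjusted_rand_score(a, b))


def _is_singular(labels: np.ndarray) -> bool:
    return len(np.unique(labels)) <= 1


def mean_pairwise_ari(partitions: Sequence[Sequence[int]]) -> tuple[float, list[float]]:
    """Mean ARI over all unordered pairs of partitions.

    A clustering that puts every item into one cluster carries no grouping
    information, so any pair involving such a singular partition contributes
    0 to the mean rather than an undefined/degenerate ARI.
    """
    parts = [np.asarray(p) for p in partitions]
    if len(parts) < 2:
        raise ValueError("need at least two partitions")
    pair_values = []
    for p, q in itertools.combinations(parts, 2):
        if _is_singular(p) or _is_singular(q):
            pair_values.append(0.0)
        else:
            pair_values.append(adjusted_rand_index(p, q))
    return float(np.mean(pair_values)), pair_values


def auroc(y: Sequence[int], scores: Sequence[float]) -> float:
    """Rank-based area under the ROC curve (tied scores averaged)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("AUROC undefined with a single outcome class")
    return float(roc_auc_score(y, scores))


def auprc(y: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the precision-recall curve (step-integral / average precision)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("AUPRC undefined with a single outcome class")
    return float(average_precision_score(y, scores))


@dataclass
class BrierDecomposition:
    """Binned decomposition of the Brier score:
    ``brier = reliability - resolution + uncertainty`` (exact identity when
    each forecast is replaced by its bin mean)."""

    uncertainty: float
    resolution: float
    reliability: float
    n_bins: int
    brier: float


def brier_decomposition(y: Sequence[int], p: Sequence[float], n_bins: int = 10) -> BrierDecomposition:
    """Decompose the Brier score of probability forecasts ``p`` with
    equal-width probability bins.

    uncertainty = ybar(1-ybar); resolution = sum (n_b/n)(ybar_b - ybar)^2;
    reliability = sum (n_b/n)(pbar_b - ybar_b)^2.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.size == 0:
        raise ValueError("empty input")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("forecast probabilities must lie in [0,1]")
    ybar = y.mean()
    bins = np.clip((p * n_bins).astype(int), 0, n_bins - 1)
    resolution = reliability = 0.0
    n = len(y)
    for b in range(n_bins):
        sel = bins == b
        nb = sel.sum()
        if nb == 0:
            continue
        yb, pb = y[sel].mean(), p[sel].mean()
        resolution += nb / n * (yb - ybar) ** 2
        reliability += nb / n * (pb - yb) ** 2
    return BrierDecomposition(
        uncertainty=float(ybar * (1 - ybar)),
        resolution=float(resolution),
        reliability=float(reliability),
        n_bins=n_bins,
        brier=float(((p - y) ** 2).mean()),
    )


# --- grid search -----------------------------------------------------------


@dataclass
class GridResult:
    """Long-format per-(metric, lambda, K) means with 95% CI half-widths
    (mean ± 1.96 * SE over folds)."""

    table: pd.DataFrame  # columns: metric, l2, K, mean, ci, ci_low, ci_high
    l2_grid: tuple
    k_grid: tuple
    seed: int

    def cell(self, metric: str, l2: float, K: int) -> tuple[float, float]:
        row = self.table[
            (self.table.metric == metric) & (np.isclose(self.table.l2, l2)) & (self.table.K == K)
        ]
        if row.empty:
            raise KeyError((metric, l2, K))
        return float(row["mean"].iloc[0]), float(row["ci"].iloc[0])


def _ci(values: Sequence[float]) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    se = v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0
    return float(v.mean()), float(1.96 * se)


def run_grid(
    table: CohortTable,
    config_template: MoEConfig,
    l2_grid: Sequence[float] = DEFAULT_L2_GRID,
    k_grid: Sequence[int] = DEFAULT_K_GRID,
    fold_plan: Optional[FoldPlan] = None,
    ari_on: str = "full",
) -> GridResult:
    """Train one MoE per (lambda, K, fold); score test-fold AUROC / AUPRC /
    Brier components and cross-fold cluster stability.

    For stability, each fold's trained selector is applied to the full cohort
    (``ari_on="full"``) so that every pair of fold partitions shares an item
    set; ``ari_on="test"`` restricts each pairwise comparison to the items
    outside both folds' training data (pairing on test-set intersections).
    """
    if not len(l2_grid) or not len(k_grid):
        raise ValueError("empty grid")
    plan = fold_plan or make_fold_plan(table.n, config_template.seed, y=table.outcome)
    rows = []
    for l2, K in itertools.product(l2_grid, k_grid):
        fold_metrics: dict[str, list[float]] = {m: [] for m in
            ("auroc", "auprc", "uncertainty", "resolution", "reliability")}
        partitions = []
        for fold in range(plan.n_folds):
            cfg = replace(config_template, gating_l2=float(l2), n_experts=int(K),
                          seed=config_template.seed + 997 * fold)
            try:
                model = build_moe(cfg, table.schema)
                model, _ = train_moe(model, table.subset(plan.train_idx[fold]),
                                     table.subset(plan.val_idx[fold]))
            except Exception as exc:  # annotate with the grid cell
                raise RuntimeError(f"training failed at grid cell (l2={l2}, K={K}, fold={fold})") from exc
            test = plan.test_folds[fold]
            pred = predict_table(model, table.subset(test))
            fold_metrics["auroc"].append(auroc(table.outcome[test], pred.final_risk))
            fold_metrics["auprc"].append(auprc(table.outcome[test], pred.final_risk))
            bd = brier_decomposition(table.outcome[test], pred.final_risk)
            fold_metrics["uncertainty"].append(bd.uncertainty)
            fold_metrics["resolution"].append(bd.resolution)
            fold_metrics["reliability"].append(bd.reliability)
            full_pred = predict_table(model, table)
            labels, _ = assign_clusters(full_pred)
            partitions.append(labels)
        if ari_on == "full":
            ari_mean, ari_pairs = mean_pairwise_ari(partitions)
        else:
            pair_vals = []
            for (i, p), (j, q) in itertools.combinations(enumerate(partitions), 2):
                keep = np.intersect1d(plan.test_folds[i], plan.test_folds[j])
                keep = keep if len(keep) else np.union1d(plan.test_folds[i], plan.test_folds[j])
                pi, qi = p[keep], q[keep]
                pair_vals.append(0.0 if _is_singular(pi) or _is_singular(qi)
                                 else adjusted_rand_index(pi, qi))
            ari_pairs = pair_vals
            ari_mean = float(np.mean(pair_vals))
        _, ari_ci = _ci(ari_pairs)
        rows.append({"metric": "ari", "l2": l2, "K": K, "mean": ari_mean, "ci": ari_ci})
        for metric, vals in fold_metrics.items():
            mean, ci = _ci(vals)
            rows.append({"metric": metric, "l2": l2, "K": K, "mean": mean, "ci": ci})
    df = pd.DataFrame(rows)
    df["ci_low"] = df["mean"] - df["ci"]
    df["ci_high"] = df["mean"] + df["ci"]
    return GridResult(table=df, l2_grid=tuple(l2_grid), k_grid=tuple(k_grid),
                      seed=config_template.seed)


def select_configuration(grid: GridResult) -> tuple[int, float]:
    """Two-stage configuration choice: cluster stability first, then AUROC.

    Stage 1: shortlist L2 penalties whose best mean pairwise ARI (over K) is
    within one CI half-width of the global best; the expert count is the mode
    of the ARI-maximizing K over the shortlisted penalties (ties -> smaller K).
    Stage 2: among shortlisted penalties at the chosen K, take the one with
    the highest mean AUROC (ties -> smaller penalty).

    Returns ``(K, l2)``.
    """
    ari = grid.table[grid.table.metric == "ari"]
    best_per_l2 = ari.loc[ari.groupby("l2")["mean"].idxmax()]
    global_best = best_per_l2.loc[best_per_l2["mean"].idxmax()]
    thresh = global_best["mean"] - global_best["ci"]
    shortlist = best_per_l2[best_per_l2["mean"] >= thresh]
    ks = shortlist["K"].astype(int)
    counts = ks.value_counts()
    chosen_K = int(min(counts[counts == counts.max()].index))
    au = grid.table[(grid.table.metric == "auroc") & (grid.table.K == chosen_K)]
    au = au[au.l2.isin(shortlist.l2)]
    best_au = au["mean"].max()
    chosen_l2 = float(au[np.isclose(au["mean"], best_au)]["l2"].min())
    return chosen_K, chosen_l2


def cluster_size_check(
    hard_labels: Sequence[int],
    weight_shares: Sequence[float],
    n_clusters: Optional[int] = None,
    size_frac: float = 0.10,
    weight_frac: float = 0.10,
) -> pd.DataFrame:
    """Flag clusters that are too small to support per-phenotype modeling.

    A cluster passes iff its membership count is at least ``size_frac`` of the
    largest cluster's count AND its share of total gate weight is strictly
    greater than ``weight_frac``.
    """
    labels = np.asarray(hard_labels)
    shares = np.asarray(weight_shares, dtype=float)
    K = n_clusters or len(shares)
    sizes = np.bincount(labels, minlength=K)
    largest = sizes.max()
    rows = []
    for k in range(K):
        size_ok = sizes[k] >= size_frac * largest
        weight_ok = shares[k] > weight_frac
        rows.append({"cluster": k, "size": int(sizes[k]), "weight_share": shares[k],
                     "size_ok": bool(size_ok), "weight_ok": bool(weight_ok),
                     "passes": bool(size_ok and weight_ok)})
    return pd.DataFrame(rows)


def logistic_baseline(
    table: CohortTable,
    fold_plan: Optional[FoldPlan] = None,
    c_grid: Sequence[float] = (0.01, 0.1, 1.0, 10.0),
    seed: int = 0,
) -> list[float]:
    """Pooled ridge-penalized logistic regression baseline: per outer fold,
    the penalty strength is tuned on the inner validation split and the test
    AUROC reported."""
    from .moe import fit_preprocessing, apply_preprocessing

    plan = fold_plan or make_fold_plan(table.n, seed, y=table.outcome)
    out = []
    for fold in range(plan.n_folds):
        tr, va, te = plan.train_idx[fold], plan.val_idx[fold], plan.test_folds[fold]
        stats = fit_preprocessing(table.subset(tr), table.schema)
        X = apply_preprocessing(table, stats, table.schema).features.to_numpy(dtype=float)
        y = table.outcome
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"fold {fold}: single-class training data")
        best_c, best_val = None, -np.inf
        for c in c_grid:
            clf = LogisticRegression(C=c, max_iter=2000)
            clf.fit(X[tr], y[tr])
            val_score = roc_auc_score(y[va], clf.predict_proba(X[va])[:, 1])
            if val_score > best_val:
                best_c, best_val = c, val_score
        clf = LogisticRegression(C=best_c, max_iter=2000)
        clf.fit(X[np.concatenate([tr, va])], y[np.concatenate([tr, va])])
        out.append(float(roc_auc_score(y[te], clf.predict_proba(X[te])[:, 1])))
    return out
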