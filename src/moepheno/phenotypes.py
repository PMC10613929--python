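"""Phenotype characterization from trained-model gate outputs.

Turns soft memberships into the reporting artifacts used to read a fitted
mixture clinically: experts ordered and relabeled A, B, C, ... by total gate
weight; each expert's share of the overall vote; per-cluster feature summary
tables; and per-cluster mortality rates, overall and within mechanical-
circulatory-support treatment groups (only-IABP / only-LVAD / none), with
exact Clopper-Pearson binomial confidence intervals and a flag for clusters
whose rate is statistically indistinguishable from the population rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta, binomtest

from .schema import CohortSchema, CohortTable

__all__ = [
    "order_experts_by_weight",
    "weight_contribution",
    "clopper_pearson_interval",
    "cluster_characteristics",
    "derive_treatment_groups",
    "cluster_outcome_rates",
    "EXPERT_LABELS",
]

EXPERT_LABELS = "ABCDEFGHIJ"


def weight_contribution(gates: np.ndarray) -> np.ndarray:
    """Per-expert share of total gate mass: ``share_k = sum_rows g_k / n``.

    Because each row's gates sum to 1, the shares themselves sum to 1; they
    quantify how much of the final weighted vote each expert carries (and
    hence how much is lost when a plot truncates to the top three experts).
    """
    g = np.atleast_2d(np.asarray(gates, dtype=float))
    return g.mean(axis=0)


def order_experts_by_weight(gates: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Sort experts by descending total gate weight; ties keep original index
    order.  Returns the permutation (expert indices, heaviest first) and their
    display labels "A", "B", ...  Invariant to row permutations of ``gates``.
    """
    shares = weight_contribution(gates)
    order = np.argsort(-shares, kind="stable")
    return order, [EXPERT_LABELS[i] for i in range(len(order))]


def clopper_pearson_interval(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for a proportion.

    lower = Beta(k, n-k+1) quantile at alpha/2 (0 when k=0);
    upper = Beta(k+1, n-k) quantile at 1-alpha/2 (1 when k=n).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    alpha = 1.0 - confidence
    lower = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


def cluster_characteristics(table: CohortTable, hard_labels: Sequence[int],
                            n_clusters: Optional[int] = None) -> pd.DataFrame:
    """Per-cluster feature summary: size, mean (SD) for continuous features,
    percentage for binary features.  One column per cluster (labeled A, B, ...
    in cluster-index order), one row per feature.  Empty clusters report n=0
    and blank statistics."""
    labels = np.asarray(hard_labels)
    if len(labels) != table.n:
        raise ValueError("labels not aligned to table rows")
    K = n_clusters or int(labels.max()) + 1
    cols = {}
    for k in range(K):
        sel = labels == k
        col: dict[str, str] = {"Number": str(int(sel.sum()))}
        sub = table.features[sel]
        for f in table.schema.features:
            if sel.sum() == 0:
                col[f.name] = ""
            elif f.kind == "continuous":
                col[f.name] = f"{sub[f.name].mean():.1f} ({sub[f.name].std():.1f})"
            else:
                col[f.name] = f"{100 * sub[f.name].mean():.1f}%"
        col["Mortality"] = "" if sel.sum() == 0 else f"{100 * table.outcome[sel].mean():.1f}%"
        cols[EXPERT_LABELS[k]] = col
    return pd.DataFrame(cols)


def derive_treatment_groups(
    table: CohortTable,
    iabp_col: str = "mcs_iabp",
    lvad_col: str = "mcs_lvad",
    other_mcs_cols: Sequence[str] = ("mcs_ecmo", "mcs_other"),
) -> np.ndarray:
    """Partition patients by mechanical-support exposure: "only_iabp" (IABP
    and no other MCS device), "only_lvad" (LVAD and no other device), "none"
    (no device at all), or "other" (any remaining combination)."""
    df = table.features
    iabp = df[iabp_col].to_numpy() > 0.5
    lvad = df[lvad_col].to_numpy() > 0.5
    other = np.zeros(table.n, dtype=bool)
    for c in other_mcs_cols:
        if c in df.columns:
            other |= df[c].to_numpy() > 0.5
    groups = np.full(table.n, "other", dtype=object)
    groups[iabp & ~lvad & ~other] = "only_iabp"
    groups[lvad & ~iabp & ~other] = "only_lvad"
    groups[~iabp & ~lvad & ~other] = "none"
    return groups


@dataclass
class RateCell:
    n: int
    deaths: int
    rate: float  # percent
    ci_low: float  # percent
    ci_high: float  # percent
    non_significant: Optional[bool] = None

    def formatted(self) -> str:
        if self.n == 0:
            return "no data"
        return f"{self.rate:.1f} ({self.ci_low:.1f}–{self.ci_high:.1f})"


def _rate_cell(y: np.ndarray) -> RateCell:
    n = len(y)
    if n == 0:
        return RateCell(n=0, deaths=0, rate=np.nan, ci_low=np.nan, ci_high=np.nan)
    k = int(y.sum())
    lo, hi = clopper_pearson_interval(k, n)
    return RateCell(n=n, deaths=k, rate=100 * k / n, ci_low=100 * lo, ci_high=100 * hi)


def cluster_outcome_rates(
    hard_labels: Sequence[int],
    outcome: Sequence[int],
    treatment_groups: Sequence[str],
    n_clusters: Optional[int] = None,
    flag: str = "ci_contains",
) -> pd.DataFrame:
    """Mortality rate (%) with exact 95% CI per (cluster x treatment group),
    plus whole-cohort rows, and a non-significance flag against the total
    population.

    ``flag="ci_contains"`` marks a cell non-significant when its CI contains
    the corresponding total-population point rate (the weakest reading of "no
    significant difference"); ``flag="binom_test"`` uses an exact binomial
    test of the cell's deaths against the population rate at the 5% level.
    """
    labels = np.asarray(hard_labels)
    y = np.asarray(outcome)
    tg = np.asarray(treatment_groups, dtype=object)
    if not (len(labels) == len(y) == len(tg)):
        raise ValueError("inputs not aligned")
    K = n_clusters or int(labels.max()) + 1
    group_names = ["entire_group", "only_iabp", "only_lvad", "none"]

    def cell_for(sel: np.ndarray, group: str) -> RateCell:
        if group == "entire_group":
            return _rate_cell(y[sel])
        return _rate_cell(y[sel & (tg == group)])

    everyone = np.ones(len(y), dtype=bool)
    pop = {g: cell_for(everyone, g) for g in group_names}
    rows = []
    for k in list(range(K)) + ["all"]:
        sel = everyone if k == "all" else labels == k
        row: dict = {"cluster": "All" if k == "all" else EXPERT_LABELS[k]}
        for g in group_names:
            c = cell_for(sel, g)
            ref = pop[g]
            if c.n > 0 and ref.n > 0:
                if flag == "ci_contains":
                    c.non_significant = bool(c.ci_low <= ref.rate <= c.ci_high)
                else:
                    c.non_significant = bool(
                        binomtest(c.deaths, c.n, ref.rate / 100).pvalue > 0.05
                    )
            row[g] = c.formatted()
            row[f"{g}_n"] = c.n
            row[f"{g}_rate"] = c.rate
            row[f"{g}_ci_low"] = c.ci_low
            row[f"{g}_ci_high"] = c.ci_high
            row[f"{g}_nonsig"] = c.non_significant
        rows.append(row)
    return pd.DataFrame(rows)
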