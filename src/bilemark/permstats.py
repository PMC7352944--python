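"""Permutation-based inference and the descriptive summaries built on it.

Clinical omics tables are rarely normal, rarely share a distribution
across groups, and come in unbalanced designs, so group differences are
tested by permutation: under the null the group labels are exchangeable,
and the p-value is the fraction of label arrangements whose statistic is
at least as extreme as the observed one.  When the number of distinct
arrangements is small enough they are enumerated exhaustively (the
p-value is then exact); otherwise a Monte-Carlo sample of arrangements is
drawn and the add-one estimator p = (b + 1) / (m + 1) is used, which can
never return zero.

The default two-group statistic is the absolute difference of group
means, giving a two-sided test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CohortLabels, FeatureTable

__all__ = [
    "PermTestResult",
    "permutation_p",
    "group_summary",
    "differential_features",
    "correlate_perm",
]

EXHAUSTIVE_LIMIT = 50_000
DEFAULT_N_MC = 9_999


@dataclass
class PermTestResult:
    observed: float
    p_value: float
    n_arrangements: int
    exhaustive: bool
    seed: int | None = None
    coefficient: float | None = None  # populated by correlate_perm


def _abs_mean_diff(x: np.ndarray, y: np.ndarray) -> float:
    return abs(float(np.mean(x)) - float(np.mean(y)))


def permutation_p(values: Sequence[float], labels: Sequence,
                  statistic: Callable[[np.ndarray, np.ndarray], float] | None = None,
                  exhaustive_limit: int = EXHAUSTIVE_LIMIT,
                  n_mc: int = DEFAULT_N_MC,
                  seed: int | None = None) -> PermTestResult:
    """Two-group permutation test; exhaustive when the number of distinct
    group splits is within ``exhaustive_limit``, else Monte Carlo with the
    add-one correction."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {list(uniq)}")
    mask_a = labels == uniq[0]
    n_a = int(mask_a.sum())
    n_b = int(values.size - n_a)
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")
    stat = statistic or _abs_mean_diff
    observed = stat(values[mask_a], values[~mask_a])

    n_splits = comb(values.size, n_a)
    if n_splits <= exhaustive_limit:
        idx_all = np.arange(values.size)
        count = 0
        for combo in combinations(idx_all, n_a):
            sel = np.zeros(values.size, dtype=bool)
            sel[list(combo)] = True
            if stat(values[sel], values[~sel]) >= observed:
                count += 1
        return PermTestResult(observed=float(observed), p_value=count / n_splits,
                              n_arrangements=n_splits, exhaustive=True)

    rng = np.random.default_rng(seed)
    if statistic is None:
        # vectorized |mean difference| over n_mc random splits
        total = float(values.sum())
        keys = rng.random((n_mc, values.size))
        idx = np.argpartition(keys, n_a - 1, axis=1)[:, :n_a]
        sums = values[idx].sum(axis=1)
        stats_mc = np.abs(sums / n_a - (total - sums) / n_b)
        b = int(np.count_nonzero(stats_mc >= observed))
    else:
        b = 0
        for _ in range(n_mc):
            perm = rng.permutation(values.size)
            sel = np.zeros(values.size, dtype=bool)
            sel[perm[:n_a]] = True
            if stat(values[sel], values[~sel]) >= observed:
                b += 1
    return PermTestResult(observed=float(observed), p_value=(b + 1) / (n_mc + 1),
                          n_arrangements=n_mc, exhaustive=False, seed=seed)


@dataclass
class GroupSummary:
    """Per-group descriptive summary with pairwise permutation p-values
    against a reference group."""

    summary: pd.DataFrame      # rows: feature, columns: (group, mean|sd)
    ratios: pd.DataFrame       # rows: ratio name, columns: groups
    p_values: pd.DataFrame     # rows: feature, columns: non-reference groups
    reference_group: str

    def formatted(self, digits: int = 1) -> pd.DataFrame:
        """"mean ± SD" presentation, one column per group."""
        groups = self.ratios.columns
        out = {}
        for g in groups:
            m = self.summary[(g, "mean")]
            s = self.summary[(g, "sd")]
            out[g] = [f"{mi:.{digits}f} ± {si:.{digits}f}" for mi, si in zip(m, s)]
        return pd.DataFrame(out, index=self.summary.index)


def group_summary(table: FeatureTable, labels: CohortLabels,
                  ratio_specs: Sequence[tuple[str, Sequence[str], Sequence[str]]] = (),
                  reference_group: str | None = None,
                  n_mc: int = 999, exhaustive_limit: int = EXHAUSTIVE_LIMIT,
                  seed: int | None = 0) -> GroupSummary:
    """Mean ± SD per feature and group, aggregate ratios of feature-set
    group-mean sums, and pairwise permutation p-values of every feature in
    each non-reference group against the reference group."""
    labels = labels.align_to(table)
    groups = labels.groups
    ref = reference_group or groups[0]
    if ref not in groups:
        raise ValueError(f"reference group {ref!r} not among {groups}")

    means, sds = {}, {}
    for g in groups:
        sub = table.data.loc[labels.members(g)]
        means[g] = sub.mean(axis=0)
        sds[g] = sub.std(axis=0, ddof=1)
    summary = pd.concat({(g, "mean"): means[g] for g in groups}
                        | {(g, "sd"): sds[g] for g in groups}, axis=1)
    summary = summary[[(g, k) for g in groups for k in ("mean", "sd")]]

    ratio_rows = {}
    for name, num, den in ratio_specs:
        row = {}
        for g in groups:
            num_sum = float(means[g].loc[list(num)].sum())
            den_sum = float(means[g].loc[list(den)].sum())
            if den_sum <= 0:
                raise ValueError(f"ratio {name!r}: non-positive denominator sum in group {g!r}")
            row[g] = num_sum / den_sum
        ratio_rows[name] = row
    ratios = pd.DataFrame(ratio_rows).T if ratio_rows else pd.DataFrame(columns=groups)
    ratios = ratios.reindex(columns=groups)

    ss = np.random.SeedSequence(seed)
    others = [g for g in groups if g != ref]
    pvals = pd.DataFrame(index=table.feature_ids, columns=others, dtype=float)
    for g in others:
        pair = labels.members(ref) + labels.members(g)
        lab = np.array([ref] * len(labels.members(ref)) + [g] * len(labels.members(g)))
        sub = table.data.loc[pair]
        for feat, child in zip(table.feature_ids, ss.spawn(table.n_features)):
            res = permutation_p(sub[feat].to_numpy(), lab, n_mc=n_mc,
                                exhaustive_limit=exhaustive_limit,
                                seed=int(child.generate_state(1)[0] % (2**31)))
            pvals.loc[feat, g] = res.p_value
    return GroupSummary(summary=summary, ratios=ratios, p_values=pvals,
                        reference_group=ref)


def differential_features(table: FeatureTable, labels: CohortLabels,
                          n_mc: int = 999, seed: int | None = 0,
                          exhaustive_limit: int = EXHAUSTIVE_LIMIT) -> pd.DataFrame:
    """Per-feature log2 fold-change of group means (second group over
    first), permutation p and Benjamini–Hochberg q, suitable for volcano
    plots.  A pseudocount of half the smallest positive observed value is
    applied only where a group mean is zero."""
    labels = labels.align_to(table)
    groups = labels.groups
    if len(groups) != 2:
        raise ValueError("differential_features requires exactly two groups")
    if any(n < 2 for n in labels.counts().values()):
        raise ValueError("each group needs >= 2 samples")
    if table.has_missing:
        raise ValueError("impute missing values first")

    a, b = groups
    mean_a = table.data.loc[labels.members(a)].mean(axis=0)
    mean_b = table.data.loc[labels.members(b)].mean(axis=0)
    pos = table.values[table.values > 0]
    pseudo = 0.5 * float(pos.min()) if pos.size else 1.0
    num = mean_b.where(mean_b != 0, mean_b + pseudo)
    den = mean_a.where(mean_a != 0, mean_a + pseudo)
    if (num < 0).any() or (den < 0).any():
        raise ValueError("negative group means: fold-change undefined")
    log2fc = np.log2(num / den)

    lab = labels.series.loc[table.sample_ids].to_numpy()
    ss = np.random.SeedSequence(seed)
    pvals = np.empty(table.n_features)
    for j, child in enumerate(ss.spawn(table.n_features)):
        res = permutation_p(table.values[:, j], lab, n_mc=n_mc,
                            exhaustive_limit=exhaustive_limit,
                            seed=int(child.generate_state(1)[0] % (2**31)))
        pvals[j] = res.p_value
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return pd.DataFrame({"log2fc": log2fc.to_numpy(), "p": pvals, "q": qvals},
                        index=table.feature_ids)


def correlate_perm(x: Sequence[float], y: Sequence[float],
                   n_mc: int = DEFAULT_N_MC, seed: int | None = 0,
                   exhaustive_limit: int = EXHAUSTIVE_LIMIT) -> PermTestResult:
    """Spearman rank correlation with a two-sided permutation p-value
    obtained by shuffling ``y``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho = float(stats.spearmanr(x, y).statistic)
    observed = abs(rho)

    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_mc):
        if abs(float(stats.spearmanr(x, rng.permutation(y)).statistic)) >= observed:
            b += 1
    return PermTestResult(observed=observed, p_value=(b + 1) / (n_mc + 1),
                          n_arrangements=n_mc, exhaustive=False, seed=seed,
                          coefficient=rho)
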