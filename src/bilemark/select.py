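"""Feature reduction: DAPC contributions, random-forest importance and
per-feature AUC, plus construction of nested candidate panels (3–10
features).

DAPC (discriminant analysis of principal components) z-scores each
feature, reduces to a handful of principal components (enough to reach a
target share of total variance, capped at n - groups so the within-group
scatter stays invertible), and runs linear discriminant analysis on the
retained component scores.  Each feature's contribution to between-group
separation is the eigenvalue-share-weighted squared loading of the
discriminant axes back-projected to feature space, normalized to sum to
one — the convention used for DAPC "loading plots" in population
genetics, carried over here to omics feature tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .containers import CohortLabels, FeatureTable

__all__ = [
    "PcaResult",
    "DapcModel",
    "FeatureRanking",
    "FeaturePanel",
    "fit_pca",
    "fit_dapc",
    "dapc_select",
    "rf_importance",
    "auc_rank",
    "candidate_panels",
]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: pd.DataFrame                 # samples x components
    loadings: pd.DataFrame               # features x components
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    scale: np.ndarray | None


def fit_pca(table: FeatureTable, n_components: int | None = None,
            scale: bool = False) -> PcaResult:
    """Centered (optionally unit-variance scaled) SVD-based PCA with a
    deterministic sign convention: the largest-magnitude loading of each
    component is positive."""
    if table.has_missing:
        raise ValueError("PCA requires a complete table")
    x = table.values.astype(float)
    n, p = x.shape
    max_k = min(n - 1, p)
    k = max_k if n_components is None else int(n_components)
    if not (1 <= k <= max_k):
        raise ValueError(f"n_components must be in [1, {max_k}]")
    mean = x.mean(axis=0)
    xc = x - mean
    sc = None
    if scale:
        sc = x.std(axis=0, ddof=1)
        if np.any(sc == 0):
            bad = [table.feature_ids[j] for j in np.flatnonzero(sc == 0)]
            raise ValueError(f"constant features with scaling on: {bad}")
        xc = xc / sc
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s ** 2
    evr = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    # sign convention
    for i in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    comps = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(u[:, :k] * s[:k], index=table.sample_ids, columns=comps),
        loadings=pd.DataFrame(vt[:k].T, index=table.feature_ids, columns=comps),
        explained_variance_ratio=evr[:k],
        mean=mean, scale=sc,
    )


# ---------------------------------------------------------------------------
# DAPC
# ---------------------------------------------------------------------------

@dataclass
class DapcModel:
    center: np.ndarray
    scale: np.ndarray
    pca_loadings: np.ndarray             # p x n_pcs
    pca_explained: np.ndarray
    n_pcs: int
    axes: np.ndarray                     # n_pcs x n_da discriminant coefficients
    axis_shares: np.ndarray              # eigenvalue shares, sum 1
    contributions: pd.Series             # per-feature, non-negative, sums to 1
    feature_ids: list[str]
    groups: list[str]

    def transform(self, table: FeatureTable) -> pd.DataFrame:
        x = (table.data.loc[:, self.feature_ids].to_numpy() - self.center) / self.scale
        scores = (x @ self.pca_loadings) @ self.axes
        cols = [f"LD{i + 1}" for i in range(scores.shape[1])]
        return pd.DataFrame(scores, index=table.sample_ids, columns=cols)


def fit_dapc(table: FeatureTable, labels: CohortLabels,
             n_pcs: int | str = "auto", n_da: int | None = None,
             var_threshold: float = 0.90) -> DapcModel:
    """Fit DAPC: z-score -> PCA -> LDA on retained component scores.

    ``n_pcs="auto"`` retains the smallest number of components reaching
    ``var_threshold`` of total variance, capped at n - groups.
    """
    if table.has_missing:
        raise ValueError("DAPC requires a complete table")
    labels = labels.align_to(table)
    groups = labels.groups
    if len(groups) < 2:
        raise ValueError("DAPC requires >= 2 groups")
    counts = labels.counts()
    if any(c < 2 for c in counts.values()):
        raise ValueError("each group needs >= 2 samples")

    x = table.values.astype(float)
    n, p = x.shape
    center = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    scale = np.where(sd > 0, sd, 1.0)
    z = (x - center) / scale

    cap = max(1, min(n - len(groups), p))
    u, s, vt = np.linalg.svd(z - z.mean(axis=0), full_matrices=False)
    var = s ** 2
    evr = var / var.sum()
    if n_pcs == "auto":
        k = int(np.searchsorted(np.cumsum(evr), var_threshold) + 1)
        k = min(k, cap)
    else:
        k = int(n_pcs)
        if k > cap:
            warnings.warn(f"n_pcs={k} exceeds n - groups; clamped to {cap}",
                          stacklevel=2)
            k = cap
    k = max(1, min(k, vt.shape[0]))
    loadings = vt[:k].T                      # p x k
    scores = z @ loadings                    # n x k

    # LDA on PC scores: generalized eigenproblem between/within scatter
    overall = scores.mean(axis=0)
    sb = np.zeros((k, k))
    sw = np.zeros((k, k))
    for g in groups:
        sub = scores[np.asarray(labels.series.to_numpy() == g)]
        mg = sub.mean(axis=0)
        d = (mg - overall)[:, None]
        sb += sub.shape[0] * (d @ d.T)
        c = sub - mg
        sw += c.T @ c
    sb /= n
    sw /= n
    ridge = 1e-8 * (np.trace(sw) / k if np.trace(sw) > 0 else 1.0)
    evals, evecs = linalg.eigh(sb, sw + ridge * np.eye(k))
    order = np.argsort(evals)[::-1]
    n_axes = n_da if n_da is not None else len(groups) - 1
    n_axes = max(1, min(n_axes, k))
    evals = np.clip(evals[order][:n_axes], 0.0, None)
    axes = evecs[:, order][:, :n_axes]
    shares = evals / evals.sum() if evals.sum() > 0 else np.full(n_axes, 1.0 / n_axes)

    back = loadings @ axes                   # p x n_axes, discriminant axes in z-space
    contrib = (back ** 2) @ shares
    total = contrib.sum()
    contrib = contrib / total if total > 0 else np.full(p, 1.0 / p)

    return DapcModel(center=center, scale=scale, pca_loadings=loadings,
                     pca_explained=evr[:k], n_pcs=k, axes=axes, axis_shares=shares,
                     contributions=pd.Series(contrib, index=table.feature_ids),
                     feature_ids=list(table.feature_ids), groups=groups)


# ---------------------------------------------------------------------------
# rankings
# ---------------------------------------------------------------------------

@dataclass
class FeatureRanking:
    method: str                          # DAPC | RF | AUC
    scores: pd.Series                    # per-feature score
    semantics: str                       # contribution share | importance | per-feature AUC

    @property
    def order(self) -> list[str]:
        # descending score, ties broken by ascending feature id
        df = pd.DataFrame({"score": self.scores})
        df["fid"] = df.index.astype(str)
        df = df.sort_values(["score", "fid"], ascending=[False, True])
        return list(df.index)

    def __len__(self) -> int:
        return len(self.scores)

    def to_frame(self) -> pd.DataFrame:
        ordered = self.scores.loc[self.order]
        return pd.DataFrame({"feature": ordered.index, "method": self.method,
                             "score": ordered.to_numpy(),
                             "rank": np.arange(1, len(ordered) + 1)})


@dataclass
class FeaturePanel:
    features: list[str]
    method: str
    rule: str = "top-k"

    def __post_init__(self):
        if len(set(self.features)) != len(self.features):
            raise ValueError("panel features must be unique")
        if not self.features:
            raise ValueError("panel must contain at least one feature")
        # candidate panels built from rankings obey the 3-10 range; smaller
        # panels are permitted for diagnostics (single-feature robustness tests)
        if self.rule == "top-k" and not (3 <= len(self.features) <= 10):
            raise ValueError("top-k panel size must be between 3 and 10")

    @property
    def size(self) -> int:
        return len(self.features)


def dapc_select(model: DapcModel, threshold: float = 0.02) -> FeatureRanking:
    """Features whose DAPC contribution reaches ``threshold`` (default: at
    least 2% of the between-group variability), ranked descending."""
    keep = model.contributions[model.contributions >= threshold]
    if keep.empty:
        warnings.warn(f"no feature reaches contribution {threshold}; empty ranking",
                      stacklevel=2)
    return FeatureRanking(method="DAPC", scores=keep, semantics="contribution share")


def dapc_rank(model: DapcModel) -> FeatureRanking:
    """Full DAPC contribution ranking (no threshold)."""
    return FeatureRanking(method="DAPC", scores=model.contributions,
                          semantics="contribution share")


def rf_importance(table: FeatureTable, labels: CohortLabels,
                  n_trees: int = 200, seed: int = 0,
                  n_repeats: int = 5) -> FeatureRanking:
    """Permutation importance (mean decrease in accuracy) of a fitted
    random-forest classifier; deterministic under a fixed seed."""
    if table.has_missing:
        raise ValueError("random forest requires a complete table")
    labels = labels.align_to(table)
    y = labels.series.to_numpy()
    if len(set(y)) < 2:
        raise ValueError("labels must contain at least two classes")
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    rf.fit(table.values, y)
    imp = permutation_importance(rf, table.values, y, n_repeats=n_repeats,
                                 random_state=seed)
    return FeatureRanking(method="RF",
                          scores=pd.Series(imp.importances_mean, index=table.feature_ids),
                          semantics="importance")


def mann_whitney_auc(values: np.ndarray, positive: np.ndarray) -> float:
    """AUC as the normalized Mann–Whitney U statistic with midranks for
    ties: P(score_pos > score_neg) + 0.5 P(tie)."""
    values = np.asarray(values, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    n1 = int(positive.sum())
    n0 = int(positive.size - n1)
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(values)  # midranks
    r1 = float(ranks[positive].sum())
    return (r1 - n1 * (n1 + 1) / 2) / (n1 * n0)


def auc_rank(table: FeatureTable, labels: CohortLabels) -> FeatureRanking:
    """Direction-free per-feature AUC ranking: score = max(AUC, 1-AUC)."""
    if table.has_missing:
        raise ValueError("AUC ranking requires a complete table")
    labels = labels.align_to(table)
    groups = labels.groups
    if len(groups) != 2:
        raise ValueError("AUC ranking requires exactly two groups")
    pos = labels.series.to_numpy() == groups[1]
    scores = {}
    for j, feat in enumerate(table.feature_ids):
        a = mann_whitney_auc(table.values[:, j], pos)
        scores[feat] = max(a, 1.0 - a)
    return FeatureRanking(method="AUC", scores=pd.Series(scores),
                          semantics="per-feature AUC")


def candidate_panels(ranking: FeatureRanking, k_min: int = 3,
                     k_max: int = 10) -> list[FeaturePanel]:
    """Nested top-k panels for k = k_min .. min(k_max, ranking size)."""
    order = ranking.order
    if len(order) < k_min:
        raise ValueError(f"ranking has {len(order)} features; need >= {k_min}")
    return [FeaturePanel(features=order[:k], method=ranking.method)
            for k in range(k_min, min(k_max, len(order)) + 1)]
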