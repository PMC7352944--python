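"""Moment-based synthetic-data augmentation.

Small clinical cohorts cannot feed data-hungry classifiers directly, so
training data is augmented: per-group sample means, standard deviations
and Pearson correlations are estimated from the real table, and synthetic
samples are drawn from a multivariate normal with covariance
``D @ R @ D`` (``D`` the diagonal SD matrix, ``R`` the correlation
matrix).  Decimal draws serve metabolomics-like tables; integer mode
(round half away from zero, clamp at 0) serves proteomics-like counts.

With very few real samples per group (the 5 vs 5 proteomics regime with
~2000 features) the estimated correlation matrix is massively
rank-deficient and numerically indefinite; it is repaired by flooring its
eigenvalues at zero (plus a tiny jitter) and renormalizing the diagonal
to 1, and the magnitude of the repair is logged in the cohort provenance.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CohortLabels, FeatureTable

__all__ = ["GroupMoments", "SyntheticCohort", "estimate_moments", "generate_synthetic"]


@dataclass
class GroupMoments:
    """Per-group mean vector, SD vector (ddof=1) and Pearson correlation
    matrix over a common feature list.  Features with zero SD in a group
    get a zeroed correlation row/column (unit diagonal) and are flagged."""

    feature_ids: list[str]
    means: dict[str, np.ndarray]
    sds: dict[str, np.ndarray]
    correlations: dict[str, np.ndarray]
    zero_sd_features: dict[str, list[str]] = field(default_factory=dict)

    @property
    def groups(self) -> list[str]:
        return list(self.means)

    def validate(self) -> None:
        p = len(self.feature_ids)
        for g in self.groups:
            if self.means[g].shape != (p,) or self.sds[g].shape != (p,):
                raise ValueError(f"moment dimensions inconsistent for group {g!r}")
            r = self.correlations[g]
            if r.shape != (p, p):
                raise ValueError(f"correlation shape mismatch for group {g!r}")
            if np.any(self.sds[g] < 0):
                raise ValueError("SDs must be >= 0")
            if not np.allclose(r, r.T, atol=1e-8):
                raise ValueError("correlation matrix must be symmetric")
            if not np.allclose(np.diag(r), 1.0, atol=1e-8):
                raise ValueError("correlation diagonal must be 1")
            if np.any(np.abs(r) > 1 + 1e-8):
                raise ValueError("correlation entries must be in [-1, 1]")

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(",".join(self.feature_ids).encode())
        for g in self.groups:
            h.update(g.encode())
            for arr in (self.means[g], self.sds[g], self.correlations[g]):
                h.update(np.ascontiguousarray(arr, dtype=float).tobytes())
        return h.hexdigest()[:16]

    def write(self, prefix) -> None:
        for g in self.groups:
            base = f"{prefix}.{g}"
            pd.DataFrame({"mean": self.means[g], "sd": self.sds[g]},
                         index=self.feature_ids).to_csv(f"{base}.moments.tsv", sep="\t",
                                                        index_label="feature")
            pd.DataFrame(self.correlations[g], index=self.feature_ids,
                         columns=self.feature_ids).to_csv(f"{base}.correlation.tsv",
                                                          sep="\t", index_label="feature")


@dataclass
class SyntheticCohort:
    table: FeatureTable
    labels: CohortLabels
    provenance: dict


def estimate_moments(table: FeatureTable, labels: CohortLabels) -> GroupMoments:
    """Per-group sample mean, SD (n-1 denominator) and Pearson correlation
    of a complete table."""
    if table.has_missing:
        raise ValueError("table has missing values; impute first")
    labels = labels.align_to(table)
    means, sds, corrs, flags = {}, {}, {}, {}
    for g in labels.groups:
        sub = table.data.loc[labels.members(g)].to_numpy()
        if sub.shape[0] < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        mu = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1)
        zero = sd == 0
        safe = np.where(zero, 1.0, sd)
        z = (sub - mu) / safe
        r = (z.T @ z) / (sub.shape[0] - 1)
        r[zero, :] = 0.0
        r[:, zero] = 0.0
        np.fill_diagonal(r, 1.0)
        r = np.clip(r, -1.0, 1.0)
        means[g], sds[g], corrs[g] = mu, sd, r
        flags[g] = [table.feature_ids[j] for j in np.flatnonzero(zero)]
    return GroupMoments(feature_ids=list(table.feature_ids), means=means, sds=sds,
                        correlations=corrs, zero_sd_features=flags)


def _repair_correlation(r: np.ndarray, jitter: float = 1e-10) -> tuple[np.ndarray, dict]:
    """Floor eigenvalues at 0 (+jitter), renormalize to unit diagonal.
    Returns the eigenvector/eigenvalue factorization of the repaired
    matrix along with a repair report."""
    w, v = np.linalg.eigh((r + r.T) / 2)
    min_eig = float(w.min())
    clipped = np.clip(w, 0.0, None) + jitter
    repaired = (v * clipped) @ v.T
    d = np.sqrt(np.diag(repaired))
    d = np.where(d > 0, d, 1.0)
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    report = {
        "repaired": bool(min_eig < 0),
        "min_eigenvalue": min_eig,
        "clip_magnitude": float(max(0.0, -min_eig)),
        "rank": int(np.count_nonzero(w > max(1e-12, 1e-9 * w.max()))),
    }
    return repaired, report


def generate_synthetic(moments: GroupMoments, n_per_group: int | dict[str, int] = 500,
                       mode: str = "decimal", seed: int = 0,
                       jitter_sd: float = 0.0, clamp_negative: bool = False,
                       ) -> SyntheticCohort:
    """Draw a synthetic cohort from per-group moments.

    Parameters
    ----------
    n_per_group
        Either one count shared by every group or a per-group mapping.
    mode
        "decimal" keeps raw Gaussian draws (negatives preserved unless
        ``clamp_negative``); "integer" rounds half away from zero and
        clamps at 0.
    jitter_sd
        Optional extra i.i.d. Gaussian noise (in SD units per feature)
        added on top of the moment-matched draws; off by default because
        the sample covariance already embodies measurement noise.
    """
    moments.validate()
    if mode not in ("decimal", "integer"):
        raise ValueError("mode must be 'decimal' or 'integer'")
    sizes = ({g: int(n_per_group) for g in moments.groups}
             if np.isscalar(n_per_group) else dict(n_per_group))
    for g in moments.groups:
        if sizes.get(g, 0) < 1:
            raise ValueError(f"n_per_group must be >= 1 for group {g!r}")

    rng = np.random.default_rng(seed)
    p = len(moments.feature_ids)
    rows, labels, ids = [], [], []
    repair_reports = {}
    counter = 0
    for g in moments.groups:
        n = sizes[g]
        r, report = _repair_correlation(moments.correlations[g])
        repair_reports[g] = report
        w, v = np.linalg.eigh(r)
        w = np.clip(w, 0.0, None)
        half = v * np.sqrt(w)  # half @ half.T == r
        z = rng.standard_normal((n, p))
        draws = moments.means[g] + (z @ half.T) * moments.sds[g]
        if jitter_sd > 0:
            draws = draws + rng.standard_normal((n, p)) * (jitter_sd * moments.sds[g])
        rows.append(draws)
        labels.extend([g] * n)
        ids.extend(f"syn{counter + i + 1:05d}" for i in range(n))
        counter += n

    values = np.vstack(rows)
    if mode == "integer":
        values = np.maximum(np.floor(np.abs(values) + 0.5) * np.sign(values), 0.0)
        values = values + 0.0  # normalize -0.0
    elif clamp_negative:
        values = np.maximum(values, 0.0)

    table = FeatureTable(pd.DataFrame(values, index=ids, columns=moments.feature_ids),
                         kind=mode)
    cohort_labels = CohortLabels(pd.Series(labels, index=ids))
    provenance = {
        "source_moments_hash": moments.content_hash(),
        "n_per_group": sizes,
        "seed": seed,
        "mode": mode,
        "jitter_sd": jitter_sd,
        "clamp_negative": clamp_negative,
        "pd_repair": repair_reports,
    }
    return SyntheticCohort(table=table, labels=cohort_labels, provenance=provenance)
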