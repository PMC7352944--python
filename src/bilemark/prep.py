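"""Preprocessing: kNN imputation and the 1H-NMR processing chain.

The NMR chain mirrors common bile-metabolomics practice: spectra are
referenced to the internal-standard (TSP) methyl peak at 0.00 ppm, binned
into fixed-width rectangular buckets over the informative spectral region
(default 0.01 ppm over δ 0.261–8.757), buckets overlapping the residual
water and contrast-reagent (iohexol) regions are discarded, and the
resulting bucket table is normalized first to total spectral area and
then by probabilistic quotient normalization (PQN), which estimates a
per-sample dilution factor as the median bucketwise quotient against a
reference spectrum.

Bucketing convention: half-open intervals ``[low + i*w, low + (i+1)*w)``
anchored at the region's low edge; the final bucket is truncated at the
high edge and kept.  Bucket values are exact trapezoidal integrals of the
piecewise-linear spectrum over the interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .containers import FeatureTable, SpectrumSet

__all__ = [
    "BucketingConfig",
    "BucketTable",
    "impute_missing",
    "reference_to_standard",
    "bucket_spectra",
    "normalize_buckets",
]

#: water + contrast-reagent exclusion windows (ppm), low < high
DEFAULT_EXCLUSIONS = (
    (4.59, 4.78),  # residual water
    (1.92, 1.98),  # iohexol (contrast reagent)
    (2.39, 2.43),
    (3.39, 3.71),
    (3.76, 4.18),
)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def impute_missing(table: FeatureTable, k: int = 5) -> FeatureTable:
    """Replace missing entries by the distance-weighted mean of the ``k``
    nearest samples (Euclidean distance over z-scored co-observed
    features).  Observed entries are untouched; a complete table is
    returned unchanged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not table.has_missing:
        return table

    vals = table.values.copy()
    all_missing = np.all(np.isnan(vals), axis=0)
    if np.any(all_missing):
        bad = [table.feature_ids[j] for j in np.flatnonzero(all_missing)]
        raise ValueError(f"features missing in all samples: {bad}")
    if k >= table.n_samples:
        warnings.warn(f"k={k} >= n_samples={table.n_samples}; clamping to "
                      f"{table.n_samples - 1}", stacklevel=2)
        k = table.n_samples - 1

    mu = np.nanmean(vals, axis=0)
    sd = np.nanstd(vals, axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (vals - mu) / sd
    imputer = KNNImputer(n_neighbors=k, weights="distance")
    z_imp = imputer.fit_transform(z)
    out = z_imp * sd + mu
    # keep observed entries bitwise identical
    obs = ~np.isnan(vals)
    out[obs] = vals[obs]
    if table.kind == "integer":
        imp = ~obs
        out[imp] = np.maximum(np.floor(out[imp] + 0.5), 0.0)
    return FeatureTable(pd.DataFrame(out, index=table.sample_ids,
                                     columns=table.feature_ids), kind=table.kind)


# ---------------------------------------------------------------------------
# spectral referencing
# ---------------------------------------------------------------------------

def reference_to_standard(spectra: SpectrumSet,
                          search_window: tuple[float, float] = (-0.2, 0.2)) -> SpectrumSet:
    """Shift each spectrum so the maximum inside ``search_window`` sits at
    0.00 ppm, re-interpolating intensities linearly onto the common grid."""
    lo, hi = search_window
    ppm = spectra.ppm
    if lo < ppm[0] or hi > ppm[-1]:
        raise ValueError("search window outside ppm axis range")
    win = (ppm >= lo) & (ppm <= hi)
    if not np.any(win):
        raise ValueError("search window contains no grid points")

    out = np.empty_like(spectra.intensities)
    for s in range(spectra.n_samples):
        y = spectra.intensities[s]
        yw = y[win]
        if np.ptp(yw) == 0:
            warnings.warn(f"flat signal in reference window for sample "
                          f"{spectra.sample_ids[s]}; no shift applied", stacklevel=2)
            out[s] = y
            continue
        shift = ppm[win][int(np.argmax(yw))]
        out[s] = np.interp(ppm + shift, ppm, y)
    return SpectrumSet(ppm.copy(), out, sample_ids=list(spectra.sample_ids))


# ---------------------------------------------------------------------------
# bucketing
# ---------------------------------------------------------------------------

@dataclass
class BucketingConfig:
    width: float = 0.01
    region: tuple[float, float] = (0.261, 8.757)
    exclusions: tuple[tuple[float, float], ...] = DEFAULT_EXCLUSIONS

    def validate(self) -> None:
        if self.width <= 0:
            raise ValueError("bucket width must be > 0")
        lo, hi = self.region
        if lo >= hi:
            raise ValueError("region must have low < high")


@dataclass
class BucketTable:
    """Integrated bucket intensities plus enough bookkeeping to audit the
    dropped (excluded) buckets and the normalization state."""

    intervals: list[tuple[float, float]]
    values: pd.DataFrame            # samples x kept buckets
    normalization: str = "raw"      # raw | total_area | pqn
    dilution_factors: pd.Series | None = None
    dropped_intervals: list[tuple[float, float]] = field(default_factory=list)
    dropped_values: pd.DataFrame | None = None
    total_area: pd.Series | None = None  # per-sample row sum before total-area scaling

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.index]

    def write(self, path, sep: str = "\t") -> None:
        self.values.to_csv(path, sep=sep, index_label="sample")


def _bucket_edges(cfg: BucketingConfig) -> np.ndarray:
    lo, hi = cfg.region
    ratio = (hi - lo) / cfg.width
    n = int(round(ratio)) if abs(ratio - round(ratio)) < 1e-9 else int(math.ceil(ratio))
    edges = lo + cfg.width * np.arange(n + 1)
    edges[-1] = hi  # final bucket truncated at the high edge
    return edges


def _cumulative_integral(ppm: np.ndarray, y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Exact integral of the piecewise-linear spectrum from ppm[0] to each x
    (trapezoid rule, with partial end segments handled analytically)."""
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(ppm))])
    idx = np.clip(np.searchsorted(ppm, x, side="right") - 1, 0, ppm.size - 2)
    x0 = ppm[idx]
    y0 = y[idx]
    yx = y0 + (y[idx + 1] - y0) * (x - x0) / (ppm[idx + 1] - x0)
    return cum[idx] + 0.5 * (y0 + yx) * (x - x0)


def _overlaps(a: tuple[float, float], b: tuple[float, float]) -> bool:
    # half-open [a0, a1) vs open-measure exclusion (b0, b1): positive overlap
    return a[0] < b[1] and b[0] < a[1]


def bucket_spectra(spectra: SpectrumSet, cfg: BucketingConfig | None = None) -> BucketTable:
    """Integrate spectra into fixed-width buckets, dropping any bucket that
    overlaps an exclusion region (overlap of positive measure)."""
    cfg = cfg or BucketingConfig()
    cfg.validate()
    lo, hi = cfg.region
    if lo < spectra.ppm[0] or hi > spectra.ppm[-1]:
        raise ValueError("requested region extends beyond the ppm axis")

    for ex in cfg.exclusions:
        if ex[1] <= lo or ex[0] >= hi:
            warnings.warn(f"exclusion region {ex} outside spectral region; ignored",
                          stacklevel=2)

    edges = _bucket_edges(cfg)
    intervals = [(float(edges[i]), float(edges[i + 1])) for i in range(edges.size - 1)]
    keep = [not any(_overlaps(iv, ex) for ex in cfg.exclusions) for iv in intervals]

    n_samples = spectra.n_samples
    integrals = np.empty((n_samples, len(intervals)))
    for s in range(n_samples):
        cum = _cumulative_integral(spectra.ppm, spectra.intensities[s], edges)
        integrals[s] = np.diff(cum)

    kept_iv = [iv for iv, k in zip(intervals, keep) if k]
    drop_iv = [iv for iv, k in zip(intervals, keep) if not k]
    keep_mask = np.asarray(keep)

    def _frame(ivs, mat):
        cols = [f"{0.5 * (a + b):.4f}" for a, b in ivs]
        return pd.DataFrame(mat, index=spectra.sample_ids, columns=cols)

    return BucketTable(
        intervals=kept_iv,
        values=_frame(kept_iv, integrals[:, keep_mask]),
        dropped_intervals=drop_iv,
        dropped_values=_frame(drop_iv, integrals[:, ~keep_mask]),
    )


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_buckets(buckets: BucketTable, method: str = "total_area",
                      reference: np.ndarray | pd.Series | None = None) -> BucketTable:
    """Normalize a bucket table.

    ``total_area`` divides each row by its sum.  ``pqn`` divides each row
    by the median of its bucketwise quotients against the reference row
    (default: the bucketwise median across samples) and records that
    quotient as the sample's dilution factor; buckets where the reference
    is zero are excluded from the median.
    """
    vals = buckets.values.to_numpy()
    if method == "total_area":
        totals = vals.sum(axis=1)
        bad = np.flatnonzero(totals == 0)
        if bad.size:
            raise ValueError(f"zero total area for samples: "
                             f"{[buckets.sample_ids[i] for i in bad]}")
        out = vals / totals[:, None]
        return replace(buckets,
                       values=pd.DataFrame(out, index=buckets.values.index,
                                           columns=buckets.values.columns),
                       normalization="total_area",
                       total_area=pd.Series(totals, index=buckets.values.index,
                                            name="total_area"))
    if method == "pqn":
        ref = (np.median(vals, axis=0) if reference is None
               else np.asarray(reference, dtype=float))
        if ref.shape != (vals.shape[1],):
            raise ValueError("reference length must match bucket count")
        usable = ref > 0
        if not np.any(usable):
            raise ValueError("reference spectrum has no positive buckets")
        factors = np.median(vals[:, usable] / ref[usable], axis=1)
        bad = np.flatnonzero(factors == 0)
        if bad.size:
            raise ValueError(f"zero PQN dilution factor for samples: "
                             f"{[buckets.sample_ids[i] for i in bad]}")
        out = vals / factors[:, None]
        return replace(buckets,
                       values=pd.DataFrame(out, index=buckets.values.index,
                                           columns=buckets.values.columns),
                       normalization="pqn",
                       dilution_factors=pd.Series(factors, index=buckets.values.index,
                                                  name="pqn_dilution_factor"))
    raise ValueError(f"unknown normalization method {method!r}")


def process_spectra(spectra: SpectrumSet, cfg: BucketingConfig | None = None,
                    search_window: tuple[float, float] = (-0.2, 0.2)) -> BucketTable:
    """Full chain: reference -> bucket -> total-area -> PQN."""
    refd = reference_to_standard(spectra, search_window)
    bt = bucket_spectra(refd, cfg)
    bt = normalize_buckets(bt, "total_area")
    return normalize_buckets(bt, "pqn")
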