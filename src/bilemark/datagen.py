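"""Synthetic cohorts and toy NMR spectra with planted ground truth.

The study data this package targets — bile lipidomics (162 continuous
features over 36 benign / 36 CCA / 57 PDAC samples) and bile proteomics
(~2000 spectral counts over 5 vs 5 samples) — is not available as tables,
so every downstream stage is exercised on simulated cohorts whose effects
are known by construction.

Abundance model: each feature's log-abundance is Gaussian,
``x = base_mean + base_sd * z`` with ``z`` standard normal, and the
reported abundance is ``exp(x)``.  Correlated feature blocks are imposed
on the latent ``z`` via a Gaussian copula (Cholesky factor of the block
correlation matrix).  A planted group effect shifts the latent mean of the
affected features by ``effect_size`` within-group standard deviations in
every non-reference group.  Missingness is completely at random.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import CohortLabels, FeatureTable, SpectrumSet

__all__ = [
    "GroundTruthSpec",
    "SpectrumSimSpec",
    "generate_cohort",
    "generate_spectra",
    "lipidomics_spec",
    "proteomics_spec",
]


@dataclass
class GroundTruthSpec:
    """Recipe for a synthetic cohort with known ground truth.

    ``effect_size`` is expressed in within-group SD units on the latent
    (log) scale; ``correlation_blocks`` is a list of (feature index set,
    intra-block correlation) pairs with disjoint index sets.
    """

    n_per_group: Sequence[int] = (36, 36, 57)
    n_features: int = 162
    planted_features: Sequence[int] = ()
    effect_size: float = 0.0
    correlation_blocks: Sequence[tuple[Sequence[int], float]] = ()
    base_mean: float = 2.0
    base_sd: float = 0.6
    missing_rate: float = 0.0
    mode: str = "decimal"
    seed: int = 0
    group_names: Sequence[str] | None = None

    def validate(self) -> None:
        if len(self.n_per_group) < 2:
            raise ValueError("need at least two groups")
        if any(n < 2 for n in self.n_per_group):
            raise ValueError("each group needs >= 2 samples")
        if self.n_features < 1:
            raise ValueError("n_features must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.effect_size > 0 and len(self.planted_features) == 0:
            raise ValueError("effect_size > 0 requires at least one planted feature")
        if any(not (0 <= j < self.n_features) for j in self.planted_features):
            raise ValueError("planted_features outside feature index range")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.mode not in ("decimal", "integer"):
            raise ValueError("mode must be 'decimal' or 'integer'")
        seen: set[int] = set()
        for idx, rho in self.correlation_blocks:
            idx = set(int(i) for i in idx)
            if idx & seen:
                raise ValueError("correlation block index sets must be disjoint")
            if any(not (0 <= j < self.n_features) for j in idx):
                raise ValueError("correlation block index outside feature range")
            if not (0 <= rho < 1):
                raise ValueError("intra-block correlation must be in [0, 1)")
            seen |= idx

    def resolved_group_names(self) -> list[str]:
        if self.group_names is not None:
            names = [str(g) for g in self.group_names]
            if len(names) != len(self.n_per_group):
                raise ValueError("group_names length must match n_per_group")
            return names
        defaults = ["benign", "CCA", "PDAC"]
        k = len(self.n_per_group)
        if k <= len(defaults):
            return defaults[:k]
        return defaults + [f"group{i + 1}" for i in range(len(defaults), k)]


def lipidomics_spec(effect_size: float = 1.5, n_planted: int = 10,
                    groups: Sequence[int] = (36, 36, 57), seed: int = 0,
                    missing_rate: float = 0.0,
                    correlation_blocks: Sequence[tuple[Sequence[int], float]] | None = None,
                    ) -> GroundTruthSpec:
    """Lipidomics-like fixture: 162 continuous features, benign/CCA/PDAC
    cohort sizes, the first ``n_planted`` features carrying the effect."""
    if correlation_blocks is None:
        correlation_blocks = ((tuple(range(20, 30)), 0.6), (tuple(range(30, 40)), 0.3))
    return GroundTruthSpec(
        n_per_group=tuple(groups), n_features=162,
        planted_features=tuple(range(n_planted)), effect_size=effect_size,
        correlation_blocks=tuple(correlation_blocks),
        base_mean=2.0, base_sd=0.6, missing_rate=missing_rate,
        mode="decimal", seed=seed,
    )


def proteomics_spec(effect_size: float = 1.5, n_planted: int = 5,
                    n_features: int = 2000, seed: int = 0) -> GroundTruthSpec:
    """Proteomics-like fixture: ~2000 integer spectral-count features over a
    5 vs 5 benign/CCA comparison."""
    return GroundTruthSpec(
        n_per_group=(5, 5), n_features=n_features,
        planted_features=tuple(range(n_planted)), effect_size=effect_size,
        correlation_blocks=((tuple(range(50, 70)), 0.5),),
        base_mean=4.0, base_sd=0.8, missing_rate=0.0,
        mode="integer", seed=seed, group_names=("benign", "CCA"),
    )


def _latent_draws(spec: GroundTruthSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    z = rng.standard_normal((n, spec.n_features))
    for idx, rho in spec.correlation_blocks:
        idx = np.asarray(sorted(int(i) for i in idx))
        k = idx.size
        if k < 2:
            continue
        block = np.full((k, k), rho)
        np.fill_diagonal(block, 1.0)
        chol = np.linalg.cholesky(block)
        z[:, idx] = z[:, idx] @ chol.T
    return z


def generate_cohort(spec: GroundTruthSpec) -> tuple[FeatureTable, CohortLabels, dict]:
    """Draw a cohort from ``spec``.

    Returns the feature table, the labels (first group is the reference and
    carries no effect) and a ground-truth record of what was planted.
    Identical spec + seed gives a bitwise-identical table.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    names = spec.resolved_group_names()
    n_total = int(sum(spec.n_per_group))

    z = _latent_draws(spec, n_total, rng)
    latent = spec.base_mean + spec.base_sd * z

    group_of = np.repeat(np.arange(len(names)), spec.n_per_group)
    planted = np.asarray(sorted(int(j) for j in spec.planted_features), dtype=int)
    if planted.size and spec.effect_size > 0:
        shift = spec.effect_size * spec.base_sd
        latent[np.ix_(group_of > 0, planted)] += shift

    values = np.exp(latent)
    if spec.mode == "integer":
        values = np.floor(values + 0.5)  # round half away from zero; values > 0
        values = np.maximum(values, 0.0)
    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        values = np.where(mask, np.nan, values)

    sample_ids = [f"S{i + 1:03d}" for i in range(n_total)]
    feature_ids = [f"F{j + 1:04d}" for j in range(spec.n_features)]
    table = FeatureTable(pd.DataFrame(values, index=sample_ids, columns=feature_ids),
                         kind=spec.mode)
    labels = CohortLabels(pd.Series([names[g] for g in group_of], index=sample_ids))
    truth = {
        "planted_features": [feature_ids[j] for j in planted],
        "planted_indices": planted.tolist(),
        "effect_size": spec.effect_size,
        "reference_group": names[0],
        "group_names": names,
        "n_per_group": list(spec.n_per_group),
        "correlation_blocks": [(sorted(int(i) for i in idx), float(rho))
                               for idx, rho in spec.correlation_blocks],
        "base_mean": spec.base_mean,
        "base_sd": spec.base_sd,
        "missing_rate": spec.missing_rate,
        "mode": spec.mode,
        "seed": spec.seed,
    }
    return table, labels, truth


@dataclass
class SpectrumSimSpec:
    """Recipe for toy 1D NMR spectra: Lorentzian peaks on a ppm grid, a
    TSP-like reference peak near 0 ppm, per-sample dilution factors,
    optional artifact regions (e.g. residual water or contrast-reagent
    signal) and additive Gaussian noise."""

    ppm_grid: tuple[float, float, float] = (-0.5, 9.5, 0.001)
    peaks: Sequence[tuple[float, float, float]] = ((1.33, 10.0, 0.01), (3.05, 6.0, 0.01),
                                                   (5.23, 4.0, 0.015), (8.45, 2.0, 0.01))
    dilution_factors: Sequence[float] | None = None
    artifact_regions: Sequence[tuple[float, float]] = ()
    noise_sd: float = 0.0
    reference_peak_offset: float | Sequence[float] = 0.0
    reference_peak_height: float = 15.0
    seed: int = 0

    def validate(self, n_samples: int) -> None:
        lo, hi, step = self.ppm_grid
        if step <= 0:
            raise ValueError("ppm grid step must be > 0")
        if lo >= hi:
            raise ValueError("ppm grid must have low < high")
        if len(self.peaks) == 0:
            raise ValueError("at least one peak is required")
        for c, h, w in self.peaks:
            if not (lo <= c <= hi):
                raise ValueError(f"peak center {c} outside ppm grid")
            if w <= 0:
                raise ValueError("peak half-width must be > 0")
        if self.dilution_factors is not None:
            if len(self.dilution_factors) != n_samples:
                raise ValueError("one dilution factor per sample required")
            if any(d <= 0 for d in self.dilution_factors):
                raise ValueError("dilution factors must be > 0")
        offs = np.atleast_1d(np.asarray(self.reference_peak_offset, dtype=float))
        if offs.size not in (1, n_samples):
            raise ValueError("reference_peak_offset must be scalar or per-sample")


def _lorentzian(x: np.ndarray, center: float, height: float, hw: float) -> np.ndarray:
    return height * hw ** 2 / ((x - center) ** 2 + hw ** 2)


def generate_spectra(spec: SpectrumSimSpec, n_samples: int) -> tuple[SpectrumSet, np.ndarray]:
    """Simulate ``n_samples`` spectra; returns the set and the true dilution
    factors.  Each spectrum is ``d_s * (signal peaks + reference peak) +
    artifacts + noise``; artifacts do not scale with dilution."""
    spec.validate(n_samples)
    rng = np.random.default_rng(spec.seed)
    lo, hi, step = spec.ppm_grid
    ppm = np.arange(lo, hi + step / 2, step)

    dil = (np.ones(n_samples) if spec.dilution_factors is None
           else np.asarray(spec.dilution_factors, dtype=float))
    offs = np.atleast_1d(np.asarray(spec.reference_peak_offset, dtype=float))
    if offs.size == 1:
        offs = np.repeat(offs, n_samples)

    spectra = np.empty((n_samples, ppm.size))
    for s in range(n_samples):
        signal = np.zeros_like(ppm)
        for c, h, w in spec.peaks:
            signal += _lorentzian(ppm, c, h, w)
        if spec.reference_peak_height > 0:
            signal += _lorentzian(ppm, offs[s], spec.reference_peak_height, 2 * step)
        y = dil[s] * signal
        for a_lo, a_hi in spec.artifact_regions:
            center = 0.5 * (a_lo + a_hi)
            width = max((a_hi - a_lo) / 4, step)
            y += _lorentzian(ppm, center, rng.uniform(1.0, 5.0), width)
        if spec.noise_sd > 0:
            y += rng.normal(0.0, spec.noise_sd, ppm.size)
        spectra[s] = y

    return SpectrumSet(ppm, spectra), dil
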