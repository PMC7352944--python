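"""Shared data containers: feature tables, cohort labels and NMR spectra.

Everything downstream speaks in terms of three objects:

* :class:`FeatureTable` — a sample × feature abundance matrix.  Missing
  entries are NaN; ``kind`` records whether observed values are continuous
  ("decimal", the metabolomics case) or whole counts ("integer", the
  proteomics case).
* :class:`CohortLabels` — the sample → group assignment.
* :class:`SpectrumSet` — 1D NMR spectra sharing a single ppm axis.

All three round-trip through plain tab-separated text so every pipeline
stage can be re-run from files.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "CohortLabels", "SpectrumSet"]


def _check_unique(ids: Sequence, what: str) -> None:
    if len(set(map(str, ids))) != len(ids):
        raise ValueError(f"duplicate {what} ids")


class FeatureTable:
    """Sample × feature abundance matrix with an implicit missing mask.

    Parameters
    ----------
    data
        DataFrame indexed by sample id with one column per feature id.
        NaN marks a missing measurement.
    kind
        "decimal" for continuous abundances, "integer" for count data.
        Integer tables must contain only non-negative whole numbers where
        observed.
    """

    KINDS = ("decimal", "integer")

    def __init__(self, data: pd.DataFrame, kind: str = "decimal"):
        if kind not in self.KINDS:
            raise ValueError(f"kind must be one of {self.KINDS}, got {kind!r}")
        _check_unique(list(data.index), "sample")
        _check_unique(list(data.columns), "feature")
        data = data.astype(float)
        if kind == "integer":
            vals = data.to_numpy()
            obs = vals[np.isfinite(vals)]
            if obs.size and (np.any(obs < 0) or np.any(obs != np.round(obs))):
                raise ValueError("integer table contains negative or fractional values")
        self.data = data
        self.kind = kind

    # -- basic introspection -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def feature_ids(self) -> list[str]:
        return [str(f) for f in self.data.columns]

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    @property
    def has_missing(self) -> bool:
        return bool(self.data.isna().to_numpy().any())

    # -- manipulation --------------------------------------------------------
    def subset(self, features: Iterable[str]) -> "FeatureTable":
        features = list(features)
        missing = [f for f in features if f not in self.data.columns]
        if missing:
            raise KeyError(f"features not in table: {missing}")
        return FeatureTable(self.data.loc[:, features].copy(), kind=self.kind)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.data.copy(), kind=self.kind)

    def __eq__(self, other) -> bool:  # value equality, used by tests
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return self.kind == other.kind and self.data.equals(other.data)

    def __repr__(self) -> str:
        return (
            f"FeatureTable({self.n_samples} samples x {self.n_features} "
            f"features, kind={self.kind!r}, "
            f"missing={int(self.data.isna().to_numpy().sum())})"
        )

    # -- I/O -----------------------------------------------------------------
    def write(self, path, sep: str = "\t") -> None:
        self.data.to_csv(path, sep=sep, index_label="sample")

    @classmethod
    def read(cls, path, kind: str = "decimal", sep: str = "\t") -> "FeatureTable":
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
        return cls(df, kind=kind)


class CohortLabels:
    """Sample → group assignment.

    Group order follows first appearance in the mapping, so the clinically
    designated reference group (e.g. the benign strictures) can be listed
    first and stays first.
    """

    def __init__(self, mapping: pd.Series | dict):
        series = pd.Series(mapping, dtype=object)
        _check_unique(list(series.index), "sample")
        if series.isna().any():
            raise ValueError("every sample must have a group")
        self.series = series.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.series.index]

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.series:
            seen.setdefault(g, None)
        return list(seen)

    def counts(self) -> dict[str, int]:
        return {g: int((self.series == g).sum()) for g in self.groups}

    def members(self, group: str) -> list[str]:
        return [str(s) for s in self.series.index[self.series == group]]

    def require_groups(self, min_groups: int = 2, min_per_group: int = 3) -> None:
        counts = self.counts()
        if len(counts) < min_groups:
            raise ValueError(f"need >= {min_groups} groups, got {len(counts)}")
        small = {g: n for g, n in counts.items() if n < min_per_group}
        if small:
            raise ValueError(f"groups below {min_per_group} samples: {small}")

    def align_to(self, table: FeatureTable) -> "CohortLabels":
        """Labels reordered to the table's samples; errors on any mismatch."""
        missing = set(table.sample_ids) ^ set(self.sample_ids)
        if missing:
            raise ValueError(f"sample ids mismatch between table and labels: {sorted(missing)}")
        return CohortLabels(self.series.loc[table.sample_ids])

    def __eq__(self, other) -> bool:
        if not isinstance(other, CohortLabels):
            return NotImplemented
        return self.series.equals(other.series)

    def write(self, path, sep: str = "\t") -> None:
        self.series.rename("group").to_csv(path, sep=sep, index_label="sample")

    @classmethod
    def read(cls, path, sep: str = "\t") -> "CohortLabels":
        df = pd.read_csv(path, sep=sep, index_col=0)
        return cls(df.iloc[:, 0])


class SpectrumSet:
    """Aligned 1D NMR spectra: one strictly monotone ppm axis, one intensity
    row per sample."""

    def __init__(self, ppm: np.ndarray, intensities: np.ndarray, sample_ids: Sequence[str] | None = None):
        ppm = np.asarray(ppm, dtype=float)
        intensities = np.atleast_2d(np.asarray(intensities, dtype=float))
        if ppm.ndim != 1:
            raise ValueError("ppm axis must be 1-D")
        d = np.diff(ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotone")
        if intensities.shape[1] != ppm.size:
            raise ValueError("intensity matrix width must match ppm axis")
        if not np.all(np.isfinite(intensities)):
            raise ValueError("intensities must be finite")
        if sample_ids is None:
            sample_ids = [f"spec{i + 1}" for i in range(intensities.shape[0])]
        sample_ids = [str(s) for s in sample_ids]
        if len(sample_ids) != intensities.shape[0]:
            raise ValueError("one sample id per spectrum required")
        _check_unique(sample_ids, "spectrum")
        # store with ascending ppm for convenience
        if d[0] < 0:
            ppm = ppm[::-1]
            intensities = intensities[:, ::-1]
        self.ppm = ppm
        self.intensities = intensities
        self.sample_ids = sample_ids

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    def write(self, path, sep: str = "\t") -> None:
        df = pd.DataFrame(self.intensities.T, columns=self.sample_ids)
        df.insert(0, "ppm", self.ppm)
        df.to_csv(path, sep=sep, index=False)

    @classmethod
    def read(cls, path, sep: str = "\t") -> "SpectrumSet":
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
        return cls(df["ppm"].to_numpy(), df.drop(columns="ppm").to_numpy().T,
                   sample_ids=list(df.columns[1:]))
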