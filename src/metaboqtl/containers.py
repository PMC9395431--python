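"""Core in-memory containers shared across the pipeline.

The pipeline is DataFrame-first: intensity matrices, dosage matrices and
summary statistics live in :class:`pandas.DataFrame` objects, with small
dataclass wrappers carrying the metadata that the individual stages need
(injection order and pooled-QC flags for drift correction, variant
coordinates for locus definition, fragment lists for spectral scoring).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "GenotypeData",
    "MsmsSpectrum",
    "MqtlRegion",
    "NormalizedPhenotypes",
]


@dataclass
class FeatureTable:
    """Sample x feature LC-MS intensity matrix plus metadata.

    Parameters
    ----------
    intensities
        Samples in rows, features in columns; missing cells are NaN.
    features
        Indexed by feature id, with columns ``mz`` (Da), ``rt`` (min),
        ``identity`` (known compound name or empty string) and optionally
        ``mode`` (acquisition mode).
    samples
        Indexed by sample id, with columns ``is_qc`` (pooled-QC flag),
        ``injection_order`` (unique within ``batch``) and ``batch``.
    """

    intensities: pd.DataFrame
    features: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.intensities.columns.equals(self.features.index):
            self.features = self.features.loc[self.intensities.columns]
        if not self.intensities.index.equals(self.samples.index):
            self.samples = self.samples.loc[self.intensities.index]
        if (self.features["mz"] <= 0).any():
            raise ValueError("feature m/z values must be positive")
        if (self.features["rt"] < 0).any():
            raise ValueError("feature retention times must be non-negative")
        dup = self.samples.groupby("batch")["injection_order"].apply(
            lambda s: s.duplicated().any()
        )
        if dup.any():
            raise ValueError("injection orders must be unique within a batch")

    @property
    def qc_mask(self) -> pd.Series:
        return self.samples["is_qc"].astype(bool)

    def biological(self) -> pd.DataFrame:
        """Intensity rows for study (non pooled-QC) samples."""
        return self.intensities.loc[~self.qc_mask]

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.intensities.copy(), self.features.copy(), self.samples.copy()
        )


@dataclass
class GenotypeData:
    """Sample x variant dosage matrix with variant coordinates.

    ``dosages`` holds additive allele counts in {0, 1, 2} (NaN = missing);
    ``variants`` is indexed by variant id with columns ``chrom``, ``pos``
    (1-based), ``ref`` and ``alt``.
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dosages.columns.equals(self.variants.index):
            self.variants = self.variants.loc[self.dosages.columns]
        if (self.variants["pos"] <= 0).any():
            raise ValueError("variant positions must be positive")

    def minor_allele_counts(self) -> pd.Series:
        """MAC per variant over non-missing samples."""
        d = self.dosages
        n_called = d.notna().sum(axis=0)
        alt = d.sum(axis=0, skipna=True)
        return pd.concat([alt, 2 * n_called - alt], axis=1).min(axis=1).astype(int)


@dataclass
class MsmsSpectrum:
    """A fragmentation spectrum of one selected precursor ion.

    Peaks are kept sorted by fragment m/z; ``collision_energy`` may be a
    number or the label ``"stepped"``.
    """

    precursor_mz: float
    rt: float
    collision_energy: object
    mz: np.ndarray
    intensity: np.ndarray
    feature_id: str | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class NormalizedPhenotypes:
    """Inverse-normalized metabolite residuals ready for association.

    ``values`` is a sample x metabolite matrix of rank-based inverse normal
    transformed residuals; ``covariates_used`` records the design columns
    that were regressed out.
    """

    values: pd.DataFrame
    covariates_used: list[str] = field(default_factory=list)


@dataclass
class MqtlRegion:
    """A merged metabolite quantitative trait locus.

    The interval is 1-based inclusive; ``members`` is the association
    summary-statistics frame restricted to hits inside the region and the
    sentinel is the member with the lowest p-value.
    """

    metabolite: str
    chrom: str
    start: int
    end: int
    members: pd.DataFrame
    sentinel: str
    sentinel_p: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start must not exceed end")
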