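"""Genotype containers shared across the pipeline.

Genotypes are stored as an individuals x markers matrix of allele-dosage
calls in {0, 1, 2} with -1 marking missing data.  Which allele is counted is
recorded per marker in ``alleles`` (column ``counted``), so orientation can
be flipped without touching the call matrix semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

MAP_COLUMNS = ["marker_id", "chromosome", "position_bp", "genetic_pos_cM"]


def validate_marker_map(marker_map: pd.DataFrame) -> pd.DataFrame:
    """Check a marker map for the invariants the pipeline assumes.

    Positions must be strictly increasing and genetic positions
    non-decreasing within each chromosome; marker ids must be unique.
    Returns the map unchanged on success.
    """
    missing_cols = [c for c in MAP_COLUMNS if c not in marker_map.columns]
    if missing_cols:
        raise ValueError(f"marker map missing columns: {missing_cols}")
    if len(marker_map) == 0:
        raise ValueError("marker map is empty")
    if marker_map["marker_id"].duplicated().any():
        dups = marker_map.loc[marker_map["marker_id"].duplicated(), "marker_id"]
        raise ValueError(f"duplicate marker ids: {sorted(set(dups))[:5]}")
    for chrom, sub in marker_map.groupby("chromosome", sort=False):
        pos = sub["position_bp"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"positions not strictly increasing on chromosome {chrom}")
        cm = sub["genetic_pos_cM"].to_numpy(dtype=float)
        if np.any(np.diff(cm) < 0):
            raise ValueError(f"genetic positions decreasing on chromosome {chrom}")
    return marker_map


def uniform_marker_map(
    n_chromosomes: int = 19,
    markers_per_chromosome: int = 100,
    chrom_length_bp: int = 100_000_000,
    cm_per_mb: float = 1.0,
) -> pd.DataFrame:
    """Evenly spaced marker map; 1 cM = 1 Mb by default."""
    rows = []
    spacing = chrom_length_bp // (markers_per_chromosome + 1)
    for c in range(1, n_chromosomes + 1):
        for i in range(markers_per_chromosome):
            pos = (i + 1) * spacing
            rows.append((f"m{c}_{i + 1}", c, pos, pos / 1e6 * cm_per_mb))
    return pd.DataFrame(rows, columns=MAP_COLUMNS)


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage matrix plus marker metadata.

    Parameters
    ----------
    calls : int array (n_samples, n_markers) with values in {0, 1, 2, -1}.
    samples : sample identifiers, length n_samples.
    marker_map : DataFrame with ``MAP_COLUMNS`` rows aligned to call columns.
    alleles : DataFrame with columns ``counted`` and ``other`` (allele labels),
        aligned to call columns.
    """

    calls: np.ndarray
    samples: list[str]
    marker_map: pd.DataFrame
    alleles: pd.DataFrame = field(default=None)

    def __post_init__(self):
        self.calls = np.asarray(self.calls)
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype calls must be in {0, 1, 2, missing}")
        validate_marker_map(self.marker_map)
        if self.calls.shape != (len(self.samples), len(self.marker_map)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.marker_map)} markers"
            )
        if self.alleles is None:
            self.alleles = pd.DataFrame(
                {"counted": ["A"] * self.n_markers, "other": ["B"] * self.n_markers}
            )
        self.marker_map = self.marker_map.reset_index(drop=True)
        self.alleles = self.alleles.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    @property
    def marker_ids(self) -> pd.Index:
        return pd.Index(self.marker_map["marker_id"])

    def marker_index(self, marker_id: str) -> int:
        idx = np.flatnonzero((self.marker_map["marker_id"] == marker_id).to_numpy())
        if idx.size == 0:
            raise KeyError(f"marker {marker_id!r} not found")
        return int(idx[0])

    def dosages(self, impute: bool = False) -> np.ndarray:
        """Calls as float with missing -> NaN (or marker-mean imputed)."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        if impute:
            means = np.nanmean(d, axis=0)
            means = np.where(np.isnan(means), 0.0, means)
            idx = np.where(np.isnan(d))
            d[idx] = means[idx[1]]
        return d

    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted allele per marker (missing excluded)."""
        d = self.dosages()
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def call_rate_samples(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=1)

    def missing_rate_markers(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    def subset(self, sample_idx=None, marker_idx=None) -> "GenotypeMatrix":
        sample_idx = (
            np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        )
        marker_idx = (
            np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        )
        return GenotypeMatrix(
            calls=self.calls[np.ix_(sample_idx, marker_idx)].copy(),
            samples=[self.samples[i] for i in sample_idx],
            marker_map=self.marker_map.iloc[marker_idx].reset_index(drop=True),
            alleles=self.alleles.iloc[marker_idx].reset_index(drop=True),
        )

    def to_minor_allele(self) -> "GenotypeMatrix":
        """Re-orient so the counted allele is the within-cohort minor allele."""
        f = self.allele_freq()
        flip = f > 0.5
        calls = self.calls.copy()
        cols = np.flatnonzero(flip)
        sub = calls[:, cols]
        obs = sub != MISSING
        sub[obs] = 2 - sub[obs]
        calls[:, cols] = sub
        alleles = self.alleles.copy()
        counted = alleles["counted"].to_numpy().copy()
        other = alleles["other"].to_numpy().copy()
        counted[flip], other[flip] = other[flip].copy(), counted[flip].copy()
        alleles = pd.DataFrame({"counted": counted, "other": other})
        return replace(self, calls=calls, alleles=alleles)
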