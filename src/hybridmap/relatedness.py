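"""Genomic relatedness matrices: centred, standardised and LOCO.

Centred GRM:      K = (1/p) * sum_i (x_i - mean_i)(x_i - mean_i)^T
Standardised GRM: as centred, but each marker's term is divided by the
biased (1/n) sample variance of its dosages, which makes trace(K) = n.

Missing dosages are mean-imputed per marker before centring.  The LOCO
(leave-one-chromosome-out) variant excludes one chromosome's markers, the
convention used when testing SNPs on that chromosome to avoid proximal
contamination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeMatrix

__all__ = ["GRM", "grm_centred", "grm_standardised", "grm_loco"]


@dataclass
class GRM:
    matrix: np.ndarray
    flavour: str  # 'centred' | 'standardised'
    samples: list[str]
    n_markers: int
    excluded_chromosome: object | None = None

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def _centred_columns(g: GenotypeMatrix) -> np.ndarray:
    x = g.dosages(impute=True)
    return x - x.mean(axis=0, keepdims=True)


def grm_centred(g: GenotypeMatrix, _exclude: np.ndarray | None = None) -> GRM:
    """Centred GRM over all markers (monomorphic columns contribute zero)."""
    xc = _centred_columns(g)
    if _exclude is not None:
        xc = xc[:, ~_exclude]
    p = xc.shape[1]
    if p == 0 or not np.any(xc.var(axis=0) > 0):
        raise ValueError("no polymorphic markers available for the GRM")
    k = (xc @ xc.T) / p
    return GRM(matrix=k, flavour="centred", samples=list(g.samples), n_markers=p)


def grm_standardised(g: GenotypeMatrix, _exclude: np.ndarray | None = None) -> GRM:
    """Standardised GRM; zero-variance markers are excluded (p adjusted)."""
    xc = _centred_columns(g)
    if _exclude is not None:
        xc = xc[:, ~_exclude]
    v = xc.var(axis=0)  # biased (1/n) variance
    poly = v > 0
    n_dropped = int((~poly).sum())
    if n_dropped:
        warnings.warn(f"excluding {n_dropped} zero-variance markers from standardised GRM")
    if not poly.any():
        raise ValueError("no polymorphic markers available for the GRM")
    z = xc[:, poly] / np.sqrt(v[poly])
    p = z.shape[1]
    k = (z @ z.T) / p
    return GRM(matrix=k, flavour="standardised", samples=list(g.samples), n_markers=p)


def grm_loco(g: GenotypeMatrix, chromosome, flavour: str = "centred") -> GRM:
    """GRM from all markers *not* on ``chromosome``."""
    on = (g.marker_map["chromosome"] == chromosome).to_numpy()
    if on.all():
        raise ValueError("all markers are on the excluded chromosome")
    sub = g.subset(marker_idx=np.flatnonzero(~on))
    fn = {"centred": grm_centred, "standardised": grm_standardised}[flavour]
    grm = fn(sub)
    grm.excluded_chromosome = chromosome
    return grm


def loco_grms(g: GenotypeMatrix, flavour: str = "centred") -> dict:
    """LOCO GRM for every chromosome present in the map."""
    return {
        c: grm_loco(g, c, flavour=flavour)
        for c in g.marker_map["chromosome"].unique()
    }
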