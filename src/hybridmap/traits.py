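"""Taxon count tables and their conversion to mapping-ready traits.

Count tables are taxa x samples.  The mapping traits are inverse-logit
transformed relative abundances of the "core" taxa (prevalence and median
non-zero abundance thresholds evaluated on the rarefied table), plus the
Shannon and Chao1 alpha-diversity indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from skbio.diversity.alpha import chao1, shannon

RANKS = ("ASV", "genus", "family", "order", "class", "phylum")
# core-microbiome median non-zero relative-abundance cutoffs per rank
_CORE_ABUNDANCE_CUTOFF = {
    "ASV": 0.002,
    "genus": 0.002,
    "family": 0.005,
    "order": 0.005,
    "class": 0.005,
    "phylum": 0.005,
}
CORE_PREVALENCE = 0.25

__all__ = [
    "AbundanceTable",
    "TraitMatrix",
    "rarefy",
    "core_filter",
    "transform_traits",
    "alpha_diversity",
    "bray_curtis",
]


@dataclass
class AbundanceTable:
    """Taxon-by-sample count table with rank metadata.

    ``counts``: DataFrame (taxa rows x sample columns), non-negative ints.
    ``ranks``: Series mapping taxon -> taxonomic rank.
    ``level``: 'DNA' or 'RNA' profiling level.
    """

    counts: pd.DataFrame
    ranks: pd.Series
    level: str = "DNA"

    def __post_init__(self):
        vals = self.counts.to_numpy()
        if (vals < 0).any() or not np.issubdtype(vals.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        if self.level not in ("DNA", "RNA"):
            raise ValueError("level must be 'DNA' or 'RNA'")
        self.ranks = self.ranks.reindex(self.counts.index)
        unknown = set(self.ranks.dropna()) - set(RANKS)
        if unknown:
            raise ValueError(f"unknown taxonomic ranks: {sorted(unknown)}")

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def relative(self) -> pd.DataFrame:
        return self.counts / self.counts.sum(axis=0)


@dataclass
class TraitMatrix:
    """Samples x traits matrix of mapping phenotypes plus trait metadata."""

    values: pd.DataFrame  # samples x traits
    meta: pd.DataFrame  # trait, taxon, rank, level

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]


def rarefy(t: AbundanceTable, depth: int = 10_000, seed: int = 0) -> AbundanceTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped with a
    warning, mirroring per-level sample attrition in real profiling runs.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    totals = t.counts.sum(axis=0)
    keep = totals[totals >= depth].index
    dropped = [c for c in t.counts.columns if c not in set(keep)]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} samples below rarefaction depth {depth}"
        )
    rng = np.random.default_rng(seed)
    out = {}
    for s in keep:
        col = t.counts[s].to_numpy(dtype=np.int64)
        if col.sum() == depth:
            out[s] = col
        else:
            out[s] = rng.multivariate_hypergeometric(col, depth)
    counts = pd.DataFrame(out, index=t.counts.index, dtype=np.int64)
    return AbundanceTable(counts=counts, ranks=t.ranks, level=t.level)


def core_filter(t: AbundanceTable) -> list[str]:
    """Core taxa: prevalence > 25% and rank-dependent median abundance.

    Median is taken over *non-zero* relative abundances; cutoffs are 0.2%
    for ASV/genus and 0.5% for family, order, class and phylum.
    """
    rel = t.relative()
    core = []
    for taxon in t.counts.index:
        rank = t.ranks.loc[taxon]
        if rank not in _CORE_ABUNDANCE_CUTOFF:
            raise ValueError(f"unknown rank {rank!r} for taxon {taxon!r}")
        row = rel.loc[taxon]
        prevalence = (row > 0).mean()
        if prevalence <= CORE_PREVALENCE:
            continue
        nonzero = row[row > 0]
        if len(nonzero) and nonzero.median() > _CORE_ABUNDANCE_CUTOFF[rank]:
            core.append(taxon)
    return core


def transform_traits(
    t: AbundanceTable, core: list[str], include_diversity: bool = True
) -> TraitMatrix:
    """Inverse-logit transform relative abundances of core taxa.

    The transform is exp(x)/(1+exp(x)) applied to the proportion x itself,
    so trait values lie in [0.5, e/(1+e)].  Shannon and Chao1 columns are
    appended untransformed when ``include_diversity`` is set.
    """
    missing = [c for c in core if c not in t.counts.index]
    if missing:
        raise ValueError(f"core taxa absent from table: {missing}")
    rel = t.relative().loc[core].T  # samples x taxa
    values = pd.DataFrame(expit(rel.to_numpy()), index=rel.index, columns=rel.columns)
    meta = pd.DataFrame(
        {
            "trait": core,
            "taxon": core,
            "rank": [t.ranks.loc[c] for c in core],
            "level": t.level,
        }
    )
    if include_diversity:
        alpha = alpha_diversity(t)
        for name in ("shannon", "chao1"):
            values[name] = alpha[name]
            meta = pd.concat(
                [
                    meta,
                    pd.DataFrame(
                        [{"trait": name, "taxon": None, "rank": None, "level": t.level}]
                    ),
                ],
                ignore_index=True,
            )
    return TraitMatrix(values=values, meta=meta)


def alpha_diversity(t: AbundanceTable) -> pd.DataFrame:
    """Shannon (natural log) and Chao1 per sample."""
    rows = {}
    for s in t.counts.columns:
        col = t.counts[s].to_numpy(dtype=np.int64)
        if col.sum() == 0:
            raise ValueError(f"sample {s!r} has zero total count")
        # bias-corrected Chao1: S_obs + F1*(F1-1)/(2*(F2+1))
        rows[s] = (shannon(col, base=np.e), chao1(col, bias_corrected=True))
    return pd.DataFrame.from_dict(rows, orient="index", columns=["shannon", "chao1"])


def bray_curtis(t: AbundanceTable) -> pd.DataFrame:
    """Bray-Curtis dissimilarity, samples x samples."""
    x = t.counts.to_numpy(dtype=float).T  # samples x taxa
    sums = x.sum(axis=1)
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        mins = np.minimum(x[i], x[i + 1 :]).sum(axis=1)
        d[i, i + 1 :] = 1.0 - 2.0 * mins / (sums[i] + sums[i + 1 :])
    d = d + d.T
    return pd.DataFrame(d, index=t.counts.columns, columns=t.counts.columns)
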