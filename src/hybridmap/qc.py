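"""Genotype quality control, LD pruning, AIM detection and hybrid index.

Filters follow standard array-QC practice: individuals with low call rate
are removed first, then markers failing missingness, minor-allele-frequency
or Hardy-Weinberg exact-test thresholds.  The HWE test is the exact
conditional test (sum over heterozygote counts with probability less than
or equal to the observed one, given the allele counts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "QCReport",
    "qc_filter",
    "hwe_exact_test",
    "ld_r2",
    "ld_prune",
    "find_aims",
    "hybrid_index",
]


@dataclass
class QCReport:
    thresholds: dict
    removed_individuals: dict = field(default_factory=dict)
    removed_markers: dict = field(default_factory=dict)
    n_individuals_in: int = 0
    n_individuals_out: int = 0
    n_markers_in: int = 0
    n_markers_out: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [("individuals", k, v) for k, v in self.removed_individuals.items()]
        rows += [("markers", k, v) for k, v in self.removed_markers.items()]
        return pd.DataFrame(rows, columns=["axis", "filter", "n_removed"])


def hwe_exact_test(n_AA: int, n_AB: int, n_BB: int) -> float:
    """Exact Hardy-Weinberg test p-value by enumeration over het counts.

    Conditional on the observed allele counts, heterozygote counts with
    probability <= that of the observed configuration are summed
    (standard, not mid-p).  Monomorphic or empty samples give p = 1.
    """
    if min(n_AA, n_AB, n_BB) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_AB + n_BB
    if n == 0:
        return 1.0
    n_a = 2 * n_AA + n_AB  # minor or major, symmetric
    rare = min(n_a, 2 * n - n_a)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(n_AB = h | allele counts) up to a shared constant
    homr = (rare - hets) // 2
    homc = (2 * n - rare - hets) // 2
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(homr + 1)
        - gammaln(homc + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = prob[np.flatnonzero(hets == n_AB)[0]]
    return float(min(1.0, prob[prob <= obs * (1 + 1e-12)].sum()))


def _genotype_counts(calls_col: np.ndarray) -> tuple[int, int, int]:
    obs = calls_col[calls_col != MISSING]
    return int((obs == 2).sum()), int((obs == 1).sum()), int((obs == 0).sum())


def qc_filter(
    g: GenotypeMatrix,
    ind_call_rate: float = 0.90,
    snp_missing: float = 0.10,
    maf: float = 0.05,
    hwe_p: float = 1e-10,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove low-call-rate individuals, then failing markers.

    Marker filters: missingness > ``snp_missing``, MAF < ``maf``, HWE exact
    p < ``hwe_p``.  Non-biallelic markers are assumed removed upstream (the
    dosage representation is biallelic by construction).
    """
    for name, v in (("ind_call_rate", ind_call_rate), ("snp_missing", snp_missing),
                    ("maf", maf), ("hwe_p", hwe_p)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    report = QCReport(
        thresholds={
            "ind_call_rate": ind_call_rate,
            "snp_missing": snp_missing,
            "maf": maf,
            "hwe_p": hwe_p,
        },
        n_individuals_in=g.n_samples,
        n_markers_in=g.n_markers,
    )
    keep_ind = g.call_rate_samples() >= ind_call_rate
    report.removed_individuals["call_rate"] = int((~keep_ind).sum())
    g2 = g.subset(sample_idx=np.flatnonzero(keep_ind))

    if g2.n_samples == 0:
        warnings.warn("all individuals removed by call-rate filter")
        report.n_individuals_out = 0
        report.n_markers_out = 0
        return g2.subset(marker_idx=np.array([], dtype=int)), report

    miss = g2.missing_rate_markers()
    fail_miss = miss > snp_missing
    mafs = np.where(np.isnan(g2.maf()), 0.0, g2.maf())
    fail_maf = (~fail_miss) & (mafs < maf)
    fail_hwe = np.zeros(g2.n_markers, dtype=bool)
    for j in np.flatnonzero(~(fail_miss | fail_maf)):
        nAA, nAB, nBB = _genotype_counts(g2.calls[:, j])
        if hwe_exact_test(nAA, nAB, nBB) < hwe_p:
            fail_hwe[j] = True
    report.removed_markers["missingness"] = int(fail_miss.sum())
    report.removed_markers["maf"] = int(fail_maf.sum())
    report.removed_markers["hwe"] = int(fail_hwe.sum())
    keep = ~(fail_miss | fail_maf | fail_hwe)
    out = g2.subset(marker_idx=np.flatnonzero(keep))
    if out.n_markers == 0:
        warnings.warn("all markers removed by QC filters")
    out = out.to_minor_allele() if out.n_markers else out
    report.n_individuals_out = out.n_samples
    report.n_markers_out = out.n_markers
    return out, report


def ld_r2(g: GenotypeMatrix, i, j) -> float:
    """Squared Pearson correlation of dosages over pairwise-complete calls.

    ``i``/``j`` may be marker ids or column indices.  Zero variance in
    either marker over the complete pairs yields NaN.
    """
    i = g.marker_index(i) if isinstance(i, str) else int(i)
    j = g.marker_index(j) if isinstance(j, str) else int(j)
    xi, xj = g.calls[:, i], g.calls[:, j]
    ok = (xi != MISSING) & (xj != MISSING)
    if ok.sum() < 2:
        return float("nan")
    a, b = xi[ok].astype(float), xj[ok].astype(float)
    va, vb = a.var(), b.var()
    if va == 0 or vb == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _pairwise_r2(calls: np.ndarray) -> np.ndarray:
    """All-pairs r^2 for a small block of markers (pairwise complete)."""
    m = calls.shape[1]
    out = np.full((m, m), np.nan)
    for i in range(m):
        out[i, i] = 1.0
        for j in range(i + 1, m):
            xi, xj = calls[:, i], calls[:, j]
            ok = (xi != MISSING) & (xj != MISSING)
            if ok.sum() < 2:
                continue
            a, b = xi[ok].astype(float), xj[ok].astype(float)
            if a.var() == 0 or b.var() == 0:
                continue
            r = np.corrcoef(a, b)[0, 1]
            out[i, j] = out[j, i] = r * r
    return out


def ld_prune(
    g: GenotypeMatrix, window: int = 5, step: int = 1, r2_max: float = 0.9
) -> list[str]:
    """Greedy sliding-window LD pruning; returns retained marker ids.

    Within each window of ``window`` markers (advanced by ``step``), while
    any surviving pair has r^2 > ``r2_max``, the member of the worst pair
    with the lower MAF is dropped (tie: the later position).  Markers must
    be sorted by chromosome and position (the map invariant guarantees
    position order within chromosome).
    """
    mafs = np.where(np.isnan(g.maf()), 0.0, g.maf())
    ids = g.marker_map["marker_id"].to_numpy()
    chroms = g.marker_map["chromosome"].to_numpy()
    removed = np.zeros(g.n_markers, dtype=bool)
    for chrom in pd.unique(chroms):
        cols = np.flatnonzero(chroms == chrom)
        for start in range(0, len(cols), step):
            win = cols[start : start + window]
            if len(win) < 2:
                continue
            r2 = _pairwise_r2(g.calls[:, win])
            alive = ~removed[win]
            while True:
                cand = None
                for a in range(len(win)):
                    if not alive[a]:
                        continue
                    for b in range(a + 1, len(win)):
                        if alive[b] and r2[a, b] > r2_max:
                            cand = (a, b)
                            break
                    if cand:
                        break
                if cand is None:
                    break
                a, b = cand
                ia, ib = win[a], win[b]
                if mafs[ia] < mafs[ib]:
                    drop = a
                elif mafs[ib] < mafs[ia]:
                    drop = b
                else:  # tie -> later position
                    drop = b
                alive[drop] = False
                removed[win[drop]] = True
    return [ids[k] for k in np.flatnonzero(~removed)]


def find_aims(
    ref_musculus: GenotypeMatrix,
    ref_domesticus: GenotypeMatrix,
    min_calls: int = 10,
    min_freq_diff: float = 0.3,
) -> pd.DataFrame:
    """Ancestry-informative markers from two subspecies reference panels.

    A marker qualifies iff both panels have >= ``min_calls`` allele calls,
    the major allele differs between panels, and the absolute counted-allele
    frequency difference exceeds ``min_freq_diff``.  Returns a table with
    the allele tagging *musculus* ancestry.
    """
    if not ref_musculus.marker_map["marker_id"].equals(
        ref_domesticus.marker_map["marker_id"]
    ):
        raise ValueError("reference panels must share the marker map")
    rows = []
    for j in range(ref_musculus.n_markers):
        xm = ref_musculus.calls[:, j]
        xd = ref_domesticus.calls[:, j]
        nm = int((xm != MISSING).sum())
        nd = int((xd != MISSING).sum())
        if nm < min_calls or nd < min_calls:
            continue
        fm = xm[xm != MISSING].mean() / 2.0
        fd = xd[xd != MISSING].mean() / 2.0
        major_m = fm >= 0.5
        major_d = fd >= 0.5
        if major_m == major_d:
            continue
        if abs(fm - fd) <= min_freq_diff:
            continue
        counted = ref_musculus.alleles["counted"].iloc[j]
        other = ref_musculus.alleles["other"].iloc[j]
        rows.append(
            {
                "marker_id": ref_musculus.marker_map["marker_id"].iloc[j],
                "musculus_allele": counted if fm > fd else other,
                "freq_musculus": fm,
                "freq_domesticus": fd,
            }
        )
    return pd.DataFrame(
        rows, columns=["marker_id", "musculus_allele", "freq_musculus", "freq_domesticus"]
    )


def hybrid_index(g: GenotypeMatrix, aims: pd.DataFrame) -> pd.Series:
    """Per-individual fraction of non-missing AIM alleles that are musculus."""
    ids = g.marker_map["marker_id"]
    keep = ids.isin(aims["marker_id"])
    if not keep.any():
        raise ValueError("no AIMs present in genotype matrix")
    cols = np.flatnonzero(keep.to_numpy())
    mus_allele = aims.set_index("marker_id")["musculus_allele"]
    counted_is_mus = (
        g.alleles["counted"].iloc[cols].to_numpy()
        == mus_allele.loc[ids.iloc[cols]].to_numpy()
    )
    calls = g.calls[:, cols].astype(float)
    obs = calls != MISSING
    mus_copies = np.where(counted_is_mus[None, :], calls, 2 - calls)
    mus_copies[~obs] = 0.0
    denom = 2.0 * obs.sum(axis=1)
    with np.errstate(invalid="ignore"):
        hi = np.where(denom > 0, mus_copies.sum(axis=1) / denom, np.nan)
    if np.isnan(hi).any():
        warnings.warn("individuals with zero AIM calls: hybrid index set to NaN")
    return pd.Series(hi, index=pd.Index(g.samples, name="individual"), name="hybrid_index")
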