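"""Dominance architecture of mapped loci and percent variance explained.

The degree of dominance at a locus is summarised by d/|a|, the dominance
deviation over the absolute additive effect.  Because the sign of `a` is
tied to the (biologically arbitrary) within-cohort major allele, dividing
by |a| orients the ratio to the allele associated with higher trait values:
+1 means complete dominance of the high allele, -1 complete recessivity,
and values beyond +/-1.25 over/underdominance.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix
from .lmm import RandomTerm, reml_fit
from .relatedness import GRM
from .scan import EncodedSNP

__all__ = [
    "classify_dominance",
    "transgressive_test",
    "allele_origin",
    "pve",
    "DOMINANCE_CLASSES",
]

DOMINANCE_CLASSES = (
    "underdominant",
    "recessive",
    "partially recessive",
    "additive",
    "partially dominant",
    "dominant",
    "overdominant",
)


def classify_dominance(a: float, d: float) -> tuple[float, str]:
    """d/|a| ratio and its dominance class.

    Bins: < -1.25 underdominant; [-1.25, -0.75] recessive (of the high
    allele); (-0.75, -0.25) partially recessive; [-0.25, 0.25] additive;
    (0.25, 0.75) partially dominant; [0.75, 1.25] dominant;
    > 1.25 overdominant.
    """
    if a == 0.0 and d == 0.0:
        return 0.0, "additive"
    if a == 0.0:
        warnings.warn("additive effect is zero; class from sign of d")
        ratio = np.inf if d > 0 else -np.inf
    else:
        ratio = d / abs(a)
    if ratio < -1.25:
        cls = "underdominant"
    elif ratio <= -0.75:
        cls = "recessive"
    elif ratio < -0.25:
        cls = "partially recessive"
    elif ratio <= 0.25:
        cls = "additive"
    elif ratio < 0.75:
        cls = "partially dominant"
    elif ratio <= 1.25:
        cls = "dominant"
    else:
        cls = "overdominant"
    return float(ratio), cls


def transgressive_test(y, genotypes, alpha: float = 0.05) -> str:
    """Welch-test screen for transgressive heterozygote phenotypes.

    ``genotypes`` are dosage calls in {0, 1, 2} (missing allowed).  Returns
    'low' if the heterozygote mean is significantly below both homozygote
    means (two Welch two-sample tests, each at ``alpha``), 'high' for the
    symmetric case, else 'none'.
    """
    y = np.asarray(y, dtype=float)
    genotypes = np.asarray(genotypes)
    groups = {}
    for code in (0, 1, 2):
        vals = y[genotypes == code]
        if len(vals) < 3:
            warnings.warn(f"genotype class {code} has < 3 individuals")
            return "none"
        groups[code] = vals
    het = groups[1]
    p_lo = stats.ttest_ind(het, groups[0], equal_var=False).pvalue
    p_hi = stats.ttest_ind(het, groups[2], equal_var=False).pvalue
    m_het, m0, m2 = het.mean(), groups[0].mean(), groups[2].mean()
    if p_lo < alpha and p_hi < alpha:
        if m_het < min(m0, m2):
            return "low"
        if m_het > max(m0, m2):
            return "high"
    return "none"


def allele_origin(marker_id: str, aims: pd.DataFrame, high_allele: str) -> str:
    """Subspecies origin of the high-abundance allele at an AIM.

    Non-AIM markers are 'uninformative'.
    """
    row = aims.loc[aims["marker_id"] == marker_id]
    if row.empty:
        return "uninformative"
    return "musculus" if high_allele == row["musculus_allele"].iloc[0] else "domesticus"


def high_allele(enc: EncodedSNP, a_hat: float) -> str:
    """Allele associated with higher trait values given the fitted sign of a.

    With Xa = +1 for major-allele homozygotes, a positive additive estimate
    points at the major allele.
    """
    return enc.major_allele if a_hat >= 0 else enc.minor_allele


def _drop_collinear(X: np.ndarray, names: list[str]):
    """Add columns left to right, dropping any that do not raise the rank."""
    keep_cols, keep_names = [], []
    cur = np.empty((X.shape[0], 0))
    for j, name in enumerate(names):
        cand = np.column_stack([cur, X[:, j]])
        if np.linalg.matrix_rank(cand) > cur.shape[1]:
            cur = cand
            keep_cols.append(j)
            keep_names.append(name)
        else:
            warnings.warn(f"dropping collinear column {name!r}")
    return cur, keep_names


def pve(
    y,
    markers: list[EncodedSNP],
    pedigree: pd.DataFrame,
    grm: GRM,
    mode: str = "peak-additive+dominance",
) -> float:
    """Marginal R2: variance explained by the SNP fixed effects.

    Fits an LMM with intercept plus the requested marker codings as fixed
    effects and mating pair + kinship as random effects, and returns

        Var(X beta) / (Var(X beta) + sum_k sigma2_k + sigma2_e)

    where the kinship component contributes sigma2_g times the mean GRM
    diagonal.  Modes: 'peak-additive+dominance' (single peak SNP),
    'all-additive', 'all-additive+dominance'.
    """
    if mode not in ("peak-additive+dominance", "all-additive",
                    "all-additive+dominance"):
        raise ValueError(f"unknown mode {mode!r}")
    y = np.asarray(y, dtype=float)
    n = len(y)
    with_dom = mode.endswith("additive+dominance")
    if mode.startswith("peak") and len(markers) != 1:
        raise ValueError("peak mode expects exactly one marker")
    cols, names = [], []
    for enc in markers:
        if not enc.mask.all():
            raise ValueError("pve requires complete genotypes for the markers")
        cols.append(enc.xa)
        names.append(f"{enc.marker_id}:a")
        if with_dom:
            cols.append(enc.xd)
            names.append(f"{enc.marker_id}:d")
    Xm = np.column_stack(cols)
    Xm, kept = _drop_collinear(Xm, names)
    X = np.column_stack([np.ones(n), Xm])
    ped = pedigree.set_index("individual").loc[list(grm.samples)]
    terms = [
        RandomTerm("mating_pair", kind="grouping",
                   labels=ped["mating_pair"].to_numpy()),
        RandomTerm("polygenic", kind="kernel", matrix=grm.matrix),
    ]
    fit = reml_fit(y, X, terms, method="reml")
    fixed_pred = Xm @ fit.beta[1:]
    var_f = float(np.var(fixed_pred, ddof=1)) if Xm.shape[1] else 0.0
    c = fit.variance_components
    var_rand = (
        c["mating_pair"]
        + c["polygenic"] * float(np.mean(np.diag(grm.matrix)))
        + c["residual"]
    )
    return float(var_f / (var_f + var_rand))
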