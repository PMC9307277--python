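"""Narrow-sense and chip heritability, and the cospeciation comparison.

Narrow-sense h2 is estimated from an LMM with the centred GRM as a genetic
kernel plus mating-pair-nested-within-subcross and subcross grouping terms:

    h2 = sigma2_g / (sigma2_g + sigma2_m + sigma2_s + sigma2_e)

Chip heritability (CH) uses the standardised GRM in the same model; it is
the fraction of phenotypic variance attributable to genotyped SNPs.
Significance of the genetic component comes from a restricted
likelihood-ratio test against a parametric-bootstrap null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .lmm import RandomTerm, reml_fit, rlrt_test
from .relatedness import GRM

__all__ = [
    "HeritabilityRecord",
    "estimate_h2",
    "estimate_chip_h2",
    "cospeciation_analysis",
]


@dataclass
class HeritabilityRecord:
    trait: str
    h2: float
    components: dict
    p_rlrt: float | None
    flavour: str  # 'narrow-sense' (centred GRM) or 'chip' (standardised)
    boundary: bool  # genetic component pinned at zero


def _pedigree_terms(pedigree: pd.DataFrame, samples) -> list[RandomTerm]:
    ped = pedigree.set_index("individual")
    missing = [s for s in samples if s not in ped.index]
    if missing:
        raise ValueError(f"pedigree labels missing for samples: {missing[:10]}")
    ped = ped.loc[list(samples)]
    if ped[["mating_pair", "subcross"]].isna().any().any():
        bad = ped.index[ped[["mating_pair", "subcross"]].isna().any(axis=1)]
        raise ValueError(f"pedigree labels missing for samples: {list(bad)[:10]}")
    pair_in_sub = (ped["subcross"].astype(str) + ":" + ped["mating_pair"].astype(str))
    return [
        RandomTerm("mating_pair", kind="grouping", labels=pair_in_sub.to_numpy()),
        RandomTerm("subcross", kind="grouping", labels=ped["subcross"].to_numpy()),
    ]


def _estimate(y, grm: GRM, pedigree, trait, flavour, n_sim, seed, rlrt):
    y = np.asarray(y, dtype=float)
    terms = [RandomTerm("genetic", kind="kernel", matrix=grm.matrix)]
    terms += _pedigree_terms(pedigree, grm.samples)
    X = np.ones((len(y), 1))
    fit = reml_fit(y, X, terms, method="reml")
    c = fit.variance_components
    total = c["genetic"] + c["mating_pair"] + c["subcross"] + c["residual"]
    h2 = c["genetic"] / total if total > 0 else 0.0
    boundary = "genetic" in fit.boundary
    p = None
    if rlrt:
        if boundary:
            p = 1.0  # component pinned at zero: statistic 0 by construction
        else:
            _, p = rlrt_test(
                y, X,
                tested_term=terms[0],
                nuisance_terms=terms[1:],
                n_sim=n_sim,
                seed=seed,
            )
    return HeritabilityRecord(
        trait=trait, h2=float(h2), components=dict(c), p_rlrt=p,
        flavour=flavour, boundary=boundary,
    )


def estimate_h2(
    y, grm_centred: GRM, pedigree: pd.DataFrame, trait: str = "trait",
    rlrt: bool = False, n_sim: int = 1000, seed: int = 0,
) -> HeritabilityRecord:
    """Narrow-sense heritability of one trait (centred GRM kernel)."""
    return _estimate(y, grm_centred, pedigree, trait, "narrow-sense",
                     n_sim, seed, rlrt)


def estimate_chip_h2(
    y, grm_standardised: GRM, pedigree: pd.DataFrame, trait: str = "trait",
    rlrt: bool = False, n_sim: int = 1000, seed: int = 0,
) -> HeritabilityRecord:
    """Chip heritability of one trait (standardised GRM kernel)."""
    return _estimate(y, grm_standardised, pedigree, trait, "chip",
                     n_sim, seed, rlrt)


def cospeciation_analysis(
    records: list[HeritabilityRecord] | pd.DataFrame,
    cospec: pd.DataFrame,
    abundances: pd.Series,
):
    """Spearman correlation of h2 with cospeciation rate, plus a joint OLS.

    ``records`` may be HeritabilityRecords for genus-level traits or a
    DataFrame with columns (genus, h2); ``cospec`` has columns
    (genus, rate); ``abundances`` maps genus -> median relative abundance.
    Genera are matched on exact name.  Returns (rho, p_spearman,
    regression table) where the table carries per-coefficient estimates and
    t-test p-values plus the overall F-test.
    """
    if isinstance(records, pd.DataFrame):
        h2 = records.set_index("genus")["h2"]
    else:
        h2 = pd.Series({r.trait: r.h2 for r in records})
    shared = h2.index.intersection(cospec["genus"])
    if len(shared) < 5:
        raise ValueError(f"only {len(shared)} shared genera (need >= 5)")
    rate = cospec.set_index("genus")["rate"].loc[shared]
    hh = h2.loc[shared]
    rho, p_s = stats.spearmanr(hh, rate)
    X = pd.DataFrame({"rate": rate, "abundance": abundances.loc[shared]})
    X.insert(0, "intercept", 1.0)
    ols = sm.OLS(hh.to_numpy(), X).fit()
    table = pd.DataFrame(
        {
            "term": list(X.columns),
            "estimate": ols.params.to_numpy(),
            "p_t": ols.pvalues.to_numpy(),
        }
    )
    table.attrs["r_squared"] = float(ols.rsquared)
    table.attrs["f_stat"] = float(ols.fvalue)
    table.attrs["p_f"] = float(ols.f_pvalue)
    table.attrs["df"] = (int(ols.df_model), int(ols.df_resid))
    return float(rho), float(p_s), table
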