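"""Forward simulation of a multi-line hybrid-zone intercross.

Emulates the study design the analysis modules assume: eight partially
inbred founder lines derived from two house-mouse subspecies pools
(*M. m. musculus* and *M. m. domesticus*), crossed in eight G1 pairings and
eight G2 sub-crosses so that every G2 individual carries one grandparent
from each of four breeding stocks.  Meiosis follows Haldane's model
(Poisson crossovers on the genetic map, no interference).

Abundance traits are generated on a latent log-abundance scale per taxon as

    latent = mu + a*Xa + d*Xd + mating-pair + subcross + polygenic + residual

with the polygenic term drawn from MVN(0, sigma_g^2 * GRM), then pushed
through a softmax across taxa and sampled multinomially at a fixed
sequencing depth, mimicking compositional 16S count profiles.  A
``TruthRecord`` keeps the latent values and generative parameters so
downstream estimators can be validated by parameter recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, validate_marker_map

__all__ = [
    "FounderSet",
    "CrossDesign",
    "TraitModel",
    "TruthRecord",
    "simulate_founders",
    "simulate_cross",
    "simulate_traits",
    "default_design",
    "split_seed",
]


def split_seed(seed: int, n: int) -> list[int]:
    """Derive n independent substream seeds (< 2**31) from one global seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


@dataclass
class FounderSet:
    """Founder lines as pairs of haplotypes over the marker map.

    ``haplotypes[line, hap, marker]`` holds 0/1 allele codes, where 1 is the
    allele tagged as *musculus* at subspecies-diagnostic markers.
    """

    line_ids: list[str]
    haplotypes: np.ndarray  # (n_lines, 2, n_markers) uint8
    subspecies_weights: np.ndarray  # expected musculus ancestry per line
    inbreeding: float
    diagnostic: np.ndarray  # bool mask over markers
    marker_map: pd.DataFrame

    def heterozygosity(self) -> np.ndarray:
        return (self.haplotypes[:, 0, :] != self.haplotypes[:, 1, :]).mean(axis=1)

    def realised_musculus_fraction(self) -> np.ndarray:
        """Fraction of musculus alleles per line at diagnostic markers."""
        if not self.diagnostic.any():
            raise ValueError("no diagnostic markers in founder set")
        return self.haplotypes[:, :, self.diagnostic].mean(axis=(1, 2))


@dataclass
class CrossDesign:
    """G1 pairings and G2 sub-crosses.

    ``g1_pairings``: list of (dam_line, sire_line) label pairs.
    ``g2_subcrosses``: list of dicts with keys ``dam_cross`` and
    ``sire_cross`` (indices into ``g1_pairings``), ``n_offspring`` and
    ``n_mating_pairs``.
    """

    g1_pairings: list[tuple[str, str]]
    g2_subcrosses: list[dict]


def default_design(n_offspring: int = 40, n_mating_pairs: int = 8) -> CrossDesign:
    """Eight G1 crosses, eight G2 sub-crosses x ``n_offspring`` males.

    Lines come two per breeding stock from four stocks (two predominantly
    *domesticus*: FS, HO; two predominantly *musculus*: HA, TU); each G1
    pairing mates one domesticus-like with one musculus-like line, and each
    sub-cross combines two G1 crosses covering all four stocks.
    """
    g1 = [
        ("FS1", "HA1"), ("HO1", "TU1"), ("FS2", "HA2"), ("HO2", "TU2"),
        ("HA1", "FS2"), ("TU1", "HO2"), ("HA2", "FS1"), ("TU2", "HO1"),
    ]
    # pair G1 crosses so the four grandparental stocks are all distinct
    subcross_pairs = [(0, 1), (2, 3), (4, 5), (6, 7), (1, 2), (3, 4), (5, 6), (7, 0)]
    g2 = [
        {
            "dam_cross": i,
            "sire_cross": j,
            "n_offspring": n_offspring,
            "n_mating_pairs": n_mating_pairs,
        }
        for i, j in subcross_pairs
    ]
    return CrossDesign(g1_pairings=g1, g2_subcrosses=g2)


def default_line_weights(line_ids) -> np.ndarray:
    """Domesticus-like stocks (FS, HO) get musculus weight 0.1; HA/TU 0.9."""
    return np.array(
        [0.1 if lid[:2] in ("FS", "HO") else 0.9 for lid in line_ids]
    )


def simulate_founders(
    marker_map: pd.DataFrame,
    n_lines: int = 8,
    subspecies_weights=None,
    diagnostic_fraction: float = 0.3,
    inbreeding: float = 0.85,
    seed: int = 0,
    line_ids: list[str] | None = None,
    ancestry_block_cm: float = 10.0,
) -> FounderSet:
    """Draw founder-line haplotypes as subspecies-background mosaics.

    A ``diagnostic_fraction`` of markers is fixed between subspecies pools
    (allele 1 in *musculus*, 0 in *domesticus*); the rest segregate at a
    shared frequency in both pools.  Each haplotype is a mosaic of ancestry
    blocks (mean length ``ancestry_block_cm``) that are *musculus* with the
    line's ``subspecies_weight``.  The second haplotype copies the first at
    a fraction ``inbreeding`` of markers (identity by descent).
    """
    validate_marker_map(marker_map)
    if not 0.0 <= diagnostic_fraction <= 1.0:
        raise ValueError("diagnostic_fraction must be in [0, 1]")
    if not 0.0 <= inbreeding <= 1.0:
        raise ValueError("inbreeding must be in [0, 1]")
    if line_ids is None:
        if n_lines == 8:  # match the default cross design's line labels
            line_ids = ["FS1", "FS2", "HO1", "HO2", "HA1", "HA2", "TU1", "TU2"]
        else:
            line_ids = [f"L{i + 1}" for i in range(n_lines)]
    if subspecies_weights is None:
        subspecies_weights = default_line_weights(line_ids)
    subspecies_weights = np.asarray(subspecies_weights, dtype=float)
    if subspecies_weights.shape != (n_lines,):
        raise ValueError("subspecies_weights must have length n_lines")

    rng = np.random.default_rng(seed)
    p = len(marker_map)
    n_diag = int(round(diagnostic_fraction * p))
    diag_idx = rng.choice(p, size=n_diag, replace=False)
    diagnostic = np.zeros(p, dtype=bool)
    diagnostic[diag_idx] = True
    shared_freq = rng.uniform(0.1, 0.9, size=p)  # non-diagnostic markers

    chrom = marker_map["chromosome"].to_numpy()
    cm = marker_map["genetic_pos_cM"].to_numpy(dtype=float)

    def mosaic_ancestry(w: float) -> np.ndarray:
        """Per-marker musculus/domesticus indicator with block structure.

        Block boundaries follow exponential lengths (mean
        ``ancestry_block_cm``); block states are assigned by stratified
        sampling so the realised musculus fraction tracks ``w`` tightly.
        """
        block_of = np.empty(p, dtype=np.int64)
        n_blocks = 0
        for c in np.unique(chrom):
            m = chrom == c
            pos = cm[m]
            ids = np.empty(m.sum(), dtype=np.int64)
            ids[0] = n_blocks
            gaps = np.diff(pos)
            switch = rng.random(gaps.size) < 1 - np.exp(-gaps / ancestry_block_cm)
            for i, sw in enumerate(switch):
                if sw:
                    n_blocks += 1
                ids[i + 1] = n_blocks
            block_of[m] = ids
            n_blocks += 1
        # marker-weighted stratification: fill a random block order with
        # musculus states until the marker fraction reaches w (the realised
        # fraction then deviates by at most one block)
        sizes = np.bincount(block_of, minlength=n_blocks)
        states = np.zeros(n_blocks, dtype=np.uint8)
        target = w * p
        filled = 0
        for b in rng.permutation(n_blocks):
            if filled + sizes[b] <= target:
                states[b] = 1
                filled += sizes[b]
        remainder = target - filled
        free = np.flatnonzero(states == 0)
        if remainder > 0 and free.size:
            b = free[np.argmin(np.abs(sizes[free] - remainder))]
            if abs(sizes[b] - remainder) < remainder:
                states[b] = 1
        return states[block_of]

    haps = np.empty((n_lines, 2, p), dtype=np.uint8)
    for li, w in enumerate(subspecies_weights):
        h1_anc = mosaic_ancestry(w)
        h1 = np.where(
            diagnostic, h1_anc, (rng.random(p) < shared_freq).astype(np.uint8)
        )
        h2_anc = mosaic_ancestry(w)
        h2_new = np.where(
            diagnostic, h2_anc, (rng.random(p) < shared_freq).astype(np.uint8)
        )
        ibd = rng.random(p) < inbreeding
        h2 = np.where(ibd, h1, h2_new)
        haps[li, 0] = h1
        haps[li, 1] = h2

    return FounderSet(
        line_ids=list(line_ids),
        haplotypes=haps,
        subspecies_weights=subspecies_weights,
        inbreeding=inbreeding,
        diagnostic=diagnostic,
        marker_map=marker_map.reset_index(drop=True),
    )


def _gamete(hap_pair: np.ndarray, chrom: np.ndarray, cm: np.ndarray, rng) -> np.ndarray:
    """One recombinant gamete from a haplotype pair (Haldane model).

    Crossover count per chromosome is Poisson(L/100 Morgans) with uniform
    positions; the starting phase is random, so transmission is fair.
    """
    gam = np.empty(hap_pair.shape[1], dtype=np.uint8)
    for c in np.unique(chrom):
        m = chrom == c
        pos = cm[m]
        length = pos[-1] - pos[0]
        n_co = rng.poisson(length / 100.0)
        phase = rng.integers(2)
        if n_co == 0:
            gam[m] = hap_pair[phase, m]
            continue
        xovers = np.sort(rng.uniform(pos[0], pos[-1], size=n_co))
        # phase at each marker = initial phase + #crossovers before it
        flips = np.searchsorted(xovers, pos, side="left")
        ph = (phase + flips) % 2
        sub = hap_pair[:, m]
        gam[m] = sub[ph, np.arange(m.sum())]
    return gam


def simulate_cross(
    founders: FounderSet,
    design: CrossDesign,
    marker_map: pd.DataFrame | None = None,
    seed: int = 0,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate G1 and G2 generations, returning G2 genotypes + pedigree.

    Each sub-cross draws ``n_mating_pairs`` G1 dam/sire pairs (fresh meioses
    from the founder lines of the referenced G1 pairings) and distributes
    offspring across pairs as evenly as possible.  The pedigree records
    individual, subcross, mating_pair, dam and sire labels.
    """
    if marker_map is None:
        marker_map = founders.marker_map
    validate_marker_map(marker_map)
    chrom = marker_map["chromosome"].to_numpy()
    cm = marker_map["genetic_pos_cM"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    line_index = {lid: i for i, lid in enumerate(founders.line_ids)}
    for dam_line, sire_line in design.g1_pairings:
        for lid in (dam_line, sire_line):
            if lid not in line_index:
                raise ValueError(f"G1 pairing references unknown line {lid!r}")

    def g1_individual(pairing_idx: int) -> np.ndarray:
        dam_line, sire_line = design.g1_pairings[pairing_idx]
        h_dam = _gamete(founders.haplotypes[line_index[dam_line]], chrom, cm, rng)
        h_sire = _gamete(founders.haplotypes[line_index[sire_line]], chrom, cm, rng)
        return np.stack([h_dam, h_sire])

    calls, rows = [], []
    counter = 0
    for sc_i, sc in enumerate(design.g2_subcrosses):
        label = f"SC{sc_i + 1}"
        n_off = sc["n_offspring"]
        n_pairs = min(sc.get("n_mating_pairs", 1), n_off)
        # offspring split across mating pairs as evenly as possible
        per_pair = [n_off // n_pairs + (1 if k < n_off % n_pairs else 0)
                    for k in range(n_pairs)]
        for pair_k, n_kids in enumerate(per_pair):
            dam = g1_individual(sc["dam_cross"])
            sire = g1_individual(sc["sire_cross"])
            pair_label = f"{label}_P{pair_k + 1}"
            dam_id = f"{pair_label}_dam"
            sire_id = f"{pair_label}_sire"
            for _ in range(n_kids):
                counter += 1
                gd = _gamete(dam, chrom, cm, rng)
                gs = _gamete(sire, chrom, cm, rng)
                calls.append((gd + gs).astype(np.int8))
                rows.append(
                    {
                        "individual": f"G2_{counter:04d}",
                        "subcross": label,
                        "mating_pair": pair_label,
                        "dam": dam_id,
                        "sire": sire_id,
                    }
                )
    pedigree = pd.DataFrame(rows)
    geno = GenotypeMatrix(
        calls=np.asarray(calls, dtype=np.int8),
        samples=pedigree["individual"].tolist(),
        marker_map=marker_map,
        alleles=pd.DataFrame(
            {"counted": ["M"] * len(marker_map), "other": ["D"] * len(marker_map)}
        ),
    )
    return geno, pedigree


@dataclass
class TraitModel:
    """Generative parameters for latent abundance traits."""

    n_taxa: int
    causal_snps: list[tuple[str, int, float, float]] = field(default_factory=list)
    # (marker_id, taxon index, additive effect a, dominance effect d)
    sigma2_g: float = 0.0
    sigma2_m: float = 0.0
    sigma2_s: float = 0.0
    sigma2_e: float = 1.0
    baseline_log_abundances: np.ndarray | None = None
    sequencing_depth: int = 10_000

    def __post_init__(self):
        for name in ("sigma2_g", "sigma2_m", "sigma2_s", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.baseline_log_abundances is None:
            self.baseline_log_abundances = np.zeros(self.n_taxa)
        self.baseline_log_abundances = np.asarray(
            self.baseline_log_abundances, dtype=float
        )
        if self.baseline_log_abundances.shape != (self.n_taxa,):
            raise ValueError("baseline_log_abundances must have length n_taxa")

    @property
    def true_h2(self) -> float:
        tot = self.sigma2_g + self.sigma2_m + self.sigma2_s + self.sigma2_e
        return self.sigma2_g / tot if tot > 0 else 0.0


@dataclass
class TruthRecord:
    """Generative truth for parameter-recovery tests."""

    h2: np.ndarray  # per taxon (latent scale)
    causal_effects: pd.DataFrame  # marker, taxon, a, d, d_over_abs_a
    polygenic: np.ndarray  # (n_samples, n_taxa)
    latent: np.ndarray  # (n_samples, n_taxa) latent trait values


def simulate_traits(
    genotypes: GenotypeMatrix,
    pedigree: pd.DataFrame,
    grm,
    model: TraitModel,
    seed: int = 0,
):
    """Simulate taxon counts with additive/dominance/polygenic structure.

    Returns ``(AbundanceTable, TruthRecord)``.  Counts per sample sum
    exactly to ``model.sequencing_depth``.
    """
    from .traits import AbundanceTable  # local import avoids a cycle

    rng = np.random.default_rng(seed)
    n = genotypes.n_samples
    K = np.asarray(grm.matrix if hasattr(grm, "matrix") else grm, dtype=float)
    if K.shape != (n, n):
        raise ValueError("GRM dimension does not match genotypes")
    vals, vecs = np.linalg.eigh(K)
    if vals.min() < -1e-8:
        raise ValueError(
            f"GRM is not positive semidefinite (eigenvalue {vals.min():.3e})"
        )
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))

    for marker_id, taxon, _a, _d in model.causal_snps:
        genotypes.marker_index(marker_id)  # raises if absent
        if not 0 <= taxon < model.n_taxa:
            raise ValueError(f"causal taxon index {taxon} out of range")

    pair_codes, pair_uniques = pd.factorize(pedigree["mating_pair"])
    sub_codes, sub_uniques = pd.factorize(pedigree["subcross"])

    latent = np.tile(model.baseline_log_abundances, (n, 1))
    for marker_id, taxon, a, d in model.causal_snps:
        g = genotypes.calls[:, genotypes.marker_index(marker_id)].astype(float)
        g[g == MISSING] = 1.0  # midpoint for the rare missing call
        xa = g - 1.0  # counted-allele homozygote = +1
        xd = (g == 1.0).astype(float)
        latent[:, taxon] += a * xa + d * xd

    polygenic = np.zeros((n, model.n_taxa))
    for t in range(model.n_taxa):
        if model.sigma2_g > 0:
            polygenic[:, t] = np.sqrt(model.sigma2_g) * (
                root @ rng.standard_normal(n)
            )
        if model.sigma2_m > 0:
            eff = rng.normal(0, np.sqrt(model.sigma2_m), size=len(pair_uniques))
            latent[:, t] += eff[pair_codes]
        if model.sigma2_s > 0:
            eff = rng.normal(0, np.sqrt(model.sigma2_s), size=len(sub_uniques))
            latent[:, t] += eff[sub_codes]
        if model.sigma2_e > 0:
            latent[:, t] += rng.normal(0, np.sqrt(model.sigma2_e), size=n)
    latent = latent + polygenic

    # softmax composition per sample, multinomial counts at fixed depth
    shifted = latent - latent.max(axis=1, keepdims=True)
    probs = np.exp(shifted)
    probs /= probs.sum(axis=1, keepdims=True)
    counts = np.empty((model.n_taxa, n), dtype=np.int64)
    for i in range(n):
        counts[:, i] = rng.multinomial(model.sequencing_depth, probs[i])

    taxa = [f"taxon_{t + 1}" for t in range(model.n_taxa)]
    table = AbundanceTable(
        counts=pd.DataFrame(counts, index=taxa, columns=genotypes.samples),
        ranks=pd.Series(["genus"] * model.n_taxa, index=taxa),
        level="DNA",
    )
    effects = pd.DataFrame(
        [
            {
                "marker_id": m,
                "taxon": taxa[t],
                "a": a,
                "d": d,
                "d_over_abs_a": d / abs(a) if a != 0 else np.nan,
            }
            for m, t, a, d in model.causal_snps
        ],
        columns=["marker_id", "taxon", "a", "d", "d_over_abs_a"],
    )
    truth = TruthRecord(
        h2=np.full(model.n_taxa, model.true_h2),
        causal_effects=effects,
        polygenic=polygenic,
        latent=latent,
    )
    return table, truth
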