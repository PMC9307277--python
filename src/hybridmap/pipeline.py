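"""End-to-end orchestration: simulate -> qc -> grm -> traits -> heritability
-> association scan -> architecture -> regions.

All stage parameters live in a flat config mapping with defaults matching
the analysis conventions used throughout the package (QC thresholds, core
rules, 10,000-read rarefaction, LD and region cutoffs).  All randomness
derives from the single config seed via per-stage substreams, so re-running
with the same config reproduces outputs bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .architecture import classify_dominance, pve
from .genotypes import uniform_marker_map
from .heritability import estimate_chip_h2, estimate_h2
from .qc import ld_prune, qc_filter
from .regions import assign_genes, expand_region, merge_regions, read_bed, \
    regions_to_frame
from .relatedness import grm_centred, grm_standardised, loco_grms
from .scan import annotate_significance, effective_tests, encode_genotypes, \
    genomic_control, scan_trait, thresholds
from .simulate import TraitModel, default_design, simulate_cross, \
    simulate_founders, simulate_traits, split_seed
from .traits import core_filter, rarefy, transform_traits

log = logging.getLogger("hybridmap")

DEFAULT_CONFIG = {
    "seed": 1,
    "simulate": True,
    # simulator scale (demo-sized; the study design is 19 chromosomes,
    # 8 subcrosses x 40 males)
    "n_chromosomes": 5,
    "markers_per_chromosome": 400,
    "n_offspring": 20,
    "n_taxa": 20,
    "sequencing_depth": 10_000,
    "diagnostic_fraction": 0.3,
    "inbreeding": 0.85,
    "sigma2_g": 1.0,
    "sigma2_m": 0.2,
    "sigma2_s": 0.1,
    "sigma2_e": 1.0,
    "n_causal": 4,
    "causal_a": 1.0,
    "causal_d": 0.0,
    # QC (array-QC defaults)
    "ind_call_rate": 0.90,
    "snp_missing": 0.10,
    "maf": 0.05,
    "hwe_p": 1e-10,
    "ld_window": 5,
    "ld_step": 1,
    "ld_r2_max": 0.9,
    # traits
    "rarefaction_depth": 10_000,
    # heritability
    "herit_rlrt": False,
    "rlrt_sims": 200,
    "max_traits": None,
    # scan
    "scan_mode": "approximate",
    "alpha": 0.05,
    # regions
    "region_r2": 0.9,
    "region_merge_gap_bp": 10_000_000,
    "annotation_bed": None,
    # optional external inputs (used when simulate is false)
    "genotypes_prefix": None,
    "pedigree": None,
    "abundance": None,
}


def load_config(path=None, **overrides) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        import yaml

        user = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    cfg.update({k: v for k, v in overrides.items() if v is not None})
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(cfg: dict, outdir) -> Path:
    """Run every stage and write deterministic artifacts to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = split_seed(int(cfg["seed"]), 8)

    # --- inputs: simulate or load -----------------------------------------
    if cfg["simulate"]:
        marker_map = uniform_marker_map(
            n_chromosomes=cfg["n_chromosomes"],
            markers_per_chromosome=cfg["markers_per_chromosome"],
        )
        founders = simulate_founders(
            marker_map,
            diagnostic_fraction=cfg["diagnostic_fraction"],
            inbreeding=cfg["inbreeding"],
            seed=seeds[0],
        )
        design = default_design(n_offspring=cfg["n_offspring"])
        geno, pedigree = simulate_cross(founders, design, seed=seeds[1])
        grm_sim = grm_centred(geno)
        rng = np.random.default_rng(seeds[2])
        poly = [
            geno.marker_map["marker_id"].iloc[j]
            for j in np.flatnonzero(geno.maf() > 0.2)
        ]
        causal = [
            (poly[int(k)], int(t), cfg["causal_a"], cfg["causal_d"])
            for t, k in enumerate(
                rng.choice(len(poly), size=min(cfg["n_causal"], len(poly)),
                           replace=False)
            )
        ]
        model = TraitModel(
            n_taxa=cfg["n_taxa"],
            causal_snps=causal,
            sigma2_g=cfg["sigma2_g"], sigma2_m=cfg["sigma2_m"],
            sigma2_s=cfg["sigma2_s"], sigma2_e=cfg["sigma2_e"],
            sequencing_depth=cfg["sequencing_depth"],
        )
        table, truth = simulate_traits(geno, pedigree, grm_sim, model,
                                       seed=seeds[3])
        hio.write_ped_map(geno, outdir / "genotypes", pedigree)
        hio.write_pedigree(pedigree, outdir / "pedigree.tsv")
        hio.write_abundance(table, outdir / "abundance.tsv")
        hio.write_truth(truth, outdir / "truth.json")
    else:
        if not cfg["genotypes_prefix"]:
            raise FileNotFoundError("genotypes_prefix required when simulate=false")
        for key in ("pedigree", "abundance"):
            if not cfg[key] or not Path(cfg[key]).exists():
                raise FileNotFoundError(f"missing input file for {key!r}: {cfg[key]}")
        geno = hio.read_ped_map(cfg["genotypes_prefix"])
        pedigree = hio.read_pedigree(cfg["pedigree"])
        table = hio.read_abundance(cfg["abundance"])
    log.info("inputs: %d individuals x %d markers, %d taxa",
             geno.n_samples, geno.n_markers, table.n_taxa)

    # --- QC + LD pruning ---------------------------------------------------
    qc_geno, report = qc_filter(
        geno, ind_call_rate=cfg["ind_call_rate"], snp_missing=cfg["snp_missing"],
        maf=cfg["maf"], hwe_p=cfg["hwe_p"],
    )
    report.to_frame().to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
    kept = ld_prune(qc_geno, window=cfg["ld_window"], step=cfg["ld_step"],
                    r2_max=cfg["ld_r2_max"])
    pruned = qc_geno.subset(
        marker_idx=[qc_geno.marker_index(m) for m in kept]
    )
    pd.Series(kept, name="marker_id").to_csv(
        outdir / "retained_markers.tsv", sep="\t", index=False
    )
    log.info("QC: %d markers kept, %d after LD pruning",
             qc_geno.n_markers, pruned.n_markers)

    # --- GRMs --------------------------------------------------------------
    k_centred = grm_centred(pruned)
    k_std = grm_standardised(pruned)
    loco = loco_grms(pruned, flavour="centred")
    hio.write_grm(k_centred, outdir / "grm_centred")
    hio.write_grm(k_std, outdir / "grm_standardised")

    # --- traits ------------------------------------------------------------
    rare = rarefy(table, depth=cfg["rarefaction_depth"], seed=seeds[4])
    rare = type(rare)(
        counts=rare.counts[[s for s in pruned.samples if s in rare.counts]],
        ranks=rare.ranks, level=rare.level,
    )
    core = core_filter(rare)
    traits = transform_traits(rare, core)
    traits.values.to_csv(outdir / "traits.tsv", sep="\t")
    sample_order = [s for s in pruned.samples if s in traits.values.index]
    sample_idx = [pruned.samples.index(s) for s in sample_order]
    pruned = pruned.subset(sample_idx=sample_idx)
    k_centred = grm_centred(pruned)
    k_std = grm_standardised(pruned)
    loco = loco_grms(pruned, flavour="centred")
    Y = traits.values.loc[sample_order]
    trait_names = list(Y.columns)
    if cfg["max_traits"]:
        trait_names = trait_names[: int(cfg["max_traits"])]

    # --- heritability ------------------------------------------------------
    hrows = []
    for name in trait_names:
        y = Y[name].to_numpy(dtype=float)
        rec = estimate_h2(y, k_centred, pedigree, trait=name,
                          rlrt=cfg["herit_rlrt"], n_sim=cfg["rlrt_sims"],
                          seed=seeds[5])
        chip = estimate_chip_h2(y, k_std, pedigree, trait=name, rlrt=False)
        hrows.append(
            {
                "trait": name, "h2": rec.h2, "p_h2": rec.p_rlrt,
                "chip_h2": chip.h2,
                **{f"sigma2_{k}": v for k, v in rec.components.items()},
            }
        )
    herit = pd.DataFrame(hrows)
    herit.to_csv(outdir / "heritability.tsv", sep="\t", index=False)

    # --- association scan --------------------------------------------------
    meff = effective_tests(Y[trait_names])
    gw, sw = thresholds(pruned.n_markers, meff, alpha=cfg["alpha"])
    lambdas = {}
    scans = []
    for name in trait_names:
        res = scan_trait(Y[name].to_numpy(dtype=float), pruned, pedigree,
                         loco, mode=cfg["scan_mode"], trait=name)
        lam, adj = genomic_control(res["p_total"].to_numpy())
        res["p_adjusted"] = adj
        lambdas[name] = lam
        res = annotate_significance(res, gw, sw)
        res.to_csv(outdir / f"scan_{name}.tsv", sep="\t", index=False)
        scans.append(res)
    scan_all = pd.concat(scans, ignore_index=True)
    run_meta = {
        "lambda_gc": lambdas,
        "meff": meff,
        "genome_wide_threshold": gw,
        "study_wide_threshold": sw,
        "n_markers": pruned.n_markers,
    }
    (outdir / "scan_run.json").write_text(json.dumps(run_meta, indent=1))

    # --- architecture ------------------------------------------------------
    arows = []
    sig = scan_all[scan_all["study_wide"]]
    for _, r in sig.iterrows():
        ratio, cls = classify_dominance(r["a"], r["d"])
        enc = encode_genotypes(pruned, r["marker_id"])
        effect = pve(
            Y[r["trait"]].to_numpy(dtype=float), [enc], pedigree, k_centred,
            mode="peak-additive+dominance",
        )
        arows.append(
            {
                "trait": r["trait"], "marker_id": r["marker_id"],
                "a": r["a"], "d": r["d"], "d_over_abs_a": ratio,
                "class": cls, "pve_peak": effect,
            }
        )
    arch = pd.DataFrame(
        arows, columns=["trait", "marker_id", "a", "d", "d_over_abs_a",
                        "class", "pve_peak"]
    )
    arch.to_csv(outdir / "architecture.tsv", sep="\t", index=False)

    # --- regions -----------------------------------------------------------
    regions = [
        expand_region(m, qc_geno, r2_min=cfg["region_r2"],
                      taxa=set(sig.loc[sig["marker_id"] == m, "trait"]))
        for m in sig["marker_id"].unique()
    ]
    merged = merge_regions(regions, max_gap_bp=cfg["region_merge_gap_bp"])
    if cfg["annotation_bed"]:
        merged = assign_genes(merged, read_bed(cfg["annotation_bed"]))
    regions_to_frame(merged).to_csv(outdir / "regions.tsv", sep="\t", index=False)

    manifest = {
        "seed": cfg["seed"],
        "config_hash": config_hash(cfg),
        "config": {k: str(v) for k, v in cfg.items()},
        "n_individuals": pruned.n_samples,
        "n_markers": pruned.n_markers,
        "n_traits": len(trait_names),
        "n_study_wide_hits": int(sig.shape[0]),
        "n_regions": len(merged),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir
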