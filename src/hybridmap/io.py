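"""Readers and writers for the pipeline's plain-text interchange formats.

Genotypes: PLINK-style .ped/.map text and minimal VCF (GT field, via
cyvcf2).  Pedigree and abundance tables are TSV; GRMs are TSV matrices with
a JSON side-car recording flavour, marker count and any excluded
chromosome; simulation truth is JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, validate_marker_map
from .relatedness import GRM

__all__ = [
    "write_ped_map", "read_ped_map", "read_vcf",
    "write_pedigree", "read_pedigree",
    "write_abundance", "read_abundance",
    "write_grm", "read_grm",
    "write_truth",
]


def write_ped_map(g: GenotypeMatrix, prefix, pedigree: pd.DataFrame | None = None):
    """Write PLINK text .ped/.map; allele codes from the alleles table."""
    prefix = Path(prefix)
    mp = g.marker_map
    with open(prefix.with_suffix(".map"), "w") as fh:
        for _, r in mp.iterrows():
            fh.write(
                f"{r['chromosome']}\t{r['marker_id']}\t"
                f"{r['genetic_pos_cM']:.6f}\t{int(r['position_bp'])}\n"
            )
    ped_info = None
    if pedigree is not None:
        ped_info = pedigree.set_index("individual")
    counted = g.alleles["counted"].to_numpy()
    other = g.alleles["other"].to_numpy()
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, sample in enumerate(g.samples):
            fam, pat, mat = sample, "0", "0"
            if ped_info is not None and sample in ped_info.index:
                fam = str(ped_info.loc[sample, "subcross"])
                pat = str(ped_info.loc[sample, "sire"])
                mat = str(ped_info.loc[sample, "dam"])
            fields = [fam, sample, pat, mat, "1", "-9"]
            calls = g.calls[i]
            for j, c in enumerate(calls):
                if c == MISSING:
                    fields += ["0", "0"]
                else:
                    fields += [counted[j]] * c + [other[j]] * (2 - c)
            fh.write(" ".join(map(str, fields)) + "\n")


def read_ped_map(prefix) -> GenotypeMatrix:
    """Read PLINK text .ped/.map.

    The counted allele per marker is the first allele label observed in the
    file (orientation is recorded; re-orient with ``to_minor_allele``).
    """
    prefix = Path(prefix)
    mp = pd.read_csv(
        prefix.with_suffix(".map"), sep=r"\s+", header=None,
        names=["chromosome", "marker_id", "genetic_pos_cM", "position_bp"],
    )[["marker_id", "chromosome", "position_bp", "genetic_pos_cM"]]
    validate_marker_map(mp)
    p = len(mp)
    samples, rows = [], []
    allele_pairs = [[None, None] for _ in range(p)]
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            samples.append(parts[1])
            al = parts[6:]
            if len(al) != 2 * p:
                raise ValueError(
                    f"ped line for {parts[1]} has {len(al)} alleles, expected {2 * p}"
                )
            row = np.empty(p, dtype=np.int8)
            for j in range(p):
                a, b = al[2 * j], al[2 * j + 1]
                if a == "0" or b == "0":
                    row[j] = MISSING
                    continue
                pair = allele_pairs[j]
                for x in (a, b):
                    if x not in pair:
                        if pair[0] is None:
                            pair[0] = x
                        elif pair[1] is None:
                            pair[1] = x
                        else:
                            raise ValueError(
                                f"marker {mp['marker_id'].iloc[j]} is not biallelic"
                            )
                row[j] = (a == pair[0]) + (b == pair[0])
            rows.append(row)
    alleles = pd.DataFrame(
        {
            "counted": [pr[0] if pr[0] is not None else "A" for pr in allele_pairs],
            "other": [pr[1] if pr[1] is not None else "B" for pr in allele_pairs],
        }
    )
    return GenotypeMatrix(
        calls=np.asarray(rows, dtype=np.int8), samples=samples,
        marker_map=mp, alleles=alleles,
    )


def read_vcf(path) -> GenotypeMatrix:
    """Minimal VCF reader (GT only) via cyvcf2; counts the ALT allele."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, mrows, arows = [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue  # biallelic only
        gt = var.gt_types  # cyvcf2: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        dos = np.where(gt == 2, MISSING, np.where(gt == 3, 2, gt)).astype(np.int8)
        rows.append(dos)
        mrows.append((var.ID or f"{var.CHROM}:{var.POS}", var.CHROM, var.POS,
                      var.POS / 1e6))
        arows.append((var.ALT[0], var.REF))
    mp = pd.DataFrame(
        mrows, columns=["marker_id", "chromosome", "position_bp", "genetic_pos_cM"]
    )
    alleles = pd.DataFrame(arows, columns=["counted", "other"])
    return GenotypeMatrix(
        calls=np.asarray(rows, dtype=np.int8).T, samples=samples,
        marker_map=mp, alleles=alleles,
    )


def write_pedigree(pedigree: pd.DataFrame, path):
    pedigree.to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> pd.DataFrame:
    ped = pd.read_csv(path, sep="\t", dtype=str)
    required = {"individual", "subcross", "mating_pair", "dam", "sire"}
    missing = required - set(ped.columns)
    if missing:
        raise ValueError(f"pedigree file missing columns: {sorted(missing)}")
    return ped


def write_abundance(table, path):
    df = table.counts.copy()
    df.insert(0, "rank", table.ranks.to_numpy())
    df.index.name = "taxon"
    df.to_csv(path, sep="\t")


def read_abundance(path, level: str = "DNA", default_rank: str = "ASV"):
    """Taxon-by-sample TSV with a ``rank`` column; BIOM-style TSV (leading
    comment line, no rank column) is accepted with ``default_rank``."""
    from .traits import AbundanceTable

    with open(path) as fh:
        first = fh.readline()
    skip = 1 if first.startswith("# ") else 0  # BIOM "# Constructed from..." line
    df = pd.read_csv(path, sep="\t", index_col=0, skiprows=skip)
    if "rank" in df.columns:
        ranks = df.pop("rank")
    else:
        ranks = pd.Series(default_rank, index=df.index)
    df.index.name = ranks.index.name = None
    return AbundanceTable(counts=df.astype(np.int64), ranks=ranks, level=level)


def write_grm(grm: GRM, prefix):
    prefix = Path(prefix)
    pd.DataFrame(grm.matrix, index=grm.samples, columns=grm.samples).to_csv(
        str(prefix) + ".tsv", sep="\t"
    )
    meta = {
        "flavour": grm.flavour,
        "n_markers": grm.n_markers,
        "excluded_chromosome": (
            None if grm.excluded_chromosome is None else str(grm.excluded_chromosome)
        ),
    }
    Path(str(prefix) + ".json").write_text(json.dumps(meta, indent=1))


def read_grm(prefix) -> GRM:
    prefix = Path(prefix)
    df = pd.read_csv(str(prefix) + ".tsv", sep="\t", index_col=0)
    meta = json.loads(Path(str(prefix) + ".json").read_text())
    return GRM(
        matrix=df.to_numpy(dtype=float),
        flavour=meta["flavour"],
        samples=list(df.index.astype(str)),
        n_markers=int(meta["n_markers"]),
        excluded_chromosome=meta["excluded_chromosome"],
    )


def write_truth(truth, path):
    payload = {
        "h2": np.asarray(truth.h2).tolist(),
        "causal_effects": truth.causal_effects.to_dict(orient="records"),
        "polygenic": np.asarray(truth.polygenic).tolist(),
    }
    Path(path).write_text(json.dumps(payload))
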