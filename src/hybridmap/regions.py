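"""LD-defined significant regions, gene assignment and permutation tests.

Coordinates are 1-based inclusive throughout; BED input is converted from
0-based half-open at the boundary.  A significant LD-pruned SNP is expanded
to the interval spanned by the most distant same-chromosome markers in the
full (pre-pruning) genotype set with r^2 above a threshold; intervals
closer than a gap cutoff are merged transitively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "SignificantRegion",
    "expand_region",
    "merge_regions",
    "assign_genes",
    "nearest_genes",
    "overlap_permutation",
    "geneset_enrichment",
    "read_bed",
    "regions_to_frame",
]


@dataclass
class SignificantRegion:
    chromosome: object
    start_bp: int
    end_bp: int
    markers: list = field(default_factory=list)
    taxa: set = field(default_factory=set)
    genes: list = field(default_factory=list)

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValueError("region start after end")

    @property
    def length(self) -> int:
        return self.end_bp - self.start_bp + 1


def expand_region(
    sig_marker: str,
    full_genotypes: GenotypeMatrix,
    r2_min: float = 0.9,
    taxa=(),
) -> SignificantRegion:
    """LD interval of a significant SNP in the pre-pruning genotype set.

    Spans from the most distant upstream to the most distant downstream
    same-chromosome marker with r^2 > ``r2_min`` to the index SNP; a marker
    with no LD partners yields a 1-bp interval at its own position.
    """
    g = full_genotypes
    j = g.marker_index(sig_marker)
    chrom = g.marker_map["chromosome"].iloc[j]
    cols = np.flatnonzero((g.marker_map["chromosome"] == chrom).to_numpy())
    x = g.calls[:, j]
    partners = [j]
    for k in cols:
        if k == j:
            continue
        xi, xk = x, g.calls[:, k]
        ok = (xi != MISSING) & (xk != MISSING)
        if ok.sum() < 2:
            continue
        a, b = xi[ok].astype(float), xk[ok].astype(float)
        if a.var() == 0 or b.var() == 0:
            continue
        r = np.corrcoef(a, b)[0, 1]
        if r * r > r2_min:
            partners.append(k)
    pos = g.marker_map["position_bp"].iloc[partners]
    return SignificantRegion(
        chromosome=chrom,
        start_bp=int(pos.min()),
        end_bp=int(pos.max()),
        markers=[sig_marker],
        taxa=set(taxa),
    )


def merge_regions(
    intervals: list[SignificantRegion], max_gap_bp: int = 10_000_000
) -> list[SignificantRegion]:
    """Transitively merge same-chromosome intervals closer than the gap.

    The gap between [s1, e1] and [s2, e2] (s2 > e1) is s2 - e1 - 1 bases;
    merging applies when gap < ``max_gap_bp`` (strict).  Member markers and
    taxa are unioned.  Idempotent and input-order independent.
    """
    if not intervals:
        return []
    ordered = sorted(intervals, key=lambda r: (str(r.chromosome), r.start_bp, r.end_bp))
    out = []
    cur = None
    for r in ordered:
        if (
            cur is not None
            and r.chromosome == cur.chromosome
            and r.start_bp - cur.end_bp - 1 < max_gap_bp
        ):
            cur = SignificantRegion(
                chromosome=cur.chromosome,
                start_bp=cur.start_bp,
                end_bp=max(cur.end_bp, r.end_bp),
                markers=sorted(set(cur.markers) | set(r.markers)),
                taxa=cur.taxa | r.taxa,
                genes=sorted(set(cur.genes) | set(r.genes)),
            )
        else:
            if cur is not None:
                out.append(cur)
            cur = r
    out.append(cur)
    return out


def read_bed(path) -> pd.DataFrame:
    """BED (0-based half-open) -> 1-based inclusive annotation table."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chromosome", "start_bp", "end_bp", "gene_id", "score", "strand"]
    df.columns = cols[: df.shape[1]]
    df["start_bp"] = df["start_bp"].astype(int) + 1
    df["end_bp"] = df["end_bp"].astype(int)
    if "gene_id" not in df:
        df["gene_id"] = [f"feature_{i}" for i in range(len(df))]
    if "strand" not in df:
        df["strand"] = "."
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids in annotation")
    return df[["gene_id", "chromosome", "start_bp", "end_bp", "strand"]]


def assign_genes(
    regions: list[SignificantRegion], annotation: pd.DataFrame
) -> list[SignificantRegion]:
    """Attach genes overlapping each region (1-based inclusive overlap)."""
    if len(annotation) and len(regions):
        region_chroms = {str(r.chromosome) for r in regions}
        ann_chroms = set(annotation["chromosome"].astype(str))
        unmatched = region_chroms - ann_chroms
        if unmatched and not ann_chroms & region_chroms:
            raise ValueError(f"annotation contigs do not match regions: {sorted(unmatched)}")
    for r in regions:
        sub = annotation[annotation["chromosome"].astype(str) == str(r.chromosome)]
        hit = sub[(sub["start_bp"] <= r.end_bp) & (sub["end_bp"] >= r.start_bp)]
        r.genes = hit["gene_id"].tolist()
    return regions


def nearest_genes(chromosome, position_bp: int, annotation: pd.DataFrame) -> list[str]:
    """Up to two genes flanking (or containing) a SNP position.

    Returns the nearest gene upstream and the nearest downstream; a gene
    containing the SNP counts once, paired with the next nearest gene on
    the other side.
    """
    sub = annotation[annotation["chromosome"].astype(str) == str(chromosome)]
    if sub.empty:
        return []
    inside = sub[(sub["start_bp"] <= position_bp) & (sub["end_bp"] >= position_bp)]
    if not inside.empty:
        containing = inside.iloc[0]["gene_id"]
        rest = sub[sub["gene_id"] != containing]
        if rest.empty:
            return [containing]
        dist = np.minimum(
            np.abs(rest["start_bp"] - position_bp),
            np.abs(rest["end_bp"] - position_bp),
        )
        return [containing, rest.loc[dist.idxmin(), "gene_id"]]
    up = sub[sub["end_bp"] < position_bp]
    down = sub[sub["start_bp"] > position_bp]
    out = []
    if not up.empty:
        out.append(up.loc[(position_bp - up["end_bp"]).idxmin(), "gene_id"])
    if not down.empty:
        out.append(down.loc[(down["start_bp"] - position_bp).idxmin(), "gene_id"])
    return out


def _to_interval_frame(intervals) -> pd.DataFrame:
    if isinstance(intervals, pd.DataFrame):
        return intervals[["chromosome", "start_bp", "end_bp"]].copy()
    return pd.DataFrame(
        [
            {"chromosome": r.chromosome, "start_bp": r.start_bp, "end_bp": r.end_bp}
            for r in intervals
        ],
        columns=["chromosome", "start_bp", "end_bp"],
    )


def _count_overlaps(a: pd.DataFrame, b: pd.DataFrame) -> int:
    count = 0
    for chrom, sa in a.groupby("chromosome"):
        sb = b[b["chromosome"] == chrom]
        if sb.empty:
            continue
        s1 = sa["start_bp"].to_numpy()[:, None]
        e1 = sa["end_bp"].to_numpy()[:, None]
        s2 = sb["start_bp"].to_numpy()[None, :]
        e2 = sb["end_bp"].to_numpy()[None, :]
        count += int(((s1 <= e2) & (e1 >= s2)).sum())
    return count


def overlap_permutation(
    set_a,
    set_b,
    genome: dict,
    n_perm: int = 10_000,
    seed: int = 0,
    max_region_bp: int | None = None,
) -> tuple[int, float, float]:
    """Permutation test for interval-set overlap enrichment.

    Observed statistic: number of (a, b) interval pairs that overlap.  The
    null places each ``set_a`` interval uniformly at random within its own
    chromosome (lengths preserved); p = (1 + #{perm >= obs}) / (n_perm + 1).
    For cross-study comparisons pass ``max_region_bp=10_000_000`` to drop
    oversized intervals from both sets first, the usual convention.
    Returns (observed, permuted mean, p).
    """
    a = _to_interval_frame(set_a)
    b = _to_interval_frame(set_b)
    if max_region_bp is not None:
        a = a[(a["end_bp"] - a["start_bp"] + 1) <= max_region_bp]
        b = b[(b["end_bp"] - b["start_bp"] + 1) <= max_region_bp]
    if a.empty:
        return 0, 0.0, 1.0
    lengths = (a["end_bp"] - a["start_bp"] + 1).to_numpy()
    chroms = a["chromosome"].to_numpy()
    for chrom, ln in zip(chroms, lengths):
        if chrom not in genome:
            raise ValueError(f"chromosome {chrom!r} absent from genome table")
        if ln > genome[chrom]:
            raise ValueError(f"interval longer than chromosome {chrom!r}")
    observed = _count_overlaps(a, b)
    rng = np.random.default_rng(seed)
    perm_counts = np.empty(n_perm, dtype=np.int64)
    chrom_len = np.array([genome[c] for c in chroms], dtype=np.int64)
    for t in range(n_perm):
        starts = rng.integers(1, chrom_len - lengths + 2)
        perm = pd.DataFrame(
            {
                "chromosome": chroms,
                "start_bp": starts,
                "end_bp": starts + lengths - 1,
            }
        )
        perm_counts[t] = _count_overlaps(perm, b)
    p = (1.0 + np.sum(perm_counts >= observed)) / (n_perm + 1.0)
    return observed, float(perm_counts.mean()), float(p)


def geneset_enrichment(
    hit_genes,
    gene_set,
    universe,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[int, float, float, float]:
    """Permutation + Fisher tests for gene-set overrepresentation.

    Draws |hit| genes uniformly from the universe ``n_perm`` times;
    enrichment p = (1 + #{perm >= observed}) / (n_perm + 1).  Returns
    (observed overlap, permuted mean, p_perm, p_fisher).
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("empty gene universe")
    uni = set(universe)
    hits = set(hit_genes)
    gset = set(gene_set)
    if not hits <= uni or not gset <= uni:
        raise ValueError("hit_genes and gene_set must be subsets of the universe")
    observed = len(hits & gset)
    rng = np.random.default_rng(seed)
    uni_arr = np.array(universe)
    in_set = np.isin(uni_arr, list(gset))
    k = len(hits)
    perm = np.empty(n_perm, dtype=np.int64)
    for t in range(n_perm):
        idx = rng.choice(len(uni_arr), size=k, replace=False)
        perm[t] = int(in_set[idx].sum())
    p_perm = (1.0 + np.sum(perm >= observed)) / (n_perm + 1.0)
    table = [
        [observed, k - observed],
        [len(gset) - observed, len(uni) - len(gset) - k + observed],
    ]
    _, p_fisher = stats.fisher_exact(table, alternative="greater")
    return observed, float(perm.mean()), float(p_perm), float(p_fisher)


def regions_to_frame(regions: list[SignificantRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chromosome": r.chromosome,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "length_bp": r.length,
                "markers": ",".join(map(str, r.markers)),
                "taxa": ",".join(sorted(map(str, r.taxa))),
                "genes": ",".join(map(str, r.genes)),
            }
            for r in regions
        ]
    )
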