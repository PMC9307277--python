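import numpy as np
import pandas as pd
import pytest

from hybridmap.genotypes import GenotypeMatrix, uniform_marker_map
from hybridmap.relatedness import grm_centred, loco_grms
from hybridmap.simulate import default_design, simulate_cross, simulate_founders


@pytest.fixture(scope="session")
def cohort_small():
    """80 G2s over 5 chromosomes x 40 markers (fast unit-test cohort)."""
    mm = uniform_marker_map(n_chromosomes=5, markers_per_chromosome=40)
    founders = simulate_founders(mm, seed=11)
    geno, ped = simulate_cross(founders, default_design(n_offspring=10), seed=12)
    return geno, ped


@pytest.fixture(scope="session")
def cohort320():
    """Study-scale cohort: 8 subcrosses x 40 males, 10 chromosomes x 200 markers."""
    mm = uniform_marker_map(n_chromosomes=10, markers_per_chromosome=200)
    founders = simulate_founders(mm, seed=101)
    geno, ped = simulate_cross(founders, default_design(n_offspring=40), seed=102)
    return geno, ped


@pytest.fixture(scope="session")
def founders320():
    mm = uniform_marker_map(n_chromosomes=10, markers_per_chromosome=200)
    return simulate_founders(mm, seed=101)


@pytest.fixture(scope="session")
def grm320(cohort320):
    geno, _ = cohort320
    return grm_centred(geno)


@pytest.fixture(scope="session")
def grm_root320(grm320):
    vals, vecs = np.linalg.eigh(grm320.matrix)
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


@pytest.fixture(scope="session")
def loco320(cohort320):
    geno, _ = cohort320
    return loco_grms(geno, flavour="centred")


def make_genotypes(calls, chrom=None, positions=None, counted=None, other=None):
    """Small hand-built GenotypeMatrix for targeted tests."""
    calls = np.asarray(calls, dtype=np.int8)
    n, p = calls.shape
    chrom = [1] * p if chrom is None else list(chrom)
    if positions is None:
        positions = []
        seen = {}
        for c in chrom:
            seen[c] = seen.get(c, 0) + 1
            positions.append(seen[c] * 1000)
    mp = pd.DataFrame(
        {
            "marker_id": [f"snp{j + 1}" for j in range(p)],
            "chromosome": chrom,
            "position_bp": positions,
            "genetic_pos_cM": [pos / 1e6 for pos in positions],
        }
    )
    alleles = pd.DataFrame(
        {
            "counted": counted if counted is not None else ["A"] * p,
            "other": other if other is not None else ["G"] * p,
        }
    )
    return GenotypeMatrix(
        calls=calls, samples=[f"ind{i + 1}" for i in range(n)],
        marker_map=mp, alleles=alleles,
    )
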