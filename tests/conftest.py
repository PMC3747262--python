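import numpy as np
import pandas as pd
import pytest

import tilemeth as tm


@pytest.fixture(scope="session")
def two_locus_loci():
    return (
        tm.LocusSpec("L1", "chr1", 0, 30_000),
        tm.LocusSpec("L2", "chr2", 100_000, 30_000),
    )


@pytest.fixture(scope="session")
def null_spec(two_locus_loci):
    """Study-sized cohort (8 vs 12, triplicates) with no planted regions."""
    return tm.SimulationSpec(loci=two_locus_loci, cell_types=("T_cell",), seed=11)


@pytest.fixture(scope="session")
def planted_spec(two_locus_loci):
    """One upward and one downward 1000-bp DMR plus a linked phenotype."""
    return tm.SimulationSpec(
        loci=two_locus_loci,
        planted_dmrs=(
            tm.PlantedDMR("L1", 5_000, 6_000, 1.0, "up1"),
            tm.PlantedDMR("L2", 110_000, 111_000, -1.0, "dn1"),
        ),
        phenotype_links=(tm.PhenotypeLink("up1", "IL6", slope=1.0, intercept=10.0, noise_sd=0.05),),
        cell_types=("T_cell",),
        seed=17,
    )


@pytest.fixture(scope="session")
def planted_cohort(planted_spec):
    intensities, sheet, truth = tm.simulate_cohort(planted_spec)
    return intensities, sheet, truth


@pytest.fixture(scope="session")
def planted_matrix(planted_cohort):
    intensities, sheet, truth = planted_cohort
    matrix = tm.normalize_study(intensities, sheet, "T_cell")
    return matrix, sheet, truth


@pytest.fixture()
def tiny_design():
    return tm.simulate_design([("L1", "chr1", 0, 3000)], 100)


@pytest.fixture()
def toy_genes():
    return pd.DataFrame(
        {
            "gene_id": ["GENE1"],
            "chrom": ["chr1"],
            "tss": [10_000],
            "strand": ["+"],
            "tes": [20_000],
        }
    )


def brute_force_rank_sum(region_scores, background_scores):
    """Exhaustive enumeration oracle for the rank-sum region test.

    Enumerates every same-size subset of pooled positions, computes midrank
    sums, and returns (p_up, p_down) inclusive of the observed statistic.
    """
    from itertools import combinations

    from scipy.stats import rankdata

    pooled = np.concatenate([region_scores, background_scores])
    ranks = rankdata(pooled, method="average")
    m = len(region_scores)
    observed = ranks[:m].sum()
    sums = [sum(ranks[list(c)]) for c in combinations(range(len(pooled)), m)]
    sums = np.asarray(sums)
    eps = 1e-9
    p_up = np.mean(sums >= observed - eps)
    p_down = np.mean(sums <= observed + eps)
    return float(p_up), float(p_down)


def brute_force_bh(p_values):
    """Reference Benjamini-Hochberg step-up q-values (quadratic loop)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    q = np.empty(m)
    for i, pi in enumerate(p):
        candidates = []
        for j, pj in enumerate(p):
            if pj >= pi - 1e-15:
                rank_j = np.sum(p <= pj + 1e-15)
                candidates.append(m * pj / rank_j)
        q[i] = min(1.0, min(candidates))
    return q
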