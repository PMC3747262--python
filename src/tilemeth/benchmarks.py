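"""Repeated-simulation operating characteristics of the calling pipeline.

These helpers measure, over many seeded synthetic studies, the quantities a
methodologist cares about: the false-discovery proportion under a complete
null, and the sensitivity and direction accuracy for planted ~1000-bp
regions at the study's sample sizes (8 vs 12 subjects, 3 replicate arrays,
100-bp probe spacing).  Replicated runs use two 30-kb loci per study, which
keeps 50-fold replication cheap while preserving the region/background
geometry of the locus-wide design.
"""

from __future__ import annotations

import numpy as np

from .normalize import normalize_study
from .probestats import GroupDesign
from .regions import CallingThresholds, run_contrast_pipeline, run_correlation_pipeline
from .simulate import (
    LocusSpec,
    PhenotypeLink,
    PlantedDMR,
    SimulationSpec,
    simulate_cohort,
    simulate_phenotype,
)


def bench_loci() -> tuple[LocusSpec, ...]:
    """Two 30-kb loci: the replicated-simulation problem size."""
    return (
        LocusSpec("L1", "chr1", 0, 30_000),
        LocusSpec("L2", "chr2", 100_000, 30_000),
    )


def _sub_seed(seed: int, index: int) -> int:
    return (1009 * int(seed) + index) % (2**31 - 1)


def _run_one(spec: SimulationSpec, thresholds: CallingThresholds):
    intensities, sheet, truth = simulate_cohort(spec)
    matrix = normalize_study(intensities, sheet, spec.cell_types[0])
    design = GroupDesign.from_sample_sheet(sheet)
    calls = run_contrast_pipeline(matrix, design, truth.design, thresholds)
    return calls, matrix, truth


def null_calibration(
    n_sims: int = 50, seed: int = 0, thresholds: CallingThresholds | None = None
) -> dict:
    """False-discovery proportion of the full pipeline under a complete null.

    Every call on null data is false, so the per-study FDP is 1 when
    anything is called and 0 otherwise; the mean over studies estimates the
    realized FDR of the combined probe/region rule.
    """
    thresholds = thresholds or CallingThresholds()
    fdps, n_called = [], []
    for i in range(n_sims):
        spec = SimulationSpec(loci=bench_loci(), cell_types=("T_cell",), seed=_sub_seed(seed, i))
        calls, _, _ = _run_one(spec, thresholds)
        n = int(calls["called"].sum())
        n_called.append(n)
        fdps.append(1.0 if n > 0 else 0.0)
    return {
        "n_sims": n_sims,
        "mean_fdp": float(np.mean(fdps)),
        "total_false_calls": int(np.sum(n_called)),
        "n_regions_per_sim": int(calls["testable"].sum()),
    }


def dmr_recovery(
    n_sims: int = 50,
    seed: int = 0,
    effect: float = 1.0,
    thresholds: CallingThresholds | None = None,
) -> dict:
    """Sensitivity for planted 1000-bp regions of |log2 effect| = ``effect``.

    Each study plants one upward and one downward region; a planted region
    counts as recovered only when its window is called with the correct
    direction.
    """
    thresholds = thresholds or CallingThresholds()
    hits = direction_ok = 0
    for i in range(n_sims):
        spec = SimulationSpec(
            loci=bench_loci(),
            planted_dmrs=(
                PlantedDMR("L1", 5_000, 6_000, abs(effect), "up1"),
                PlantedDMR("L2", 110_000, 111_000, -abs(effect), "dn1"),
            ),
            cell_types=("T_cell",),
            seed=_sub_seed(seed, i),
        )
        calls, _, _ = _run_one(spec, thresholds)
        calls = calls.set_index("region_id")
        for rid, want in (("L1_r0005", "higher_in_A"), ("L2_r0010", "higher_in_B")):
            if calls.loc[rid, "called"]:
                hits += 1
                direction_ok += calls.loc[rid, "direction"] == want
    total = 2 * n_sims
    return {
        "n_sims": n_sims,
        "sensitivity": direction_ok / total,
        "called_any_direction": hits / total,
        "direction_accuracy": (direction_ok / hits) if hits else float("nan"),
    }


def correlation_recovery(
    n_sims: int = 50,
    seed: int = 0,
    slope: float = 1.0,
    noise_sd: float = 0.05,
    thresholds: CallingThresholds | None = None,
) -> dict:
    """Recovery of a phenotype-linked planted region by the correlation arm."""
    thresholds = thresholds or CallingThresholds()
    hits = 0
    for i in range(n_sims):
        spec = SimulationSpec(
            loci=bench_loci(),
            planted_dmrs=(PlantedDMR("L1", 5_000, 6_000, 1.0, "up1"),),
            phenotype_links=(
                PhenotypeLink("up1", "IL6", slope=slope, intercept=10.0, noise_sd=noise_sd),
            ),
            cell_types=("T_cell",),
            seed=_sub_seed(seed, i),
        )
        intensities, sheet, truth = simulate_cohort(spec)
        matrix = normalize_study(intensities, sheet, "T_cell")
        phenotype = simulate_phenotype(truth)
        calls = run_correlation_pipeline(matrix, phenotype, "IL6", truth.design, thresholds)
        calls = calls.set_index("region_id")
        hits += bool(calls.loc["L1_r0005", "called"] and calls.loc["L1_r0005", "direction"] == "positive")
    return {"n_sims": n_sims, "recovery_rate": hits / n_sims}
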