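"""Region-level DMR calling.

Loci are partitioned into fixed, disjoint windows (default 1000 bp) anchored
at the first tiled position of each locus.  Each testable window is scored by
Wilcoxon rank-sum enrichment of its probe statistics (moderated t for the
group contrast, Pearson r for the phenotype arm) against background probes,
two one-sided tests combined as p = min(1, 2 * min(p_up, p_down)) to retain a
direction per region.  Benjamini-Hochberg FDR is applied across all testable
regions jointly, and a region is called only if, in addition to the FDR
threshold, it contains at least one individually significant probe whose
effect sign agrees with the region's direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DomainError
from .probestats import GroupDesign, moderated_t, probe_phenotype_correlation

__all__ = [
    "CallingThresholds",
    "partition_regions",
    "region_rank_sum",
    "bh_fdr",
    "call_regions",
    "run_contrast_pipeline",
    "run_correlation_pipeline",
]


@dataclass(frozen=True)
class CallingThresholds:
    """Dual probe/region calling thresholds.

    Defaults: a probe counts as significant at p <= 0.05 with |log2-fold
    change| >= 0.25 (or |r| >= 0.5 for the correlation arm); a region is
    called at BH-FDR <= 0.2 over 1000-bp windows with at least 3 probes.
    """

    probe_p_max: float = 0.05
    probe_lfc_min: float = 0.25
    probe_r_min: float = 0.5
    region_fdr_max: float = 0.2
    region_width: int = 1000
    min_probes_per_region: int = 3
    background: str = "locus"  # or "array"
    exact_limit: int = 25  # exact rank-sum enumeration up to this many probes

    def __post_init__(self) -> None:
        if not (0 <= self.probe_p_max <= 1 and 0 <= self.region_fdr_max <= 1):
            raise DomainError("probability thresholds must lie in [0, 1]")
        if self.probe_lfc_min < 0 or not (0 <= self.probe_r_min <= 1):
            raise DomainError("effect-size thresholds out of range")
        if self.region_width <= 0 or self.min_probes_per_region < 1:
            raise DomainError("region width and probe minimum must be positive")
        if self.background not in ("locus", "array"):
            raise DomainError(f"unknown background {self.background!r}")


def partition_regions(
    design: pd.DataFrame, width: int = 1000, min_probes: int = 3
) -> tuple[pd.DataFrame, pd.Series]:
    """Fixed-width disjoint windows per locus, anchored at the first probe start.

    The last window of a locus is truncated at the end of the tiled span.
    Probes are assigned by start coordinate.  Returns (regions, assignment)
    where ``assignment`` maps probe_id to region_id.  Regions with fewer
    than ``min_probes`` probes are marked untestable.
    """
    if width <= 0:
        raise DomainError("region width must be positive")
    design = design.sort_values(["chrom", "start", "probe_id"], kind="mergesort")
    region_rows = []
    assign: dict[str, str] = {}
    for locus_id, sub in design.groupby("locus_id", sort=True):
        lo = int(sub["start"].min())
        hi = int(sub["end"].max())
        idx = ((sub["start"] - lo) // width).astype(int)
        for k, probes in sub.groupby(idx, sort=True):
            region_id = f"{locus_id}_r{int(k):04d}"
            start = lo + int(k) * width
            end = min(start + width, hi)
            region_rows.append(
                {
                    "region_id": region_id,
                    "chrom": probes["chrom"].iloc[0],
                    "start": start,
                    "end": end,
                    "locus_id": locus_id,
                    "n_probes": len(probes),
                    "testable": len(probes) >= min_probes,
                }
            )
            for pid in probes["probe_id"]:
                assign[pid] = region_id
    regions = pd.DataFrame(region_rows)
    assignment = pd.Series(assign, name="region_id")
    assignment.index.name = "probe_id"
    return regions, assignment


def _exact_rank_sum_p(ranks2: np.ndarray, in_region: np.ndarray) -> tuple[float, float]:
    """Exact one-sided rank-sum p-values by subset enumeration (counting DP).

    ``ranks2`` are doubled midranks (integers); the permutation null draws
    the region's positions uniformly among all same-size subsets.  Returns
    (p_up, p_down), both inclusive of the observed statistic.
    """
    m = int(in_region.sum())
    w_obs = int(ranks2[in_region].sum())
    order = np.sort(ranks2)[::-1]
    s_max = int(order[:m].sum())
    # dp[k, s]: number of size-k subsets with doubled-rank sum s
    dp = np.zeros((m + 1, s_max + 1), dtype=np.int64)
    dp[0, 0] = 1
    for val in ranks2:
        v = int(val)
        for k in range(m, 0, -1):
            dp[k, v:] += dp[k - 1, : s_max + 1 - v]
    total = dp[m].sum()
    counts = dp[m]
    p_up = counts[w_obs:].sum() / total
    p_down = counts[: w_obs + 1].sum() / total
    return float(p_up), float(p_down)


def _normal_rank_sum_p(ranks: np.ndarray, in_region: np.ndarray) -> tuple[float, float]:
    """Normal approximation with tie correction and 0.5 continuity correction."""
    n_total = len(ranks)
    m = int(in_region.sum())
    n_bg = n_total - m
    w = float(ranks[in_region].sum())
    mean = m * (n_total + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3) - tie_counts).sum())
    var = m * n_bg / 12.0 * ((n_total + 1) - tie_term / (n_total * (n_total - 1)))
    if var <= 0:
        return 1.0, 1.0
    sd = math.sqrt(var)
    p_up = stats.norm.sf((w - mean - 0.5) / sd)
    p_down = stats.norm.cdf((w - mean + 0.5) / sd)
    return float(p_up), float(p_down)


def region_rank_sum(
    region_scores, background_scores, exact_limit: int = 25
) -> tuple[float, str]:
    """Two-sided-by-doubling Wilcoxon rank-sum test of region vs background scores.

    Midranks handle ties.  The exact permutation null is enumerated whenever
    region + background holds at most ``exact_limit`` probes; otherwise a
    normal approximation with tie correction and continuity correction is
    used.  Returns (p_region, direction) with direction 'up' when the region
    scores are shifted upward relative to the background.
    """
    region_scores = np.asarray(region_scores, dtype=float)
    background_scores = np.asarray(background_scores, dtype=float)
    if len(region_scores) == 0 or len(background_scores) == 0:
        raise DomainError("region and background score sets must be non-empty")
    pooled = np.concatenate([region_scores, background_scores])
    in_region = np.zeros(len(pooled), dtype=bool)
    in_region[: len(region_scores)] = True
    ranks = stats.rankdata(pooled, method="average")
    if len(pooled) <= exact_limit:
        ranks2 = np.round(2.0 * ranks).astype(np.int64)
        p_up, p_down = _exact_rank_sum_p(ranks2, in_region)
    else:
        p_up, p_down = _normal_rank_sum_p(ranks, in_region)
    p_region = min(1.0, 2.0 * min(p_up, p_down))
    direction = "up" if p_up <= p_down else "down"
    return p_region, direction


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


_DIRECTION_NAMES = {
    "group_contrast": {"up": "higher_in_A", "down": "higher_in_B"},
    "phenotype_correlation": {"up": "positive", "down": "negative"},
}


def call_regions(
    probe_stats: pd.DataFrame,
    regions: pd.DataFrame,
    assignment: pd.Series,
    thresholds: CallingThresholds | None = None,
    kind: str = "group_contrast",
) -> pd.DataFrame:
    """Score every testable region and emit directional calls.

    ``probe_stats`` must carry per-probe columns (probe_id, t_mod, p_t, lfc)
    for the group contrast or (probe_id, r, p_r) for the correlation arm.
    The FDR family is all testable regions jointly; a called region needs
    q <= region_fdr_max plus at least one in-region probe that individually
    passes the probe thresholds with a sign matching the region direction.
    """
    if thresholds is None:
        thresholds = CallingThresholds()
    if kind not in _DIRECTION_NAMES:
        raise DomainError(f"unknown statistic kind {kind!r}")
    score_col, p_col, effect_col, effect_min = (
        ("t_mod", "p_t", "lfc", thresholds.probe_lfc_min)
        if kind == "group_contrast"
        else ("r", "p_r", "r", thresholds.probe_r_min)
    )
    stats_idx = probe_stats.set_index("probe_id")
    missing = [p for p in assignment.index if p not in stats_idx.index]
    if missing:
        raise DomainError(f"probe statistics missing for probes {missing[:5]}")
    joined = stats_idx.loc[assignment.index].assign(region_id=assignment.to_numpy())
    joined = joined.join(regions.set_index("region_id")["locus_id"], on="region_id")
    valid = joined[np.isfinite(joined[score_col])]

    testable_ids = set(regions.loc[regions["testable"], "region_id"])
    if not testable_ids:
        raise DomainError("no testable regions")

    by_region = dict(tuple(valid.groupby("region_id", sort=False)))
    empty = valid.iloc[0:0]

    rows = []
    for region in regions.itertuples(index=False):
        rid = region.region_id
        in_region = by_region.get(rid, empty)
        testable = rid in testable_ids and len(in_region) >= thresholds.min_probes_per_region
        row = {
            "region_id": rid,
            "chrom": region.chrom,
            "start": region.start,
            "end": region.end,
            "locus_id": region.locus_id,
            "statistic_kind": kind,
            "n_probes": region.n_probes,
            "testable": testable,
            "p_region": np.nan,
            "q_region": np.nan,
            "direction": "",
            "n_sig_probes": 0,
            "mean_effect": float(in_region[effect_col].mean()) if len(in_region) else np.nan,
            "called": False,
        }
        if testable:
            region_scores = in_region[score_col].to_numpy()
            # background: every other scored probe of the same locus (default)
            # or of the whole array
            mask = np.ones(len(valid), dtype=bool) if thresholds.background == "array" else (
                valid["locus_id"] == region.locus_id
            ).to_numpy()
            mask &= (valid["region_id"] != rid).to_numpy()
            background = valid.loc[mask, score_col].to_numpy()
            if len(background) == 0:
                row["testable"] = False
            else:
                p_region, direction = region_rank_sum(
                    region_scores, background, exact_limit=thresholds.exact_limit
                )
                row["p_region"] = p_region
                row["direction"] = _DIRECTION_NAMES[kind][direction]
                sign = 1.0 if direction == "up" else -1.0
                sig = (
                    (in_region[p_col] <= thresholds.probe_p_max)
                    & (in_region[effect_col].abs() >= effect_min)
                    & (np.sign(in_region[effect_col]) == sign)
                )
                row["n_sig_probes"] = int(sig.sum())
        rows.append(row)
    calls = pd.DataFrame(rows)
    testable_mask = calls["testable"].to_numpy()
    if testable_mask.any():
        calls.loc[testable_mask, "q_region"] = bh_fdr(calls.loc[testable_mask, "p_region"])
    calls["called"] = (
        testable_mask
        & (calls["q_region"] <= thresholds.region_fdr_max)
        & (calls["n_sig_probes"] >= 1)
    )
    effect_name = "mean_lfc" if kind == "group_contrast" else "mean_r"
    return calls.rename(columns={"mean_effect": effect_name})


def run_contrast_pipeline(
    matrix: pd.DataFrame,
    group_design: GroupDesign,
    design: pd.DataFrame,
    thresholds: CallingThresholds | None = None,
) -> pd.DataFrame:
    """Moderated t per probe, then region partition, rank-sum scoring and calls."""
    if thresholds is None:
        thresholds = CallingThresholds()
    stats_table, _ = moderated_t(matrix, group_design)
    regions, assignment = partition_regions(
        design, thresholds.region_width, thresholds.min_probes_per_region
    )
    return call_regions(stats_table, regions, assignment, thresholds, kind="group_contrast")


def run_correlation_pipeline(
    matrix: pd.DataFrame,
    phenotype: pd.DataFrame,
    analyte: str,
    design: pd.DataFrame,
    thresholds: CallingThresholds | None = None,
) -> pd.DataFrame:
    """Probe-phenotype Pearson correlations, then region-level calls."""
    if thresholds is None:
        thresholds = CallingThresholds()
    corr_table = probe_phenotype_correlation(matrix, phenotype, analyte)
    regions, assignment = partition_regions(
        design, thresholds.region_width, thresholds.min_probes_per_region
    )
    calls = call_regions(corr_table, regions, assignment, thresholds, kind="phenotype_correlation")
    calls.insert(6, "analyte", analyte)
    return calls
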