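"""Per-probe inference: moderated t-statistics and phenotype correlations.

The group contrast uses the empirical-Bayes moderated t-statistic: each
probe's pooled within-group variance s^2 (df residual degrees of freedom) is
shrunk toward a prior variance s0^2 with prior degrees of freedom d0,

    s_tilde^2 = (d0 * s0^2 + df * s^2) / (d0 + df),
    t_mod     = (mean_A - mean_B) / (s_tilde * sqrt(1/nA + 1/nB)),

with two-sided p-values from a t distribution on d0 + df degrees of freedom
(standard normal when d0 is infinite).  The hyperparameters (d0, s0^2) are
fitted across all probes by matching the mean and spread of log s^2 to their
digamma/trigamma expectations under a scaled-F marginal for s^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import DomainError

__all__ = [
    "GroupDesign",
    "EBHyper",
    "fit_eb_hyperparameters",
    "moderated_t",
    "probe_phenotype_correlation",
]


@dataclass(frozen=True)
class GroupDesign:
    """Subject-to-group assignment for a two-group contrast (A vs B)."""

    groups: tuple[tuple[str, str], ...]  # (subject_id, 'A'|'B')

    @classmethod
    def from_sample_sheet(cls, sheet: pd.DataFrame) -> "GroupDesign":
        sub = sheet.drop_duplicates("subject_id")
        return cls(groups=tuple(zip(sub["subject_id"], sub["group"])))

    @classmethod
    def from_mapping(cls, mapping) -> "GroupDesign":
        return cls(groups=tuple(mapping.items()))

    def labels(self, subjects) -> np.ndarray:
        lookup = dict(self.groups)
        missing = [s for s in subjects if s not in lookup]
        if missing:
            raise DomainError(f"subjects without group assignment: {missing[:5]}")
        labels = np.array([lookup[s] for s in subjects])
        if not set(labels) <= {"A", "B"}:
            raise DomainError("group labels must be 'A' or 'B'")
        return labels


@dataclass(frozen=True)
class EBHyper:
    """Prior degrees of freedom and prior variance of the variance model."""

    d0: float  # may be math.inf
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0 or self.s0_sq <= 0:
            raise DomainError("d0 must be >= 0 and s0_sq > 0")


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise DomainError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < tol * x:
            break
    return float(x)


def fit_eb_hyperparameters(residual_variances, df_per_probe: int) -> EBHyper:
    """Method-of-moments fit of (d0, s0^2) from per-probe pooled variances.

    Matches the mean and excess spread of log s^2 against digamma/trigamma
    expressions.  When the observed spread of log s^2 does not exceed its
    pure-sampling expectation, there is no evidence of variance
    heterogeneity: d0 is infinite and s0^2 is the geometric mean of the
    observed variances (so posterior variances equal the common variance
    when all inputs coincide).
    """
    s2 = np.asarray(residual_variances, dtype=float)
    s2 = s2[np.isfinite(s2)]
    if (s2 < 0).any():
        raise DomainError("negative residual variance")
    if (s2 == 0).all() or len(s2) == 0:
        raise DomainError("all residual variances are zero: degenerate input")
    positive = s2[s2 > 0]
    if len(positive) < 2:
        raise DomainError("need at least 2 probes with positive variance")
    if df_per_probe < 1:
        raise DomainError("df per probe must be >= 1")
    df = float(df_per_probe)
    z = np.log(positive)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return EBHyper(d0=math.inf, s0_sq=float(np.exp(np.mean(z))))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_sq = math.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    return EBHyper(d0=d0, s0_sq=s0_sq)


def moderated_t(
    matrix: pd.DataFrame, design: GroupDesign, eb: EBHyper | None = None
) -> tuple[pd.DataFrame, EBHyper]:
    """Moderated two-sample t-statistics for every probe of a methylation matrix.

    ``matrix`` is probes x subjects.  ``eb`` overrides the fitted
    hyperparameters (d0 = 0 recovers the ordinary pooled t).  Returns
    (table, hyperparameters) where the table has columns probe_id, lfc, s2,
    t_mod, p_t.
    """
    labels = design.labels(matrix.columns)
    a = matrix.loc[:, labels == "A"].to_numpy(dtype=float)
    b = matrix.loc[:, labels == "B"].to_numpy(dtype=float)
    n_a, n_b = a.shape[1], b.shape[1]
    if n_a < 2 or n_b < 2:
        raise DomainError(f"each group needs >= 2 subjects (got {n_a} and {n_b})")
    df = n_a + n_b - 2
    lfc = a.mean(axis=1) - b.mean(axis=1)
    ss = a.var(axis=1, ddof=1) * (n_a - 1) + b.var(axis=1, ddof=1) * (n_b - 1)
    s2 = ss / df
    if eb is None:
        eb = fit_eb_hyperparameters(s2, df)
    if math.isinf(eb.d0):
        s2_post = np.full_like(s2, eb.s0_sq)
        df_total = np.inf
    else:
        s2_post = (eb.d0 * eb.s0_sq + df * s2) / (eb.d0 + df)
        df_total = eb.d0 + df
    denom = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(denom > 0, lfc / denom, 0.0)
    p_t = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    table = pd.DataFrame(
        {"probe_id": matrix.index, "lfc": lfc, "s2": s2, "t_mod": t_mod, "p_t": p_t}
    ).reset_index(drop=True)
    return table, eb


def probe_phenotype_correlation(
    matrix: pd.DataFrame, phenotype: pd.DataFrame, analyte: str
) -> pd.DataFrame:
    """Pearson correlation of each probe's methylation with a phenotype.

    Subjects missing the phenotype are excluded pairwise; at least 3 paired
    subjects are required.  p-values come from the exact t transform,
    t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom.  Returns a
    table with columns probe_id, r, p_r, n.
    """
    pheno = phenotype[phenotype["analyte"] == analyte]
    levels = pheno.dropna(subset=["level"]).set_index("subject_id")["level"]
    common = [s for s in matrix.columns if s in levels.index]
    if len(common) < 3:
        raise DomainError(f"need >= 3 subjects with phenotype {analyte!r}, got {len(common)}")
    y = levels.loc[common].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        raise DomainError(f"phenotype {analyte!r} is constant across subjects")
    x = matrix[common].to_numpy(dtype=float)
    n = len(common)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    x_ss = (xc**2).sum(axis=1)
    y_ss = float((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc) / np.sqrt(x_ss * y_ss)
    r = np.clip(r, -1.0, 1.0)
    r[x_ss == 0] = np.nan  # constant probe: correlation undefined
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 0.0))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return pd.DataFrame({"probe_id": matrix.index, "r": r, "p_r": p, "n": n}).reset_index(drop=True)
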