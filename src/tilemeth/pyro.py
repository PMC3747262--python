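"""Statistics for targeted bisulfite-pyrosequencing validation data.

Pyrosequencing reports percent methylation per CpG site per subject, usually
in technical triplicate.  Replicates are averaged within subject first; group
means and standard errors are then computed over subjects, compared with a
two-sided two-sample Student t-test (equal variances by default, Welch by
flag), both per CpG and for the mean across all CpG sites of the region.
The region mean per subject can be correlated with a plasma phenotype by
Pearson correlation with the exact t-transform p-value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, FormatError
from .probestats import GroupDesign

PYRO_COLUMNS = ["subject_id", "cpg_id", "replicate", "percent_methylation"]


def _significance_marker(p: float) -> str:
    if p <= 0.05:
        return "*"
    if p <= 0.1:
        return "#"
    return ""


def subject_means(table: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates within subject x CpG (subjects x CpGs)."""
    missing = [c for c in PYRO_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"pyro table missing columns {missing}")
    vals = table["percent_methylation"].astype(float)
    if ((vals < 0) | (vals > 100)).any():
        raise FormatError("percent methylation outside [0, 100]")
    return table.pivot_table(
        index="subject_id", columns="cpg_id", values="percent_methylation", aggfunc="mean"
    )


def summarize_pyro(
    table: pd.DataFrame, groups: GroupDesign, equal_var: bool = True
) -> pd.DataFrame:
    """Group mean, SEM and t-test per CpG plus the all-CpG region mean.

    Returns one row per CpG and a final ``region_mean`` row; columns are
    mean/SEM per group, t, p and a significance marker ('#' for p <= 0.1,
    '*' for p <= 0.05).
    """
    means = subject_means(table)
    labels = groups.labels(means.index)
    a = means.loc[labels == "A"]
    b = means.loc[labels == "B"]
    if len(a) < 2 or len(b) < 2:
        raise DomainError(f"each group needs >= 2 subjects (got {len(a)} and {len(b)})")
    rows = []
    units = [(cpg, a[cpg], b[cpg]) for cpg in means.columns]
    units.append(("region_mean", a.mean(axis=1), b.mean(axis=1)))
    for name, xa, xb in units:
        t, p = stats.ttest_ind(xa.dropna(), xb.dropna(), equal_var=equal_var)
        rows.append(
            {
                "cpg_id": name,
                "mean_A": float(xa.mean()),
                "sem_A": float(xa.std(ddof=1) / np.sqrt(xa.notna().sum())),
                "mean_B": float(xb.mean()),
                "sem_B": float(xb.std(ddof=1) / np.sqrt(xb.notna().sum())),
                "t": float(t),
                "p": float(p),
                "marker": _significance_marker(float(p)),
            }
        )
    return pd.DataFrame(rows)


def region_means_per_subject(table: pd.DataFrame) -> pd.Series:
    """Mean methylation over all CpG sites, one value per subject."""
    return subject_means(table).mean(axis=1)


def correlate_pyro_phenotype(region_means: pd.Series, phenotype: pd.Series) -> tuple[float, float]:
    """Pearson correlation of per-subject region methylation with a phenotype.

    Pairwise-complete over the shared subjects; requires at least 3 pairs.
    Returns (r, two-sided p from the t transform).
    """
    joined = pd.concat([region_means.rename("x"), phenotype.rename("y")], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise DomainError(f"need >= 3 paired subjects, got {len(joined)}")
    x, y = joined["x"].to_numpy(), joined["y"].to_numpy()
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise DomainError("constant input: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
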