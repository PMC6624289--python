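"""Replicate-hierarchical aggregation, hypothesis tests and kinetics summaries.

The independent experiment (replicate) is the unit of replication: per-cell
displayed ratios are first averaged within (condition, replicate), then the
condition mean and SEM are computed across replicate means.  Category counts
are compared across conditions by a Pearson chi-square test on pooled
counts; condition effects on the displayed ratio are tested by fixed-effects
two-way ANOVA on replicate-level means.  P values map onto the conventional
star annotation (* P<=0.05, ** P<=0.01, *** P<=0.001).  A time course is
summarized by when the grand-mean displayed ratio crosses 0 (the ratio
crossing 1): first negative timepoint = nucleolar release, first later
non-negative timepoint = recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "ChiSqResult",
    "AnovaResult",
    "KineticsSummary",
    "DegenerateMarginError",
    "aggregate",
    "chisq_test",
    "anova_two_way",
    "significance_stars",
    "kinetics_summary",
]


class DegenerateMarginError(ValueError):
    """A contingency table has an all-zero row or column margin."""


def aggregate(
    dataset: pd.DataFrame,
    grouping: Sequence[str],
    value_col: str = "displayed_ratio",
    replicate_col: str = "replicate_id",
) -> pd.DataFrame:
    """Hierarchical condition summaries: replicate means, grand mean, SEM.

    Cells are first averaged within (condition, replicate); the grand mean
    and SEM (sd of replicate means / sqrt(n_replicates), ddof=1) are then
    computed across replicate means, so replicates with unequal cell counts
    weigh equally.  Conditions with a single replicate report an empty SEM
    with a warning.

    Returns one row per condition with columns ``grouping + [grand_mean,
    sem, n_replicates, n_cells, replicate_means]``.
    """
    grouping = list(grouping)
    if replicate_col not in dataset.columns:
        raise ValueError(f"dataset lacks replicate column {replicate_col!r}")
    data = dataset.dropna(subset=[value_col])
    rows = []
    for key, grp in data.groupby(grouping, dropna=False, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        rep_means = grp.groupby(replicate_col)[value_col].mean()
        n_rep = len(rep_means)
        row = dict(zip(grouping, key))
        row["grand_mean"] = float(rep_means.mean())
        if n_rep >= 2:
            row["sem"] = float(rep_means.std(ddof=1) / np.sqrt(n_rep))
        else:
            warnings.warn(
                f"condition {dict(zip(grouping, key))} has a single replicate; "
                "SEM undefined",
                stacklevel=2,
            )
            row["sem"] = np.nan
        row["n_replicates"] = n_rep
        row["n_cells"] = int(len(grp))
        row["replicate_means"] = [float(v) for v in rep_means]
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ChiSqResult:
    """Pearson chi-square test on a conditions x categories count table."""

    statistic: float
    df: int
    p_value: float
    observed: np.ndarray
    expected: np.ndarray


def chisq_test(table: Union[np.ndarray, Sequence[Sequence[float]], pd.DataFrame]) -> ChiSqResult:
    """Pearson chi-square on observed counts, expected from the margins.

    No continuity correction is applied, so the 2x2 statistic equals the
    closed form N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    row_margin = obs.sum(axis=1)
    col_margin = obs.sum(axis=0)
    if np.any(row_margin == 0):
        raise DegenerateMarginError(
            f"all-zero row margin at row(s) {np.flatnonzero(row_margin == 0).tolist()}"
        )
    if np.any(col_margin == 0):
        raise DegenerateMarginError(
            f"all-zero column margin at column(s) {np.flatnonzero(col_margin == 0).tolist()}"
        )
    stat, p, df, expected = sps.chi2_contingency(obs, correction=False)
    return ChiSqResult(
        statistic=float(stat), df=int(df), p_value=float(p),
        observed=obs, expected=np.asarray(expected),
    )


@dataclass
class AnovaResult:
    """Fixed-effects two-way ANOVA decomposition.

    ``table`` has one row per term (factor_a, factor_b, optional
    interaction, residual) with columns sum_sq, df, F, p.
    ``interaction_dropped`` marks designs without within-cell replication.
    """

    table: pd.DataFrame
    factor_a: str
    factor_b: str
    interaction_dropped: bool = False

    def term(self, name: str) -> pd.Series:
        return self.table.loc[name]


def anova_two_way(
    data: pd.DataFrame,
    response: str,
    factor_a: str,
    factor_b: str,
) -> AnovaResult:
    """Two-way fixed-effects ANOVA with interaction on replicate-level means.

    Requires >=2 levels per factor.  With fewer than 2 observations in any
    factor-combination cell the interaction term cannot be estimated and is
    dropped with a warning (additive model).  Terms with zero sum of
    squares report F=0, p=1 by convention so that degenerate (constant)
    inputs do not produce NaNs.
    """
    df = data.dropna(subset=[response]).copy()
    for f in (factor_a, factor_b):
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >=2 levels")
    cell_counts = df.groupby([factor_a, factor_b], dropna=False)[response].count()
    with_interaction = bool((cell_counts >= 2).all())
    if not with_interaction:
        warnings.warn(
            "fewer than 2 replicates in at least one cell; "
            "interaction term dropped (additive model)",
            stacklevel=2,
        )
    op = "*" if with_interaction else "+"
    formula = f"Q('{response}') ~ C(Q('{factor_a}')) {op} C(Q('{factor_b}'))"
    model = smf.ols(formula, data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # 0/0 on constant data
        raw = anova_lm(model, typ=2)

    rename = {}
    for idx in raw.index:
        if factor_a in idx and factor_b in idx:
            rename[idx] = "interaction"
        elif factor_a in idx:
            rename[idx] = factor_a
        elif factor_b in idx:
            rename[idx] = factor_b
        else:
            rename[idx] = "residual"
    table = raw.rename(index=rename)[["sum_sq", "df", "F", "PR(>F)"]]
    table.columns = ["sum_sq", "df", "F", "p"]

    # zero-variance convention: a term explaining (numerically) nothing is
    # F=0, p=1 rather than the NaN a 0/0 ratio would give
    eff = table.index != "residual"
    tol = 1e-12 * max(float(table["sum_sq"].sum()), 1.0)
    zero = eff & ((table["sum_sq"] <= tol) | table["F"].isna())
    table.loc[zero, "F"] = 0.0
    table.loc[zero, "p"] = 1.0
    table.loc["residual", ["F", "p"]] = np.nan
    return AnovaResult(
        table=table,
        factor_a=factor_a,
        factor_b=factor_b,
        interaction_dropped=not with_interaction,
    )


def significance_stars(p: float) -> str:
    """Map a P value to the conventional annotation.

    '***' iff P <= 0.001, '**' iff P <= 0.01, '*' iff P <= 0.05, else ''.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p value must lie in [0, 1], got {p}")
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


@dataclass
class KineticsSummary:
    """Sign-crossing summary of a displayed-ratio time course.

    Release is the first timepoint where the grand-mean displayed ratio
    goes negative (mean R below 1, protein depleted from nucleoli);
    recovery is the first later timepoint where it is non-negative again.
    """

    timepoints: List[float]
    grand_means: List[float]
    release_time: Optional[float] = None
    recovery_time: Optional[float] = None
    no_release: bool = False
    no_recovery: bool = False


def kinetics_summary(
    summaries: Union[pd.DataFrame, Sequence[Tuple[float, float]]],
    timepoint_col: str = "timepoint",
    mean_col: str = "grand_mean",
) -> KineticsSummary:
    """Detect nucleolar release and recovery from per-timepoint grand means."""
    if isinstance(summaries, pd.DataFrame):
        pairs = sorted(zip(summaries[timepoint_col], summaries[mean_col]))
    else:
        pairs = sorted((float(t), float(m)) for t, m in summaries)
    if len(pairs) < 2:
        raise ValueError("kinetics summary needs >=2 timepoints")
    times = [t for t, _ in pairs]
    means = [m for _, m in pairs]
    out = KineticsSummary(timepoints=times, grand_means=means)
    for t, m in pairs:
        if out.release_time is None:
            if m < 0:
                out.release_time = t
        elif m >= 0:
            out.recovery_time = t
            break
    out.no_release = out.release_time is None
    out.no_recovery = out.release_time is not None and out.recovery_time is None
    return out
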