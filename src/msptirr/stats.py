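"""Per-scale two-group comparison of multiscale profiles.

Mirrors the study protocol: normality (Lilliefors-corrected K-S) and
equal-variance (F) checks, a two-tailed independent-samples t test per
scale factor (pooled variance when the F check passes, Welch otherwise),
a two-way fixed-effects ANOVA for group x band / group x region layouts
at a single scale, and the base-0.05 log transform used when plotting
p-value curves (values above 1 mean p < 0.05).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._exceptions import InvalidInputError, ParameterError
from .multiscale import ScaleProfile

__all__ = [
    "AssumptionResult",
    "CohortResult",
    "SignificanceIntervals",
    "AnovaResult",
    "assumption_checks",
    "per_scale_ttest",
    "two_factor_anova",
    "log_p_transform",
    "significance_intervals",
    "group_curve",
    "results_frame",
    "benjamini_hochberg",
]

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class AssumptionResult:
    """Normality and variance-homogeneity checks for two samples."""

    normal_p: tuple[float, float]
    normal_ok: tuple[bool, bool]
    f_statistic: float
    variance_p: float
    equal_variance_ok: bool


@dataclass(frozen=True)
class CohortResult:
    """One per-scale group comparison."""

    scale: int
    statistic: float
    p_value: float
    test: str  # "t-pooled" or "t-welch"
    group_means: tuple[float, float]
    group_sems: tuple[float, float]


@dataclass(frozen=True)
class SignificanceIntervals:
    """Maximal runs of consecutive scales with p below alpha."""

    intervals: tuple[tuple[int, int], ...]
    alpha: float

    def __str__(self) -> str:
        if not self.intervals:
            return "No significant difference"
        return " and ".join(f"[{a},{b}]" for a, b in self.intervals)


@dataclass(frozen=True)
class AnovaResult:
    """Two-way fixed-effects ANOVA: group, factor and interaction effects."""

    factor_name: str
    f_statistics: dict[str, float]
    p_values: dict[str, float]
    table: pd.DataFrame


def _sem(x: np.ndarray) -> float:
    return float(x.std(ddof=1) / math.sqrt(x.size)) if x.size > 1 else 0.0


def assumption_checks(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alpha: float = ALPHA_DEFAULT,
) -> AssumptionResult:
    """Normality per group (Lilliefors K-S against a fitted normal) and an
    equal-variance F test; each flagged at `alpha`."""
    from statsmodels.stats.diagnostic import lilliefors

    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    for name, g in (("group_a", a), ("group_b", b)):
        if g.size < 3:
            raise ParameterError(f"{name} has {g.size} values; at least 3 required")

    def _norm_p(g: np.ndarray) -> float:
        if g.std(ddof=1) == 0:
            return 1.0  # degenerate sample; K-S statistic undefined
        return float(lilliefors(g, dist="norm")[1])

    pa, pb = _norm_p(a), _norm_p(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == vb:
        f_stat, p_var = 1.0, 1.0
    elif vb == 0 or va == 0:
        f_stat, p_var = math.inf, 0.0
    else:
        f_stat = float(va / vb)
        cdf = sps.f.cdf(f_stat, a.size - 1, b.size - 1)
        p_var = float(2 * min(cdf, 1 - cdf))
    return AssumptionResult(
        normal_p=(pa, pb),
        normal_ok=(pa >= alpha, pb >= alpha),
        f_statistic=f_stat,
        variance_p=p_var,
        equal_variance_ok=p_var >= alpha,
    )


def _profiles_to_matrix(
    profiles: Sequence[ScaleProfile] | np.ndarray,
) -> tuple[np.ndarray, tuple[int, ...] | None]:
    if isinstance(profiles, np.ndarray):
        mat = np.atleast_2d(np.asarray(profiles, dtype=float))
        return mat, None
    scale_sets = {p.scales for p in profiles}
    if len(scale_sets) != 1:
        raise InvalidInputError("subject profiles cover different scale sets")
    scales = next(iter(scale_sets))
    return np.vstack([p.as_array() for p in profiles]), scales


def per_scale_ttest(
    group_a_profiles: Sequence[ScaleProfile] | np.ndarray,
    group_b_profiles: Sequence[ScaleProfile] | np.ndarray,
    scales: Sequence[int] | None = None,
    alpha: float = ALPHA_DEFAULT,
) -> list[CohortResult]:
    """Two-tailed independent-samples t test at every scale.

    The equal-variance F check selects pooled-variance vs Welch per scale.
    Inputs are lists of subject :class:`ScaleProfile` (all on the same
    scale set) or plain subjects x scales arrays (then pass `scales`).
    """
    mat_a, scales_a = _profiles_to_matrix(group_a_profiles)
    mat_b, scales_b = _profiles_to_matrix(group_b_profiles)
    if scales_a is not None and scales_b is not None and scales_a != scales_b:
        raise InvalidInputError("the two groups cover different scale sets")
    if mat_a.shape[1] != mat_b.shape[1]:
        raise InvalidInputError(
            f"scale-set mismatch: {mat_a.shape[1]} vs {mat_b.shape[1]} scales"
        )
    if scales is None:
        scales = scales_a or scales_b or tuple(range(1, mat_a.shape[1] + 1))
    if len(scales) != mat_a.shape[1]:
        raise InvalidInputError("scales length does not match the profiles")
    if mat_a.shape[0] < 2 or mat_b.shape[0] < 2:
        raise ParameterError("each group needs at least 2 subjects")

    results = []
    for k, scale in enumerate(scales):
        a, b = mat_a[:, k], mat_b[:, k]
        va, vb = a.var(ddof=1), b.var(ddof=1)
        if va == 0 and vb == 0:
            # degenerate: no within-group spread
            stat = 0.0 if a.mean() == b.mean() else math.inf
            p = 1.0 if a.mean() == b.mean() else 0.0
            test = "t-pooled"
        else:
            if va == vb:
                equal_var = True
            else:
                f_stat = va / vb if vb > 0 else math.inf
                if math.isinf(f_stat):
                    equal_var = False
                else:
                    cdf = sps.f.cdf(f_stat, a.size - 1, b.size - 1)
                    equal_var = 2 * min(cdf, 1 - cdf) >= alpha
            stat, p = sps.ttest_ind(a, b, equal_var=equal_var)
            if math.isnan(stat):
                stat, p = 0.0, 1.0
            test = "t-pooled" if equal_var else "t-welch"
        results.append(
            CohortResult(
                scale=int(scale),
                statistic=float(stat),
                p_value=float(p),
                test=test,
                group_means=(float(a.mean()), float(b.mean())),
                group_sems=(_sem(a), _sem(b)),
            )
        )
    return results


def two_factor_anova(
    data: pd.DataFrame,
    factor_name: str = "region",
    value_col: str = "value",
    group_col: str = "group",
) -> AnovaResult:
    """Two-way fixed-effects ANOVA (type II): group, factor, interaction.

    `data` is tidy with one observation per row and columns
    ``group_col``, ``factor_name`` and ``value_col``; every
    group x level cell needs at least 2 observations.  Designs with zero
    between-cell variation report F = 0, p = 1 for the affected effects.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for col in (group_col, factor_name, value_col):
        if col not in data.columns:
            raise InvalidInputError(f"data lacks column {col!r}")
    groups = data[group_col].unique()
    levels = data[factor_name].unique()
    if len(groups) < 2 or len(levels) < 2:
        raise ParameterError("need at least 2 groups and 2 factor levels")
    cell_sizes = data.groupby([group_col, factor_name], observed=True).size()
    if len(cell_sizes) < len(groups) * len(levels):
        raise ParameterError("the design has empty group x level cells")
    if (cell_sizes < 2).any():
        raise ParameterError("every group x level cell needs >= 2 observations")

    df = data.rename(columns={value_col: "_value", group_col: "_group", factor_name: "_factor"})
    model = smf.ols("_value ~ C(_group) * C(_factor)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    key_map = {
        "C(_group)": "group",
        "C(_factor)": factor_name,
        "C(_group):C(_factor)": "interaction",
    }
    f_stats: dict[str, float] = {}
    p_vals: dict[str, float] = {}
    for row, name in key_map.items():
        ss = float(table.loc[row, "sum_sq"])
        f = table.loc[row, "F"]
        p = table.loc[row, "PR(>F)"]
        if ss <= 1e-12 or not np.isfinite(f):
            f, p = 0.0, 1.0
        f_stats[name] = float(f)
        p_vals[name] = float(p)
    table = table.rename(index=key_map)
    return AnovaResult(
        factor_name=factor_name, f_statistics=f_stats, p_values=p_vals, table=table
    )


def log_p_transform(p):
    """log of p with base 0.05: 1 at p = 0.05, 0 at p = 1, > 1 means
    significant at the 5% level.  Accepts scalars or arrays."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0) or np.any(arr > 1):
        raise ParameterError("p values must lie in (0, 1]")
    out = np.log(arr) / math.log(0.05)
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def significance_intervals(
    results: Sequence[CohortResult], alpha: float = ALPHA_DEFAULT
) -> SignificanceIntervals:
    """Maximal runs of consecutive scale factors with p < alpha."""
    ordered = sorted(results, key=lambda r: r.scale)
    intervals: list[tuple[int, int]] = []
    start = prev = None
    for r in ordered:
        if r.p_value < alpha:
            if start is None:
                start = prev = r.scale
            elif r.scale == prev + 1:
                prev = r.scale
            else:
                intervals.append((start, prev))
                start = prev = r.scale
        elif start is not None:
            intervals.append((start, prev))
            start = prev = None
    if start is not None:
        intervals.append((start, prev))
    return SignificanceIntervals(intervals=tuple(intervals), alpha=alpha)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p values across scales (optional; off by default in the
    pipeline, which reports raw per-scale p values)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


def group_curve(
    profiles: Sequence[ScaleProfile],
) -> tuple[np.ndarray, np.ndarray]:
    """Group mean and standard error across subject mean profiles, per
    scale (the quantities plotted as a line with an SEM shade)."""
    mat, _ = _profiles_to_matrix(profiles)
    mean = mat.mean(axis=0)
    if mat.shape[0] > 1:
        sem = mat.std(axis=0, ddof=1) / math.sqrt(mat.shape[0])
    else:
        sem = np.zeros(mat.shape[1])
    return mean, sem


def results_frame(
    results: Sequence[CohortResult],
    group_names: tuple[str, str] = ("A", "B"),
    **labels,
) -> pd.DataFrame:
    """Tidy table of per-scale test results, with the base-0.05 log-p
    column used for plotting."""
    na, nb = group_names
    df = pd.DataFrame(
        {
            "scale": [r.scale for r in results],
            "statistic": [r.statistic for r in results],
            "p": [r.p_value for r in results],
            "neg_log05_p": [
                log_p_transform(r.p_value) if r.p_value > 0 else math.inf
                for r in results
            ],
            "test": [r.test for r in results],
            f"mean_{na}": [r.group_means[0] for r in results],
            f"sem_{na}": [r.group_sems[0] for r in results],
            f"mean_{nb}": [r.group_means[1] for r in results],
            f"sem_{nb}": [r.group_sems[1] for r in results],
        }
    )
    for key, val in labels.items():
        df.insert(0, key, val)
    return df
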