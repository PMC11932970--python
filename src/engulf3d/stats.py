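"""Factorial ANOVA, Welch's t, Sidak adjustment and BCa bootstrap estimation.

The statistical layer of the assay: per-animal metrics are compared with

* two-way ANOVA (factors such as sex x incision; Type III sums of squares
  with sum-to-zero contrasts, so the tests are sensible for mildly
  unbalanced cohorts and coincide with the textbook decomposition on
  balanced data),
* one-way ANOVA across several conditions,
* Welch's unequal-variance t-test for planned two-group contrasts,
* Sidak-adjusted post-hoc p-values (p_adj = 1 - (1 - p)^m), and
* estimation statistics: the mean difference between two groups with a
  bias-corrected and accelerated (BCa) bootstrap confidence interval
  (default 95%, 5000 resamples), resampling independently within groups.

Significance defaults to alpha = 0.05.  All bootstrap randomness is driven
by an explicit seed; there is no hidden global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "AnovaTable",
    "BootstrapEstimate",
    "SignificancePolicy",
    "two_way_anova",
    "one_way_anova",
    "welch_t",
    "sidak_adjust",
    "bca_ci",
]


@dataclass(frozen=True)
class SignificancePolicy:
    """Significance level and post-hoc method for a statistics plan."""

    alpha: float = 0.05
    post_hoc: str = "sidak"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class AnovaTable:
    """An ANOVA decomposition: one (ss, df, F, p) row per effect.

    ``effects`` maps effect name -> dict with keys ``ss``, ``df``, ``F``,
    ``p``; the residual row has ``ss`` and ``df`` only.
    """

    effects: dict
    residual: dict
    factor_names: tuple[str, ...]
    cell_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, row in self.effects.items():
            if row["df"] < 1:
                raise ValueError(f"effect {name} has df {row['df']} < 1")
            if not 0 <= row["p"] <= 1 or row["F"] < 0:
                raise ValueError(f"effect {name} has invalid F/p: {row}")

    def p(self, effect: str) -> float:
        return self.effects[effect]["p"]

    def F(self, effect: str) -> float:
        return self.effects[effect]["F"]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"effect": k, **v} for k, v in self.effects.items()
        ] + [{"effect": "residual", **self.residual}]
        return pd.DataFrame(rows)


@dataclass
class BootstrapEstimate:
    """Mean difference (group2 - group1) with a BCa bootstrap CI."""

    mean_difference: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    n_boot: int = 5000
    seed: int | None = None
    degenerate: bool = False
    z0: float = 0.0
    acceleration: float = 0.0


def two_way_anova(
    values,
    factor_a,
    factor_b,
    names: tuple[str, str] = ("A", "B"),
) -> AnovaTable:
    """Full-factorial two-way ANOVA with interaction.

    Uses Type III sums of squares with sum-to-zero contrasts, which for
    balanced data reduce to the classical cell-means decomposition.  Raises
    on empty cells (the interaction is then inestimable) and on designs
    with fewer than 2 residual degrees of freedom.
    """
    y = np.asarray(values, dtype=float)
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    if not (len(y) == len(a) == len(b)):
        raise ValueError("values and factors must have equal length")
    df = pd.DataFrame({"y": y, "a": a.astype(str), "b": b.astype(str)})
    for col, nm in (("a", names[0]), ("b", names[1])):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {nm!r} has fewer than 2 levels")
    cells = df.groupby(["a", "b"], sort=True).size()
    n_cells = len(df["a"].unique()) * len(df["b"].unique())
    if len(cells) < n_cells:
        raise ValueError("empty cell in the two-way design; interaction inestimable")
    resid_df = len(df) - n_cells
    if resid_df < 2:
        raise ValueError(f"only {resid_df} residual df; need >= 2")
    dfs = {
        names[0]: len(df["a"].unique()) - 1,
        names[1]: len(df["b"].unique()) - 1,
    }
    dfs[f"{names[0]}:{names[1]}"] = dfs[names[0]] * dfs[names[1]]
    if y.var() == 0:  # constant response: every effect is exactly null
        return AnovaTable(
            effects={
                k: {"ss": 0.0, "df": d, "F": 0.0, "p": 1.0} for k, d in dfs.items()
            },
            residual={"ss": 0.0, "df": resid_df},
            factor_names=names,
            cell_counts={k: int(v) for k, v in cells.items()},
        )
    model = smf.ols("y ~ C(a, Sum) * C(b, Sum)", data=df).fit()
    tab = anova_lm(model, typ=3)

    def row(key):
        r = tab.loc[key]
        f = float(r["F"])
        p = float(r["PR(>F)"])
        if not math.isfinite(f):  # zero residual variance (all values equal)
            f, p = 0.0, 1.0
        return {
            "ss": float(r["sum_sq"]),
            "df": int(r["df"]),
            "F": max(f, 0.0),
            "p": min(max(p, 0.0), 1.0),
        }

    effects = {
        names[0]: row("C(a, Sum)"),
        names[1]: row("C(b, Sum)"),
        f"{names[0]}:{names[1]}": row("C(a, Sum):C(b, Sum)"),
    }
    residual = {
        "ss": float(tab.loc["Residual", "sum_sq"]),
        "df": int(tab.loc["Residual", "df"]),
    }
    return AnovaTable(
        effects=effects,
        residual=residual,
        factor_names=names,
        cell_counts={k: int(v) for k, v in cells.items()},
    )


def one_way_anova(groups) -> AnovaTable:
    """One-way ANOVA across two or more groups.

    Standard between/within decomposition: ``F = MS_between / MS_within``
    with df ``(k - 1, N - k)``.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in gs):
        raise ValueError("a group has 0 observations")
    n = sum(len(g) for g in gs)
    k = len(gs)
    if n - k < 2:
        raise ValueError(f"only {n - k} residual df; need >= 2")
    grand = np.concatenate(gs).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_b, df_w = k - 1, n - k
    if ss_within == 0:
        f, p = (0.0, 1.0) if ss_between == 0 else (math.inf, 0.0)
        f = 0.0 if ss_between == 0 else f
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
        p = float(sps.f.sf(f, df_b, df_w))
    if not math.isfinite(f):
        f, p = 0.0, 1.0
    return AnovaTable(
        effects={"group": {"ss": float(ss_between), "df": df_b, "F": float(f),
                           "p": float(min(max(p, 0.0), 1.0))}},
        residual={"ss": float(ss_within), "df": df_w},
        factor_names=("group",),
        cell_counts={i: len(g) for i, g in enumerate(gs)},
    )


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, df, two-sided p).

    Degrees of freedom follow the Welch-Satterthwaite approximation, which
    reduces exactly to ``n_a + n_b - 2`` for equal variances and equal n.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # zero-variance degenerate case: no evidence either way
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("both samples have zero variance but unequal means")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def sidak_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Sidak multiplicity adjustment: ``p_adj = 1 - (1 - p)^m``.

    ``m`` defaults to the number of comparisons supplied and must be at
    least that number.  Results are clipped to [0, 1] and are monotone in
    both p and m.
    """
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError(f"family size m={m} < number of comparisons {len(p)}")
    return np.clip(1.0 - (1.0 - p) ** m, 0.0, 1.0)


def _bca_quantile_levels(
    boot: np.ndarray, theta_hat: float, accel: float, level: float
) -> tuple[float, float, float]:
    """BCa-adjusted percentile levels (alpha_lo, alpha_hi) and z0."""
    b = len(boot)
    prop = np.count_nonzero(boot < theta_hat) / b
    # guard the probit against 0/1 (extremely skewed bootstrap distributions)
    prop = min(max(prop, 0.5 / b), 1 - 0.5 / b)
    z0 = float(sps.norm.ppf(prop))
    zlo = sps.norm.ppf((1 - level) / 2)
    zhi = -zlo
    alphas = []
    for z in (zlo, zhi):
        num = z0 + z
        adj = z0 + num / (1 - accel * num)
        alphas.append(float(sps.norm.cdf(adj)))
    return alphas[0], alphas[1], z0


def bca_ci(
    group1,
    group2,
    n_boot: int = 5000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = 0,
) -> BootstrapEstimate:
    """BCa bootstrap CI for the mean difference ``mean(group2) - mean(group1)``.

    Resampling is independent within each group.  The bias correction z0 is
    the probit of the proportion of bootstrap statistics below the point
    estimate; the acceleration a comes from the jackknife of the statistic
    (leave-one-out over both groups combined):
    ``a = sum(d^3) / (6 (sum(d^2))^(3/2))`` with ``d`` the deviations of
    jackknife values from their mean.  Zero-variance inputs give a
    zero-width interval at the point estimate, flagged degenerate; a
    degenerate jackknife falls back to a = 0.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_rec = seed if isinstance(seed, int) else None
    theta_hat = float(y.mean() - x.mean())

    if x.var() == 0 and y.var() == 0:
        return BootstrapEstimate(
            mean_difference=theta_hat, ci_low=theta_hat, ci_high=theta_hat,
            level=level, n_boot=n_boot, seed=seed_rec, degenerate=True,
        )

    bx = x[rng.integers(0, len(x), size=(n_boot, len(x)))].mean(axis=1)
    by = y[rng.integers(0, len(y), size=(n_boot, len(y)))].mean(axis=1)
    boot = by - bx
    if np.all(boot == boot[0]):
        return BootstrapEstimate(
            mean_difference=theta_hat, ci_low=float(boot[0]),
            ci_high=float(boot[0]), level=level, n_boot=n_boot, seed=seed_rec,
            degenerate=True,
        )

    # jackknife acceleration: leave-one-out over each group in turn
    jx = (x.sum() - x) / (len(x) - 1)  # leave-one-out means of group1
    jy = (y.sum() - y) / (len(y) - 1)
    jack = np.concatenate([y.mean() - jx, jy - x.mean()])
    d = jack.mean() - jack
    denom = (d**2).sum() ** 1.5
    accel = float((d**3).sum() / (6 * denom)) if denom > 0 else 0.0

    a_lo, a_hi, z0 = _bca_quantile_levels(boot, theta_hat, accel, level)
    ci_low, ci_high = np.quantile(boot, [a_lo, a_hi])
    return BootstrapEstimate(
        mean_difference=theta_hat,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        level=level,
        n_boot=n_boot,
        seed=seed_rec,
        degenerate=False,
        z0=z0,
        acceleration=accel,
    )
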