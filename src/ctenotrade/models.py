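"""Treatment-level comparisons of egg output and offspring viability.

Two model families mirror the original analysis workflow:

* a fixed-effects least-squares model ``response ~ treatment + block``
  for the three blocked treatments, with the treatment effect tested by
  a marginal (partial) F test so unbalanced tables are handled;
* a plain one-way ANOVA across all four treatments (the sealed arm has
  no block structure, so block effects are dropped there).

Pairwise treatment contrasts use Tukey's HSD on the studentized range;
when a blocked fit is supplied its residual mean square and degrees of
freedom are used, so the pairwise tests are adjusted for block just as
the omnibus test is.  Viability is the fraction of spawned eggs showing
development 24 h post-fertilisation and is analysed as a linear-model
response on that fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "LinearModelFit",
    "TukeyResult",
    "UndefinedViabilityError",
    "blocked_least_squares",
    "one_way_anova",
    "tukey_hsd",
    "viability_fraction",
]

_VAR_FLOOR = 1e-12  # below this the response is treated as constant


class UndefinedViabilityError(ValueError):
    """Viability is undefined for an arena that spawned no eggs; such
    arenas are excluded (they also fail the low-egg-count rule)."""


@dataclass(frozen=True)
class LinearModelFit:
    response_name: str
    effect_F: float
    effect_df: tuple[int, int]
    effect_p: float
    block_p: float | None
    residuals: np.ndarray
    mse: float
    df_resid: int
    degenerate: bool = False


@dataclass(frozen=True)
class TukeyResult:
    """All pairwise comparisons: (label_i, label_j, mean_diff,
    q_statistic, adjusted_p), with mean_diff = mean_i - mean_j."""

    pairs: tuple[tuple[str, str, float, float, float], ...]

    def pair(self, a: str, b: str) -> tuple[str, str, float, float, float]:
        for i, j, d, q, p in self.pairs:
            if (i, j) == (a, b):
                return (i, j, d, q, p)
            if (j, i) == (a, b):
                return (a, b, -d, q, p)
        raise KeyError((a, b))


def _prepare(rows: pd.DataFrame, response: str, required: list[str]) -> pd.DataFrame:
    missing = [c for c in required if c not in rows.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    return rows.dropna(subset=required).copy()


def blocked_least_squares(
    rows: pd.DataFrame,
    response: str = "response",
    treatment: str = "treatment",
    block: str = "block",
) -> LinearModelFit:
    """Fit ``response ~ treatment + block`` (both categorical, fixed) and
    test the treatment effect with a marginal F test.

    Requires at least two treatment levels and two blocks.  A constant
    response is flagged degenerate (F = 0, p = 1) rather than producing
    a 0/0 statistic.
    """
    data = _prepare(rows, response, [response, treatment, block])
    n_treat = data[treatment].nunique()
    n_block = data[block].nunique()
    if n_treat < 2:
        raise ValueError("need at least 2 treatment levels")
    if n_block < 2:
        raise ValueError("need at least 2 blocks")
    data = data.rename(columns={response: "_y", treatment: "_t", block: "_b"})

    if np.var(data["_y"].to_numpy(dtype=float)) < _VAR_FLOOR:
        return LinearModelFit(
            response_name=response, effect_F=0.0,
            effect_df=(n_treat - 1, max(len(data) - n_treat - n_block + 1, 1)),
            effect_p=1.0, block_p=1.0,
            residuals=np.zeros(len(data)), mse=0.0,
            df_resid=max(len(data) - n_treat - n_block + 1, 1),
            degenerate=True,
        )

    fit = smf.ols("_y ~ C(_t, Sum) + C(_b, Sum)", data=data).fit()
    table = sm.stats.anova_lm(fit, typ=3)
    t_row = table.loc["C(_t, Sum)"]
    b_row = table.loc["C(_b, Sum)"]
    return LinearModelFit(
        response_name=response,
        effect_F=float(t_row["F"]),
        effect_df=(int(t_row["df"]), int(fit.df_resid)),
        effect_p=float(t_row["PR(>F)"]),
        block_p=float(b_row["PR(>F)"]),
        residuals=np.asarray(fit.resid),
        mse=float(fit.mse_resid),
        df_resid=int(fit.df_resid),
    )


def one_way_anova(
    rows: pd.DataFrame, response: str = "response", group: str = "group"
) -> LinearModelFit:
    """Standard one-way F test across groups, no blocking term."""
    data = _prepare(rows, response, [response, group])
    groups = [g.to_numpy(dtype=float) for _, g in data.groupby(group)[response]]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 observations")
    n = sum(len(g) for g in groups)
    df1, df2 = len(groups) - 1, n - len(groups)
    y = data[response].to_numpy(dtype=float)
    grand = y.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if np.var(y) < _VAR_FLOOR:
        return LinearModelFit(
            response_name=response, effect_F=0.0, effect_df=(df1, df2),
            effect_p=1.0, block_p=None,
            residuals=np.zeros(n), mse=0.0, df_resid=df2, degenerate=True,
        )
    mse = ss_within / df2
    F = (ss_between / df1) / mse
    p = float(stats.f.sf(F, df1, df2))
    residuals = np.concatenate([g - g.mean() for g in groups])
    return LinearModelFit(
        response_name=response, effect_F=float(F), effect_df=(df1, df2),
        effect_p=p, block_p=None, residuals=residuals, mse=float(mse),
        df_resid=df2,
    )


def tukey_hsd(
    rows: pd.DataFrame,
    response: str = "response",
    group: str = "group",
    fit: LinearModelFit | None = None,
) -> TukeyResult:
    """Tukey's HSD pairwise comparisons on the studentized range.

    By default the error variance is the one-way pooled mean square;
    passing a :class:`LinearModelFit` from :func:`blocked_least_squares`
    uses that model's residual mean square and degrees of freedom
    instead, adjusting the pairwise tests for block.  Unequal group
    sizes use the Tukey-Kramer form.
    """
    data = _prepare(rows, response, [response, group])
    stats_by_group = data.groupby(group)[response].agg(["mean", "count"])
    k = len(stats_by_group)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if fit is None:
        fit = one_way_anova(data, response=response, group=group)
    if fit.degenerate or fit.mse <= 0:
        pairs = tuple(
            (a, b,
             float(stats_by_group.loc[a, "mean"] - stats_by_group.loc[b, "mean"]),
             0.0, 1.0)
            for a, b in combinations(stats_by_group.index, 2)
        )
        return TukeyResult(pairs=pairs)
    out = []
    for a, b in combinations(stats_by_group.index, 2):
        ma, na = stats_by_group.loc[a, "mean"], stats_by_group.loc[a, "count"]
        mb, nb = stats_by_group.loc[b, "mean"], stats_by_group.loc[b, "count"]
        diff = float(ma - mb)
        se = np.sqrt(fit.mse / 2.0 * (1.0 / na + 1.0 / nb))
        q = abs(diff) / se
        p = float(stats.studentized_range.sf(q, k, fit.df_resid))
        out.append((a, b, diff, float(q), min(max(p, 0.0), 1.0)))
    return TukeyResult(pairs=tuple(out))


def viability_fraction(developed: int, spawned: int) -> float:
    """Offspring viability: developed / spawned.

    Raises :class:`UndefinedViabilityError` when nothing was spawned.
    """
    if spawned < 0 or developed < 0:
        raise ValueError("counts must be non-negative")
    if spawned == 0:
        raise UndefinedViabilityError("viability undefined when no eggs were spawned")
    if developed > spawned:
        raise ValueError("developed count cannot exceed spawned count")
    return developed / spawned
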