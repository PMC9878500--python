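"""One-way fixed-effects ANOVA with planned diet contrasts.

The experimental design is a completely randomized one-way layout (diet with
levels CON / NFDM / BC, unbalanced group sizes) analysed with planned contrasts
against the animal-within-treatment (residual) mean square:

    t = sum_i w_i * ybar_i / sqrt( MSE * sum_i w_i^2 / n_i ),   df = N - g

Two-sided p-values come from the t distribution on the residual df.  An
optional additive replicate block adjusts the error term when the experiment
was run in repeated trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class ContrastSpec:
    """Named contrast: weights per factor level, summing to zero.

    e.g. ``ContrastSpec("BC vs CON", {"CON": -1, "NFDM": 0, "BC": 1})``.
    """

    name: str
    weights: dict[str, float]
    note: str = ""

    def __post_init__(self) -> None:
        if abs(sum(self.weights.values())) > 1e-9:
            raise ValueError(f"contrast {self.name!r}: weights must sum to 0")


@dataclass
class ContrastResult:
    name: str
    estimate: float
    se: float
    t: float
    df: float
    p: float


@dataclass
class AnovaResult:
    """ANOVA table plus per-contrast tests for one response variable."""

    ss_between: float
    ss_within: float
    df_between: int
    df_within: int
    f: float
    p: float
    contrasts: list[ContrastResult]
    group_means: dict[str, float]
    group_n: dict[str, int]

    @property
    def mse(self) -> float:
        return self.ss_within / self.df_within

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "contrast": c.name,
                "estimate": c.estimate,
                "se": c.se,
                "t": c.t,
                "df": c.df,
                "p": c.p,
            }
            for c in self.contrasts
        ]
        return pd.DataFrame(rows)


def glm_anova(
    y: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
    contrasts: list[ContrastSpec] | None = None,
    block: pd.Series | np.ndarray | None = None,
) -> AnovaResult:
    """Fixed-effects ANOVA of ``y`` on ``groups`` with planned contrasts.

    The residual (animal-within-treatment) mean square is the error term.
    With ``block`` given (e.g. experiment replicate), the block's sum of
    squares is removed from the residual first (additive two-way layout).
    """
    y = np.asarray(y, dtype=float)
    groups = pd.Series(np.asarray(groups), name="group")
    if y.shape[0] != groups.shape[0]:
        raise ValueError("y and groups have different lengths")
    levels = list(pd.unique(groups))
    n_i = {g: int((groups == g).sum()) for g in levels}
    if any(n < 2 for n in n_i.values()):
        raise ValueError("need >=2 observations per group")
    means = {g: float(y[groups.values == g].mean()) for g in levels}
    grand = float(y.mean())
    ss_between = sum(n_i[g] * (means[g] - grand) ** 2 for g in levels)
    ss_within = sum(
        float(((y[groups.values == g] - means[g]) ** 2).sum()) for g in levels
    )
    df_between = len(levels) - 1
    df_within = len(y) - len(levels)

    if block is not None:
        block = pd.Series(np.asarray(block))
        resid = y - np.array([means[g] for g in groups])
        bl_means = resid_groupby_mean(resid, block)
        ss_block = sum(
            int((block == b).sum()) * m**2 for b, m in bl_means.items()
        )
        ss_within = max(ss_within - ss_block, 0.0)
        df_within -= len(bl_means) - 1
    if df_within <= 0:
        raise ValueError("no residual degrees of freedom")
    mse = ss_within / df_within
    if mse > 0:
        f = (ss_between / df_between) / mse
        p = float(sps.f.sf(f, df_between, df_within))
    else:
        f, p = np.inf, 0.0

    results = []
    for c in contrasts or []:
        missing = [lv for lv, w in c.weights.items() if w != 0 and lv not in levels]
        if missing:
            raise ValueError(f"contrast {c.name!r} references absent level(s) {missing}")
        est = sum(w * means[lv] for lv, w in c.weights.items() if lv in levels)
        var = mse * sum(w**2 / n_i[lv] for lv, w in c.weights.items() if lv in levels)
        se = float(np.sqrt(var))
        if se > 0:
            t = est / se
            pc = float(2.0 * sps.t.sf(abs(t), df_within))
        else:
            t = 0.0 if est == 0 else np.inf * np.sign(est)
            pc = 1.0 if est == 0 else 0.0
        results.append(ContrastResult(c.name, float(est), se, float(t), df_within, pc))

    return AnovaResult(
        ss_between=float(ss_between),
        ss_within=float(ss_within),
        df_between=df_between,
        df_within=df_within,
        f=float(f),
        p=p,
        contrasts=results,
        group_means=means,
        group_n=n_i,
    )


def resid_groupby_mean(resid: np.ndarray, block: pd.Series) -> dict:
    return {b: float(resid[block.values == b].mean()) for b in pd.unique(block)}


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional; raw contrast p-values are the default
    convention for this design)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvals, float), method="fdr_bh")[1]


def contrast_table(
    responses: pd.DataFrame,
    groups: pd.Series,
    contrasts: list[ContrastSpec],
    block: pd.Series | None = None,
) -> pd.DataFrame:
    """Tidy table: one row per response column x contrast."""
    rows = []
    for col in responses.columns:
        res = glm_anova(responses[col], groups, contrasts, block=block)
        for c in res.contrasts:
            rows.append(
                {"response": col, "contrast": c.name, "estimate": c.estimate,
                 "se": c.se, "t": c.t, "df": c.df, "p": c.p}
            )
    return pd.DataFrame(rows)
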