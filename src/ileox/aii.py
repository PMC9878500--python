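"""Anti-inflammatory index (A-i-i) construction.

The index is the per-animal sum of Scaled Imputed Values of the candidate
metabolite groups retained by an iterative forward procedure: candidates are
offered to a multiple regression of log10 NT (nitrotyrosine pixels per cell)
one at a time, and a candidate is kept only if it strictly increases the
adjusted R² of the model.  Candidates must first qualify on three screens:
(a) literature-documented anti-inflammatory character, (b) a significant diet
contrast, and (c) the same-direction result in both experiment replicates.

``AiiModel`` holds the data and configuration; ``AiiModel.fit()`` runs the
retention and the final index-vs-NT regression and returns ``AiiResults``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metabolome import GroupSumTable
from .stats import ContrastSpec, glm_anova

logger = logging.getLogger(__name__)

RETENTION_TOL = 1e-10


@dataclass
class NTTable:
    """Per-animal nitrotyrosine readout: immunofluorescence pixel counts
    normalized by nuclei counts (pixels per cell), log10-transformed.

    Zero densities are floored at half the smallest positive observed density
    before taking log10 (logged); animals with missing NT are dropped listwise.
    """

    pixels: pd.Series
    nuclei: pd.Series
    density: pd.Series = field(init=False)
    log10_nt: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        if (self.nuclei < 1).any():
            raise ValueError("nuclei counts must be >= 1")
        if (self.pixels < 0).any():
            raise ValueError("pixel counts must be nonnegative")
        keep = self.pixels.notna() & self.nuclei.notna()
        dropped = int((~keep).sum())
        if dropped:
            logger.info("dropping %d animals with missing NT", dropped)
        self.pixels = self.pixels[keep]
        self.nuclei = self.nuclei[keep]
        self.density = self.pixels / self.nuclei
        dens = self.density.copy()
        if (dens == 0).any():
            floor = dens[dens > 0].min() / 2.0
            n0 = int((dens == 0).sum())
            logger.info("flooring %d zero NT densities at %.3g", n0, floor)
            dens = dens.clip(lower=floor)
        self.log10_nt = np.log10(dens)
        self.log10_nt.name = "log10_nt"

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "NTTable":
        return cls(pixels=df["nt_pixels"], nuclei=df["nuclei"])


@dataclass
class CandidateSet:
    """Qualified candidate predictors (group sums and/or single-metabolite
    SIV columns) with the per-candidate qualification record."""

    predictors: pd.DataFrame            # animals x candidates
    qualification: pd.DataFrame         # candidate x (literature, contrast, replication)

    @property
    def names(self) -> list[str]:
        return list(self.predictors.columns)


def adjusted_r2(y: np.ndarray | pd.Series, X: np.ndarray | pd.DataFrame) -> float:
    """Adjusted R² of the OLS fit of ``y`` on ``X`` (intercept added):
    1 − (1 − R²)(n − 1)/(n − p − 1).

    Raises on rank-deficient predictors or n ≤ p + 1.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < p + 1:
        raise ValueError("predictor matrix is rank deficient")
    r2 = _r_squared(y, design)
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _r_squared(y: np.ndarray, design: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        return 1.0
    return 1.0 - float((resid**2).sum()) / tss


def _adj_r2_lenient(y: np.ndarray, X: np.ndarray) -> float:
    """Adjusted R² that charges every offered column against the df budget,
    so a duplicate (collinear) candidate can only lower it."""
    n, p = X.shape
    if n <= p + 1:
        return -np.inf
    design = np.column_stack([np.ones(n), X])
    r2 = _r_squared(y, design)
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def qualify_candidates(
    group_sums: GroupSumTable,
    animal_meta: pd.DataFrame,
    literature_flags: dict[str, bool],
    contrasts: list[ContrastSpec] | None = None,
    alpha: float = 0.05,
    trend_alpha: float = 0.10,
) -> CandidateSet:
    """Screen candidate groups on the three qualification criteria.

    A group qualifies when it (a) carries a literature anti-inflammatory flag,
    (b) shows a significant (p < alpha) diet contrast on the pooled data, and
    (c) shows the same-direction significant-or-trend (p < trend_alpha)
    contrast in each experiment replicate separately.  Requires a
    ``replicate`` column in ``animal_meta``.
    """
    if "replicate" not in animal_meta.columns:
        raise ValueError("animal_meta must carry a 'replicate' column")
    if contrasts is None:
        contrasts = [
            ContrastSpec("BC vs CON", {"CON": -1.0, "NFDM": 0.0, "BC": 1.0}),
            ContrastSpec("NFDM vs CON", {"CON": -1.0, "NFDM": 1.0, "BC": 0.0}),
        ]
    sums = group_sums.sums
    meta = animal_meta.loc[sums.index]
    reps = sorted(meta["replicate"].unique())
    rows, kept = [], []
    for name in sums.columns:
        lit = bool(literature_flags.get(name, False))
        pooled_ok, pooled_why = False, None
        if lit:
            res = glm_anova(sums[name], meta["diet"], contrasts)
            for c in res.contrasts:
                if c.p < alpha:
                    pooled_ok, pooled_why = True, c.name
                    break
        rep_ok = False
        if pooled_ok:
            rep_ok = True
            signs = []
            for r in reps:
                sub = meta.index[meta["replicate"] == r]
                rres = glm_anova(
                    sums.loc[sub, name], meta.loc[sub, "diet"],
                    [c for c in contrasts if c.name == pooled_why],
                )
                cr = rres.contrasts[0]
                if cr.p >= trend_alpha:
                    rep_ok = False
                signs.append(np.sign(cr.estimate))
            if len(set(signs)) > 1:
                rep_ok = False
        qualified = lit and pooled_ok and rep_ok
        reason = (
            "qualified" if qualified
            else "literature" if not lit
            else "contrast" if not pooled_ok
            else "replication"
        )
        rows.append(
            {"candidate": name, "literature": lit, "contrast": pooled_ok,
             "replication": rep_ok, "reason": reason}
        )
        if qualified:
            kept.append(name)
    qual = pd.DataFrame(rows).set_index("candidate")
    logger.info("qualified %d/%d candidates", len(kept), len(sums.columns))
    return CandidateSet(predictors=sums[kept], qualification=qual)


@dataclass
class RetentionStep:
    candidate: str
    adj_r2_with: float
    adj_r2_without: float
    included: bool


@dataclass
class AiiResults:
    """Fitted anti-inflammatory index.

    ``steps`` records the adjusted-R² comparison behind every inclusion
    decision, in the order candidates were offered (always reported, since
    the outcome is order-dependent).
    """

    included: list[str]
    steps: list[RetentionStep]
    r2_trajectory: list[float]
    index_per_animal: pd.Series
    final_adjusted_r2: float
    final_r2: float
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    order: list[str]
    order_rule: str

    @property
    def excluded(self) -> dict[str, float]:
        return {s.candidate: s.adj_r2_with for s in self.steps if not s.included}

    def summary(self) -> pd.DataFrame:
        """Retention table: candidate, adjusted R² with it in the model,
        included yes/no — the layout of an iterative-retention report."""
        return pd.DataFrame(
            [
                {
                    "candidate": s.candidate,
                    "adjusted_R2": s.adj_r2_with,
                    "model_inclusion": "Yes" if s.included else "No",
                }
                for s in self.steps
            ]
        )


def forward_retention(
    y: pd.Series,
    candidates: CandidateSet | pd.DataFrame,
    order_rule: str = "corr",
    order: list[str] | None = None,
    fit: str = "best",
    tol: float = RETENTION_TOL,
) -> tuple[list[str], list[RetentionStep], list[float], list[str]]:
    """Iterative adjusted-R² retention.

    Candidates are offered in the configured order (default: descending
    |Pearson correlation| with ``y``, alphabetical tie-break; or the explicit
    ``order`` list with ``order_rule='given'``).  A candidate is retained iff
    the adjusted R² of the model including it strictly exceeds (by > ``tol``)
    that of the model without it.  ``fit`` selects the response scale offered
    to the comparison: 'linear' (y as given, i.e. log10 NT), 'exp'
    (log-linearized exponential y = a·e^{bx}, algebraically an affine
    transform of the linear response and hence the same R²), or 'best'
    (the larger adjusted R² of the two).
    """
    preds = candidates.predictors if isinstance(candidates, CandidateSet) else candidates
    if preds.shape[1] == 0:
        raise ValueError("no candidates to offer")
    common = y.index.intersection(preds.index)
    y = y.loc[common].astype(float)
    preds = preds.loc[common]
    if order_rule == "given":
        if order is None:
            raise ValueError("order_rule='given' requires an explicit order")
        seq = list(order)
    elif order_rule == "corr":
        corr = preds.apply(lambda col: abs(sps.pearsonr(col, y)[0])
                           if col.std() > 0 else 0.0)
        seq = sorted(preds.columns, key=lambda c: (-corr[c], c))
    else:
        raise ValueError(f"unknown order_rule {order_rule!r}")

    responses = {"linear": [y.values],
                 "exp": [np.log(10.0) * y.values],
                 "best": [y.values, np.log(10.0) * y.values]}[fit]

    def best_adj_r2(cols: list[str]) -> float:
        if not cols:
            return 0.0
        X = preds[cols].values
        return max(_adj_r2_lenient(resp, X) for resp in responses)

    included: list[str] = []
    steps: list[RetentionStep] = []
    trajectory: list[float] = []
    current = 0.0
    for name in seq:
        trial = best_adj_r2(included + [name])
        keep = trial > current + tol
        steps.append(RetentionStep(name, trial, current, keep))
        logger.info(
            "candidate %s: adjR2 %.6f vs %.6f -> %s",
            name, trial, current, "kept" if keep else "dropped",
        )
        if keep:
            included.append(name)
            current = trial
            trajectory.append(trial)
    if not included:
        logger.warning("no candidate improved over the null model")
    return included, steps, trajectory, seq


def compute_index(predictors: pd.DataFrame, included: list[str]) -> pd.Series:
    """Per-animal A-i-i: exact sum of the included predictors' SIV sums."""
    if not included:
        raise ValueError("included set is empty")
    idx = predictors[included].sum(axis=1)
    idx.name = "aii"
    return idx


def regress_nt_on_index(
    index: pd.Series, log10_nt: pd.Series
) -> tuple[float, float, float, float]:
    """OLS of log10 NT on the index: (slope, intercept, R², p of slope)."""
    common = index.index.intersection(log10_nt.index)
    if len(common) < 3:
        raise ValueError("need >= 3 paired animals")
    x = index.loc[common].astype(float).values
    y = log10_nt.loc[common].astype(float).values
    if np.std(x) == 0:
        raise ValueError("index has zero variance")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2), float(res.pvalue)


class AiiModel:
    """Anti-inflammatory-index model: log10 NT regressed on candidate metabolite
    group sums, with candidates retained by forward adjusted-R² improvement.

    Parameters
    ----------
    nt : NTTable or Series of log10 NT per animal
    candidates : CandidateSet or DataFrame of candidate predictors per animal
    order_rule, order, fit, tol : retention configuration (see
        :func:`forward_retention`).
    """

    def __init__(
        self,
        nt: NTTable | pd.Series,
        candidates: CandidateSet | pd.DataFrame,
        order_rule: str = "corr",
        order: list[str] | None = None,
        fit: str = "best",
        tol: float = RETENTION_TOL,
    ):
        self.log10_nt = nt.log10_nt if isinstance(nt, NTTable) else nt
        self.candidates = candidates
        self.order_rule = order_rule
        self.order = order
        self.fit_mode = fit
        self.tol = tol

    def fit(self) -> AiiResults:
        preds = (
            self.candidates.predictors
            if isinstance(self.candidates, CandidateSet)
            else self.candidates
        )
        included, steps, trajectory, seq = forward_retention(
            self.log10_nt, preds, order_rule=self.order_rule,
            order=self.order, fit=self.fit_mode, tol=self.tol,
        )
        if included:
            index = compute_index(preds, included)
            slope, intercept, r2, p = regress_nt_on_index(index, self.log10_nt)
            common = index.index.intersection(self.log10_nt.index)
            final_adj = adjusted_r2(
                self.log10_nt.loc[common], preds.loc[common, included]
            )
            design = np.column_stack(
                [np.ones(len(common)), preds.loc[common, included].values]
            )
            final_r2 = _r_squared(self.log10_nt.loc[common].values, design)
        else:
            index = pd.Series(dtype=float, name="aii")
            slope = intercept = r2 = p = np.nan
            final_adj = final_r2 = 0.0
        return AiiResults(
            included=included,
            steps=steps,
            r2_trajectory=trajectory,
            index_per_animal=index,
            final_adjusted_r2=float(final_adj),
            final_r2=float(final_r2),
            slope=slope,
            intercept=intercept,
            r_squared=r2,
            p_value=p,
            order=seq,
            order_rule=self.order_rule,
        )
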