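"""Metabolite-table normalization: Scaled Imputed Values (SIV) and pathway-group sums.

Raw untargeted-metabolomics output arrives as an animals x metabolites matrix of
"Original Scale" area counts with missing entries (compounds below the limit of
detection in a given animal).  The normalization convention used here is the one
common for vendor-processed datasets of this kind:

1. impute each missing cell with the per-metabolite minimum *observed* value
   (missingness in LC-MS data is dominated by left-censoring, so the minimum
   observed intensity is the conventional stand-in);
2. rescale each metabolite column so its across-animal median equals exactly 1,
   every animal's value scaled proportionately.

The resulting Scaled Imputed Values (SIVs) are unitless relative abundances
comparable across metabolites, and are what every downstream stage (pathway-group
sums, anti-inflammatory index, diet contrasts) consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DIETS = ("CON", "NFDM", "BC")


@dataclass
class RawMetaboliteTable:
    """Animals x metabolites matrix of raw area counts, NaN = below detection.

    ``animal_meta`` is indexed like ``values`` and carries at least a ``diet``
    column (levels CON / NFDM / BC) and usually ``replicate`` (1 or 2) and
    ``colostrum_source``.  ``detection_threshold`` optionally gives a
    per-metabolite limit of detection; without it a compound counts as detected
    wherever it was observed (non-missing).
    """

    values: pd.DataFrame
    animal_meta: pd.DataFrame
    detection_threshold: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.values < 0).any().any():
            raise ValueError("raw metabolite intensities must be nonnegative")
        if "diet" not in self.animal_meta.columns:
            raise ValueError("animal_meta must contain a 'diet' column")
        unknown = set(self.animal_meta["diet"]) - set(DIETS)
        if unknown:
            raise ValueError(f"unknown diet labels: {sorted(unknown)}")
        if not self.values.index.equals(self.animal_meta.index):
            self.animal_meta = self.animal_meta.loc[self.values.index]


@dataclass
class SIVTable:
    """Median-scaled imputed metabolite table.

    ``values`` has no missing entries and every column's median is exactly 1.
    ``imputed`` is a boolean mask marking cells that were filled in rather than
    observed.
    """

    values: pd.DataFrame
    imputed: pd.DataFrame
    animal_meta: pd.DataFrame

    def check(self, tol: float = 1e-12) -> None:
        med = self.values.median(axis=0)
        if not np.allclose(med, 1.0, atol=tol):
            bad = med[np.abs(med - 1.0) > tol]
            raise AssertionError(f"column medians differ from 1: {bad.to_dict()}")


@dataclass
class PathwayGroup:
    """A named set of metabolites acting through one anti-inflammatory pathway.

    Examples in the application domain: flavonoids/isoflavones (apigenin,
    daidzein, genistein, naringenin), glutathione precursors (glycine, cystine,
    N-acetylglycine, gamma-glutamylcysteine), primary/secondary bile acids,
    sialyllactose oligosaccharides, tocopherols, tryptophan indoles, itaconate.
    """

    name: str
    members: list[str]
    anti_inflammatory: bool = True
    citation_note: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway group {self.name!r} has no members")


@dataclass
class GroupSumTable:
    """Per-animal summated SIV per pathway group (animals x groups)."""

    sums: pd.DataFrame
    groups: list[PathwayGroup] = field(default_factory=list)
    missing_members: dict[str, list[str]] = field(default_factory=dict)


def impute_and_scale(raw: RawMetaboliteTable) -> SIVTable:
    """Impute missing cells with the per-metabolite minimum observed value,
    then rescale each column to median 1.

    Raises ``ValueError`` naming any metabolite that was observed in no animal.
    """
    values = raw.values.astype(float)
    all_missing = values.columns[values.isna().all(axis=0)]
    if len(all_missing):
        raise ValueError(
            f"metabolite(s) observed in no animal: {list(all_missing)}"
        )
    imputed = values.isna()
    col_min = values.min(axis=0)
    filled = values.fillna(col_min)
    med = filled.median(axis=0)
    siv = filled / med
    n_imp = int(imputed.values.sum())
    if n_imp:
        logger.info("imputed %d missing cells with per-metabolite minima", n_imp)
    out = SIVTable(values=siv, imputed=imputed, animal_meta=raw.animal_meta.copy())
    out.check()
    return out


def flag_detected(
    raw: RawMetaboliteTable, subset: list[str] | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-cell detection matrix and per-diet detected-compound counts.

    A cell is detected if observed (non-missing) and, when a detection
    threshold is supplied for that metabolite, at or above it.  A compound
    counts as detected in a diet if detected in at least one animal of that
    diet.  ``subset`` restricts the per-diet counting to a designated compound
    list (e.g. plant-derived xenobiotics) without affecting the matrix.
    """
    values = raw.values
    detected = values.notna()
    if raw.detection_threshold is not None:
        thr = raw.detection_threshold.reindex(values.columns)
        detected &= values.ge(thr, axis=1).fillna(False)
    cols = subset if subset is not None else list(values.columns)
    missing_cols = [c for c in cols if c not in values.columns]
    if missing_cols:
        raise KeyError(f"subset compounds absent from table: {missing_cols}")
    diets = raw.animal_meta["diet"]
    counts = {}
    for diet in DIETS:
        animals = diets.index[diets == diet]
        if len(animals) == 0:
            counts[diet] = 0
        else:
            counts[diet] = int(detected.loc[animals, cols].any(axis=0).sum())
    return detected, pd.Series(counts, name="n_detected")


def exclude_outlier_animals(
    siv: SIVTable, k: float = 3.0
) -> tuple[SIVTable, list]:
    """Drop animals whose metabolite profile is a > k-SD outlier in its diet.

    Each animal's summary score is the mean of its per-metabolite z-scores
    (z computed within diet); an animal is excluded when its score deviates
    from the diet-group mean score by more than ``k`` score-SDs.  Refuses to
    reduce any diet group below two animals.
    """
    values = siv.values
    diets = siv.animal_meta["diet"]
    for diet, n in diets.value_counts().items():
        if n < 3:
            raise ValueError(f"need >=3 animals per diet; {diet} has {n}")
    excluded: list = []
    if np.isfinite(k):
        for diet in diets.unique():
            animals = diets.index[diets == diet]
            block = values.loc[animals]
            sd = block.std(axis=0, ddof=1)
            sd = sd.replace(0.0, np.nan)
            z = (block - block.mean(axis=0)) / sd
            score = z.mean(axis=1, skipna=True)
            score_sd = score.std(ddof=1)
            if not np.isfinite(score_sd) or score_sd == 0:
                continue
            flag = (score - score.mean()).abs() > k * score_sd
            excluded.extend(list(animals[flag]))
    if excluded:
        keep = values.index.difference(excluded)
        remaining = diets.loc[keep].value_counts()
        if (remaining < 2).any():
            raise ValueError(
                "outlier exclusion would leave a diet group with <2 animals"
            )
        logger.info("excluded outlier animals (> %.1f SD): %s", k, excluded)
        sub = SIVTable(
            values=values.loc[keep],
            imputed=siv.imputed.loc[keep],
            animal_meta=siv.animal_meta.loc[keep],
        )
        return sub, excluded
    return siv, []


def sum_groups(siv: SIVTable, groups: list[PathwayGroup]) -> GroupSumTable:
    """Per-animal arithmetic sum of member SIVs for each pathway group.

    Members absent from the table are reported in ``missing_members`` (and
    logged), never silently dropped; a group with no resolvable member raises.
    """
    sums = {}
    missing: dict[str, list[str]] = {}
    for g in groups:
        present = [m for m in g.members if m in siv.values.columns]
        absent = [m for m in g.members if m not in siv.values.columns]
        if absent:
            missing[g.name] = absent
            logger.warning("group %s: members absent from table: %s", g.name, absent)
        if not present:
            raise ValueError(f"group {g.name!r} has no members present in the table")
        sums[g.name] = siv.values[present].sum(axis=1)
    return GroupSumTable(sums=pd.DataFrame(sums), groups=list(groups),
                         missing_members=missing)


def percent_difference(mean_a: float, mean_b: float) -> float:
    """Percent by which ``mean_a`` exceeds ``mean_b``: 100*(a/b - 1)."""
    if mean_b <= 0:
        raise ValueError("reference mean must be positive")
    return 100.0 * (mean_a / mean_b - 1.0)


def precursor_to_gsh_ratio(
    group_sums: GroupSumTable, precursor_group: str, gshr_column: pd.Series
) -> pd.Series:
    """Per-animal ratio of summated glutathione-precursor SIV to reduced
    glutathione (GSHr) SIV.

    Animals with nonpositive GSHr are flagged with a warning and returned as
    NaN so that ratio statistics exclude them.
    """
    prec = group_sums.sums[precursor_group]
    gshr = gshr_column.reindex(prec.index)
    bad = gshr <= 0
    if bad.any():
        logger.warning(
            "nonpositive GSHr for animals %s; excluded from ratio",
            list(prec.index[bad]),
        )
    ratio = prec / gshr.where(~bad)
    ratio.name = f"{precursor_group}_to_GSHr"
    return ratio
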