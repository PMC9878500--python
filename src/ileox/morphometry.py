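"""Ileal morphometric indices and nitrotyrosine density summaries.

Works on per-animal measurements extracted upstream from stained sections:
villi per standardized length of tissue, mid-villus width, villus length and
crypt depth (µm), plus nitrotyrosine pixel and nuclei counts per region of
interest.  The relative villus area (RVA) is the three-factor product
width x length x villus density — a relative index of absorptive surface, so
no unit normalization is applied.  Per-animal ratios are computed before any
group averaging.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .metabolome import percent_difference

MORPHO_COLUMNS = [
    "villi_per_unit_length", "mid_villus_width", "villus_length", "crypt_depth",
]


def _check_positive(df: pd.DataFrame, cols: list[str]) -> None:
    for c in cols:
        if (df[c] <= 0).any():
            bad = list(df.index[df[c] <= 0])
            raise ValueError(f"nonpositive {c} for animals {bad}")


def relative_villus_area(records: pd.DataFrame) -> pd.Series:
    """RVA per animal: mid-villus width x villus length x villi per unit length."""
    _check_positive(records, MORPHO_COLUMNS[:3])
    rva = (
        records["mid_villus_width"]
        * records["villus_length"]
        * records["villi_per_unit_length"]
    )
    rva.name = "rva"
    return rva


def villus_crypt_ratio(records: pd.DataFrame) -> pd.Series:
    """Villus length / crypt depth per animal."""
    _check_positive(records, ["villus_length", "crypt_depth"])
    ratio = records["villus_length"] / records["crypt_depth"]
    ratio.name = "villus_crypt_ratio"
    return ratio


def nt_density(pixels: pd.Series, nuclei: pd.Series) -> pd.Series:
    """Nitrotyrosine pixels per cell (pixels / nuclei)."""
    if (nuclei < 1).any():
        raise ValueError("nuclei counts must be >= 1")
    dens = pixels / nuclei
    dens.name = "nt_density"
    return dens


def group_summary(values: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Mean ± SEM per group, plus pairwise percent differences."""
    df = pd.DataFrame({"value": values, "group": groups.loc[values.index]})
    agg = df.groupby("group")["value"].agg(["mean", "sem", "count"])
    return agg


def percent_differences(summary: pd.DataFrame) -> pd.DataFrame:
    """Percent by which each group's mean exceeds each other group's mean."""
    rows = []
    for a in summary.index:
        for b in summary.index:
            if a == b:
                continue
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "percent_difference": percent_difference(
                        float(summary.loc[a, "mean"]), float(summary.loc[b, "mean"])
                    ),
                }
            )
    return pd.DataFrame(rows)


def morphometry_report(records: pd.DataFrame) -> dict:
    """Group summaries of RVA, villus:crypt ratio and villus density."""
    out = {}
    groups = records["diet"]
    for name, series in (
        ("rva", relative_villus_area(records)),
        ("villus_crypt_ratio", villus_crypt_ratio(records)),
        ("villus_density", records["villi_per_unit_length"]),
    ):
        summ = group_summary(series, groups)
        out[name] = {
            "per_group": summ.to_dict(orient="index"),
            "percent_differences": percent_differences(summ).to_dict(
                orient="records"
            ),
        }
    return out
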