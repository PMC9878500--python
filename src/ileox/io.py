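"""Table readers/writers and pipeline configuration.

All tables are UTF-8 TSV with one header row, ``NA`` for missing values and
``.`` as the decimal point; the first column holds identifiers and is never
parsed as a number.  Pathway-group definitions travel as JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from .metabolome import PathwayGroup, RawMetaboliteTable


def read_table(path: str | Path, index_col: int = 0) -> pd.DataFrame:
    """Read a TSV table (NA = missing, first column = identifiers)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    body = header[1:]                  # pandas mangles duplicates, check raw
    dup = sorted({c for c in body if body.count(c) > 1})
    if dup:
        raise ValueError(f"{path}: duplicated column header(s): {dup}")
    return pd.read_csv(path, sep="\t", index_col=index_col, na_values=["NA"],
                       keep_default_na=True, dtype={0: str})


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", na_rep="NA")


def read_metabolite_table(
    values_path: str | Path, meta_path: str | Path,
    thresholds_path: str | Path | None = None,
) -> RawMetaboliteTable:
    values = read_table(values_path)
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise ValueError(f"{values_path}: non-numeric metabolite column: {exc}")
    meta = read_table(meta_path)
    missing = values.index.difference(meta.index)
    if len(missing):
        raise ValueError(f"animals missing from metadata: {list(missing)}")
    thr = None
    if thresholds_path is not None:
        thr = read_table(thresholds_path).iloc[:, 0]
    return RawMetaboliteTable(
        values=values, animal_meta=meta.loc[values.index], detection_threshold=thr
    )


def read_groups(path: str | Path) -> list[PathwayGroup]:
    """Pathway-group definitions from JSON: a list of objects with ``name``,
    ``members``, optional ``anti_inflammatory`` and ``citation_note``."""
    with open(path) as fh:
        raw = json.load(fh)
    groups = []
    for g in raw:
        groups.append(
            PathwayGroup(
                name=g["name"],
                members=list(g["members"]),
                anti_inflammatory=bool(g.get("anti_inflammatory", True)),
                citation_note=g.get("citation_note", ""),
            )
        )
    return groups


def write_groups(groups: list[PathwayGroup], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(
            [
                {
                    "name": g.name,
                    "members": g.members,
                    "anti_inflammatory": g.anti_inflammatory,
                    "citation_note": g.citation_note,
                }
                for g in groups
            ],
            fh,
            indent=1,
        )


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (YAML-loadable).

    Unknown keys in the YAML are rejected so typos never silently fall back
    to defaults.
    """

    metabolites: str = "metabolites.tsv"
    animals: str = "animals.tsv"
    nt: str = "nt.tsv"
    otu: str = "otu.tsv"
    otu_meta: str = "otu_meta.tsv"
    morphometry: str = "morphometry.tsv"
    groups: str | None = None          # groups JSON; None = derive from truth.json
    outdir: str = "report"
    alpha: float = 0.05
    retention_tol: float = 1e-10
    order_rule: str = "corr"
    k_types: int = 5
    mcmc_iters: int = 10_000
    mcmc_burn: int = 10_000
    mcmc_chains: int = 4
    mcmc_thin: int = 10
    outlier_sd: float = 3.0
    seed: int = 0
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)} - {"extras"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(
            {f.name: getattr(self, f.name) for f in fields(self)},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
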