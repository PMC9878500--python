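"""Synthetic study generator.

Emulates the statistical structure of a diet-supplementation trial in a fast
growing broiler-chicken model: three diets (CON = basal feed, NFDM = nonfat
dried-milk control, BC = defatted bovine colostrum), two experiment replicates,
and for each animal

* an ileal-digesta metabolite table (log-normal intensities, diet-specific
  multiplicative effects on planted anti-inflammatory pathway groups,
  left-censored missingness),
* a nitrotyrosine (NT) immunofluorescence readout whose log10 pixels-per-cell
  is linearly and negatively tied to the planted anti-inflammatory index
  (the summed SIVs of the informative groups),
* 16S phylotype count tables with latent community types whose frequencies
  depend on diet (Dirichlet-multinomial draws around type-specific
  compositions), including a segmented-filamentous-bacteria phylotype whose
  mucosa-associated log10 abundance tracks the animal's sialyllactose level,
* ileal morphometry records (villus density, width, length, crypt depth).

Every planted parameter is recorded in a JSON-serializable ``truth`` record so
that downstream recovery can be scored without re-deriving anything.  One RNG
stream per table is derived from the master seed by fixed offsets, so adding a
table never perturbs existing ones; a fixed seed yields bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metabolome as mb
from .metabolome import DIETS, PathwayGroup, RawMetaboliteTable

SFB_NAME = "Candidatus_Arthromitus"
OLIGO_GROUP = "oligosaccharides"
OLIGO_MEMBERS = ["3-sialyllactose", "6-sialyllactose"]

# fixed per-table stream offsets (never renumber)
_STREAMS = {"metabolites": 0, "nt": 2, "otu": 3, "sfb": 4, "morphometry": 5}


def _default_type_frequencies() -> dict[str, list[float]]:
    # BC enriched in types I and IV, CON depleted, mirroring the qualitative
    # diet->community-type shifts the analysis is built to detect
    return {
        "CON": [0.10, 0.30, 0.30, 0.05, 0.25],
        "NFDM": [0.25, 0.30, 0.15, 0.15, 0.15],
        "BC": [0.35, 0.20, 0.05, 0.30, 0.10],
    }


def _default_group_effects(n_groups: int) -> dict[str, dict[str, float]]:
    eff = {}
    for i in range(n_groups):
        eff[f"ai_group_{i + 1}"] = {"CON": 1.0, "NFDM": 1.4, "BC": 2.5}
    return eff


@dataclass
class StudyConfig:
    """Parameters of a synthetic study.  Defaults mirror the study design the
    generator emulates: 11 / 11 / 20 animals (CON/NFDM/BC) pooled over two
    replicates, five community types, ~50k sequences per 16S sample."""

    n_animals_per_diet: dict[str, int] = field(
        default_factory=lambda: {"CON": 11, "NFDM": 11, "BC": 20}
    )
    n_metabolites: int = 120
    n_groups: int = 6                 # informative (index-forming) groups
    n_noise_groups: int = 4           # literature-flagged but inert groups
    members_per_group: int = 3
    group_effect_sizes: dict[str, dict[str, float]] | None = None
    oligo_effect_by_diet: dict[str, float] = field(
        default_factory=lambda: {"CON": 1.0, "NFDM": 2.0, "BC": 5.7}
    )
    log_intensity_sd: float = 0.4     # within-metabolite lognormal sd (ln scale)
    missing_rate: float = 0.15        # left-censoring fraction per metabolite
    nt_intercept: float = 3.0         # log10 pixels/cell at index 0
    nt_slope: float = -0.05           # planted anti-inflammatory-index coefficient
    nt_noise_sd: float = 0.25
    nuclei_mean: int = 200
    n_phylotypes: int = 100
    n_community_types: int = 5
    type_frequency_by_diet: dict[str, list[float]] | None = None
    dirichlet_concentration: float = 200.0
    sequencing_depth: int = 50_000
    sites: tuple[str, ...] = ("ileum",)
    fractions: tuple[str, ...] = ("digesta", "scraping")
    sfb_intercept: float = 1.0        # log10 count at zero oligosaccharide SIV sum
    sfb_oligo_slope: float = 0.8
    sfb_noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_effect_sizes is None:
            self.group_effect_sizes = _default_group_effects(self.n_groups)
        if self.type_frequency_by_diet is None:
            if self.n_community_types == 5:
                self.type_frequency_by_diet = _default_type_frequencies()
            else:
                k = self.n_community_types
                self.type_frequency_by_diet = {d: [1.0 / k] * k for d in DIETS}
        self.validate()

    def validate(self) -> None:
        for d, n in self.n_animals_per_diet.items():
            if n <= 0:
                raise ValueError(f"n_animals_per_diet[{d}] must be positive")
        for name, n in [
            ("n_metabolites", self.n_metabolites),
            ("n_groups", self.n_groups),
            ("members_per_group", self.members_per_group),
            ("n_phylotypes", self.n_phylotypes),
            ("n_community_types", self.n_community_types),
            ("sequencing_depth", self.sequencing_depth),
        ]:
            if n <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be positive")
        for d, freq in self.type_frequency_by_diet.items():
            freq = np.asarray(freq, float)
            if len(freq) != self.n_community_types:
                raise ValueError(f"type frequencies for {d}: wrong length")
            if (freq < 0).any() or abs(freq.sum() - 1.0) > 1e-12:
                raise ValueError(f"type frequencies for {d} are not a simplex")
        needed = (self.n_groups + self.n_noise_groups) * self.members_per_group
        if self.n_metabolites < needed + len(OLIGO_MEMBERS):
            raise ValueError(
                f"n_metabolites={self.n_metabolites} too small for "
                f"{needed + len(OLIGO_MEMBERS)} group members"
            )

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])


@dataclass
class SyntheticStudy:
    """All tables of one synthetic study plus the planted-parameter record."""

    metabolite_table: RawMetaboliteTable
    nt_table: pd.DataFrame            # animal x (nt_pixels, nuclei)
    otu_table: pd.DataFrame           # sample x phylotype counts
    otu_meta: pd.DataFrame            # sample x (animal, diet, site, fraction)
    morphometry_table: pd.DataFrame
    truth: dict

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.metabolite_table.values.to_csv(
            outdir / "metabolites.tsv", sep="\t", na_rep="NA"
        )
        self.metabolite_table.animal_meta.to_csv(outdir / "animals.tsv", sep="\t")
        self.nt_table.to_csv(outdir / "nt.tsv", sep="\t")
        self.otu_table.to_csv(outdir / "otu.tsv", sep="\t")
        self.otu_meta.to_csv(outdir / "otu_meta.tsv", sep="\t")
        self.morphometry_table.to_csv(outdir / "morphometry.tsv", sep="\t")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


def _planted_groups(config: StudyConfig) -> tuple[list[PathwayGroup], dict]:
    """Assign metabolite identifiers to informative, noise, and oligo groups."""
    mets = [f"met_{i + 1:04d}" for i in range(config.n_metabolites)]
    groups: list[PathwayGroup] = []
    membership: dict[str, list[str]] = {}
    cursor = 0
    for i in range(config.n_groups):
        name = f"ai_group_{i + 1}"
        members = mets[cursor : cursor + config.members_per_group]
        cursor += config.members_per_group
        groups.append(PathwayGroup(name, members, anti_inflammatory=True))
        membership[name] = members
    for i in range(config.n_noise_groups):
        name = f"noise_group_{i + 1}"
        members = mets[cursor : cursor + config.members_per_group]
        cursor += config.members_per_group
        groups.append(PathwayGroup(name, members, anti_inflammatory=True))
        membership[name] = members
    # sialyllactoses: diet-affected, SFB-linked, but not index-forming
    mets[cursor] = OLIGO_MEMBERS[0]
    mets[cursor + 1] = OLIGO_MEMBERS[1]
    groups.append(PathwayGroup(OLIGO_GROUP, list(OLIGO_MEMBERS),
                               anti_inflammatory=True))
    membership[OLIGO_GROUP] = list(OLIGO_MEMBERS)
    return groups, {"metabolites": mets, "membership": membership}


def generate_study(config: StudyConfig) -> SyntheticStudy:
    """Draw a full synthetic study; identical config+seed => identical output."""
    groups, plan = _planted_groups(config)
    mets = plan["metabolites"]
    membership = plan["membership"]

    animals, diets, replicates = [], [], []
    for diet in DIETS:
        n = config.n_animals_per_diet.get(diet, 0)
        for j in range(n):
            animals.append(f"{diet}_{j + 1:02d}")
            diets.append(diet)
            replicates.append(1 + (j % 2))
    animal_meta = pd.DataFrame(
        {"diet": diets, "replicate": replicates,
         "colostrum_source": ["none"] * len(animals)},
        index=pd.Index(animals, name="animal"),
    )

    # --- metabolite intensities -------------------------------------------
    rng = config.rng("metabolites")
    n_a, n_m = len(animals), config.n_metabolites
    base_log = rng.normal(np.log(1e6), 1.0, size=n_m)          # per-metabolite level
    log_x = base_log[None, :] + rng.normal(0.0, config.log_intensity_sd,
                                           size=(n_a, n_m))
    effects = dict(config.group_effect_sizes)
    effects[OLIGO_GROUP] = config.oligo_effect_by_diet
    col_of = {m: j for j, m in enumerate(mets)}
    diet_arr = np.asarray(diets)
    for gname, diet_mult in effects.items():
        if gname not in membership:
            raise ValueError(f"effect for unknown group {gname!r}")
        cols = [col_of[m] for m in membership[gname]]
        for diet, mult in diet_mult.items():
            if mult <= 0:
                raise ValueError("effect multipliers must be positive")
            rows = np.where(diet_arr == diet)[0]
            log_x[np.ix_(rows, cols)] += np.log(mult)
    values = pd.DataFrame(np.exp(log_x), index=animal_meta.index, columns=mets)

    # left-censored missingness: censor below each metabolite's rate-quantile
    if config.missing_rate > 0:
        lod = values.quantile(config.missing_rate, axis=0)
        values = values.where(values.ge(lod, axis=1))
    raw = RawMetaboliteTable(values=values, animal_meta=animal_meta)

    # --- planted anti-inflammatory index (from the real SIV pipeline) ------
    siv = mb.impute_and_scale(raw)
    sums = mb.sum_groups(siv, groups)
    informative = [g.name for g in groups if g.name.startswith("ai_group_")]
    true_index = sums.sums[informative].sum(axis=1)
    oligo_sum = sums.sums[OLIGO_GROUP]

    # --- NT readout --------------------------------------------------------
    rng = config.rng("nt")
    log10_nt = (
        config.nt_intercept
        + config.nt_slope * true_index.values
        + (rng.normal(0.0, config.nt_noise_sd, size=n_a)
           if config.nt_noise_sd > 0 else 0.0)
    )
    nuclei = rng.poisson(config.nuclei_mean, size=n_a) + 1
    # pixels kept real-valued so pixels/nuclei reproduces the planted density
    # exactly; a real imaging assay would round to integer pixels
    nt_table = pd.DataFrame(
        {"nt_pixels": (10.0 ** log10_nt) * nuclei, "nuclei": nuclei},
        index=animal_meta.index,
    )

    # --- OTU counts with latent community types ----------------------------
    rng = config.rng("otu")
    K, P = config.n_community_types, config.n_phylotypes
    phylotypes = [f"otu_{i + 1:04d}" for i in range(P - 1)] + [SFB_NAME]
    # well-separated base compositions: each type dominated by its own block
    block = max(P // (K + 1), 1)
    base = np.full((K, P), 0.1 / P)
    for k in range(K):
        lo = k * block
        base[k, lo : lo + block] += 0.9 / block
    base /= base.sum(axis=1, keepdims=True)

    sample_ids, sample_rows, s_animal, s_diet, s_site, s_frac, s_type = (
        [], [], [], [], [], [], []
    )
    for a, diet in zip(animals, diets):
        for site in config.sites:
            for frac in config.fractions:
                freq = np.asarray(config.type_frequency_by_diet[diet], float)
                t = int(rng.choice(K, p=freq))
                comp = rng.dirichlet(config.dirichlet_concentration * base[t])
                counts = rng.multinomial(config.sequencing_depth, comp)
                sample_ids.append(f"{a}_{site}_{frac}")
                sample_rows.append(counts)
                s_animal.append(a)
                s_diet.append(diet)
                s_site.append(site)
                s_frac.append(frac)
                s_type.append(t + 1)
    otu = pd.DataFrame(
        np.vstack(sample_rows),
        index=pd.Index(sample_ids, name="sample"),
        columns=phylotypes,
    )
    otu_meta = pd.DataFrame(
        {"animal": s_animal, "diet": s_diet, "site": s_site,
         "fraction": s_frac, "true_type": s_type},
        index=otu.index,
    )

    # --- SFB tied to sialyllactose level (mucosa-associated samples) -------
    rng = config.rng("sfb")
    sfb_log10 = {}
    for a in animals:
        noise = rng.normal(0.0, config.sfb_noise_sd) if config.sfb_noise_sd > 0 else 0.0
        sfb_log10[a] = config.sfb_intercept + config.sfb_oligo_slope * float(
            oligo_sum[a]
        ) + noise
    scrape = otu_meta.index[
        (otu_meta["site"] == "ileum") & (otu_meta["fraction"] == "scraping")
    ]
    for s in scrape:
        a = otu_meta.loc[s, "animal"]
        otu.loc[s, SFB_NAME] = int(round(10.0 ** sfb_log10[a]))

    # --- morphometry -------------------------------------------------------
    rng = config.rng("morphometry")
    morpho_means = {
        # villi per standardized length, mid-villus width, villus length,
        # crypt depth (µm): colostrum raises villus density and crypt depth
        "CON": (4.0, 50.0, 265.0, 28.0),
        "NFDM": (3.8, 50.0, 280.0, 31.0),
        "BC": (5.0, 55.0, 250.0, 37.0),
    }
    rows = []
    for a, diet in zip(animals, diets):
        v, w, l, c = morpho_means[diet]
        rows.append(
            {
                "animal": a,
                "diet": diet,
                "villi_per_unit_length": max(rng.normal(v, 0.05 * v), 0.5),
                "mid_villus_width": max(rng.normal(w, 0.05 * w), 5.0),
                "villus_length": max(rng.normal(l, 0.05 * l), 20.0),
                "crypt_depth": max(rng.normal(c, 0.05 * c), 3.0),
            }
        )
    morphometry = pd.DataFrame(rows).set_index("animal")

    truth = {
        "seed": config.seed,
        "membership": membership,
        "informative_groups": informative,
        "noise_groups": [g.name for g in groups
                         if g.name.startswith("noise_group_")],
        "oligo_group": OLIGO_GROUP,
        "true_index": {a: float(v) for a, v in true_index.items()},
        "oligo_sum": {a: float(v) for a, v in oligo_sum.items()},
        "nt_intercept": config.nt_intercept,
        "nt_slope": config.nt_slope,
        "nt_noise_sd": config.nt_noise_sd,
        "log10_nt": {a: float(v) for a, v in zip(animals, log10_nt)},
        "type_labels": {s: int(t) for s, t in zip(sample_ids, s_type)},
        "type_frequency_by_diet": {
            d: list(map(float, f)) for d, f in config.type_frequency_by_diet.items()
        },
        "sfb_intercept": config.sfb_intercept,
        "sfb_oligo_slope": config.sfb_oligo_slope,
        "sfb_log10": {a: float(v) for a, v in sfb_log10.items()},
        "group_effect_sizes": effects,
    }
    return SyntheticStudy(
        metabolite_table=raw,
        nt_table=nt_table,
        otu_table=otu,
        otu_meta=otu_meta,
        morphometry_table=morphometry,
        truth=truth,
    )
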