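"""Seeded generator of MaxQuant-dialect synthetic proteomics datasets.

Emulates the design of a three-group renal-tissue study (chromophobe renal
cell carcinoma, renal oncocytoma, normal adjacent tissue): 5 biopsies per
group, each run twice on the instrument, so 30 runs in total.  Per protein
the log2 intensity of run r is

    baseline_i + shift_{i,g(r)} + bio_{i,b(r)} + tech_{i,r}

with a protein baseline drawn from a Normal distribution, pathway-structured
group shifts, biological noise shared by the two technical replicates of a
biopsy, and independent technical noise.  Cells are then masked missing
with probability ``logistic((mnar_midpoint - log2 intensity) * mnar_slope)``
— the missing-not-at-random, left-censored pattern of label-free data.
Decoy (reverse) and contaminant rows draw intensities from the same
baseline distribution so that only the flag filter removes them.

Default parameters put the generator in the regime the analysis assumes:
roughly 15% missing cells overall and ~85% of genuine proteins passing the
70%-in-one-group validity filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mq_io import PathwaySets, ProteinTable, SampleDesign

DEFAULT_GROUPS = ("chRCC", "RO", "NAT")


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Group shifts are given by ``effect_table``: pathway label -> {group ->
    mean log2 shift}; member proteins of that pathway get the shift in that
    group.  ``effect_sd`` adds a per-protein deviation around the pathway
    mean shift; with ``effect_shared=True`` the deviation is drawn once per
    protein and applied in every shifted group (tumors dysregulate the same
    proteins by similar amounts), with ``False`` it is drawn independently
    per group.
    """

    n_proteins: int = 1600
    groups: tuple[str, ...] = DEFAULT_GROUPS
    n_bio: int = 5
    n_tech: int = 2
    mw_log_mean: float = math.log(45.0)   # kDa, log-normal location
    mw_log_sd: float = 0.55
    base_log2_intensity_mean: float = 23.0
    base_log2_intensity_sd: float = 2.0
    effect_table: dict[str, dict[str, float]] = field(default_factory=dict)
    pathway_sizes: dict[str, int] = field(default_factory=dict)
    effect_sd: float = 0.0
    effect_shared: bool = True
    sigma_bio: float = 0.35
    sigma_tech: float = 0.15
    mnar_midpoint: float = 20.6
    mnar_slope: float = 2.0
    frac_decoy: float = 0.05
    frac_contaminant: float = 0.02
    frac_only_by_site: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_proteins", "n_bio", "n_tech"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        if len(self.groups) < 1:
            raise ConfigError("groups must contain at least one label")
        if len(set(self.groups)) != len(self.groups):
            raise ConfigError("groups contains duplicate labels")
        for name in ("mw_log_sd", "base_log2_intensity_sd", "sigma_bio",
                     "sigma_tech", "effect_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("frac_decoy", "frac_contaminant", "frac_only_by_site"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {getattr(self, name)}")
        for pw, shifts in self.effect_table.items():
            for g in shifts:
                if g not in self.groups:
                    raise ConfigError(f"effect_table[{pw!r}] refers to unknown group {g!r}")
        sizes = {pw: self.pathway_sizes.get(pw, 50) for pw in self.effect_table}
        if sum(sizes.values()) > self.n_proteins:
            raise ConfigError("pathway_sizes exceed n_proteins")

    @property
    def n_runs(self) -> int:
        return len(self.groups) * self.n_bio * self.n_tech


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset."""

    group_means: pd.DataFrame          # proteins x groups, true log2 means
    shifts: pd.DataFrame               # proteins x groups, planted shifts
    memberships: dict[str, list[str]]  # pathway -> member protein ids

    def differential(self, group_a: str, group_b: str) -> set[str]:
        """Proteins with a nonzero planted shift difference between groups."""
        diff = self.shifts[group_a] - self.shifts[group_b]
        return set(diff.index[diff != 0])


def generate_dataset(config: SimConfig
                     ) -> tuple[ProteinTable, SampleDesign, PathwaySets, SimTruth]:
    """Generate (protein table, run design, pathway sets, ground truth)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    ids = pd.Index([f"SP{i:05d}" for i in range(n)], name="protein_id")
    genes = pd.Series([f"GENE{i}" for i in range(n)], index=ids)

    # design: run ids <group>_b<bio>_t<tech>
    rows = []
    for g in config.groups:
        for b in range(1, config.n_bio + 1):
            for t in range(1, config.n_tech + 1):
                rows.append({"run": f"{g}_b{b}_t{t}", "group": g,
                             "bio_rep": b, "tech_rep": t})
    design = SampleDesign(pd.DataFrame(rows))
    runs = design.runs

    # pathway memberships: consecutive non-overlapping blocks
    memberships: dict[str, list[str]] = {}
    cursor = 0
    for pw in config.effect_table:
        size = config.pathway_sizes.get(pw, 50)
        memberships[pw] = list(ids[cursor:cursor + size])
        cursor += size

    # planted shifts
    shifts = pd.DataFrame(0.0, index=ids, columns=list(config.groups))
    for pw, table in config.effect_table.items():
        members = memberships[pw]
        dev_shared = rng.normal(0.0, config.effect_sd, size=len(members)) \
            if config.effect_sd > 0 else np.zeros(len(members))
        for g, mean_shift in table.items():
            if mean_shift == 0:
                continue
            dev = dev_shared if config.effect_shared else (
                rng.normal(0.0, config.effect_sd, size=len(members))
                if config.effect_sd > 0 else np.zeros(len(members)))
            shifts.loc[members, g] = mean_shift + dev

    baseline = rng.normal(config.base_log2_intensity_mean,
                          config.base_log2_intensity_sd, size=n)
    mw_kda = pd.Series(np.exp(rng.normal(config.mw_log_mean, config.mw_log_sd,
                                         size=n)), index=ids)
    group_means = shifts.add(baseline, axis=0)

    # per-(protein, biopsy) biological effect, shared by technical replicates
    n_bio_total = len(config.groups) * config.n_bio
    bio = rng.normal(0.0, config.sigma_bio, size=(n, n_bio_total))
    log2i = np.empty((n, len(runs)))
    for j, run in enumerate(runs):
        row = design.frame.iloc[j]
        g = row["group"]
        bio_index = list(config.groups).index(g) * config.n_bio + (row["bio_rep"] - 1)
        log2i[:, j] = (group_means[g].values + bio[:, bio_index]
                       + rng.normal(0.0, config.sigma_tech, size=n))

    # missing-not-at-random mask
    if config.mnar_slope > 0:
        p_miss = 1.0 / (1.0 + np.exp(-(config.mnar_midpoint - log2i)
                                     * config.mnar_slope))
        mask = rng.random(size=log2i.shape) < p_miss
    else:
        mask = np.zeros_like(log2i, dtype=bool)

    inten = np.power(2.0, log2i)
    inten[mask] = np.nan
    intensities = pd.DataFrame(inten, index=ids, columns=runs)

    # flag-only rows: decoys / contaminants from the same baseline law
    n_decoy = round(config.frac_decoy * n)
    n_cont = round(config.frac_contaminant * n)
    n_site = round(config.frac_only_by_site * n)

    def extra_rows(count: int, prefix: str):
        xids = [f"{prefix}SP{90000 + k:05d}" for k in range(count)]
        base = rng.normal(config.base_log2_intensity_mean,
                          config.base_log2_intensity_sd, size=count)
        xlog2 = (base[:, None]
                 + rng.normal(0.0, config.sigma_tech, size=(count, len(runs))))
        vals = np.power(2.0, xlog2)
        if config.mnar_slope > 0:
            p = 1.0 / (1.0 + np.exp(-(config.mnar_midpoint - xlog2)
                                    * config.mnar_slope))
            vals[rng.random(size=vals.shape) < p] = np.nan
        mw = np.exp(rng.normal(config.mw_log_mean, config.mw_log_sd, size=count))
        return xids, vals, mw

    all_ids = list(ids)
    all_genes = list(genes)
    all_mw = list(mw_kda)
    blocks = [intensities.values]
    flags = {"reverse": [False] * n, "contaminant": [False] * n,
             "only_by_site": [False] * n}
    for count, prefix, flagname in ((n_decoy, "REV__", "reverse"),
                                    (n_cont, "CON__", "contaminant"),
                                    (n_site, "SITE__", "only_by_site")):
        xids, vals, mw = extra_rows(count, prefix)
        all_ids += xids
        all_genes += [""] * count
        all_mw += list(mw)
        blocks.append(vals)
        for name in flags:
            flags[name] += [name == flagname] * count

    full_ids = pd.Index(all_ids, name="protein_id")
    table = ProteinTable(
        protein_id=full_ids,
        gene_name=pd.Series(all_genes, index=full_ids),
        mw_kda=pd.Series(all_mw, index=full_ids),
        intensities=pd.DataFrame(np.vstack(blocks), index=full_ids, columns=runs),
        reverse=pd.Series(flags["reverse"], index=full_ids),
        contaminant=pd.Series(flags["contaminant"], index=full_ids),
        only_by_site=pd.Series(flags["only_by_site"], index=full_ids),
    )
    pathway_sets = PathwaySets(
        sets={pw: set(genes[m] for m in members) or set(members)
              for pw, members in memberships.items() if members},
        descriptions={pw: "synthetic pathway" for pw in memberships if memberships[pw]},
    ) if memberships else PathwaySets(sets={}, descriptions={})
    truth = SimTruth(group_means=group_means, shifts=shifts,
                     memberships=memberships)
    return table, design, pathway_sets, truth


def missingness_rate(table: ProteinTable) -> tuple[pd.Series, float]:
    """(fraction of missing cells per run, overall fraction)."""
    if len(table) == 0 or not table.runs:
        raise ValueError("empty protein table")
    miss = table.intensities.isna()
    return miss.mean(axis=0), float(miss.values.mean())


def study_like_config(seed: int = 0, **overrides) -> SimConfig:
    """A default study-shaped configuration with pathway-structured effects.

    Plants four metabolic pathways: two dysregulated concordantly in both
    tumor groups (down- and upregulated relative to NAT), one dysregulated
    more strongly in one tumor, and one null pathway, with per-protein
    heterogeneity shared across tumors.
    """
    params = dict(
        effect_table={
            "GLUCONEOGENESIS": {"chRCC": -1.2, "RO": -1.2},
            "TCA_CYCLE": {"chRCC": 0.9, "RO": 0.9},
            "OXPHOS": {"chRCC": -0.5, "RO": -1.0},
            "RIBOSOME": {},
        },
        pathway_sizes={"GLUCONEOGENESIS": 40, "TCA_CYCLE": 40,
                       "OXPHOS": 60, "RIBOSOME": 40},
        effect_sd=0.4,
        effect_shared=True,
        seed=seed,
    )
    params.update(overrides)
    return SimConfig(**params)
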