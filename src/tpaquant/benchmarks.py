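"""Self-contained benchmark scenarios exercising the pipeline end to end.

Each function builds seeded synthetic data with :mod:`tpaquant.synthdata`,
runs the relevant part of the analysis, and returns the measured quantity:
false-discovery control on pure-null data, recovery of a planted pathway
shift, concordance of cross-contrast pathway correlations with the planted
sharing structure, and the empirical law of the downshifted-Gaussian
imputation.  They back both the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diffstats import permutation_fdr_test, quantified_fraction
from .pathways import cross_contrast_correlation
from .quantify import Log2Matrix, impute_downshift, log2_transform, tpa_concentrations
from .synthdata import SimConfig, generate_dataset

from .mq_io import SampleDesign


def _clean_config(**kwargs) -> SimConfig:
    """Simulation config without flag-only rows (statistics-only scenarios)."""
    kwargs.setdefault("frac_decoy", 0.0)
    kwargs.setdefault("frac_contaminant", 0.0)
    kwargs.setdefault("frac_only_by_site", 0.0)
    return SimConfig(**kwargs)


def _log2_tpa(table) -> Log2Matrix:
    return log2_transform(tpa_concentrations(table))


def null_fdr_fractions(n_seeds: int = 20, n_proteins: int = 1000,
                       fdr: float = 0.01, s0: float = 0.1,
                       n_perm: int = 250, base_seed: int = 0) -> list[float]:
    """Fraction of proteins called significant on pure-null data, per seed.

    Three groups of 5 biopsies x 2 technical replicates, no planted
    effects, no missingness; tests one tumor group against the reference.
    """
    fractions = []
    for i in range(n_seeds):
        seed = base_seed + i
        config = _clean_config(n_proteins=n_proteins, seed=seed,
                               mnar_slope=0.0)
        table, design, _, _ = generate_dataset(config)
        res = permutation_fdr_test(_log2_tpa(table), design, "chRCC", "NAT",
                                   fdr=fdr, s0=s0, n_perm=n_perm, seed=seed)
        fractions.append(len(res.significant) / n_proteins)
    return fractions


def planted_recovery(n_seeds: int = 10, n_proteins: int = 1000,
                     pathway_size: int = 50, shift: float = 1.0,
                     sigma: float = 0.2, fdr: float = 0.01, s0: float = 0.1,
                     n_perm: int = 250, base_seed: int = 0
                     ) -> tuple[list[float], list[float]]:
    """Sensitivity for a pathway planted up in one tumor group, per seed.

    Returns (sensitivities, direction-correct fractions among detected).
    """
    sens, direction_ok = [], []
    for i in range(n_seeds):
        seed = base_seed + i
        config = _clean_config(
            n_proteins=n_proteins, seed=seed, mnar_slope=0.0,
            sigma_bio=sigma, sigma_tech=sigma,
            effect_table={"PW": {"chRCC": shift}},
            pathway_sizes={"PW": pathway_size})
        table, design, _, truth = generate_dataset(config)
        res = permutation_fdr_test(_log2_tpa(table), design, "chRCC", "NAT",
                                   fdr=fdr, s0=s0, n_perm=n_perm, seed=seed)
        planted = truth.differential("chRCC", "NAT")
        detected = set(res.significant) & planted
        sens.append(len(detected) / len(planted))
        up = res.direction_set("up")
        direction_ok.append(
            sum(p in up for p in detected) / len(detected) if detected
            else float("nan"))
    return sens, direction_ok


def crosscontrast_pathway_r(shared: bool, n_seeds: int = 10,
                            n_proteins: int = 1000, pathway_size: int = 50,
                            shift: float = 1.0, effect_sd: float = 0.5,
                            sigma: float = 0.2, n_perm: int = 250,
                            base_seed: int = 0) -> list[float]:
    """Pathway-level Pearson r between the two tumor contrasts, per seed.

    With ``shared=True`` the per-protein planted shifts are identical in
    both tumor groups; with ``False`` they are drawn independently per
    group, so the two contrasts' fold changes should decorrelate.
    """
    rs = []
    for i in range(n_seeds):
        seed = base_seed + i
        config = _clean_config(
            n_proteins=n_proteins, seed=seed, mnar_slope=0.0,
            sigma_bio=sigma, sigma_tech=sigma,
            effect_table={"PW": {"chRCC": shift, "RO": shift}},
            pathway_sizes={"PW": pathway_size},
            effect_sd=effect_sd, effect_shared=shared)
        table, design, _, truth = generate_dataset(config)
        log2m = _log2_tpa(table)
        res_a = permutation_fdr_test(log2m, design, "chRCC", "NAT",
                                     n_perm=n_perm, seed=seed)
        res_b = permutation_fdr_test(log2m, design, "RO", "NAT",
                                     n_perm=n_perm, seed=seed)
        out = cross_contrast_correlation(
            res_a.table["log2fc"], res_b.table["log2fc"],
            {"PW": truth.memberships["PW"]}, restrict="either",
            significant_a=set(res_a.significant),
            significant_b=set(res_b.significant))
        rs.append(float(out["r"].iloc[0]))
    return rs


def imputation_law(n_obs: int = 150_000, n_miss: int = 120_000,
                   mu: float = 20.0, sigma: float = 2.0,
                   width: float = 0.5, downshift: float = 1.8,
                   seed: int = 0) -> tuple[float, float, int]:
    """(empirical mean, SD, count) of imputed cells for a matrix whose
    observed cells have sample mean ``mu`` and sample SD ``sigma`` exactly
    (the generated draws are affinely standardized to those moments)."""
    rng = np.random.default_rng(seed)
    obs = rng.normal(size=n_obs)
    obs = (obs - obs.mean()) / obs.std(ddof=1) * sigma + mu
    vals = np.concatenate([obs, np.full(n_miss, np.nan)])
    rng.shuffle(vals)
    n_col = 300
    n_row = vals.size // n_col
    frame = pd.DataFrame(vals[: n_row * n_col].reshape(n_row, n_col),
                         columns=[f"r{i}" for i in range(n_col)])
    log2m = Log2Matrix(values=frame)
    miss_mask = frame.isna().values
    out = impute_downshift(log2m, width=width, downshift=downshift,
                           seed=seed + 1)
    imputed = out.values.values[miss_mask]
    return float(imputed.mean()), float(imputed.std(ddof=1)), imputed.size


def quantified_fraction_example(n_pass: int = 1379, n_total: int = 1610,
                                ) -> tuple[int, int, float]:
    """Quantified-fraction summary on a constructed table where exactly
    ``n_pass`` of ``n_total`` proteins meet the 70%-in-one-group rule
    (passing rows fully observed, failing rows present in 6 of 10 runs of
    every group)."""
    design_rows = []
    for g in ("chRCC", "RO", "NAT"):
        for b in range(1, 6):
            for t in (1, 2):
                design_rows.append({"run": f"{g}_b{b}_t{t}", "group": g,
                                    "bio_rep": b, "tech_rep": t})
    design = SampleDesign(pd.DataFrame(design_rows))
    runs = design.runs
    ids = pd.Index([f"SP{i:05d}" for i in range(n_total)], name="protein_id")
    values = np.ones((n_total, len(runs)))
    for g in ("chRCC", "RO", "NAT"):
        group_runs = [runs.index(r) for r in design.runs_for(g)]
        for j in group_runs[6:]:  # failing rows: 6 of 10 present per group
            values[n_pass:, j] = np.nan
    from .mq_io import ProteinTable
    table = ProteinTable(
        protein_id=ids,
        gene_name=pd.Series("", index=ids),
        mw_kda=pd.Series(50.0, index=ids),
        intensities=pd.DataFrame(values, index=ids, columns=runs),
        reverse=pd.Series(False, index=ids),
        contaminant=pd.Series(False, index=ids),
        only_by_site=pd.Series(False, index=ids),
    )
    return quantified_fraction(table, design, min_frac=0.7)
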