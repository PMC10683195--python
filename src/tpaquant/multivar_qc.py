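"""Replicate-reproducibility diagnostics: Pearson correlation and PCA.

Correlation is computed on the filtered, pre-imputation log2 matrix using
pairwise-complete observations (the matrix still carries missing cells at
that stage).  PCA runs on the filtered and imputed matrix, centred per
protein and unscaled, with a fixed sign convention (the largest-magnitude
loading of each component is positive) so that scores are reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .mq_io import SampleDesign
from .quantify import Log2Matrix

log = logging.getLogger(__name__)


class QCError(ValueError):
    pass


@dataclass
class CorrelationMatrix:
    """Runs x runs Pearson r plus the per-pair count of complete pairs."""

    r: pd.DataFrame
    n: pd.DataFrame


@dataclass
class PCAResult:
    scores: pd.DataFrame                 # runs x components
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame               # proteins x components


def pearson_matrix(log2m: Log2Matrix, pairwise_complete: bool = True,
                   min_obs: int = 3) -> CorrelationMatrix:
    """Run-by-run Pearson correlation of log2 values.

    With ``pairwise_complete`` each pair uses the cells observed in both
    runs; pairs with fewer than ``min_obs`` complete observations get a
    missing entry and a warning.  Complete-case mode drops every protein
    with any missing cell first.
    """
    values = log2m.values
    if values.shape[1] < 2:
        raise QCError("need >= 2 runs")
    if not pairwise_complete:
        values = values.dropna(axis=0)
    present = values.notna()
    n = present.T.astype(int) @ present.astype(int)
    r = values.corr(method="pearson", min_periods=min_obs)
    too_few = (n < min_obs) & ~np.eye(len(n), dtype=bool)
    if too_few.values.any():
        pairs = [(a, b) for a, b in zip(*np.where(too_few.values)) if a < b]
        warnings.warn(f"{len(pairs)} run pair(s) have < {min_obs} complete "
                      "observations; entries left missing")
    np.fill_diagonal(r.values, 1.0)
    return CorrelationMatrix(r=r, n=n)


def pca_scores(log2m: Log2Matrix, k: int = 2, center: str = "protein",
               scale: bool = False) -> PCAResult:
    """Project runs on the top-k principal axes of the run-by-protein matrix.

    Requires a complete (imputed) matrix.  Centring is per protein
    (feature); unit-variance scaling is off by default.  Component signs
    follow the convention that each component's largest-|loading| entry is
    positive.
    """
    values = log2m.values
    if values.isna().any().any():
        raise QCError("matrix contains missing values; impute first")
    n_runs, n_prot = values.shape[1], values.shape[0]
    if not 1 <= k <= min(n_runs - 1, n_prot):
        raise QCError(f"k={k} out of range for {n_runs} runs x {n_prot} proteins")
    X = values.T.values.astype(float)  # runs x proteins
    if center != "protein":
        raise QCError(f"unknown centering mode {center!r}")
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # proteins x k
    for j in range(k):
        i_max = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_max, j] < 0:
            loadings[:, j] = -loadings[:, j]
            scores[:, j] = -scores[:, j]
    cols = [f"PC{j + 1}" for j in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=values.columns, columns=cols),
        explained_variance_ratio=pca.explained_variance_ratio_,
        loadings=pd.DataFrame(loadings, index=values.index, columns=cols),
    )


def group_block_summary(corr: CorrelationMatrix,
                        design: SampleDesign) -> pd.DataFrame:
    """Min/mean/max Pearson r per group-pair block, diagonal excluded."""
    groups = design.groups()
    rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i:]:
            runs_a = design.runs_for(ga)
            runs_b = design.runs_for(gb)
            block = corr.r.loc[runs_a, runs_b].values.astype(float)
            if ga == gb:
                iu = np.triu_indices(len(runs_a), k=1)
                vals = block[iu]
            else:
                vals = block.ravel()
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                warnings.warn(f"block ({ga}, {gb}) has no off-diagonal pairs")
                rows.append({"group_a": ga, "group_b": gb, "n_pairs": 0,
                             "r_min": np.nan, "r_mean": np.nan, "r_max": np.nan})
                continue
            rows.append({"group_a": ga, "group_b": gb, "n_pairs": len(vals),
                         "r_min": vals.min(), "r_mean": vals.mean(),
                         "r_max": vals.max()})
    return pd.DataFrame(rows)


def replicate_block_summary(corr: CorrelationMatrix,
                            design: SampleDesign) -> pd.DataFrame:
    """Mean r among technical-replicate pairs (same biopsy) vs biological
    pairs (same group, different biopsy) vs between-group pairs."""
    frame = design.frame.set_index("run")
    buckets: dict[str, list[float]] = {"technical": [], "biological": [],
                                       "between_group": []}
    for ra, rb in combinations(corr.r.columns, 2):
        r = corr.r.loc[ra, rb]
        if np.isnan(r):
            continue
        a, b = frame.loc[ra], frame.loc[rb]
        if a["group"] != b["group"]:
            buckets["between_group"].append(r)
        elif a["bio_rep"] == b["bio_rep"]:
            buckets["technical"].append(r)
        else:
            buckets["biological"].append(r)
    rows = [{"level": level, "n_pairs": len(vals),
             "r_mean": float(np.mean(vals)) if vals else np.nan}
            for level, vals in buckets.items()]
    return pd.DataFrame(rows)
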