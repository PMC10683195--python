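"""Contrast statistics: S0-moderated t-test with permutation FDR.

The volcano-style test is the SAM/Perseus two-sample statistic: a pooled
two-sample Student t with a constant ``s0`` added to the denominator,

    t_mod = (mean(x) - mean(y)) / (s_pooled * sqrt(1/n_x + 1/n_y) + s0),

which damps the significance of small-variance, small-effect proteins.
Significance is controlled by a permutation-based FDR: the null
distribution of |t_mod| is built by re-labelling samples between the two
groups; for each candidate threshold tau (the observed |t_mod| values) the
FDR is estimated as (mean null count of |t| >= tau) / (observed count >=
tau), and the significance set is the largest one whose estimated FDR stays
at or below the nominal level.

Also here: log2 fold changes (difference of group-mean log2 values), Venn
overlap summaries between two contrasts, pairwise Mann-Whitney comparisons
of absolute concentrations, and the quantified-fraction summary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .mq_io import ProteinTable, SampleDesign
from .quantify import ConcentrationMatrix, Log2Matrix, validity_mask

log = logging.getLogger(__name__)

# star labels for pairwise Mann-Whitney comparisons
STAR_THRESHOLDS = ((1e-5, "****"), (1e-4, "***"), (1e-3, "**"))


class StatsError(ValueError):
    pass


@dataclass
class ContrastResult:
    """Per-protein result of one two-group contrast (group_a - group_b)."""

    table: pd.DataFrame  # columns: log2fc, t_mod, significant, direction
    group_a: str
    group_b: str
    fdr: float
    s0: float
    threshold: float  # |t_mod| significance threshold (inf if nothing called)

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["significant"]]

    def direction_set(self, direction: str) -> set[str]:
        sub = self.table
        return set(sub.index[sub["direction"] == direction])

    @property
    def n_up(self) -> int:
        return int((self.table["direction"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.table["direction"] == "down").sum())


def _group_matrix(log2m: Log2Matrix, design: SampleDesign, group_a: str,
                  group_b: str, collapse_technical: str | None = None):
    """Extract the two-group sample matrix, optionally averaging technical
    replicates within each biopsy (columns then are biological samples)."""
    cols_a = design.runs_for(group_a)
    cols_b = design.runs_for(group_b)
    values = log2m.values
    if collapse_technical is None:
        return values[cols_a].values, values[cols_b].values
    if collapse_technical != "mean":
        raise StatsError(f"unknown collapse_technical mode {collapse_technical!r}")

    def collapse(group: str) -> np.ndarray:
        sub = design.frame[design.frame["group"] == group]
        out = []
        for _, bio in sub.groupby("bio_rep", sort=True):
            out.append(values[bio["run"].tolist()].mean(axis=1).values)
        return np.column_stack(out)

    return collapse(group_a), collapse(group_b)


def log2_fold_change(log2m: Log2Matrix, design: SampleDesign,
                     group_a: str, group_b: str) -> pd.Series:
    """Difference of average log2 values, group_a minus group_b."""
    xa, xb = _group_matrix(log2m, design, group_a, group_b)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        fc = np.nanmean(xa, axis=1) - np.nanmean(xb, axis=1)
    return pd.Series(fc, index=log2m.values.index, name="log2fc")


def _t_moderated(xa: np.ndarray, xb: np.ndarray, s0: float,
                 variance: str = "pooled") -> np.ndarray:
    """Vectorized moderated t over rows of two (proteins x samples) blocks."""
    na, nb = xa.shape[1], xb.shape[1]
    ma = xa.mean(axis=1)
    mb = xb.mean(axis=1)
    va = xa.var(axis=1, ddof=1)
    vb = xb.var(axis=1, ddof=1)
    if variance == "pooled":
        sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
        se = sp * np.sqrt(1.0 / na + 1.0 / nb)
    elif variance == "welch":
        se = np.sqrt(va / na + vb / nb)
    else:
        raise StatsError(f"unknown variance mode {variance!r}")
    denom = se + s0
    if s0 == 0 and np.any(denom == 0):
        raise StatsError("zero denominator: zero variance with s0 = 0")
    return (ma - mb) / denom


def s0_t_statistic(x, y, s0: float = 0.1, variance: str = "pooled") -> float:
    """Moderated two-sample t for one protein; s0 = 0 gives the classical
    pooled Student statistic."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise StatsError("need >= 2 observations per group")
    if s0 < 0:
        raise StatsError("s0 must be >= 0")
    return float(_t_moderated(x[None, :], y[None, :], s0, variance)[0])


def _null_tstats(X: np.ndarray, na: int, s0: float, variance: str,
                 n_perm: int, seed: int, exhaustive_limit: int
                 ) -> tuple[np.ndarray, bool]:
    """|t| under sample-label permutations; (n_perm_used x proteins) array.

    Enumerate all distinct assignments of na columns to group A when their
    count is within ``exhaustive_limit``; otherwise sample ``n_perm``
    assignments uniformly.
    """
    n = X.shape[1]
    n_distinct = comb(n, na)
    if n_distinct <= exhaustive_limit:
        assignments = list(combinations(range(n), na))
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        assignments = [tuple(rng.permutation(n)[:na]) for _ in range(n_perm)]
        exhaustive = False
    null = np.empty((len(assignments), X.shape[0]))
    idx_all = np.arange(n)
    for k, idx_a in enumerate(assignments):
        sel = np.zeros(n, dtype=bool)
        sel[list(idx_a)] = True
        null[k] = np.abs(_t_moderated(X[:, sel], X[:, ~sel], s0, variance))
    return null, exhaustive


def permutation_fdr_test(log2m: Log2Matrix, design: SampleDesign,
                         group_a: str, group_b: str, fdr: float = 0.01,
                         s0: float = 0.1, n_perm: int = 250, seed: int = 0,
                         collapse_technical: str | None = None,
                         variance: str = "pooled",
                         exhaustive_limit: int = 10_000,
                         null_agg: str = "mean") -> ContrastResult:
    """Two-group moderated t-test with permutation-estimated FDR.

    The matrix must be complete (imputed) for the compared runs.  Ties in
    |t_mod| enter or leave the significance set together.  Deterministic
    under ``seed``.
    """
    if n_perm < 10:
        warnings.warn("n_perm < 10 gives a very coarse FDR estimate")
    xa, xb = _group_matrix(log2m, design, group_a, group_b, collapse_technical)
    if np.isnan(xa).any() or np.isnan(xb).any():
        raise StatsError("matrix contains missing values; impute first")
    na, nb = xa.shape[1], xb.shape[1]
    if na < 2 or nb < 2:
        raise StatsError("need >= 2 samples per group")
    if comb(na + nb, na) < 2:
        raise StatsError("degenerate design: only one distinct permutation")

    t_obs = _t_moderated(xa, xb, s0, variance)
    abs_obs = np.abs(t_obs)
    X = np.hstack([xa, xb])
    null, _ = _null_tstats(X, na, s0, variance, n_perm, seed, exhaustive_limit)

    # per candidate threshold tau: estimated FDR = agg_perms(#null >= tau) / #obs >= tau
    taus = np.unique(abs_obs)  # ascending
    null_sorted = np.sort(null.ravel())
    n_perm_used = null.shape[0]
    null_ge = (null_sorted.size
               - np.searchsorted(null_sorted, taus, side="left"))
    if null_agg == "mean":
        null_exceed = null_ge / n_perm_used
    elif null_agg == "median":
        per_perm = np.stack([np.sort(row) for row in null])
        null_exceed = np.median(
            per_perm.shape[1] - np.array(
                [np.searchsorted(row, taus, side="left") for row in per_perm]),
            axis=0)
    else:
        raise StatsError(f"unknown null_agg {null_agg!r}")
    obs_sorted = np.sort(abs_obs)
    obs_ge = obs_sorted.size - np.searchsorted(obs_sorted, taus, side="left")
    fdr_hat = null_exceed / obs_ge
    ok = fdr_hat <= fdr
    threshold = float(taus[ok][0]) if ok.any() else float("inf")

    significant = abs_obs >= threshold
    fc = log2_fold_change(log2m, design, group_a, group_b).values
    direction = np.where(~significant, "ns", np.where(fc > 0, "up", "down"))
    table = pd.DataFrame({"log2fc": fc, "t_mod": t_obs,
                          "significant": significant, "direction": direction},
                         index=log2m.values.index)
    return ContrastResult(table=table, group_a=group_a, group_b=group_b,
                          fdr=fdr, s0=s0, threshold=threshold)


# ---------------------------------------------------------------------------
# overlap (Venn) summaries


def overlap_summary(contrast_a: ContrastResult,
                    contrast_b: ContrastResult) -> pd.DataFrame:
    """Per-direction Venn counts of two contrasts' significant sets.

    The reported percentage is the intersection as a share of the union
    (inclusion-exclusion), rounded to the nearest integer.
    """
    rows = {}
    for direction in ("up", "down"):
        rows[direction] = overlap_from_sets(contrast_a.direction_set(direction),
                                            contrast_b.direction_set(direction))
    return pd.DataFrame(rows).T.rename_axis("direction")


def overlap_from_sets(set_a: set, set_b: set) -> dict:
    inter = len(set_a & set_b)
    union = len(set_a | set_b)
    return {"n_a": len(set_a), "n_b": len(set_b),
            "intersection": inter, "union": union,
            "percent_of_union": round(100.0 * inter / union) if union else 0}


def overlap_from_counts(n_a: int, n_b: int, intersection: int) -> dict:
    """Venn summary from counts alone (inclusion-exclusion arithmetic)."""
    if intersection > min(n_a, n_b):
        raise StatsError("intersection exceeds a set size")
    union = n_a + n_b - intersection
    return {"n_a": n_a, "n_b": n_b, "intersection": intersection,
            "union": union,
            "percent_of_union": round(100.0 * intersection / union) if union else 0}


# ---------------------------------------------------------------------------
# pairwise Mann-Whitney on absolute concentrations


def star_label(p: float) -> str:
    for threshold, label in STAR_THRESHOLDS:
        if p <= threshold:
            return label
    return ""


def pairwise_mann_whitney(conc: ConcentrationMatrix, design: SampleDesign,
                          protein_id: str) -> pd.DataFrame:
    """Two-sided Mann-Whitney U between every pair of groups for one protein.

    Uses the exact null when sample sizes allow (no ties), the
    tie-corrected normal approximation otherwise.  Star labels follow
    ** p<=1e-3, *** p<=1e-4, **** p<=1e-5.  Pairs with fewer than two
    observations in either group are skipped with a warning.
    """
    if protein_id not in conc.values.index:
        raise StatsError(f"unknown protein id {protein_id!r}")
    row = conc.values.loc[protein_id]
    rows = []
    for ga, gb in combinations(design.groups(), 2):
        va = row[design.runs_for(ga)].dropna().values
        vb = row[design.runs_for(gb)].dropna().values
        if len(va) < 2 or len(vb) < 2:
            warnings.warn(f"{protein_id}: pair ({ga}, {gb}) skipped, "
                          "insufficient observations")
            continue
        res = stats.mannwhitneyu(va, vb, alternative="two-sided", method="auto")
        rows.append({"group_a": ga, "group_b": gb, "n_a": len(va),
                     "n_b": len(vb), "U": float(res.statistic),
                     "p_value": float(min(res.pvalue, 1.0)),
                     "stars": star_label(float(res.pvalue))})
    return pd.DataFrame(rows, columns=["group_a", "group_b", "n_a", "n_b",
                                       "U", "p_value", "stars"])


# ---------------------------------------------------------------------------
# dataset-level summary


def quantified_fraction(table: ProteinTable, design: SampleDesign,
                        min_frac: float = 0.7) -> tuple[int, int, float]:
    """(n passing the validity filter, n total, percentage to 1 decimal)."""
    n_total = len(table)
    if n_total == 0:
        return 0, 0, 0.0
    keep = validity_mask(table.intensities, design, min_frac)
    n_q = int(keep.sum())
    return n_q, n_total, round(100.0 * n_q / n_total, 1)
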