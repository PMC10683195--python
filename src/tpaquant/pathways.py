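"""Pathway-level analysis.

Over-representation of differential proteins in named pathway sets
(one-sided hypergeometric tail with Benjamini-Hochberg adjustment),
cross-contrast fold-change correlations per pathway (Pearson r of the two
tumors' log2 fold changes over member proteins), per-pathway dysregulation
tables for network export, and per-complex absolute-concentration summaries
with pairwise Mann-Whitney stars.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diffstats import ContrastResult, pairwise_mann_whitney
from .mq_io import SampleDesign
from .quantify import ConcentrationMatrix

log = logging.getLogger(__name__)


class PathwayError(ValueError):
    pass


def enrich_hypergeometric(diff_set: set[str], universe: set[str],
                          sets: dict[str, list[str] | set[str]],
                          correction: str = "bh") -> pd.DataFrame:
    """Hypergeometric over-representation test per pathway.

    ``sets`` maps pathway name -> members already resolved to the analysis
    universe's identifiers.  For each pathway with K members in the
    universe and k of them in ``diff_set`` (size n, universe size M), the
    p-value is the upper tail P(X >= k) of Hypergeometric(M, K, n).
    Pathways with no members in the universe are skipped.
    """
    if not diff_set <= universe:
        raise PathwayError("diff_set must be a subset of the universe")
    M = len(universe)
    n = len(diff_set)
    rows = []
    for name, members in sets.items():
        in_universe = set(members) & universe
        if not in_universe:
            log.info("pathway %r has no members in the universe; skipped", name)
            continue
        K = len(in_universe)
        k = len(in_universe & diff_set)
        p = float(stats.hypergeom.sf(k - 1, M, K, n))
        rows.append({"pathway": name, "n_members": K, "n_diff": n,
                     "overlap": k, "p_value": min(p, 1.0)})
    df = pd.DataFrame(rows, columns=["pathway", "n_members", "n_diff",
                                     "overlap", "p_value"])
    if len(df):
        if correction == "bh":
            df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
        elif correction is None or correction == "none":
            df["p_adjusted"] = df["p_value"]
        else:
            raise PathwayError(f"unknown correction {correction!r}")
    else:
        df["p_adjusted"] = pd.Series(dtype=float)
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)


def cross_contrast_correlation(fc_a: pd.Series, fc_b: pd.Series,
                               sets: dict[str, list[str] | set[str]],
                               restrict: str = "either",
                               significant_a: set[str] | None = None,
                               significant_b: set[str] | None = None,
                               min_n: int = 3) -> pd.DataFrame:
    """Pearson r between two contrasts' log2 fold changes, per pathway.

    Measures whether the two tumors dysregulate a pathway's proteins
    concordantly.  ``restrict="either"`` keeps member proteins significant
    in at least one contrast (requires the significant sets);
    ``restrict="all"`` uses every member present in both fold-change
    vectors.  Pathways with fewer than ``min_n`` proteins after restriction
    are reported with a missing r.
    """
    shared = fc_a.index.intersection(fc_b.index)
    if restrict == "either":
        if significant_a is None or significant_b is None:
            raise PathwayError("restrict='either' needs both significant sets")
        eligible = set(shared) & (set(significant_a) | set(significant_b))
    elif restrict == "all":
        eligible = set(shared)
    else:
        raise PathwayError(f"unknown restrict mode {restrict!r}")
    rows = []
    for name, members in sets.items():
        keep = [m for m in members if m in eligible]
        keep = [m for m in keep
                if np.isfinite(fc_a[m]) and np.isfinite(fc_b[m])]
        if len(keep) < min_n:
            rows.append({"pathway": name, "n": len(keep),
                         "r": np.nan, "p_value": np.nan})
            continue
        r, p = stats.pearsonr(fc_a[keep].values, fc_b[keep].values)
        rows.append({"pathway": name, "n": len(keep),
                     "r": float(r), "p_value": float(p)})
    return pd.DataFrame(rows, columns=["pathway", "n", "r", "p_value"])


def complex_summary(conc: ConcentrationMatrix, design: SampleDesign,
                    complex_sets: dict[str, list[str] | set[str]]
                    ) -> pd.DataFrame:
    """Per complex-member protein: group means/SD of absolute concentration
    plus pairwise Mann-Whitney star labels.

    Intended for respiratory-chain complexes I-V on the pmol/mg matrix; any
    pathway sets work.  Members absent from the matrix are listed with
    status ``missing``.
    """
    groups = design.groups()
    rows = []
    for cname, members in complex_sets.items():
        for pid in members:
            if pid not in conc.values.index:
                rows.append({"complex": cname, "protein_id": pid,
                             "status": "missing"})
                continue
            row = {"complex": cname, "protein_id": pid, "status": "ok"}
            vals = conc.values.loc[pid]
            n_groups_obs = 0
            for g in groups:
                v = vals[design.runs_for(g)].dropna()
                row[f"mean_{g}"] = float(v.mean()) if len(v) else np.nan
                row[f"sd_{g}"] = float(v.std(ddof=1)) if len(v) > 1 else np.nan
                row[f"n_{g}"] = int(len(v))
                n_groups_obs += len(v) >= 2
            if n_groups_obs >= 2:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    mw = pairwise_mann_whitney(conc, design, pid)
                for _, pr in mw.iterrows():
                    row[f"stars_{pr['group_a']}_vs_{pr['group_b']}"] = pr["stars"]
                    row[f"p_{pr['group_a']}_vs_{pr['group_b']}"] = pr["p_value"]
            rows.append(row)
    return pd.DataFrame(rows)


def dysregulation_network_table(contrasts: dict[str, ContrastResult],
                                sets: dict[str, list[str] | set[str]]
                                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-pathway, per-contrast member directions and up/down counts.

    Returns (members, counts): ``members`` has one row per (pathway,
    contrast, member protein found in that contrast) with its log2 fold
    change and direction label — a node/edge table for external network
    viewers; ``counts`` aggregates up/down/total members per pathway and
    contrast.  A protein belonging to several pathways appears once per
    pathway.
    """
    member_rows = []
    count_rows = []
    for pw, members in sets.items():
        for cname, contrast in contrasts.items():
            present = [m for m in members if m in contrast.table.index]
            n_up = n_down = 0
            for m in present:
                rec = contrast.table.loc[m]
                member_rows.append({"pathway": pw, "contrast": cname,
                                    "protein_id": m,
                                    "log2fc": float(rec["log2fc"]),
                                    "direction": rec["direction"]})
                n_up += rec["direction"] == "up"
                n_down += rec["direction"] == "down"
            count_rows.append({"pathway": pw, "contrast": cname,
                               "n_members": len(present), "n_up": int(n_up),
                               "n_down": int(n_down),
                               "n_dysregulated": int(n_up + n_down)})
    members_df = pd.DataFrame(member_rows, columns=["pathway", "contrast",
                                                    "protein_id", "log2fc",
                                                    "direction"])
    counts_df = pd.DataFrame(count_rows, columns=["pathway", "contrast",
                                                  "n_members", "n_up",
                                                  "n_down", "n_dysregulated"])
    return members_df, counts_df
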