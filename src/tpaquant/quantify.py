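"""Total Protein Approach quantification and preprocessing.

The Total Protein Approach (TPA) converts a protein's summed MS signal into
an absolute concentration without spike-in standards::

    c(i) = MS signal(i) / (total MS signal * MW(i))   [mol / g total protein]

where ``total MS signal`` is the per-run sum of present intensities and
``MW(i)`` is the molecular weight in g/mol (kDa * 1000).  By construction
the per-run mass closure sum_i c(i) * MW(i) = 1 holds exactly for the
observed cells.

Downstream preprocessing follows the standard Perseus-style label-free
workflow: retain proteins quantified in at least a fraction ``min_frac``
(default 70%) of the runs of at least one tissue group, log2-transform, and
replace the remaining missing values with draws from a downshifted Gaussian
(mean mu - downshift*sigma, sd width*sigma, with mu/sigma taken from all
observed cells of the matrix), modelling left-censored missingness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mq_io import ProteinTable, SampleDesign

log = logging.getLogger(__name__)

UNIT_MOL_PER_G = "mol/g"
UNIT_PMOL_PER_MG = "pmol/mg"


class QuantifyError(ValueError):
    pass


@dataclass
class ConcentrationMatrix:
    """Absolute concentrations, proteins x runs; NaN where not quantified."""

    values: pd.DataFrame
    unit: str = UNIT_MOL_PER_G
    mw_kda: pd.Series | None = None

    @property
    def runs(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class Log2Matrix:
    """Log2 values, proteins x runs, with a per-cell imputation provenance."""

    values: pd.DataFrame
    imputed: pd.DataFrame = field(default=None)  # bool, True where imputed

    def __post_init__(self) -> None:
        if self.imputed is None:
            self.imputed = pd.DataFrame(False, index=self.values.index,
                                        columns=self.values.columns)

    @property
    def runs(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ValidityFilterReport:
    n_total: int
    n_retained: int

    @property
    def retained_fraction(self) -> float:
        return self.n_retained / self.n_total if self.n_total else float("nan")


def tpa_concentrations(table: ProteinTable) -> ConcentrationMatrix:
    """Raw intensities -> TPA concentrations in mol per g total protein.

    The table should already be flag-filtered; decoy rows would otherwise
    contribute to the total signal.
    """
    if (table.mw_kda <= 0).any():
        bad = list(table.protein_id[table.mw_kda <= 0])[:5]
        raise QuantifyError(f"non-positive molecular weight for {bad}")
    totals = table.intensities.sum(axis=0, skipna=True)
    zero = totals[totals == 0]
    if len(zero):
        raise QuantifyError(f"run(s) with zero total MS signal: {list(zero.index)}")
    mw_g_per_mol = table.mw_kda * 1000.0
    conc = table.intensities.div(totals, axis=1).div(mw_g_per_mol, axis=0)
    return ConcentrationMatrix(values=conc, unit=UNIT_MOL_PER_G,
                               mw_kda=table.mw_kda.copy())


def mass_closure(conc: ConcentrationMatrix) -> pd.Series:
    """Per-run sum of c(i)*MW(i) over observed cells; 1.0 by construction."""
    if conc.mw_kda is None:
        raise QuantifyError("concentration matrix carries no molecular weights")
    if conc.unit != UNIT_MOL_PER_G:
        raise QuantifyError("mass closure is defined on the mol/g matrix")
    return conc.values.mul(conc.mw_kda * 1000.0, axis=0).sum(axis=0, skipna=True)


def to_pmol_per_mg(conc: ConcentrationMatrix,
                   protein_mass_fraction: float = 1.0) -> ConcentrationMatrix:
    """Rescale mol/g-protein to pmol/mg of tissue.

    ``protein_mass_fraction`` is the protein mass per tissue mass (g/g); the
    default 1.0 reports pmol per mg of total protein.
    """
    if not 0 < protein_mass_fraction <= 1:
        raise QuantifyError(
            f"protein_mass_fraction must be in (0, 1], got {protein_mass_fraction}")
    if conc.unit != UNIT_MOL_PER_G:
        raise QuantifyError(f"expected a {UNIT_MOL_PER_G} matrix, got {conc.unit}")
    # mol/g = 1e12 pmol / 1e3 mg = 1e9 pmol/mg
    return ConcentrationMatrix(values=conc.values * 1e9 * protein_mass_fraction,
                               unit=UNIT_PMOL_PER_MG, mw_kda=conc.mw_kda)


def validity_mask(values: pd.DataFrame, design: SampleDesign,
                  min_frac: float = 0.7) -> pd.Series:
    """True for proteins present in >= min_frac of runs of >= 1 group."""
    if not 0 < min_frac <= 1:
        raise QuantifyError(f"min_frac must be in (0, 1], got {min_frac}")
    present = values.notna()
    keep = pd.Series(False, index=values.index)
    for group in design.groups():
        runs = design.runs_for(group)
        frac = present[runs].sum(axis=1) / len(runs)
        keep |= frac >= min_frac
    return keep


def filter_valid(matrix, design: SampleDesign, min_frac: float = 0.7):
    """Apply the group-wise validity filter to a concentration or log2 matrix.

    A protein is retained iff, for at least one group, it is quantified in
    at least ``min_frac`` of that group's runs (runs, not biological
    samples: with 5 biopsies x 2 technical replicates the criterion is 7 of
    10 runs at the default 0.7).  Returns (filtered matrix, report).
    """
    keep = validity_mask(matrix.values, design, min_frac)
    report = ValidityFilterReport(n_total=len(matrix.values),
                                  n_retained=int(keep.sum()))
    if isinstance(matrix, Log2Matrix):
        out = Log2Matrix(values=matrix.values.loc[keep],
                         imputed=matrix.imputed.loc[keep])
    else:
        out = replace(matrix, values=matrix.values.loc[keep],
                      mw_kda=None if matrix.mw_kda is None else matrix.mw_kda[keep])
    return out, report


def log2_transform(conc: ConcentrationMatrix) -> Log2Matrix:
    """Elementwise log2; missing cells stay missing."""
    vals = conc.values
    bad = (vals <= 0).any().any()
    if bad:
        raise QuantifyError("non-positive present value; cannot log2-transform")
    return Log2Matrix(values=np.log2(vals))


def impute_downshift(log2m: Log2Matrix, width: float = 0.5,
                     downshift: float = 1.8, seed: int = 0,
                     mode: str = "total") -> Log2Matrix:
    """Impute missing log2 cells from a downshifted Gaussian.

    ``mode="total"``: one mu/sigma from all observed cells of the matrix;
    each missing cell is drawn i.i.d. from
    Normal(mu - downshift*sigma, (width*sigma)^2).  ``mode="per_column"``
    estimates mu/sigma per run instead.  Observed cells are never altered;
    imputed cells are flagged in the returned provenance mask.
    """
    if width < 0 or downshift < 0:
        raise QuantifyError("width and downshift must be >= 0")
    if mode not in ("total", "per_column"):
        raise QuantifyError(f"unknown imputation mode {mode!r}")
    values = log2m.values.copy()
    missing = values.isna()
    if not missing.any().any():
        return Log2Matrix(values=values, imputed=log2m.imputed.copy())
    rng = np.random.default_rng(seed)

    def draw(block: pd.Series | pd.DataFrame, miss_mask, arr_obs: np.ndarray):
        if arr_obs.size < 2:
            raise QuantifyError("need >= 2 observed values to impute")
        mu = float(np.mean(arr_obs))
        sigma = float(np.std(arr_obs, ddof=1))
        if sigma == 0:
            raise QuantifyError("observed values have zero spread; cannot impute")
        n_miss = int(np.count_nonzero(miss_mask))
        return rng.normal(mu - downshift * sigma, width * sigma, size=n_miss)

    if mode == "total":
        obs = values.values[~missing.values]
        fills = draw(values, missing.values, obs)
        arr = values.values.copy()
        arr[missing.values] = fills
        values = pd.DataFrame(arr, index=values.index, columns=values.columns)
    else:
        for col in values.columns:
            colmiss = missing[col].values
            if not colmiss.any():
                continue
            obs = values[col].values[~colmiss]
            values.loc[colmiss, col] = draw(values[col], colmiss, obs)
    imputed = log2m.imputed | missing
    return Log2Matrix(values=values, imputed=imputed)
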