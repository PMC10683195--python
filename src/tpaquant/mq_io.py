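"""Readers, writers and flag filters for MaxQuant-style protein tables.

The entry point of the whole pipeline is a ``proteinGroups.txt``-dialect
tab-separated table: one row per protein group, a ``Mol. weight [kDa]``
column, one ``Intensity <run>`` column per LC-MS/MS run, and the usual
``Reverse`` / ``Potential contaminant`` / ``Only identified by site``
columns marked with ``+``.  An intensity of 0 means "not quantified" and is
stored as missing (NaN), matching MaxQuant/Perseus semantics.

Also handles the run-design table (run -> tissue group / biological
replicate / technical replicate) and GMT pathway-set files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

# canonical proteinGroups column names
COL_PROTEIN_ID = "Protein IDs"
COL_GENE_NAME = "Gene names"
COL_MW = "Mol. weight [kDa]"
COL_REVERSE = "Reverse"
COL_CONTAMINANT = "Potential contaminant"
COL_ONLY_SITE = "Only identified by site"
INTENSITY_PREFIX = "Intensity "

FLAG_COLUMNS = {
    "reverse": COL_REVERSE,
    "contaminant": COL_CONTAMINANT,
    "only_by_site": COL_ONLY_SITE,
}


class ParseError(ValueError):
    """Malformed input table (missing column, bad cell, duplicate run...)."""


class ValidationError(ValueError):
    """Cross-file inconsistency (design does not match the protein table...)."""


@dataclass
class ProteinTable:
    """Protein-group table: identifiers, molecular weight, flags, intensities.

    ``intensities`` is proteins x runs (float, NaN = not quantified, all
    present values > 0).  Flag vectors are booleans aligned with
    ``protein_id``.
    """

    protein_id: pd.Index
    gene_name: pd.Series
    mw_kda: pd.Series
    intensities: pd.DataFrame
    reverse: pd.Series
    contaminant: pd.Series
    only_by_site: pd.Series

    @property
    def runs(self) -> list[str]:
        return list(self.intensities.columns)

    def __len__(self) -> int:
        return len(self.protein_id)

    def flag(self, name: str) -> pd.Series:
        return {"reverse": self.reverse, "contaminant": self.contaminant,
                "only_by_site": self.only_by_site}[name]

    def subset(self, keep) -> "ProteinTable":
        """Row subset by boolean mask (aligned with protein_id, order kept)."""
        keep = np.asarray(keep, dtype=bool)
        return ProteinTable(
            protein_id=self.protein_id[keep],
            gene_name=self.gene_name[keep],
            mw_kda=self.mw_kda[keep],
            intensities=self.intensities.loc[keep],
            reverse=self.reverse[keep],
            contaminant=self.contaminant[keep],
            only_by_site=self.only_by_site[keep],
        )

    def to_frame(self) -> pd.DataFrame:
        """Assemble the full proteinGroups-dialect frame (0 = missing)."""
        df = pd.DataFrame({COL_PROTEIN_ID: self.protein_id,
                           COL_GENE_NAME: self.gene_name.values,
                           COL_MW: self.mw_kda.values})
        inten = self.intensities.fillna(0.0)
        for run in self.runs:
            df[INTENSITY_PREFIX + run] = inten[run].values
        df[COL_REVERSE] = np.where(self.reverse.values, "+", "")
        df[COL_CONTAMINANT] = np.where(self.contaminant.values, "+", "")
        df[COL_ONLY_SITE] = np.where(self.only_by_site.values, "+", "")
        return df


@dataclass
class SampleDesign:
    """Run design: each run maps to (group, biological rep, technical rep)."""

    frame: pd.DataFrame  # columns: run, group, bio_rep, tech_rep

    def __post_init__(self) -> None:
        required = ["run", "group", "bio_rep", "tech_rep"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ParseError(f"design table missing column(s): {missing}")
        if self.frame["run"].duplicated().any():
            dup = self.frame.loc[self.frame["run"].duplicated(), "run"].tolist()
            raise ValidationError(f"duplicate run(s) in design: {dup}")

    @property
    def runs(self) -> list[str]:
        return self.frame["run"].tolist()

    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.frame["group"]))

    def runs_for(self, group: str) -> list[str]:
        if group not in set(self.frame["group"]):
            raise KeyError(f"unknown group label: {group!r}")
        return self.frame.loc[self.frame["group"] == group, "run"].tolist()

    def group_of(self) -> pd.Series:
        return self.frame.set_index("run")["group"]


@dataclass
class PathwaySets:
    """Named protein sets (GMT): pathway name -> members (ids or gene symbols)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"pathway {name!r} has no members")

    def names(self) -> list[str]:
        return list(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class FlagFilterReport:
    n_input: int
    n_retained: int
    removed_reverse: int = 0
    removed_contaminant: int = 0
    removed_only_by_site: int = 0

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_retained


# ---------------------------------------------------------------------------
# proteinGroups reading / writing


def _parse_flag(series: pd.Series) -> pd.Series:
    return series.fillna("").astype(str).str.strip().eq("+")


def read_protein_groups(path: str | Path) -> ProteinTable:
    """Read a ``proteinGroups.txt``-dialect TSV.

    Zero intensities become missing; ``+`` flag markers become booleans;
    run-column order is preserved.  Unrecognized columns are ignored.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    dup = sorted({c for c in header if header.count(c) > 1})
    if dup:
        raise ParseError(f"{path}: duplicate run column(s): {dup}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return protein_table_from_frame(df, source=str(path))


def protein_table_from_frame(df: pd.DataFrame, source: str = "<frame>") -> ProteinTable:
    if COL_PROTEIN_ID not in df.columns:
        raise ParseError(f"{source}: missing {COL_PROTEIN_ID!r} column")
    if COL_MW not in df.columns:
        raise ParseError(f"{source}: missing molecular-weight column {COL_MW!r}")
    inten_cols = [c for c in df.columns if c.startswith(INTENSITY_PREFIX)]
    if not inten_cols:
        raise ParseError(f"{source}: no '{INTENSITY_PREFIX}<run>' columns found")
    runs = [c[len(INTENSITY_PREFIX):] for c in inten_cols]
    dup = [r for r in runs if runs.count(r) > 1]
    if dup:
        raise ParseError(f"{source}: duplicate run column(s): {sorted(set(dup))}")

    ids = pd.Index(df[COL_PROTEIN_ID].astype(str), name="protein_id")
    if ids.duplicated().any():
        raise ParseError(
            f"{source}: duplicate protein id(s): {ids[ids.duplicated()].tolist()[:5]}")

    mw = pd.to_numeric(df[COL_MW], errors="coerce")
    if mw.isna().any():
        row = int(np.flatnonzero(mw.isna())[0])
        raise ParseError(f"{source}: non-numeric molecular weight at row {row} "
                         f"(id {ids[row]!r})")
    inten = pd.DataFrame(index=ids)
    for col, run in zip(inten_cols, runs):
        vals = pd.to_numeric(df[col].replace("", "0"), errors="coerce")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna())[0])
            raise ParseError(f"{source}: non-numeric intensity in column {col!r} "
                             f"row {row} (value {df[col].iloc[row]!r})")
        if (vals < 0).any():
            row = int(np.flatnonzero(vals < 0)[0])
            raise ParseError(f"{source}: negative intensity in column {col!r} row {row}")
        inten[run] = vals.mask(vals == 0.0).values  # 0 -> missing

    def col_or_empty(name: str) -> pd.Series:
        if name in df.columns:
            return _parse_flag(df[name]).set_axis(ids).rename(None)
        return pd.Series(False, index=ids)

    gene = df[COL_GENE_NAME].astype(str).set_axis(ids) if COL_GENE_NAME in df.columns \
        else pd.Series("", index=ids)

    table = ProteinTable(
        protein_id=ids,
        gene_name=gene.rename(None),
        mw_kda=mw.set_axis(ids).rename(None),
        intensities=inten,
        reverse=col_or_empty(COL_REVERSE),
        contaminant=col_or_empty(COL_CONTAMINANT),
        only_by_site=col_or_empty(COL_ONLY_SITE),
    )
    bad_mw = (~table.reverse) & (table.mw_kda <= 0)
    if bad_mw.any():
        raise ParseError(f"{source}: non-positive molecular weight for non-decoy "
                         f"row(s): {list(table.protein_id[bad_mw])[:5]}")
    return table


def write_protein_groups(table: ProteinTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# flag filtering


def remove_flagged(table: ProteinTable, remove_reverse: bool = True,
                   remove_only_by_site: bool = True,
                   remove_contaminant: bool = False,
                   ) -> tuple[ProteinTable, FlagFilterReport]:
    """Drop decoy/contaminant/only-by-site rows according to the enabled flags.

    Contaminant removal is off by default (only reverse hits and
    only-by-site identifications are dropped in the standard Perseus
    workflow this mirrors); enable it explicitly when wanted.
    """
    drop = pd.Series(False, index=table.protein_id)
    report = FlagFilterReport(n_input=len(table), n_retained=len(table))
    if remove_reverse:
        report.removed_reverse = int(table.reverse.sum())
        drop |= table.reverse
    if remove_only_by_site:
        report.removed_only_by_site = int(table.only_by_site.sum())
        drop |= table.only_by_site
    if remove_contaminant:
        report.removed_contaminant = int(table.contaminant.sum())
        drop |= table.contaminant
    out = table.subset(~drop.values)
    report.n_retained = len(out)
    if report.n_retained == 0:
        log.warning("flag filter removed every row")
    return out, report


# ---------------------------------------------------------------------------
# design table


def read_design(path: str | Path, table: ProteinTable | None = None) -> SampleDesign:
    """Read the run-design TSV; if a protein table is given, cross-validate."""
    df = pd.read_csv(path, sep="\t", dtype={"run": str, "group": str},
                     comment="#")
    design = SampleDesign(df)
    if table is not None:
        validate_design(design, table)
    return design


def write_design(design: SampleDesign, path: str | Path) -> None:
    design.frame.to_csv(path, sep="\t", index=False)


def validate_design(design: SampleDesign, table: ProteinTable) -> None:
    """Every design run must be an intensity column and vice versa."""
    design_runs = set(design.runs)
    table_runs = set(table.runs)
    only_design = sorted(design_runs - table_runs)
    only_table = sorted(table_runs - design_runs)
    msgs = []
    if only_design:
        msgs.append(f"run(s) in design but not in protein table: {only_design}")
    if only_table:
        msgs.append(f"run(s) in protein table but not in design: {only_table}")
    if msgs:
        raise ValidationError("; ".join(msgs))


# ---------------------------------------------------------------------------
# GMT pathway sets


def read_gmt(path: str | Path) -> PathwaySets:
    """Read a GMT file: name <tab> description <tab> member...  per line."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: GMT lines need "
                                 "name, description and >= 1 member")
            name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if name in sets:
                raise ParseError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = set(members)
            descriptions[name] = desc
    return PathwaySets(sets=sets, descriptions=descriptions)


def write_gmt(sets: PathwaySets, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.sets.items():
            desc = sets.descriptions.get(name, "")
            fh.write("\t".join([name, desc] + sorted(members)) + "\n")


def resolve_members(sets: PathwaySets, table: ProteinTable) -> dict[str, list[str]]:
    """Map each pathway's members to protein ids present in the table.

    Matching tries the accession first, then the gene symbol, both
    case-insensitive (GMT files are usually gene-symbol keyed while
    proteinGroups rows are accession keyed).
    """
    by_id = {pid.lower(): pid for pid in table.protein_id}
    by_gene: dict[str, str] = {}
    for pid, gene in table.gene_name.items():
        g = str(gene).strip().lower()
        if g and g not in by_gene:
            by_gene[g] = pid
    order = {pid: i for i, pid in enumerate(table.protein_id)}
    resolved: dict[str, list[str]] = {}
    for name, members in sets.sets.items():
        hits = set()
        for m in members:
            key = m.lower()
            pid = by_id.get(key) or by_gene.get(key)
            if pid is not None:
                hits.add(pid)
        resolved[name] = sorted(hits, key=order.__getitem__)
        if not hits:
            log.info("pathway %r has no members in the table", name)
    return resolved
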