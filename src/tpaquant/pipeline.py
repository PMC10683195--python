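"""Pipeline orchestration: one config file drives read -> filter -> TPA ->
preprocess -> contrasts -> QC -> pathways -> report.

Every stage reads its inputs from, and writes its outputs to, the config's
output directory, so stage-wise invocation (via the CLI subcommands) and
the monolithic :func:`run_pipeline` produce identical files.  Each output
TSV starts with ``#``-prefixed provenance lines (tool version, seed, config
hash).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .mq_io import (PathwaySets, SampleDesign, read_design, read_gmt,
                    read_protein_groups, remove_flagged, resolve_members)
from .quantify import (filter_valid, impute_downshift, log2_transform,
                       tpa_concentrations, to_pmol_per_mg, Log2Matrix)
from .diffstats import (overlap_summary, permutation_fdr_test,
                        quantified_fraction)
from .multivar_qc import (group_block_summary, pca_scores, pearson_matrix,
                          replicate_block_summary)
from .pathways import (cross_contrast_correlation, complex_summary,
                       dysregulation_network_table, enrich_hypergeometric)

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """All pipeline inputs and parameters (YAML-loadable)."""

    protein_groups: str
    design: str
    outdir: str
    gmt: str | None = None
    complex_gmt: str | None = None
    min_frac: float = 0.7
    remove_contaminant: bool = False
    impute_width: float = 0.5
    impute_downshift: float = 1.8
    impute_mode: str = "total"
    fdr: float = 0.01
    s0: float = 0.1
    n_perm: int = 250
    collapse_technical: str | None = None
    variance: str = "pooled"
    reference_group: str = "NAT"
    restrict: str = "either"
    protein_mass_fraction: float = 1.0
    seed: int = 0
    plots: bool = False
    extra: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        # parameters only: the output location must not change the hash
        payload = {k: v for k, v in asdict(self).items()
                   if k not in ("extra", "outdir")}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def validate_paths(self) -> None:
        for name in ("protein_groups", "design", "gmt", "complex_gmt"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise PipelineError(f"config: {name} path does not exist: {value}")


_NESTED_KEYS = {
    ("inputs", "protein_groups"): "protein_groups",
    ("inputs", "design"): "design",
    ("inputs", "gmt"): "gmt",
    ("inputs", "complex_gmt"): "complex_gmt",
    ("impute", "width"): "impute_width",
    ("impute", "downshift"): "impute_downshift",
    ("impute", "mode"): "impute_mode",
    ("units", "protein_mass_fraction"): "protein_mass_fraction",
}


def config_from_dict(data: dict) -> PipelineConfig:
    flat: dict = {}
    data = dict(data)
    for (section, key), target in _NESTED_KEYS.items():
        if section in data and isinstance(data[section], dict) and key in data[section]:
            flat[target] = data[section][key]
    for section in ("inputs", "impute", "units"):
        data.pop(section, None)
    known = set(PipelineConfig.__dataclass_fields__) - {"extra"}
    extra = {k: v for k, v in data.items() if k not in known}
    flat.update({k: v for k, v in data.items() if k in known})
    missing = [k for k in ("protein_groups", "design", "outdir") if k not in flat]
    if missing:
        raise PipelineError(f"config: missing required key(s): {missing}")
    return PipelineConfig(extra=extra, **flat)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise PipelineError(f"config file {path} is not a mapping")
    return config_from_dict(data)


# ---------------------------------------------------------------------------
# TSV I/O with provenance headers


def _meta_lines(cfg: PipelineConfig) -> str:
    return (f"# tpaquant_version={__version__}\n"
            f"# seed={cfg.seed}\n"
            f"# config_hash={cfg.config_hash()}\n")


def write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig,
              index: bool = True) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_meta_lines(cfg))
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def _out(cfg: PipelineConfig) -> Path:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _contrast_groups(cfg: PipelineConfig, design: SampleDesign) -> list[str]:
    groups = design.groups()
    if cfg.reference_group not in groups:
        raise PipelineError(
            f"reference group {cfg.reference_group!r} not in design groups {groups}")
    return [g for g in groups if g != cfg.reference_group]


def _load_inputs(cfg: PipelineConfig):
    table = read_protein_groups(cfg.protein_groups)
    design = read_design(cfg.design, table=table)
    sets = read_gmt(cfg.gmt) if cfg.gmt else None
    return table, design, sets


# ---------------------------------------------------------------------------
# stages


def stage_quantify(cfg: PipelineConfig) -> None:
    """Flag filter -> TPA -> validity filter -> log2 -> impute; write
    matrices and the quantification summary."""
    out = _out(cfg)
    table, design, _ = _load_inputs(cfg)
    filtered_table, flag_report = remove_flagged(
        table, remove_contaminant=cfg.remove_contaminant)
    n_q, n_total, pct = quantified_fraction(filtered_table, design, cfg.min_frac)

    conc = tpa_concentrations(filtered_table)
    conc_valid, filt_report = filter_valid(conc, design, cfg.min_frac)
    log2m = log2_transform(conc_valid)
    write_tsv(log2m.values, out / "filtered_log2.tsv", cfg)
    imputed = impute_downshift(log2m, width=cfg.impute_width,
                               downshift=cfg.impute_downshift,
                               seed=cfg.seed, mode=cfg.impute_mode)
    write_tsv(imputed.values, out / "imputed_log2.tsv", cfg)
    write_tsv(imputed.imputed.astype(int), out / "imputed_flags.tsv", cfg)
    pmol = to_pmol_per_mg(conc_valid, cfg.protein_mass_fraction)
    write_tsv(pmol.values, out / "concentrations_pmol_mg.tsv", cfg)

    summary = {
        "n_rows_input": flag_report.n_input,
        "n_removed_reverse": flag_report.removed_reverse,
        "n_removed_only_by_site": flag_report.removed_only_by_site,
        "n_removed_contaminant": flag_report.removed_contaminant,
        "n_identified": n_total,
        "n_quantified": n_q,
        "quantified_percent": pct,
        "n_filtered_matrix": filt_report.n_retained,
    }
    (out / "summary_quantify.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")


def _read_log2(out: Path, name: str) -> Log2Matrix:
    path = out / name
    if not path.exists():
        raise PipelineError(f"intermediate {path} not found; run quantify first")
    values = read_tsv(path)
    flags_path = out / "imputed_flags.tsv"
    if name == "imputed_log2.tsv" and flags_path.exists():
        flags = read_tsv(flags_path).astype(bool)
        return Log2Matrix(values=values, imputed=flags)
    return Log2Matrix(values=values)


def stage_test(cfg: PipelineConfig) -> None:
    """Moderated-t contrasts of every tumor group against the reference,
    plus the per-direction overlap summary when there are two contrasts."""
    out = _out(cfg)
    _, design, _ = _load_inputs(cfg)
    imputed = _read_log2(out, "imputed_log2.tsv")
    tumors = _contrast_groups(cfg, design)
    results = {}
    for g in tumors:
        res = permutation_fdr_test(
            imputed, design, g, cfg.reference_group, fdr=cfg.fdr, s0=cfg.s0,
            n_perm=cfg.n_perm, seed=cfg.seed,
            collapse_technical=cfg.collapse_technical, variance=cfg.variance)
        results[g] = res
        write_tsv(res.table, out / f"contrast_{g}_vs_{cfg.reference_group}.tsv", cfg)
    if len(tumors) == 2:
        ov = overlap_summary(results[tumors[0]], results[tumors[1]])
        write_tsv(ov, out / "overlap_summary.tsv", cfg)


def stage_qc(cfg: PipelineConfig) -> None:
    """Pearson correlation on the pre-imputation matrix; PCA on the imputed
    matrix; block summaries; optional plots."""
    out = _out(cfg)
    _, design, _ = _load_inputs(cfg)
    filtered = _read_log2(out, "filtered_log2.tsv")
    imputed = _read_log2(out, "imputed_log2.tsv")
    corr = pearson_matrix(filtered)
    write_tsv(corr.r, out / "correlation.tsv", cfg)
    write_tsv(group_block_summary(corr, design),
              out / "correlation_group_blocks.tsv", cfg, index=False)
    write_tsv(replicate_block_summary(corr, design),
              out / "correlation_replicate_blocks.tsv", cfg, index=False)
    k = min(2, len(imputed.runs) - 1)
    pca = pca_scores(imputed, k=k)
    scores = pca.scores.copy()
    write_tsv(scores, out / "pca_scores.tsv", cfg)
    evr = pd.DataFrame({"component": scores.columns,
                        "explained_variance_ratio": pca.explained_variance_ratio})
    write_tsv(evr, out / "pca_explained_variance.tsv", cfg, index=False)
    if cfg.plots:
        _qc_plots(out, corr.r, scores, design)


def _qc_plots(out: Path, r: pd.DataFrame, scores: pd.DataFrame,
              design: SampleDesign) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(r.values, vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(r)), r.columns, rotation=90, fontsize=5)
    ax.set_yticks(range(len(r)), r.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(out / "correlation_heatmap.png", dpi=120)
    plt.close(fig)

    group_of = design.group_of()
    fig, ax = plt.subplots(figsize=(6, 5))
    for g in design.groups():
        runs = [rn for rn in scores.index if group_of[rn] == g]
        ax.scatter(scores.loc[runs, "PC1"],
                   scores.loc[runs, scores.columns[min(1, len(scores.columns) - 1)]],
                   label=g, s=25)
    ax.set_xlabel("PC1")
    ax.set_ylabel(scores.columns[min(1, len(scores.columns) - 1)])
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "pca_scores.png", dpi=120)
    plt.close(fig)


def stage_pathways(cfg: PipelineConfig) -> None:
    """Enrichment, cross-contrast correlation, dysregulation tables and
    (when a complex GMT is configured) per-complex TPA summaries."""
    out = _out(cfg)
    table, design, sets = _load_inputs(cfg)
    if sets is None:
        log.info("no GMT configured; pathway stage skipped")
        return
    filtered_table, _ = remove_flagged(table,
                                       remove_contaminant=cfg.remove_contaminant)
    resolved = resolve_members(sets, filtered_table)
    tumors = _contrast_groups(cfg, design)
    contrasts = {}
    from .diffstats import ContrastResult
    for g in tumors:
        path = out / f"contrast_{g}_vs_{cfg.reference_group}.tsv"
        if not path.exists():
            raise PipelineError(f"intermediate {path} not found; run test first")
        tab = read_tsv(path)
        tab["significant"] = tab["significant"].astype(bool)
        contrasts[g] = ContrastResult(table=tab, group_a=g,
                                      group_b=cfg.reference_group,
                                      fdr=cfg.fdr, s0=cfg.s0, threshold=np.nan)

    universe = set(next(iter(contrasts.values())).table.index)
    for g, res in contrasts.items():
        enr = enrich_hypergeometric(set(res.significant), universe, resolved)
        write_tsv(enr, out / f"enrichment_{g}_vs_{cfg.reference_group}.tsv",
                  cfg, index=False)

    members_df, counts_df = dysregulation_network_table(contrasts, resolved)
    write_tsv(members_df, out / "pathway_members.tsv", cfg, index=False)
    write_tsv(counts_df, out / "pathway_counts.tsv", cfg, index=False)

    if len(tumors) == 2:
        a, b = tumors
        corr = cross_contrast_correlation(
            contrasts[a].table["log2fc"], contrasts[b].table["log2fc"],
            resolved, restrict=cfg.restrict,
            significant_a=set(contrasts[a].significant),
            significant_b=set(contrasts[b].significant))
        write_tsv(corr, out / "crosscontrast_correlation.tsv", cfg, index=False)

    if cfg.complex_gmt:
        complexes = read_gmt(cfg.complex_gmt)
        resolved_cx = resolve_members(complexes, filtered_table)
        pmol_path = out / "concentrations_pmol_mg.tsv"
        if not pmol_path.exists():
            raise PipelineError(f"intermediate {pmol_path} not found")
        from .quantify import ConcentrationMatrix, UNIT_PMOL_PER_MG
        pmol = ConcentrationMatrix(values=read_tsv(pmol_path),
                                   unit=UNIT_PMOL_PER_MG)
        cs = complex_summary(pmol, design, resolved_cx)
        write_tsv(cs, out / "complex_summary.tsv", cfg, index=False)


def stage_report(cfg: PipelineConfig) -> dict:
    """Collect the stage outputs into summary.json and return it."""
    out = _out(cfg)
    qpath = out / "summary_quantify.json"
    if not qpath.exists():
        raise PipelineError(f"intermediate {qpath} not found; run quantify first")
    summary: dict = json.loads(qpath.read_text())
    summary["seed"] = cfg.seed
    summary["config_hash"] = cfg.config_hash()
    summary["version"] = __version__

    contrasts = {}
    for path in sorted(out.glob("contrast_*.tsv")):
        tab = read_tsv(path)
        name = path.stem.removeprefix("contrast_")
        sig = tab["significant"].astype(bool)
        contrasts[name] = {
            "n_significant": int(sig.sum()),
            "n_up": int((tab["direction"] == "up").sum()),
            "n_down": int((tab["direction"] == "down").sum()),
            "n_total": int(len(tab)),
        }
    summary["contrasts"] = contrasts
    ov_path = out / "overlap_summary.tsv"
    if ov_path.exists():
        ov = read_tsv(ov_path)
        summary["overlap"] = {d: {k: int(v) for k, v in row.items()}
                              for d, row in ov.iterrows()}
    cc_path = out / "crosscontrast_correlation.tsv"
    if cc_path.exists():
        cc = read_tsv(cc_path, index_col=None)
        summary["pathway_correlations"] = [
            {"pathway": r["pathway"], "n": int(r["n"]),
             "r": None if pd.isna(r["r"]) else round(float(r["r"]), 4)}
            for _, r in cc.iterrows()]
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


STAGES = [("quantify", stage_quantify), ("test", stage_test),
          ("qc", stage_qc), ("pathways", stage_pathways),
          ("report", stage_report)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; returns the report summary."""
    config.validate_paths()
    summary: dict = {}
    for name, fn in STAGES:
        t0 = time.perf_counter()
        try:
            result = fn(config)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        log.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
        if name == "report":
            summary = result
    return summary
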