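import numpy as np
import pandas as pd
import pytest

from tpaquant.mq_io import ProteinTable, SampleDesign


def make_table(intensities: dict[str, list], mw=None, reverse=None,
               contaminant=None, only_by_site=None, genes=None) -> ProteinTable:
    """Build a small ProteinTable from run -> values (0/None = missing)."""
    runs = list(intensities)
    n = len(intensities[runs[0]])
    ids = pd.Index([f"P{i}" for i in range(n)], name="protein_id")
    inten = pd.DataFrame(
        {r: [np.nan if v in (0, None) else float(v) for v in vals]
         for r, vals in intensities.items()}, index=ids)

    def series(vals, default):
        if vals is None:
            vals = [default] * n
        return pd.Series(vals, index=ids)

    return ProteinTable(
        protein_id=ids,
        gene_name=series(genes, ""),
        mw_kda=series(mw, 50.0),
        intensities=inten,
        reverse=series(reverse, False),
        contaminant=series(contaminant, False),
        only_by_site=series(only_by_site, False),
    )


def make_design(groups: dict[str, int], n_tech: int = 1) -> SampleDesign:
    """Design with ``groups[g]`` biological samples per group, each run
    ``n_tech`` times; run ids '<g>_b<bio>_t<tech>'."""
    rows = []
    for g, n_bio in groups.items():
        for b in range(1, n_bio + 1):
            for t in range(1, n_tech + 1):
                rows.append({"run": f"{g}_b{b}_t{t}", "group": g,
                             "bio_rep": b, "tech_rep": t})
    return SampleDesign(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_dataset():
    """A small study-shaped simulated dataset shared across tests."""
    from tpaquant.synthdata import generate_dataset, study_like_config

    config = study_like_config(seed=0, n_proteins=400,
                              pathway_sizes={"GLUCONEOGENESIS": 30,
                                             "TCA_CYCLE": 30, "OXPHOS": 40,
                                             "RIBOSOME": 30})
    return generate_dataset(config)


@pytest.fixture(scope="session")
def sim_files(tmp_path_factory, small_dataset):
    """The small dataset written to disk plus a pipeline config YAML."""
    from tpaquant.mq_io import write_design, write_gmt, write_protein_groups

    table, design, sets, _ = small_dataset
    root = tmp_path_factory.mktemp("simdata")
    write_protein_groups(table, root / "proteinGroups.txt")
    write_design(design, root / "design.tsv")
    write_gmt(sets, root / "pathways.gmt")
    cfg = root / "config.yaml"
    cfg.write_text(
        "inputs:\n"
        f"  protein_groups: {root / 'proteinGroups.txt'}\n"
        f"  design: {root / 'design.tsv'}\n"
        f"  gmt: {root / 'pathways.gmt'}\n"
        f"  complex_gmt: {root / 'pathways.gmt'}\n"
        f"outdir: {root / 'out'}\n"
        "n_perm: 100\n"
        "seed: 11\n")
    return root
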