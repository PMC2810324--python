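"""Bundled curated fold-change tables.

Two small gene tables transcribed from the published gender-stratified
PD study ship with the package: the PD-associated genes significant in
both the female and male PD contrasts, and the composite key-gene table
with fold changes across the five gender/stringency columns. Both use
the merged-matrix convention: 0 means "absent from that list".
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: canonical column names of the key-gene table fold-change columns
KEY_GENE_FC_COLUMNS = (
    "all_p01", "male_p01", "male_p05", "female_p01", "female_p05",
)


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("stratade.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_gender_shared_pd_genes() -> pd.DataFrame:
    """PD-associated genes significant in both fN_fPD and mN_mPD.

    Columns: gene, genbank_id, then the five contrast fold-change
    columns (allN_allPD, fN_fPD, mN_mPD, mN_fN, mPD_fPD).
    """
    return _read("gender_shared_pd_genes.tsv")


def load_key_gene_foldchanges() -> pd.DataFrame:
    """Composite key-gene table with five fold-change columns.

    Columns: gene, genbank_id, group, all_p01, male_p01, male_p05,
    female_p01, female_p05.
    """
    return _read("pd_key_genes.tsv")


def key_gene_merged_matrices() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Key-gene fold changes as (stringent, relaxed) merged matrices.

    Matrices are genes x contrasts with the standard column names
    ``allN_allPD``, ``mN_mPD``, ``fN_fPD``; the all-samples column is
    only reported at the stringent level and is carried into the relaxed
    matrix unchanged.
    """
    raw = load_key_gene_foldchanges().set_index("gene")
    stringent = pd.DataFrame({
        "allN_allPD": raw["all_p01"],
        "mN_mPD": raw["male_p01"],
        "fN_fPD": raw["female_p01"],
    })
    relaxed = pd.DataFrame({
        "allN_allPD": raw["all_p01"],
        "mN_mPD": raw["male_p05"],
        "fN_fPD": raw["female_p05"],
    })
    return stringent, relaxed
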