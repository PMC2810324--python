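"""Readers and writers for the plain-text formats used by the pipeline.

Expression matrices are TSV (probes x samples, first column probe id) or
GCT 1.2; metadata, probe maps, gene lists, merged matrices and Ct tables
are TSV. Gene sets use GMT (see :class:`stratade.enrichment.GeneSetCollection`).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .qpcr import CtTable
from .types import ExpressionMatrix, GeneList, SampleMetadata


def read_expression(
    path: str | Path, probe_map: pd.Series | None = None
) -> ExpressionMatrix:
    """Read a TSV or GCT expression matrix (auto-detected by suffix)."""
    path = Path(path)
    if path.suffix.lower() == ".gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if not version.startswith("#1."):
                raise ValueError(f"unsupported GCT version line {version!r}")
            n_rows, n_cols = map(int, fh.readline().split()[:2])
            table = pd.read_csv(fh, sep="\t", index_col=0)
        desc = table.iloc[:, 0]
        values = table.iloc[:, 1:].astype(float)
        if values.shape != (n_rows, n_cols):
            raise ValueError(
                f"GCT header promises {(n_rows, n_cols)}, file has "
                f"{values.shape}"
            )
        if probe_map is None and not desc.isna().all():
            probe_map = desc.astype(str)
        return ExpressionMatrix(values, probe_map)
    values = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    return ExpressionMatrix(values, probe_map)


def write_expression(x: ExpressionMatrix, path: str | Path) -> None:
    """Write as TSV, or GCT 1.2 when the suffix is ``.gct``."""
    path = Path(path)
    if path.suffix.lower() == ".gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{x.n_probes}\t{len(x.sample_ids)}\n")
            out = x.values.copy()
            out.insert(0, "Description", x.probe_to_gene.to_numpy())
            out.index.name = "Name"
            out.to_csv(fh, sep="\t")
        return
    out = x.values.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> SampleMetadata:
    table = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return SampleMetadata(table)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    out = meta.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_probe_map(path: str | Path) -> pd.Series:
    """Two-column TSV: probe id, gene symbol."""
    table = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return table.iloc[:, 0]


def write_gene_list(gl: GeneList, path: str | Path) -> None:
    # header comment keeps the labels recoverable even for empty lists
    with open(path, "w") as fh:
        fh.write(f"# contrast={gl.contrast}\tstringency={gl.stringency}\n")
        gl.entries.to_csv(fh, sep="\t", index=False)


def read_gene_list(path: str | Path) -> GeneList:
    contrast, stringency = "unnamed", "stringent"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].split():
                key, _, value = token.partition("=")
                if key == "contrast":
                    contrast = value
                elif key == "stringency":
                    stringency = value
        else:
            fh.seek(0)
        table = pd.read_csv(fh, sep="\t")
    if "probe_id" not in table.columns:
        raise ValueError(f"{path}: not a gene-list TSV")
    if "contrast" in table.columns and len(table):
        contrast = table["contrast"].iloc[0]
        stringency = table["stringency"].iloc[0]
    entries = table.drop(columns=["contrast", "stringency"], errors="ignore")
    return GeneList(contrast=contrast, stringency=stringency, entries=entries)


def write_merged_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    out = matrix.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_merged_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_ct_table(
    path: str | Path, reference_gene: str, n_replicates: int = 3
) -> CtTable:
    """Long-format TSV with columns gene, sample, replicate, ct."""
    table = pd.read_csv(path, sep="\t")
    return CtTable(table=table, reference_gene=reference_gene,
                   n_replicates=n_replicates)


def write_ct_table(ct: CtTable, path: str | Path) -> None:
    ct.table.to_csv(path, sep="\t", index=False)
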