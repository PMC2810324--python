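"""Composite key-gene tables from merged matrices and evidence flags.

A gene qualifies as a "key gene" when it carries all four externally
curated evidence flags (pathway-enrichment membership, disease-pathway
association, prior microarray support, genetic-association support) and
appears in at least one contrast list. The resulting table joins the
five fold-change columns (all-samples stringent, male and female at both
stringencies; 0 = absent) with the cross-stringency gender status.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .list_comparison import classify_gender_status

EVIDENCE_FLAGS = (
    "pathway_enrichment",
    "pd_pathway_association",
    "prior_microarray_support",
    "genetic_association_support",
)


@dataclass
class EvidenceAnnotation:
    """Per-gene boolean evidence flags with optional provenance."""

    table: pd.DataFrame  # gene index; EVIDENCE_FLAGS columns (+ "source")

    def __post_init__(self) -> None:
        missing = set(EVIDENCE_FLAGS) - set(self.table.columns)
        if missing:
            raise ValueError(f"evidence table missing flags: {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate genes in evidence table")
        self.table = self.table.copy()
        for flag in EVIDENCE_FLAGS:
            self.table[flag] = self.table[flag].astype(bool)

    def all_flags(self) -> pd.Series:
        return self.table[list(EVIDENCE_FLAGS)].all(axis=1)

    @classmethod
    def all_true(cls, genes) -> "EvidenceAnnotation":
        """Evidence with every flag set — for pre-curated gene tables."""
        table = pd.DataFrame(
            True, index=pd.Index(genes, name="gene"), columns=list(EVIDENCE_FLAGS)
        )
        return cls(table)


@dataclass
class KeyGeneTable:
    """Retained key genes with fold-change columns and gender status."""

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    def status_counts(self) -> pd.Series:
        return self.table["status"].value_counts()


def compose_key_gene_list(
    matrix_stringent: pd.DataFrame,
    matrix_relaxed: pd.DataFrame,
    evidence: EvidenceAnnotation,
    male_col: str = "mN_mPD",
    female_col: str = "fN_fPD",
    all_col: str = "allN_allPD",
) -> KeyGeneTable:
    """Assemble the key-gene table.

    Retains genes with all four evidence flags that are nonzero in at
    least one cell of either merged matrix, and annotates each with the
    five fold-change columns and the gender status classified across the
    two stringencies.
    """
    if evidence is None:
        raise ValueError("evidence annotation is required")
    status = classify_gender_status(
        matrix_stringent, matrix_relaxed, male_col=male_col,
        female_col=female_col,
    )
    flagged = set(evidence.table.index[evidence.all_flags()])
    # classify_gender_status already drops genes absent from every list
    retained = [g for g in status.index if g in flagged]

    def _cell(matrix: pd.DataFrame, gene: str, col: str) -> float:
        if col in matrix.columns and gene in matrix.index:
            return float(matrix.at[gene, col])
        return 0.0

    rows = [
        {
            "gene": g,
            "all_stringent": _cell(matrix_stringent, g, all_col),
            "male_stringent": _cell(matrix_stringent, g, male_col),
            "male_relaxed": _cell(matrix_relaxed, g, male_col),
            "female_stringent": _cell(matrix_stringent, g, female_col),
            "female_relaxed": _cell(matrix_relaxed, g, female_col),
            "status": status.at[g, "status"],
        }
        for g in retained
    ]
    columns = ["gene", "all_stringent", "male_stringent", "male_relaxed",
               "female_stringent", "female_relaxed", "status"]
    table = (
        pd.DataFrame(rows, columns=columns).set_index("gene")
        if rows else pd.DataFrame(columns=columns[1:], index=pd.Index([], name="gene"))
    )
    return KeyGeneTable(table=table)
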