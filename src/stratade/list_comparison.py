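"""Probe collapsing, merged fold-change matrices and overlap partitions.

Probe-level signed fold changes for a gene are collapsed by averaging in
linear-ratio space (a signed value -x maps to the ratio 1/x, +x to x;
the ratio mean maps back to the signed convention). Merged matrices put
collapsed fold changes for the gene lists side by side, with 0 reserved
as the "absent from that list" sentinel. Overlap partitions split a
family of lists into all membership regions, and per-gene gender status
is classified from the male/female contrast columns at two stringencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import chain

import numpy as np
import pandas as pd

from .types import GeneList

log = logging.getLogger(__name__)

GENDER_STATUSES = (
    "male-specific", "female-specific", "shared", "stringency-dependent",
)

DEFAULT_FOLD_CUTOFF = 1.5


def _to_ratio(fc: float) -> float:
    if fc == 0 or not np.isfinite(fc):
        raise ValueError(f"invalid signed fold change {fc!r}")
    return fc if fc > 0 else -1.0 / fc


def _to_signed(ratio: float) -> float:
    return ratio if ratio >= 1.0 else -1.0 / ratio


def collapse_probes(fold_changes) -> float:
    """Collapse per-probe signed fold changes of one gene to a single value.

    Each signed fold change is converted to a linear ratio, the ratios
    are averaged arithmetically, and the mean is converted back; e.g.
    probes at -2.1 and +1.3 give ratios 0.476 and 1.3, mean 0.888,
    reported as -1.13.
    """
    values = list(fold_changes)
    if not values:
        raise ValueError("collapse_probes requires at least one fold change")
    ratios = [_to_ratio(v) for v in values]
    return _to_signed(float(np.mean(ratios)))


def collapse_gene_list(gene_list: GeneList) -> pd.Series:
    """Gene-level collapsed signed fold changes for a probe-level list."""
    entries = gene_list.entries
    if entries["probe_id"].duplicated().any():
        dups = entries["probe_id"][entries["probe_id"].duplicated()]
        raise ValueError(f"duplicate probes in list: {sorted(set(dups))[:5]}")
    return (
        entries.groupby("gene")["fold_change"].apply(collapse_probes)
        .sort_index()
    )


def build_merged_matrix(lists: dict[str, GeneList]) -> pd.DataFrame:
    """Genes x lists matrix of collapsed fold changes; 0 marks absence.

    Every gene present in at least one list gets a row; a cell is the
    collapsed signed fold change when the gene is in that list and 0
    otherwise, so list membership is exactly recoverable from the
    nonzero pattern.
    """
    columns = {name: collapse_gene_list(gl) for name, gl in lists.items()}
    genes = sorted(set(chain.from_iterable(c.index for c in columns.values())))
    matrix = pd.DataFrame(0.0, index=pd.Index(genes, name="gene"),
                          columns=list(lists))
    for name, col in columns.items():
        matrix.loc[col.index, name] = col
    return matrix


def lists_from_matrix(matrix: pd.DataFrame) -> dict[str, set[str]]:
    """Recover per-list gene membership from the nonzero cells."""
    return {
        col: set(matrix.index[matrix[col] != 0]) for col in matrix.columns
    }


@dataclass
class OverlapPartition:
    """Membership regions and per-list direction counts for a list family."""

    regions: dict[frozenset, list[str]]   # signature -> sorted member ids
    per_list: pd.DataFrame                # list, n, n_up, n_down, + cutoffs
    union_size: int
    level: str
    fold_cutoff: float

    def count(self, *list_names: str) -> int:
        """Number of members whose signature is exactly the given lists."""
        return len(self.regions.get(frozenset(list_names), []))

    def shared_in(self, *list_names: str) -> set[str]:
        """Members present in all the given lists (any wider signature)."""
        wanted = frozenset(list_names)
        out: set[str] = set()
        for sig, members in self.regions.items():
            if wanted <= sig:
                out.update(members)
        return out

    def report(self, denominator: int | None = None) -> pd.DataFrame:
        """Region table with counts and percentages (1 decimal place).

        ``denominator`` defaults to the union size; pass e.g. the total
        number of deregulated probes to express regions as a share of
        the whole deregulated complement.
        """
        denom = self.union_size if denominator is None else denominator
        if denom <= 0:
            raise ValueError("denominator must be positive")
        rows = [
            ("&".join(sorted(sig)), len(members),
             round(100.0 * len(members) / denom, 1))
            for sig, members in sorted(
                self.regions.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
            )
        ]
        return pd.DataFrame(rows, columns=["region", "count", "percent"])


def partition_overlaps(
    lists: dict[str, GeneList],
    fold_cutoff: float = DEFAULT_FOLD_CUTOFF,
    level: str = "gene",
) -> OverlapPartition:
    """Partition a family of lists into exact membership regions.

    ``level`` selects whether members are gene symbols (collapsed first)
    or probe ids. Per-list statistics include up/down counts and counts
    with |fold change| above ``fold_cutoff``.
    """
    if len(lists) < 2:
        raise ValueError("need at least 2 lists to partition")
    if level not in ("gene", "probe"):
        raise ValueError("level must be 'gene' or 'probe'")

    membership: dict[str, dict[str, float]] = {}
    stats_rows = []
    for name, gl in lists.items():
        if level == "gene":
            col = collapse_gene_list(gl)
        else:
            col = gl.entries.set_index("probe_id")["fold_change"]
        membership[name] = col.to_dict()
        up = col[col > 0]
        down = col[col < 0]
        stats_rows.append((
            name, len(col), len(up), len(down),
            int((up > fold_cutoff).sum()),
            int((-down > fold_cutoff).sum()),
        ))

    signatures: dict[str, set[str]] = {}
    for name, members in membership.items():
        for mid in members:
            signatures.setdefault(mid, set()).add(name)
    regions: dict[frozenset, list[str]] = {}
    for mid, sig in signatures.items():
        regions.setdefault(frozenset(sig), []).append(mid)
    regions = {sig: sorted(members) for sig, members in regions.items()}

    per_list = pd.DataFrame(
        stats_rows,
        columns=["list", "n", "n_up", "n_down",
                 "n_up_above_cutoff", "n_down_above_cutoff"],
    )
    return OverlapPartition(
        regions=regions, per_list=per_list, union_size=len(signatures),
        level=level, fold_cutoff=fold_cutoff,
    )


def _stringency_status(male_fc: float, female_fc: float) -> str:
    if male_fc != 0 and female_fc == 0:
        return "M"
    if male_fc == 0 and female_fc != 0:
        return "F"
    if male_fc != 0 and female_fc != 0:
        return "MF"
    return "absent"


def classify_gender_status(
    matrix_stringent: pd.DataFrame,
    matrix_relaxed: pd.DataFrame,
    male_col: str = "mN_mPD",
    female_col: str = "fN_fPD",
) -> pd.DataFrame:
    """Classify genes by gender specificity across two stringencies.

    Per stringency a gene is M (male column nonzero, female zero), F
    (the converse), MF (both nonzero) or absent. The final label is
    male-specific / female-specific / shared when the per-stringency
    status is stable (M/M, F/F, MF/MF) and stringency-dependent
    otherwise. Genes absent at both stringencies are excluded with a
    logged notice.
    """
    for m, tag in ((matrix_stringent, "stringent"), (matrix_relaxed, "relaxed")):
        for col in (male_col, female_col):
            if col not in m.columns:
                raise KeyError(f"{tag} matrix lacks column {col!r}")
    genes = sorted(set(matrix_stringent.index) | set(matrix_relaxed.index))

    rows, excluded = [], []
    for gene in genes:
        per = {}
        for tag, m in (("stringent", matrix_stringent),
                       ("relaxed", matrix_relaxed)):
            male = float(m.at[gene, male_col]) if gene in m.index else 0.0
            female = float(m.at[gene, female_col]) if gene in m.index else 0.0
            per[tag] = _stringency_status(male, female)
        if per["stringent"] == "absent" and per["relaxed"] == "absent":
            excluded.append(gene)
            continue
        if per["stringent"] == per["relaxed"]:
            label = {
                "M": "male-specific",
                "F": "female-specific",
                "MF": "shared",
            }[per["stringent"]]
        else:
            label = "stringency-dependent"
        rows.append((gene, per["stringent"], per["relaxed"], label))

    if excluded:
        log.info("excluded %d gene(s) absent from both gender contrasts at "
                 "both stringencies", len(excluded))
    return pd.DataFrame(
        rows, columns=["gene", "status_stringent", "status_relaxed", "status"]
    ).set_index("gene")


def heatmap_order(matrix: pd.DataFrame) -> pd.DataFrame:
    """Deterministic row order for heatmap export.

    Rows sort by membership signature (which columns are nonzero), then
    by the first nonzero collapsed fold change, then gene symbol.
    """
    sig = matrix.ne(0).astype(int).apply(
        lambda r: "".join(map(str, r)), axis=1
    )
    first_fc = matrix.apply(
        lambda r: next((v for v in r if v != 0), 0.0), axis=1
    )
    order = pd.DataFrame({"sig": sig, "fc": first_fc}).sort_values(
        ["sig", "fc"], ascending=[False, False], kind="stable"
    )
    return matrix.loc[order.index]
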