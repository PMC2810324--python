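"""One-sided Fisher gene-set over-representation across gene lists.

Enrichment of a gene set of size K in a gene list of size n drawn from a
universe of N genes is scored by the upper-tail hypergeometric
probability P(X >= k) of the observed overlap k. Scores are assembled
into a sets x lists matrix, and comparative patterns are extracted by
anchor restriction: keeping the sets significant in both an anchor list
(the all-samples disease contrast) and a target list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass
class GeneSetCollection:
    """Named gene sets over a gene-symbol universe.

    ``sets`` maps set id to (description, sorted member list). Members
    outside the universe are dropped (with a logged count) when
    :meth:`filtered` is applied.
    """

    sets: dict[str, tuple[str, list[str]]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set().union(
                *(set(m) for _, m in self.sets.values())
            ) if self.sets else set()
        self.sets = {
            sid: (desc, sorted(set(members)))
            for sid, (desc, members) in self.sets.items()
        }

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, set_id: str) -> list[str]:
        return self.sets[set_id][1]

    def filtered(self) -> "GeneSetCollection":
        """Restrict set members to the universe; log how many were dropped."""
        out, dropped = {}, 0
        for sid, (desc, members) in self.sets.items():
            kept = [g for g in members if g in self.universe]
            dropped += len(members) - len(kept)
            out[sid] = (desc, kept)
        if dropped:
            log.info("dropped %d set members absent from the universe", dropped)
        return GeneSetCollection(sets=out, universe=set(self.universe))

    def to_gmt(self, path: str | Path) -> None:
        """Write the collection in GMT format (id, description, members)."""
        with open(path, "w") as fh:
            for sid, (desc, members) in self.sets.items():
                fh.write("\t".join([sid, desc, *members]) + "\n")

    @classmethod
    def from_gmt(cls, path: str | Path,
                 universe: set[str] | None = None) -> "GeneSetCollection":
        """Read a GMT file. Universe defaults to the union of members."""
        sets: dict[str, tuple[str, list[str]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"malformed GMT line: {line[:60]!r}")
                sets[parts[0]] = (parts[1], parts[2:])
        return cls(sets=sets, universe=universe or set())


def fisher_enrichment_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric P(X >= k): one-sided Fisher enrichment p.

    Parameters
    ----------
    k
        Observed overlap between the gene list and the set.
    K
        Gene-set size in the universe.
    n
        Gene-list size in the universe.
    N
        Universe size.
    """
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError(
            f"inconsistent counts k={k}, K={K}, n={n}, N={N}: require "
            "0 <= k <= min(K, n) and K, n <= N"
        )
    if k == 0:
        return 1.0
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))


@dataclass
class EnrichmentMatrix:
    """Sets x lists matrix of Fisher enrichment p-values with raw counts."""

    pvalues: pd.DataFrame            # sets x lists
    counts: pd.DataFrame             # long: set_id, list, k, K, n, N
    descriptions: pd.Series          # set_id -> description

    @property
    def neglog10(self) -> pd.DataFrame:
        return -np.log10(self.pvalues)

    def adjusted(self) -> pd.DataFrame:
        """Benjamini-Hochberg adjusted p-values, per list column."""
        return self.pvalues.apply(
            lambda col: stats.false_discovery_control(col, method="bh"), axis=0
        )

    def to_frame(self) -> pd.DataFrame:
        """Flat report: one row per (set, list) with p, -log10 p and counts."""
        out = self.counts.copy()
        out["p"] = [
            self.pvalues.at[s, c] for s, c in zip(out["set_id"], out["list"])
        ]
        out["neglog10_p"] = -np.log10(out["p"])
        out.insert(1, "description",
                   out["set_id"].map(self.descriptions).to_numpy())
        return out


def enrich_lists(
    lists: dict[str, set[str]],
    collection: GeneSetCollection,
    universe: set[str] | None = None,
) -> EnrichmentMatrix:
    """Score every set against every gene list by one-sided Fisher p.

    Parameters
    ----------
    lists
        Mapping list name -> gene symbols. Genes outside the universe are
        ignored for counting.
    collection
        Gene sets; members outside the universe are dropped.
    universe
        Background gene symbols (default: the collection universe, which
        for array studies should be all measured genes).
    """
    bg = set(universe) if universe is not None else set(collection.universe)
    if not bg:
        raise ValueError("empty universe")
    coll = GeneSetCollection(sets=collection.sets, universe=bg).filtered()
    N = len(bg)

    pvals = {}
    count_rows = []
    for list_name, genes in lists.items():
        list_genes = set(genes) & bg
        n = len(list_genes)
        col = {}
        for sid, (_desc, members) in coll.sets.items():
            K = len(members)
            k = len(list_genes.intersection(members))
            col[sid] = fisher_enrichment_p(k, K, n, N)
            count_rows.append((sid, list_name, k, K, n, N))
        pvals[list_name] = col

    set_ids = list(coll.sets)
    pmat = pd.DataFrame(pvals, index=set_ids, columns=list(lists))
    counts = pd.DataFrame(
        count_rows, columns=["set_id", "list", "k", "K", "n", "N"]
    )
    desc = pd.Series({sid: coll.sets[sid][0] for sid in set_ids})
    return EnrichmentMatrix(pvalues=pmat, counts=counts, descriptions=desc)


def restrict_to_anchor(
    matrix: EnrichmentMatrix,
    anchor: str,
    target: str,
    alpha: float = DEFAULT_ALPHA,
) -> list[str]:
    """Set ids significant (p < alpha) in both the anchor and target lists."""
    if anchor == target:
        raise ValueError("anchor and target must differ")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    for col in (anchor, target):
        if col not in matrix.pvalues.columns:
            raise KeyError(f"unknown list column {col!r}")
    mask = (matrix.pvalues[anchor] < alpha) & (matrix.pvalues[target] < alpha)
    return sorted(matrix.pvalues.index[mask])
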