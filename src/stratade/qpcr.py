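"""Relative quantification of qPCR Ct tables by the 2^-dCt method.

Replicate Ct values are aggregated by mean per (gene, sample), normalized
against a same-sample endogenous control gene, and converted to relative
expression ``2 ** -(Ct_gene - Ct_reference)``. A concordance report
compares the relative expression values with per-gene z-scores of a
matched array expression matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

#: replicate standard deviation (cycles) above which a measurement is flagged
REPLICATE_SD_FLAG = 0.5


@dataclass
class CtTable:
    """Long-format replicate Ct measurements.

    ``table`` columns: gene, sample, replicate, ct. ``n_replicates`` is the
    declared replicate count per (gene, sample); deviations are warned
    about, not rejected, so partially missing wells stay visible.
    """

    table: pd.DataFrame
    reference_gene: str
    n_replicates: int = 3

    def __post_init__(self) -> None:
        needed = {"gene", "sample", "replicate", "ct"}
        missing = needed - set(self.table.columns)
        if missing:
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        ct = self.table["ct"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ct)) or np.any(ct <= 0):
            raise ValueError("Ct values must be finite and positive")
        if self.reference_gene not in set(self.table["gene"]):
            raise ValueError(
                f"reference gene {self.reference_gene!r} not in Ct table"
            )
        counts = self.table.groupby(["gene", "sample"]).size()
        off = counts[counts != self.n_replicates]
        if len(off):
            warnings.warn(
                f"{len(off)} (gene, sample) pairs deviate from the declared "
                f"{self.n_replicates} replicates", stacklevel=2,
            )

    @property
    def samples(self) -> list[str]:
        return sorted(set(self.table["sample"]))

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.table["gene"]))


@dataclass
class RelativeExpression:
    """Per (gene, sample) mean Ct, delta Ct and 2^-dCt values."""

    table: pd.DataFrame  # gene, sample, mean_ct, ct_sd, flagged, delta_ct, rel_expr
    reference_gene: str

    def matrix(self) -> pd.DataFrame:
        """Relative expression as a genes x samples table."""
        return self.table.pivot(index="gene", columns="sample",
                                values="rel_expr")

    def expression_tiers(self) -> pd.Series:
        """Tier genes as high/medium/low by tertiles of mean 2^-dCt.

        The reference gene (identically 1) is excluded from tiering.
        """
        means = (
            self.table[self.table["gene"] != self.reference_gene]
            .groupby("gene")["rel_expr"].mean().sort_values()
        )
        if means.empty:
            return pd.Series(dtype=object)
        if len(means) < 3:
            return pd.Series("medium", index=means.index)
        ranks = means.rank(method="first")
        cuts = pd.qcut(ranks, 3, labels=["low", "medium", "high"])
        return pd.Series(cuts.astype(str), index=means.index)


def _aggregate_replicates(ct: CtTable, drop_outliers: bool) -> pd.DataFrame:
    rows = []
    for (gene, sample), grp in ct.table.groupby(["gene", "sample"]):
        vals = grp["ct"].to_numpy(dtype=float)
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        flagged = sd > REPLICATE_SD_FLAG
        if flagged and drop_outliers and len(vals) > 2:
            # drop the replicate furthest from the median, never more
            keep = np.argsort(np.abs(vals - np.median(vals)))[:-1]
            vals = vals[keep]
            sd = float(np.std(vals, ddof=1))
        rows.append((gene, sample, float(np.mean(vals)), sd, flagged))
    return pd.DataFrame(
        rows, columns=["gene", "sample", "mean_ct", "ct_sd", "flagged"]
    )


def relative_expression_2dct(
    ct: CtTable, drop_outliers: bool = False
) -> RelativeExpression:
    """Compute 2^-dCt relative expression against the endogenous control.

    dCt is taken within each sample: mean Ct of the gene minus mean Ct of
    the reference gene. Replicate sets with SD > 0.5 cycles are flagged
    (and optionally reduced by dropping the furthest replicate).

    Raises
    ------
    ValueError
        If the reference gene was not measured in some sample.
    """
    agg = _aggregate_replicates(ct, drop_outliers)
    ref = agg[agg["gene"] == ct.reference_gene].set_index("sample")["mean_ct"]
    missing = sorted(set(agg["sample"]) - set(ref.index))
    if missing:
        raise ValueError(
            f"reference gene {ct.reference_gene!r} missing for sample(s) "
            f"{missing}"
        )
    agg = agg.copy()
    agg["delta_ct"] = agg["mean_ct"] - agg["sample"].map(ref).to_numpy()
    agg["rel_expr"] = np.exp2(-agg["delta_ct"])
    n_flag = int(agg["flagged"].sum())
    if n_flag:
        log.info("flagged %d (gene, sample) pairs with replicate SD > %.1f "
                 "cycles", n_flag, REPLICATE_SD_FLAG)
    return RelativeExpression(table=agg, reference_gene=ct.reference_gene)


@dataclass
class ConcordanceReport:
    """Per-gene agreement between array z-scores and 2^-dCt values."""

    per_gene: pd.DataFrame  # gene, spearman_rho, spearman_p, sign_agreement, tier
    shared_samples: list[str]
    skipped: list[str] = field(default_factory=list)


def compare_with_zscores(rel: RelativeExpression, expr) -> ConcordanceReport:
    """Compare qPCR relative expression with array z-scores per gene.

    Array values are standardized per gene across the shared samples
    (z-scores); concordance is summarized as the Spearman correlation
    between z-scores and 2^-dCt values and the fraction of samples where
    the z-score sign matches the sign of the centered log2 relative
    expression. Genes with constant array values are skipped with a
    notice; genes are tiered high/medium/low by mean 2^-dCt tertiles.
    """
    gene_expr = expr.gene_level()
    rel_mat = rel.matrix()
    shared_samples = [s for s in rel_mat.columns if s in gene_expr.columns]
    if len(shared_samples) < 3:
        raise ValueError(
            f"need >= 3 shared samples, found {len(shared_samples)}"
        )
    shared_genes = [g for g in rel_mat.index
                    if g in gene_expr.index and g != rel.reference_gene]
    if not shared_genes:
        raise ValueError("no shared genes between qPCR table and array")

    tiers = rel.expression_tiers()
    rows, skipped = [], []
    for gene in shared_genes:
        x = gene_expr.loc[gene, shared_samples].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            skipped.append(gene)
            log.info("gene %s has constant array expression; z-score "
                     "undefined, skipped", gene)
            continue
        z = (x - x.mean()) / x.std()
        r = rel_mat.loc[gene, shared_samples].to_numpy(dtype=float)
        rho, pval = stats.spearmanr(z, r)
        logr = np.log2(r)
        agree = float(np.mean(np.sign(z) == np.sign(logr - logr.mean())))
        rows.append((gene, float(rho), float(pval), agree,
                     tiers.get(gene, "medium")))
    per_gene = pd.DataFrame(
        rows,
        columns=["gene", "spearman_rho", "spearman_p", "sign_agreement",
                 "tier"],
    )
    return ConcordanceReport(per_gene=per_gene, shared_samples=shared_samples,
                             skipped=skipped)
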