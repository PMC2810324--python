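"""Batch-effect removal and PCA-based QC.

Batch effects are modelled per gene as additive fixed effects alongside
disease and gender main effects; the fitted batch component (centered so
that per-gene grand means are preserved) is subtracted. PCA of the
corrected matrix is used to check class separation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, SampleMetadata

log = logging.getLogger(__name__)


def _dummies(labels: pd.Series) -> np.ndarray:
    """Drop-first treatment coding, samples x (levels - 1)."""
    levels = sorted(labels.unique())
    return np.column_stack(
        [(labels == lv).to_numpy(dtype=float) for lv in levels[1:]]
    ) if len(levels) > 1 else np.empty((len(labels), 0))


def remove_batch_effect(
    x: ExpressionMatrix, meta: SampleMetadata
) -> ExpressionMatrix:
    """Subtract per-gene additive batch effects estimated by least squares.

    A per-gene fixed-effects model with disease, gender and batch main
    effects is fit jointly for all probes; the batch component, centered
    across samples, is subtracted, so per-gene grand means are unchanged
    and a single-batch input is returned untouched.

    Raises
    ------
    ValueError
        If any batch contains a single sample.
    """
    labels = meta.table.loc[x.sample_ids]
    sizes = labels["batch"].value_counts()
    singletons = sizes[sizes < 2]
    if len(singletons):
        raise ValueError(
            f"batch(es) with a single sample: {sorted(singletons.index)}"
        )
    if labels["batch"].nunique() == 1:
        return ExpressionMatrix(x.values.copy(), x.probe_to_gene)

    # warn on confounding: batch perfectly predicts disease or vice versa
    cross = pd.crosstab(labels["batch"], labels["disease"])
    if ((cross > 0).sum(axis=1) == 1).all():
        log.warning("batch is perfectly confounded with disease; batch "
                    "removal will absorb the disease signal")

    d_disease = _dummies(labels["disease"])
    d_gender = _dummies(labels["gender"])
    d_batch = _dummies(labels["batch"])
    design = np.column_stack(
        [np.ones(len(labels)), d_disease, d_gender, d_batch]
    )
    n_batch = d_batch.shape[1]

    y = x.values.to_numpy(dtype=float).T          # samples x probes
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    batch_coef = coef[-n_batch:, :]               # (batches-1) x probes
    batch_part = d_batch @ batch_coef             # samples x probes
    batch_part -= batch_part.mean(axis=0, keepdims=True)
    corrected = (y - batch_part).T
    return ExpressionMatrix(
        pd.DataFrame(corrected, index=x.values.index, columns=x.values.columns),
        x.probe_to_gene,
    )


def pca_scores(
    x: ExpressionMatrix,
    n_components: int = 2,
    standardize: bool = True,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """PCA of samples in gene space.

    Parameters
    ----------
    x
        Expression matrix; samples are treated as observations.
    n_components
        Number of components; must not exceed min(#probes, #samples).
    standardize
        Standardize each gene to zero mean / unit variance before the
        decomposition (default, matching z-score based QC); set False to
        run on centered raw log2 values.

    Returns
    -------
    scores : DataFrame, samples x components
    variance_fractions : ndarray, non-increasing, each in [0, 1], sum <= 1
    loadings : ndarray, probes x components, orthonormal columns
    """
    if n_components < 1 or n_components > min(x.values.shape):
        raise ValueError(
            f"n_components must be in [1, {min(x.values.shape)}]"
        )
    data = x.values.to_numpy(dtype=float).T      # samples x probes
    data = data - data.mean(axis=0, keepdims=True)
    if standardize:
        sd = data.std(axis=0, ddof=0)
        keep = sd > 0
        data = data[:, keep] / sd[keep]
    total_var = float((data ** 2).sum())
    if total_var == 0:
        raise ValueError("constant expression matrix: no variance for PCA")

    u, s, vt = np.linalg.svd(data, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    fractions = (s[:n_components] ** 2) / total_var
    loadings = vt[:n_components].T
    score_df = pd.DataFrame(
        scores,
        index=x.values.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return score_df, fractions, loadings
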