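"""Two-class SAM, per-gene ANOVA, signed fold changes and contrast lists.

The SAM statistic for probe *i* is ``d_i = (mean_B - mean_A) / (s_i + s0)``
with pooled standard error ``s_i`` and a shared fudge factor ``s0`` chosen
to minimise the coefficient of variation of ``d`` across windows of ``s``.
Significance is assessed against a permutation null pooled over probes:
per-probe permutation p-values (add-one smoothed) and q-values from the
estimated false discovery rate at each |d| threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    Q_THRESHOLD,
    STRINGENCY_P,
    ExpressionMatrix,
    GeneList,
    SampleMetadata,
)

log = logging.getLogger(__name__)

FDR_METHODS = ("mean", "median", "q90")


# ---------------------------------------------------------------------------
# SAM statistic


def _pooled_d(
    x: np.ndarray,
    member_b: np.ndarray,
    n_a: int,
    n_b: int,
    s0: float,
    dtype: type | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """d and s for each probe under each column of ``member_b``.

    ``x`` is probes x samples; ``member_b`` is samples x m indicator of
    group-B membership. Returns (probes x m) arrays. The arithmetic is
    organised around the group-B sums alone (total sums are fixed), with
    in-place updates, so large permutation batches stay cheap; ``dtype``
    can downcast the null computation to float32.
    """
    if dtype is not None:
        x = np.asarray(x, dtype=dtype)
        member_b = np.asarray(member_b, dtype=dtype)
    tot = x.sum(axis=1, keepdims=True)
    tot_sq = (x * x).sum(axis=1, keepdims=True)
    u = x @ member_b  # group-B sums, probes x m
    c_ab = 1.0 / n_a + 1.0 / n_b
    scale = c_ab / (n_a + n_b - 2)

    # pooled within-group SS: tot_sq - tot^2/n_a + (2 tot/n_a) u - c_ab u^2
    ss = u * u
    ss *= -c_ab
    tmp = u * (2.0 / n_a * tot)
    ss += tmp
    ss += tot_sq - tot * tot / n_a
    np.maximum(ss, 0.0, out=ss)
    ss *= scale
    s = np.sqrt(ss, out=ss)

    # mean_B - mean_A = c_ab * u - tot/n_a
    diff = np.multiply(u, c_ab, out=tmp)
    diff -= tot / n_a

    if s0 != 0:
        denom = s + s0
        d = np.divide(diff, denom, out=diff)
    else:
        d = np.divide(diff, s, out=diff, where=s > 0)
        d[np.broadcast_to(s == 0, d.shape)] = 0.0
    return d, s


def _group_arrays(
    x: ExpressionMatrix, group_a: list[str], group_b: list[str]
) -> tuple[np.ndarray, int, int]:
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    cols = list(group_a) + list(group_b)
    return (
        x.values[cols].to_numpy(dtype=float),
        len(group_a),
        len(group_b),
    )


def sam_d_statistics(
    x: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    s0: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-probe SAM statistic d and pooled standard error s.

    With ``s0 = 0``, d is the pooled-variance two-sample t statistic.
    Probes with zero variance in both groups (and ``s0 = 0``) get d = 0
    and are counted in a log notice.
    """
    arr, n_a, n_b = _group_arrays(x, group_a, group_b)
    member_b = np.zeros((arr.shape[1], 1))
    member_b[n_a:, 0] = 1.0
    d, s = _pooled_d(arr, member_b, n_a, n_b, s0)
    degenerate = int(((s + s0) == 0).sum())
    if degenerate:
        log.info("%d probe(s) with zero pooled variance; d set to 0",
                 degenerate)
    return d[:, 0], s[:, 0]


def select_s0(
    x: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    percentiles: np.ndarray | None = None,
) -> float:
    """Choose the SAM fudge factor s0.

    Candidates are percentiles of the per-probe standard errors ``s``;
    the chosen s0 minimises the coefficient of variation of the windowed
    spread (scaled MAD) of ``d = r / (s + s0)`` across quantile windows
    of ``s``.
    """
    if percentiles is None:
        percentiles = np.arange(0, 101, 5)
    arr, n_a, n_b = _group_arrays(x, group_a, group_b)
    n_probes = arr.shape[0]
    if n_probes < 100:
        log.warning("select_s0 on %d probes; >= 100 recommended", n_probes)

    d0, s = sam_d_statistics(x, group_a, group_b, s0=0.0)
    r = d0 * s  # numerator mean_B - mean_A
    candidates = np.percentile(s, percentiles)
    if np.allclose(candidates, candidates[0]):
        return float(candidates[0])

    n_windows = int(np.clip(n_probes // 10, 2, 100))
    order = np.argsort(s, kind="stable")
    windows = np.array_split(order, n_windows)

    best_cv, best_s0 = np.inf, float(candidates[0])
    for cand in candidates:
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(s + cand > 0, r / (s + cand), 0.0)
        spreads = np.array([
            stats.median_abs_deviation(d[w], scale="normal") for w in windows
        ])
        mu = spreads.mean()
        cv = np.inf if mu == 0 else spreads.std(ddof=0) / mu
        if cv < best_cv - 1e-12:
            best_cv, best_s0 = cv, float(cand)
    return best_s0


# ---------------------------------------------------------------------------
# fold change


def signed_fold_change(
    x: ExpressionMatrix, group_a: list[str], group_b: list[str]
) -> np.ndarray:
    """Signed ratio of linear-scale group means, B relative to A.

    The ratio ``r = mean_linear(B) / mean_linear(A)`` is reported as
    ``+r`` when r >= 1 and ``-1/r`` otherwise, so |FC| >= 1 always and
    swapping the groups negates the value (+1 maps to +1).
    """
    linear = np.exp2(x.values.to_numpy(dtype=float))
    cols = x.values.columns
    mean_a = linear[:, cols.get_indexer(group_a)].mean(axis=1)
    mean_b = linear[:, cols.get_indexer(group_b)].mean(axis=1)
    if np.any(mean_a <= 0) or np.any(mean_b <= 0):
        raise RuntimeError("nonpositive linear group mean")
    ratio = mean_b / mean_a
    return np.where(ratio >= 1.0, ratio, -1.0 / ratio)


# ---------------------------------------------------------------------------
# permutation SAM


@dataclass
class SamResult:
    """Per-probe SAM output for one contrast."""

    table: pd.DataFrame  # index probe_id: gene, d, s, fold_change, q, p
    s0: float
    n_permutations: int
    exhaustive: bool
    seed: int | None
    fdr_target: float
    pi0: float
    contrast: str | None = None

    def called(self, q_threshold: float | None = None) -> pd.Index:
        thr = self.fdr_target if q_threshold is None else q_threshold
        return self.table.index[self.table["q"] < thr]


def _permutation_indicators(
    n: int, n_b: int, n_permutations: int, seed: int | None
) -> tuple[np.ndarray, bool]:
    """Samples x m indicator matrix of permuted group-B memberships."""
    n_distinct = comb(n, n_b)
    if n_distinct <= max(n_permutations, 10):
        # drop the original labeling (and its mirror for equal sizes):
        # keeping them floors the estimated FDR at ~2/n_perms because every
        # true effect re-enters the null at full strength
        n_a = n - n_b
        identity = frozenset(range(n_a, n))
        mirror = frozenset(range(n_b)) if n_a == n_b else None
        columns = [
            idx for idx in combinations(range(n), n_b)
            if frozenset(idx) not in (identity, mirror)
        ]
        member = np.zeros((n, len(columns)))
        for j, idx in enumerate(columns):
            member[list(idx), j] = 1.0
        if n_distinct < n_permutations:
            log.info(
                "only %d distinct label permutations; using exhaustive "
                "enumeration (%d after excluding the original labeling)",
                n_distinct, len(columns),
            )
        return member, True
    rng = np.random.default_rng(seed)
    member = np.zeros((n, n_permutations))
    for j in range(n_permutations):
        member[rng.permutation(n)[:n_b], j] = 1.0
    return member, False


def run_sam(
    x: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    n_permutations: int = 1000,
    seed: int | None = None,
    fdr_target: float = Q_THRESHOLD,
    s0: float | None = None,
    fdr_method: str = "mean",
    contrast: str | None = None,
) -> SamResult:
    """Two-class unpaired SAM with permutation-based p and q values.

    Per-probe p is the fraction of the pooled permutation null with
    |d*| >= |d| (add-one smoothed). The estimated FDR at each |d|
    threshold is ``pi0 * (null calls summary) / (observed calls)``; the
    q-value of a probe is the minimum FDR over thresholds that include
    it. ``fdr_method`` picks the summary of null call counts across
    permutations: ``mean`` (default), ``median`` or ``q90``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if fdr_method not in FDR_METHODS:
        raise ValueError(f"fdr_method must be one of {FDR_METHODS}")
    arr, n_a, n_b = _group_arrays(x, group_a, group_b)
    n_probes, n = arr.shape

    if s0 is None:
        s0 = select_s0(x, group_a, group_b)
    d_obs, s = sam_d_statistics(x, group_a, group_b, s0=s0)

    member, exhaustive = _permutation_indicators(
        n, n_b, n_permutations, seed
    )
    if not exhaustive and seed is None:
        raise ValueError("seed is required when permutations are sampled")
    # float32 keeps the large permutation batch memory-bandwidth friendly
    d_null, _ = _pooled_d(arr, member, n_a, n_b, s0, dtype=np.float32)
    m = member.shape[1]

    # pooled permutation p-values, add-one smoothed
    null_abs = np.sort(np.abs(d_null), axis=None)
    abs_obs = np.abs(d_obs)
    n_ge = null_abs.size - np.searchsorted(null_abs, abs_obs, side="left")
    p = (1.0 + n_ge) / (1.0 + null_abs.size)

    # pi0 from the fraction of observed d inside the null interquartile range
    q25, q75 = np.percentile(d_null, [25, 75])
    pi0 = min(1.0, ((d_obs >= q25) & (d_obs <= q75)).sum() / (0.5 * n_probes))

    # estimated FDR at each observed |d| threshold (ranks, descending |d|)
    order = np.argsort(-abs_obs, kind="stable")
    thresholds = abs_obs[order]
    ranks = np.arange(1, n_probes + 1)
    if fdr_method == "mean":
        null_calls = n_ge[order] / m
    else:
        counts = np.empty((m, n_probes))
        for j in range(m):
            col = np.sort(np.abs(d_null[:, j]))
            counts[j] = col.size - np.searchsorted(col, thresholds, side="left")
        null_calls = (
            np.median(counts, axis=0) if fdr_method == "median"
            else np.percentile(counts, 90, axis=0)
        )
    fdr = np.minimum(1.0, pi0 * null_calls / ranks)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty(n_probes)
    q[order] = q_sorted

    fc = signed_fold_change(x, group_a, group_b)
    table = pd.DataFrame(
        {
            "gene": x.probe_to_gene.to_numpy(),
            "d": d_obs,
            "s": s,
            "fold_change": fc,
            "q": q,
            "p": p,
        },
        index=x.values.index,
    )
    return SamResult(
        table=table, s0=s0, n_permutations=m, exhaustive=exhaustive,
        seed=seed, fdr_target=fdr_target, pi0=pi0, contrast=contrast,
    )


def run_sam_contrast(
    x: ExpressionMatrix,
    meta: SampleMetadata,
    contrast: str,
    **kwargs,
) -> SamResult:
    """Run SAM for a named contrast resolved from sample metadata."""
    group_a, group_b = meta.contrast_groups(contrast)
    return run_sam(x, group_a, group_b, contrast=contrast, **kwargs)


def build_contrast_list(sam: SamResult, stringency: str) -> GeneList:
    """Significance-gated entries: q < 0.05 and permutation p below gate.

    The stringent gate is p < 0.01, the relaxed gate p < 0.05. Entries
    are sorted by gene symbol then probe id.
    """
    if stringency not in STRINGENCY_P:
        raise ValueError(f"unknown stringency {stringency!r}")
    p_gate = STRINGENCY_P[stringency]
    tab = sam.table
    hit = tab[(tab["q"] < Q_THRESHOLD) & (tab["p"] < p_gate)]
    entries = (
        hit.reset_index(names="probe_id")
        [["probe_id", "gene", "fold_change", "q", "p"]]
        .sort_values(["gene", "probe_id"], kind="stable")
        .reset_index(drop=True)
    )
    return GeneList(
        contrast=sam.contrast or "unnamed",
        stringency=stringency,
        entries=entries,
    )


# ---------------------------------------------------------------------------
# per-gene ANOVA


def anova_per_gene(
    x: ExpressionMatrix,
    meta: SampleMetadata,
    factors: tuple[str, ...] = ("disease", "gender", "batch"),
    fdr_gate: float | None = None,
) -> pd.DataFrame:
    """Per-probe fixed-effects ANOVA p-values for each factor.

    Fits an additive model with all requested factors and tests each by
    the partial F comparing the full model against the model without
    that factor. Returns a probes x columns frame with ``p_<factor>``,
    BH-adjusted ``q_<factor>``, and boolean ``sig_<factor>`` gates when
    ``fdr_gate`` is given (e.g. 0.10 for an FDR10-style list).

    Raises
    ------
    ValueError
        If the full design matrix is rank deficient (aliased factors).
    """
    labels = meta.table.loc[x.sample_ids]
    blocks: dict[str, np.ndarray] = {}
    for f in factors:
        if f not in labels.columns:
            raise ValueError(f"unknown factor {f!r}")
        blocks[f] = _factor_dummies(labels[f])
    intercept = np.ones((len(labels), 1))
    full = np.column_stack([intercept, *blocks.values()])
    rank = np.linalg.matrix_rank(full)
    if rank < full.shape[1]:
        aliased = _find_aliased(blocks, intercept)
        raise ValueError(f"rank-deficient design; aliased factors: {aliased}")

    y = x.values.to_numpy(dtype=float).T
    n = y.shape[0]
    rss_full = _rss(full, y)
    dfe = n - full.shape[1]
    if dfe < 1:
        raise ValueError("no residual degrees of freedom")

    out = {}
    for f in factors:
        reduced = np.column_stack(
            [intercept, *(b for g, b in blocks.items() if g != f)]
        )
        df_num = blocks[f].shape[1]
        rss_red = _rss(reduced, y)
        with np.errstate(divide="ignore", invalid="ignore"):
            fstat = ((rss_red - rss_full) / df_num) / (rss_full / dfe)
        fstat = np.where(rss_full > 0, fstat, np.inf)
        out[f"p_{f}"] = stats.f.sf(fstat, df_num, dfe)
    result = pd.DataFrame(out, index=x.values.index)
    for f in factors:
        result[f"q_{f}"] = stats.false_discovery_control(
            result[f"p_{f}"], method="bh"
        )
    if fdr_gate is not None:
        for f in factors:
            result[f"sig_{f}"] = result[f"q_{f}"] < fdr_gate
    return result


def _factor_dummies(labels: pd.Series) -> np.ndarray:
    levels = sorted(labels.unique())
    if len(levels) < 2:
        raise ValueError(f"factor {labels.name!r} has a single level")
    return np.column_stack(
        [(labels == lv).to_numpy(dtype=float) for lv in levels[1:]]
    )


def _find_aliased(blocks: dict[str, np.ndarray], intercept: np.ndarray) -> list[str]:
    aliased = []
    base = intercept
    for name, block in blocks.items():
        cand = np.column_stack([base, block])
        if np.linalg.matrix_rank(cand) < cand.shape[1]:
            aliased.append(name)
        else:
            base = cand
    return aliased


def _rss(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return (resid ** 2).sum(axis=0)
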