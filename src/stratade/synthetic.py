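"""Synthetic expression studies with known ground truth.

Generates log2 probe-level expression matrices that emulate a small
two-gender case/control microarray cohort (default design: 3 female
controls, 3 female PD, 6 male controls, 7 male PD), with configurable
batch structure, planted gender-specific / shared differential
expression, planted enriched gene sets, and matched triplicate qPCR Ct
tables. Every output is deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection
from .qpcr import CtTable
from .types import DISEASES, GENDERS, ExpressionMatrix, SampleMetadata

#: planted-effect target categories
DE_CONTRASTS = ("male-only", "female-only", "shared")

DEFAULT_GROUP_SIZES = {
    ("female", "control"): 3,
    ("female", "PD"): 3,
    ("male", "control"): 6,
    ("male", "PD"): 7,
}


@dataclass(frozen=True)
class PlantedEffect:
    """One planted differential-expression effect.

    ``contrast`` selects which PD samples are shifted: ``male-only`` shifts
    male PD, ``female-only`` shifts female PD, ``shared`` shifts all PD.
    ``log2_effect`` is the magnitude (positive); ``direction`` is +1/-1.
    """

    gene: str
    contrast: str
    log2_effect: float
    direction: int = 1

    def __post_init__(self) -> None:
        if self.contrast not in DE_CONTRASTS:
            raise ValueError(f"unknown DE contrast {self.contrast!r}")
        if not math.isfinite(self.log2_effect) or self.log2_effect < 0:
            raise ValueError("log2_effect must be finite and non-negative")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")

    @property
    def signed_log2(self) -> float:
        return self.direction * self.log2_effect


@dataclass(frozen=True)
class EnrichedSetSpec:
    """A gene set to plant as enriched.

    ``de_fraction`` of its members are drawn from planted DE genes,
    optionally restricted to one or more DE categories via ``contrast``
    (a single category name or a tuple of them — e.g. a female-biased
    pathway mixes ``female-only`` and ``shared`` genes so it lights up
    in both the female list and the all-samples list).
    """

    set_id: str
    de_fraction: float
    contrast: str | tuple[str, ...] | None = None
    size: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in (0, 1]")
        for c in self.categories or ():
            if c not in DE_CONTRASTS:
                raise ValueError(f"unknown DE contrast {c!r}")

    @property
    def categories(self) -> tuple[str, ...] | None:
        if self.contrast is None:
            return None
        if isinstance(self.contrast, str):
            return (self.contrast,)
        return tuple(self.contrast)


@dataclass
class SimulationConfig:
    """Parameters of a synthetic study. ``seed`` is mandatory."""

    seed: int
    n_probes: int = 2000
    n_genes: int = 1800
    group_sizes: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    n_batches: int = 2
    batch_assignment: dict[str, str] | None = None
    batch_shift_sd: float = 0.0
    noise_sd: float = 0.35
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0
    probe_offset_sd: float = 0.25
    de_spec: list[PlantedEffect] = field(default_factory=list)
    enriched_sets: list[EnrichedSetSpec] = field(default_factory=list)
    n_gene_sets: int = 20
    set_size_range: tuple[int, int] = (10, 50)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_probes < 1 or self.n_genes < 1:
            raise ValueError("n_probes and n_genes must be positive")
        if self.n_genes > self.n_probes:
            raise ValueError("n_genes must not exceed n_probes")
        for key, n in self.group_sizes.items():
            if n < 1:
                raise ValueError(f"group {key} must have a positive size")
        for sd in (self.batch_shift_sd, self.noise_sd, self.baseline_sd,
                   self.probe_offset_sd):
            if sd < 0:
                raise ValueError("standard deviations must be non-negative")
        if self.n_batches < 1:
            raise ValueError("n_batches must be positive")
        lo, hi = self.set_size_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid set_size_range")


@dataclass
class SyntheticStudy:
    """A generated study plus its ground truth."""

    expression: ExpressionMatrix
    metadata: SampleMetadata
    truth_de: set[tuple[str, str, int]]  # (gene, DE contrast, direction)
    truth_enriched: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        genes = set(self.expression.probe_to_gene)
        for gene, contrast, _direction in self.truth_de:
            if gene not in genes:
                raise ValueError(f"truth gene {gene!r} not in expression")
        if list(self.metadata.table.index) != self.expression.sample_ids:
            raise ValueError("metadata samples do not match expression columns")

    def de_genes(self, contrast: str | None = None) -> set[str]:
        return {
            g for g, c, _ in self.truth_de if contrast is None or c == contrast
        }


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _sample_ids(group_sizes: dict[tuple[str, str], int]) -> pd.DataFrame:
    rows = []
    for gender in GENDERS:
        for disease in DISEASES:
            n = group_sizes.get((gender, disease), 0)
            for i in range(1, n + 1):
                sid = f"{gender[0]}{'N' if disease == 'control' else 'PD'}{i}"
                rows.append((sid, gender, disease))
    return pd.DataFrame(rows, columns=["sample_id", "gender", "disease"])


def _effect_groups(contrast: str) -> list[tuple[str, str]]:
    """Groups that must be estimable for a planted effect to be testable."""
    if contrast == "male-only":
        return [("male", "control"), ("male", "PD")]
    if contrast == "female-only":
        return [("female", "control"), ("female", "PD")]
    return [(g, d) for g in GENDERS for d in DISEASES]


def _affected_samples(contrast: str, meta: pd.DataFrame) -> pd.Index:
    pd_mask = meta["disease"] == "PD"
    if contrast == "male-only":
        pd_mask &= meta["gender"] == "male"
    elif contrast == "female-only":
        pd_mask &= meta["gender"] == "female"
    return meta.index[pd_mask]


def generate_expression_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate a probe-level log2 study with planted effects.

    The model is additive on the log2 scale::

        value = gene baseline + probe offset + batch shift
                + planted effect (PD samples of the targeted gender)
                + Gaussian noise

    Raises
    ------
    ValueError
        If a planted effect targets a contrast whose groups have fewer
        than 2 samples.
    """
    rng = np.random.default_rng(config.seed)
    samples = _sample_ids(config.group_sizes).set_index("sample_id")

    for eff in config.de_spec:
        for group in _effect_groups(eff.contrast):
            n = config.group_sizes.get(group, 0)
            if n < 2:
                raise ValueError(
                    f"planted effect on {eff.gene!r} targets contrast "
                    f"{eff.contrast!r} but group {group} has {n} sample(s); "
                    "need at least 2"
                )

    # batches interleave within each (gender, disease) group so that batch
    # is never confounded with the design factors
    if config.batch_assignment is not None:
        missing = set(samples.index) - set(config.batch_assignment)
        if missing:
            raise ValueError(f"batch_assignment missing samples: {sorted(missing)}")
        samples["batch"] = [config.batch_assignment[s] for s in samples.index]
    else:
        batch = []
        for _, grp in samples.groupby(["gender", "disease"], sort=False):
            batch.extend(
                f"B{i % config.n_batches + 1}" for i in range(len(grp))
            )
        samples["batch"] = batch

    genes = _gene_ids(config.n_genes)
    # probe 1..k per gene, extra probes distributed round-robin
    probe_gene_idx = np.arange(config.n_probes) % config.n_genes
    probe_rank = np.arange(config.n_probes) // config.n_genes + 1
    probe_ids = [
        f"{genes[g]}_p{r}" for g, r in zip(probe_gene_idx, probe_rank)
    ]
    probe_to_gene = pd.Series(
        [genes[g] for g in probe_gene_idx], index=probe_ids
    )

    n_samples = len(samples)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    probe_offset = rng.normal(0.0, config.probe_offset_sd, config.n_probes)
    probe_offset[probe_rank == 1] = 0.0

    batches = sorted(samples["batch"].unique())
    batch_shift = rng.normal(0.0, config.batch_shift_sd,
                             (len(batches), config.n_genes))
    batch_idx = samples["batch"].map({b: i for i, b in enumerate(batches)})

    values = (
        baseline[probe_gene_idx][:, None]
        + probe_offset[:, None]
        + batch_shift[batch_idx.to_numpy()][:, probe_gene_idx].T
        + rng.normal(0.0, config.noise_sd, (config.n_probes, n_samples))
    )

    gene_pos = {g: np.flatnonzero(probe_gene_idx == i)
                for i, g in enumerate(genes)}
    truth_de: set[tuple[str, str, int]] = set()
    for eff in config.de_spec:
        if eff.gene not in gene_pos:
            raise ValueError(f"planted gene {eff.gene!r} not in study")
        cols = samples.index.get_indexer(_affected_samples(eff.contrast, samples))
        values[np.ix_(gene_pos[eff.gene], cols)] += eff.signed_log2
        truth_de.add((eff.gene, eff.contrast, eff.direction))

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=probe_ids, columns=samples.index),
        probe_to_gene,
    )
    meta = SampleMetadata(samples)
    return SyntheticStudy(expr, meta, truth_de,
                          {s.set_id for s in config.enriched_sets})


def generate_gene_sets(
    config: SimulationConfig, study: SyntheticStudy
) -> GeneSetCollection:
    """Generate a GMT-serializable collection with planted enriched sets.

    Enriched sets draw ``de_fraction`` of their members from the planted
    DE genes (restricted to the matching category when the spec names
    one); the remainder, and all background sets, are drawn uniformly
    from non-DE genes of the study universe.
    """
    rng = np.random.default_rng([config.seed, 7])
    universe = sorted(set(study.expression.probe_to_gene))
    all_de = sorted(study.de_genes())
    non_de = sorted(set(universe) - set(all_de))
    lo, hi = config.set_size_range

    sets: dict[str, tuple[str, list[str]]] = {}
    for spec in config.enriched_sets:
        size = spec.size if spec.size is not None else int(rng.integers(lo, hi + 1))
        if spec.categories is None:
            pool = sorted(study.de_genes())
        else:
            pool = sorted(
                set().union(*(study.de_genes(c) for c in spec.categories))
            )
        n_de = int(round(spec.de_fraction * size))
        if n_de > len(pool):
            raise ValueError(
                f"set {spec.set_id!r} requests {n_de} DE members but only "
                f"{len(pool)} planted DE genes are available"
            )
        members = list(rng.choice(pool, n_de, replace=False))
        members += list(rng.choice(non_de, size - n_de, replace=False))
        sets[spec.set_id] = (f"planted enriched ({spec.contrast or 'any'})",
                             sorted(members))

    n_background = max(0, config.n_gene_sets - len(config.enriched_sets))
    for i in range(1, n_background + 1):
        size = int(rng.integers(lo, hi + 1))
        members = sorted(rng.choice(non_de, size, replace=False))
        sets[f"SET{i:03d}"] = ("background", members)

    return GeneSetCollection(sets=sets, universe=set(universe))


def generate_ct_table(
    study: SyntheticStudy,
    genes: list[str],
    reference_gene: str,
    replicate_sd: float,
    seed: int,
    n_replicates: int = 3,
    c0: float = 30.0,
) -> CtTable:
    """Simulate a triplicate qPCR Ct table matched to the study.

    Ct follows ``c0 - log2(expression)`` plus replicate noise, i.e. one
    PCR cycle per two-fold expression change, so downstream 2^-dCt
    recovers planted ratios in expectation.
    """
    gene_expr = study.expression.gene_level()
    wanted = list(dict.fromkeys(list(genes) + [reference_gene]))
    missing = [g for g in wanted if g not in gene_expr.index]
    if missing:
        if reference_gene in missing:
            raise ValueError(f"reference gene {reference_gene!r} not in study")
        raise ValueError(f"genes not in study: {missing}")

    rng = np.random.default_rng(seed)
    rows = []
    for gene in wanted:
        for sample in gene_expr.columns:
            base_ct = c0 - gene_expr.at[gene, sample]
            noise = rng.normal(0.0, replicate_sd, n_replicates) if replicate_sd > 0 \
                else np.zeros(n_replicates)
            for rep in range(1, n_replicates + 1):
                rows.append((gene, sample, rep, base_ct + noise[rep - 1]))
    table = pd.DataFrame(rows, columns=["gene", "sample", "replicate", "ct"])
    return CtTable(table=table, reference_gene=reference_gene,
                   n_replicates=n_replicates)
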