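"""Core value types shared across the pipeline.

The package works on log2 expression matrices (probes x samples) with a
probe-to-gene map, plus per-sample metadata carrying ``gender``, ``disease``
and ``batch`` labels. Contrast definitions name the six standard group
comparisons of a two-gender case/control design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENDERS = ("male", "female")
DISEASES = ("control", "PD")

#: contrast name -> ((gender, disease) selector for group A, same for group B).
#: ``None`` matches any value. Fold changes are reported as B relative to A.
CONTRASTS: dict[str, tuple[tuple[str | None, str], tuple[str | None, str]]] = {
    "allN_allPD": ((None, "control"), (None, "PD")),
    "mN_mPD": (("male", "control"), ("male", "PD")),
    "fN_fPD": (("female", "control"), ("female", "PD")),
    # positive fold change = higher in males
    "mN_fN": (("female", "control"), ("male", "control")),
    "mPD_fPD": (("female", "PD"), ("male", "PD")),
}

#: shorthand used in gene-list headers for the two within-gender contrasts
CONTRAST_ALIASES = {"mPD": "mN_mPD", "fPD": "fN_fPD"}

STRINGENCIES = ("stringent", "relaxed")
#: permutation p-value gate applied on top of q < 0.05
STRINGENCY_P = {"stringent": 0.01, "relaxed": 0.05}
Q_THRESHOLD = 0.05


def resolve_contrast(name: str) -> str:
    """Map a contrast alias (``mPD``, ``fPD``) to its canonical name."""
    return CONTRAST_ALIASES.get(name, name)


@dataclass
class ExpressionMatrix:
    """Log2 expression values, probes x samples, with a probe→gene map.

    Parameters
    ----------
    values
        DataFrame of log2 intensities; index = probe ids, columns = sample ids.
    probe_to_gene
        Series mapping probe id to gene symbol. Probes missing from the map
        keep their probe id as gene symbol.
    """

    values: pd.DataFrame
    probe_to_gene: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate probe ids: {list(dups[:5])}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        vals = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("expression values must be finite")
        if self.probe_to_gene is None:
            self.probe_to_gene = pd.Series(
                self.values.index, index=self.values.index
            )
        else:
            mapped = self.probe_to_gene.reindex(self.values.index)
            missing = mapped.isna()
            if missing.any():
                mapped[missing] = mapped.index[missing]
            self.probe_to_gene = mapped

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def genes(self) -> pd.Index:
        return pd.Index(sorted(set(self.probe_to_gene)))

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)], self.probe_to_gene)

    def gene_level(self) -> pd.DataFrame:
        """Average log2 values of probes mapping to the same gene."""
        return self.values.groupby(self.probe_to_gene).mean()


@dataclass
class SampleMetadata:
    """Per-sample labels: ``gender``, ``disease`` and ``batch``."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gender", "disease", "batch"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")
        if self.table[list(required)].isna().any().any():
            raise ValueError("metadata labels must be complete")
        bad_gender = set(self.table["gender"]) - set(GENDERS)
        if bad_gender:
            raise ValueError(f"unknown gender labels: {sorted(bad_gender)}")
        bad_disease = set(self.table["disease"]) - set(DISEASES)
        if bad_disease:
            raise ValueError(f"unknown disease labels: {sorted(bad_disease)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def select(self, gender: str | None = None, disease: str | None = None) -> list[str]:
        """Sample ids matching the given gender/disease selectors."""
        mask = pd.Series(True, index=self.table.index)
        if gender is not None:
            mask &= self.table["gender"] == gender
        if disease is not None:
            mask &= self.table["disease"] == disease
        return list(self.table.index[mask])

    def contrast_groups(self, contrast: str) -> tuple[list[str], list[str]]:
        """Resolve a contrast name to its (group_A, group_B) sample ids."""
        name = resolve_contrast(contrast)
        if name not in CONTRASTS:
            raise KeyError(f"unknown contrast {contrast!r}")
        (ga, da), (gb, db) = CONTRASTS[name]
        a = self.select(gender=ga, disease=da)
        b = self.select(gender=gb, disease=db)
        if not a or not b:
            raise ValueError(f"contrast {name}: empty group")
        if set(a) & set(b):
            raise ValueError(f"contrast {name}: groups overlap")
        return a, b


@dataclass
class GeneList:
    """Significance-filtered entries for one contrast at one stringency."""

    contrast: str
    stringency: str
    entries: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["probe_id", "gene", "fold_change", "q", "p"]
    ))

    def __post_init__(self) -> None:
        if self.stringency not in STRINGENCIES:
            raise ValueError(f"unknown stringency {self.stringency!r}")
        needed = {"probe_id", "gene", "fold_change"}
        missing = needed - set(self.entries.columns)
        if missing:
            raise ValueError(f"gene list missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> set[str]:
        return set(self.entries["gene"])
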