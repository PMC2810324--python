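import numpy as np
import pandas as pd
import pytest

import stratade as st


def make_expression(values, sample_ids=None, probe_ids=None, probe_to_gene=None):
    """ExpressionMatrix from a plain array (probes x samples)."""
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    probe_ids = probe_ids or [f"p{i}" for i in range(n_probes)]
    sample_ids = sample_ids or [f"s{i}" for i in range(n_samples)]
    frame = pd.DataFrame(values, index=probe_ids, columns=sample_ids)
    if probe_to_gene is not None:
        probe_to_gene = pd.Series(probe_to_gene, index=probe_ids)
    return st.ExpressionMatrix(frame, probe_to_gene)


def make_metadata(rows):
    """SampleMetadata from (sample_id, gender, disease, batch) tuples."""
    table = pd.DataFrame(
        rows, columns=["sample_id", "gender", "disease", "batch"]
    ).set_index("sample_id")
    return st.SampleMetadata(table)


def make_gene_list(contrast, genes_fcs, stringency="stringent"):
    """GeneList with one probe per gene from (gene, fold_change) pairs."""
    entries = pd.DataFrame(
        [(f"{g}_p1", g, fc, 0.01, 0.001) for g, fc in genes_fcs],
        columns=["probe_id", "gene", "fold_change", "q", "p"],
    )
    return st.GeneList(contrast=contrast, stringency=stringency,
                       entries=entries)


@pytest.fixture(scope="session")
def default_study():
    """Default-design study (3/3 female, 6/7 male) with planted effects."""
    config = st.SimulationConfig(
        seed=42,
        n_probes=400,
        n_genes=350,
        batch_shift_sd=0.5,
        de_spec=[
            st.PlantedEffect("G0001", "male-only", 1.5, -1),
            st.PlantedEffect("G0002", "female-only", 1.5, 1),
            st.PlantedEffect("G0003", "shared", 1.5, -1),
        ],
    )
    return st.generate_expression_study(config)
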