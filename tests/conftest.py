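import numpy as np
import pandas as pd
import pytest

from impnet.data_model import ExpressionMatrix, ProbeAnnotation, StudyDesign


@pytest.fixture
def design():
    return StudyDesign()


@pytest.fixture
def small_design():
    return StudyDesign(time_points=(2, 4), replicates=("M", "F"), baseline=2)


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


def make_matrix(values, design, probe_ids=None):
    values = np.asarray(values, dtype=float)
    probe_ids = probe_ids or [f"P{i:03d}" for i in range(values.shape[0])]
    data = pd.DataFrame(
        values, index=pd.Index(probe_ids, name="probe_id"),
        columns=design.sample_names,
    )
    return ExpressionMatrix(data=data, design=design)


@pytest.fixture
def random_matrix(design, rng):
    return make_matrix(rng.normal(8, 1, size=(50, 12)), design)


def make_annotation(mapping):
    """mapping: probe_id -> gene_symbol"""
    table = pd.DataFrame(
        {
            "gene_symbol": list(mapping.values()),
            "gene_id": [f"ID{i}" for i in range(len(mapping))],
        },
        index=pd.Index(list(mapping.keys()), name="probe_id"),
    )
    return ProbeAnnotation(table=table)
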