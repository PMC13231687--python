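import numpy as np
import pandas as pd
import pytest

from acprofiles import pipeline, synth
from acprofiles.matrix import ProfilingMatrix


class InstrumentedMatrix(ProfilingMatrix):
    """Profiling matrix that records every (compound, assay) cell access."""

    def __init__(self, frame):
        super().__init__(frame)
        self.accesses = []

    @classmethod
    def wrap(cls, matrix: ProfilingMatrix) -> "InstrumentedMatrix":
        return cls(matrix.to_frame())

    def _read_cells(self, compound_ids, assay_id):
        self.accesses.extend((c, assay_id) for c in compound_ids)
        return super()._read_cells(compound_ids, assay_id)

    def reset(self):
        self.accesses = []


@pytest.fixture
def instrument():
    return InstrumentedMatrix


@pytest.fixture
def tiny_matrix():
    frame = pd.DataFrame(
        [[1, 0, 1], [0, 1, 1], [0, 0, 1], [1, 1, 0]],
        index=pd.Index(["c1", "c2", "c3", "c4"], name="compound_id"),
        columns=["a1", "a2", "a3"],
    )
    return ProfilingMatrix(frame)


def random_matrix(rng, n_compounds=20, n_assays=10, p=0.3) -> ProfilingMatrix:
    values = (rng.random((n_compounds, n_assays)) < p).astype(int)
    frame = pd.DataFrame(
        values,
        index=pd.Index([f"c{i}" for i in range(n_compounds)], name="compound_id"),
        columns=[f"a{j}" for j in range(n_assays)],
    )
    return ProfilingMatrix(frame)


@pytest.fixture(scope="session")
def synth_small():
    """A small synthetic data set shared across tests (read-only)."""
    cfg = synth.SyntheticConfig(n_series=40, n_assays=40, n_test_assays=4, seed=11)
    records, truth_series, matrix, ground_truth = synth.generate(cfg)
    mms_list = pipeline.extract_series(records)
    return {
        "cfg": cfg,
        "records": records,
        "truth_series": truth_series,
        "matrix": matrix,
        "ground_truth": ground_truth,
        "mms_list": mms_list,
        "smiles_by_id": {r.compound_id: r.smiles for r in records},
    }
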