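import numpy as np
import pandas as pd
import pytest

from mirnorm.io import CqMatrix, SampleAnnotation


def make_cq(data: dict, samples=None, max_cycles=40.0) -> CqMatrix:
    """Build a CqMatrix from {gene: [cq per sample]}."""
    frame = pd.DataFrame(data).T
    if samples is not None:
        frame.columns = samples
    else:
        frame.columns = [f"s{i+1}" for i in range(frame.shape[1])]
    return CqMatrix(frame, max_cycles=max_cycles)


def make_annotation(groups: dict, **columns) -> SampleAnnotation:
    """Build an annotation from {group: [sample ids]} plus extra columns."""
    rows = [(s, g) for g, ss in groups.items() for s in ss]
    frame = pd.DataFrame(rows, columns=["sample", "group"]).set_index("sample")
    for name, values in columns.items():
        frame[name] = values
    outcome = "bmd" if "bmd" in frame.columns else None
    return SampleAnnotation(frame, outcome=outcome)


@pytest.fixture
def rng():
    return np.random.default_rng(20160347)


@pytest.fixture
def small_cq():
    return make_cq({"geneA": [20.0, 21.0, 22.0], "geneB": [25.0, 25.5, 26.0],
                    "geneC": [30.0, 29.0, 28.0]})
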