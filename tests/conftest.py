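import numpy as np
import pandas as pd
import pytest

from crdnet.cohort_io import CRDMatrix, OutcomeTable


def make_crd(values, participant_ids=None, component_ids=None) -> CRDMatrix:
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    ids = participant_ids or [f"P{i+1:03d}" for i in range(n)]
    comps = component_ids or [f"cmp{j+1:02d}" for j in range(p)]
    return CRDMatrix(pd.DataFrame(values, index=ids, columns=comps))


def make_outcomes(asthma, participant_ids=None, **continuous) -> OutcomeTable:
    asthma = np.asarray(asthma, dtype=int)
    ids = participant_ids or [f"P{i+1:03d}" for i in range(len(asthma))]
    cont = pd.DataFrame({k: np.asarray(v, float) for k, v in continuous.items()}, index=ids)
    return OutcomeTable(pd.DataFrame({"asthma": asthma}, index=ids), cont)


@pytest.fixture
def toy_crd() -> CRDMatrix:
    """3 participants x 2 components with a mix of zeros and positives."""
    return make_crd([[0.0, 0.5], [1.2, 0.0], [0.0, 2.0]])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
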