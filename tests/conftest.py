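import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")

from pcsrscan.annotation import CytobandMap, parse_cytoband_file


@pytest.fixture
def toy_map() -> CytobandMap:
    """Two chromosomes, two bands each: 1p1 [0,100), 1q1 [100,300), 2p1, 2q1."""
    text = (
        "chr1\t0\t100\tp1\tgneg\n"
        "chr1\t100\t300\tq1\tgpos50\n"
        "chr2\t0\t150\tp1\tgneg\n"
        "chr2\t150\t400\tq1\tgneg\n"
    )
    return parse_cytoband_file(io.StringIO(text))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240505)


def make_study(case: np.ndarray, control: np.ndarray, cancer_id="c1", probes=None):
    """Assemble an ExpressionStudy from case/control value arrays."""
    from pcsrscan.diffexpr import ExpressionStudy

    case = np.atleast_2d(case)
    control = np.atleast_2d(control)
    n_probes = case.shape[0]
    probes = probes or [f"p{i}" for i in range(n_probes)]
    cols = [f"case{i}" for i in range(case.shape[1])] + [
        f"ctrl{i}" for i in range(control.shape[1])
    ]
    matrix = pd.DataFrame(np.hstack([case, control]), index=probes, columns=cols)
    group = pd.Series(
        ["case"] * case.shape[1] + ["control"] * control.shape[1], index=cols
    )
    return ExpressionStudy(cancer_id=cancer_id, matrix=matrix, group=group)
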