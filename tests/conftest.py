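import numpy as np
import pandas as pd
import pytest

from homonet.design import default_paradigm
from homonet.nodes import NodeSet, default_nodeset
from homonet.synthetic import SubjectTimeSeries


@pytest.fixture(scope="session")
def nodes28():
    return default_nodeset()


@pytest.fixture(scope="session")
def paradigm():
    return default_paradigm()


@pytest.fixture
def nodes4():
    """Tiny 2-pair node set for exact-null and geometry tests."""
    return NodeSet(
        labels=("a_L", "a_R", "b_L", "b_R"),
        centers_mm=np.array([[-10.0, 0, 0], [10, 0, 0], [-10, 12, 0], [10, 12, 0]]),
        hemisphere=("L", "R", "L", "R"),
        pair_map=((0, 1), (2, 3)),
    )


@pytest.fixture
def nodes8():
    """3 pairs + 2 unpaired, small enough for exact nulls."""
    xs = [(-10, 10), (-10, 10), (-14, 14)]
    centers = []
    for k, (xl, xr) in enumerate(xs):
        centers += [[xl, 12 * k, 0], [xr, 12 * k, 0]]
    centers += [[-8, 40, 0], [0, 48, 0]]
    return NodeSet(
        labels=("p1_L", "p1_R", "p2_L", "p2_R", "p3_L", "p3_R", "u1", "vermis"),
        centers_mm=np.array(centers, dtype=float),
        hemisphere=("L", "R", "L", "R", "L", "R", "L", "M"),
        pair_map=((0, 1), (2, 3), (4, 5)),
    )


def make_timeseries(data, tr_s=2.0, subject_id="sub-01"):
    n_scans = data.shape[1]
    conf = pd.DataFrame(
        np.zeros((n_scans, 1)), columns=["c"]
    )
    return SubjectTimeSeries(
        data=data, tr_s=tr_s, confounds=conf, subject_id=subject_id
    )
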