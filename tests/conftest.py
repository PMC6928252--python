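import numpy as np
import pandas as pd
import pytest

from nestedpls.dataset import OBS_COLUMNS, TensorPair, dataset_from_frame
from nestedpls.standardize import BlockSpec, StandardizationSpec
from nestedpls.synthetic import generate, random_planted


def long_rows(block, cond, time, values_by_variable, replicate_id, pairing_id=None, unit="d"):
    return [
        (cond, float(time), unit, var, block, replicate_id,
         pairing_id if pairing_id is not None else pd.NA, float(val))
        for var, val in values_by_variable.items()
    ]


def frame(rows):
    return pd.DataFrame(rows, columns=OBS_COLUMNS)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def identity_spec():
    """No baseline, no scaling: standardization is a no-op."""
    return StandardizationSpec(x=BlockSpec(), y=BlockSpec(), zero_variance="lenient")


@pytest.fixture
def planted2():
    """Noise-free rank-2 planted model, 5 conditions, 3 replicates per cell."""
    return random_planted(
        5, 3, 4, 3, 3, n_lvs=2, seed=1, x_replicates=3, y_replicates=3
    )


@pytest.fixture
def planted2_data(planted2):
    return generate(planted2)


@pytest.fixture
def small_dataset():
    """2 conditions x 2 times x 2 variables per block, 3 replicates per cell."""
    rngl = np.random.default_rng(7)
    rows = []
    for block, variables in (("X", ["x1", "x2"]), ("Y", ["y1", "y2"])):
        for cond in ("a", "b"):
            for t in (0.0, 1.0):
                for r in range(3):
                    rows += long_rows(
                        block, cond, t,
                        {v: rngl.normal() for v in variables},
                        replicate_id=f"r{r}",
                    )
    return dataset_from_frame(frame(rows))


def random_tensor_pair(rng, i=5, j=3, k=4, l=3, m=3):
    return TensorPair(
        X=rng.standard_normal((i, j, k)),
        Y=rng.standard_normal((i, l, m)),
        conditions=tuple(f"c{a}" for a in range(i)),
        x_times=tuple(float(a) for a in range(j)),
        x_vars=tuple(f"x{a}" for a in range(k)),
        y_times=tuple(float(a) for a in range(l)),
        y_vars=tuple(f"y{a}" for a in range(m)),
    )
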