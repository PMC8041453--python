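import numpy as np
import pytest

from anchorpoint import SimDesign, fit_rasch_cml, generate_study1, make_toy


@pytest.fixture(scope="session")
def toy_pair():
    """True-parameter toy: 10 items, item 4 (0-based 3) with DIF +0.75."""
    return make_toy()


@pytest.fixture(scope="session")
def six_by_three():
    """A small printed response matrix: 6 persons x 3 items, no extreme scores."""
    return np.array(
        [
            [1, 0, 0],
            [1, 1, 0],
            [1, 0, 1],
            [0, 1, 0],
            [1, 1, 0],
            [1, 0, 0],
        ],
        dtype=np.int8,
    )


@pytest.fixture(scope="session")
def dif_fits():
    """CML fits for a large two-group sample with one strong DIF item.

    10 items, 1000 persons per group, item index 3 shifted by 1.0 logit in
    the focal group.  Session-scoped: fitting is the expensive step and
    many tests only need the resulting estimates.
    """
    design = SimDesign(
        m=10, n_ref=1000, n_foc=1000, dif_items=(3,), dif_size=1.0, reps=1, seed=42
    )
    data, truth = generate_study1(design, 0)
    ref, foc = data.split()
    return fit_rasch_cml(ref), fit_rasch_cml(foc), truth


@pytest.fixture(scope="session")
def null_fits():
    """CML fits for a two-group sample with no DIF (8 items, 500/group)."""
    design = SimDesign(m=8, n_ref=500, n_foc=500, dif_items=(), reps=1, seed=7)
    data, _ = generate_study1(design, 0)
    ref, foc = data.split()
    return fit_rasch_cml(ref), fit_rasch_cml(foc)
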