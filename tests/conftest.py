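import numpy as np
import pytest

from repdist import build_studies
from repdist.experiment import enumerate_permutations
from repdist.rates import RateEstimate, RateTable


@pytest.fixture(scope="session")
def studies():
    """The two dugong studies and their shared breeding-status result."""
    return build_studies()


@pytest.fixture(scope="session")
def dugong_cells(studies):
    study1, study2, _ = studies
    return enumerate_permutations(study1, study2)


def make_rate_table(rates, cells=None):
    """A RateTable with arbitrary per-cell rates (for distance-level tests).

    ``rates`` maps study_index -> phi; cells default to the dugong grid, and
    validity follows the cell flags (zero-convention rows must be 0).
    """
    if cells is None:
        study1, study2, _ = build_studies()
        cells = enumerate_permutations(study1, study2)
    estimates = []
    for cell in cells:
        phi = float(rates[cell.study_index])
        if cell.valid:
            estimates.append(RateEstimate(phi, 0, 0, 0, 0.0, valid_permutation=True))
        else:
            estimates.append(RateEstimate(0.0, 0, 0, 0, 0.0, valid_permutation=False))
    return RateTable(cells=tuple(cells), estimates=tuple(estimates))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
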