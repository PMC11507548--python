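"""Component distances: exact oracle values, symmetry, structural zeros."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from repdist.distance import component_distance, distance_vector
from repdist.dugong import PUBLISHED_RATES, published_rate_table
from repdist.experiment import ComponentRole, PERMUTABLE_ROLES
from repdist.rates import build_rate_table

from conftest import make_rate_table


def test_published_rates_give_published_distances():
    dvec = distance_vector(published_rate_table())
    assert dvec.d_spre == pytest.approx(0.406, abs=1e-3)
    assert dvec.d_model == pytest.approx(0.539, abs=1e-3)
    assert dvec.d_spost == pytest.approx(0.036, abs=1e-3)
    assert dvec.d_dstruct == pytest.approx(0.110, abs=1e-3)
    assert dvec.n_permutations_per_side == 8


def test_identical_rate_profiles_give_zero_distance():
    table = make_rate_table({i: 0.7 if i not in (9, 10, 11, 12) else 0.0 for i in range(1, 17)})
    # Spost and Ds splits see identical profiles on both sides
    assert component_distance(table, ComponentRole.POST_DATA) == 0.0
    assert component_distance(table, ComponentRole.DATA_STRUCTURE) == 0.0


rates_strategy = st.lists(
    st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=12, max_size=12
)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(rates_strategy)
def test_component_distance_matches_hand_oracle(valid_rates):
    # zero-convention cells 9-12 stay 0; remaining 12 rates are arbitrary
    rates = dict(zip([i for i in range(1, 17) if i not in (9, 10, 11, 12)], valid_rates))
    rates.update({i: 0.0 for i in (9, 10, 11, 12)})
    table = make_rate_table(rates)
    for role, versions in [
        (ComponentRole.PRE_DATA, [c.spre_version for c in table.cells]),
        (ComponentRole.MODEL, [c.model_version for c in table.cells]),
        (ComponentRole.POST_DATA, [c.spost_version for c in table.cells]),
        (ComponentRole.DATA_STRUCTURE, [c.dstruct_version for c in table.cells]),
    ]:
        phis = np.array([rates[i] for i in range(1, 17)])
        mask = np.array(versions) == 1
        oracle = abs(phis[mask].mean() - phis[~mask].mean())
        assert component_distance(table, role) == pytest.approx(oracle, abs=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=16, max_size=16))
def test_complement_invariance_on_fully_valid_tables(phis):
    # on a grid with no zero-convention cells, replacing every rate phi by
    # 1-phi (the complement result) leaves all four distances unchanged
    from repdist import build_studies
    from repdist.experiment import enumerate_permutations

    study1, _, _ = build_studies()
    cells = enumerate_permutations(study1, study1.replication_of("copy"))
    rates = dict(zip(range(1, 17), phis))
    flipped = {i: 1.0 - p for i, p in rates.items()}
    a = distance_vector(make_rate_table(rates, cells))
    b = distance_vector(make_rate_table(flipped, cells))
    assert a.as_tuple() == pytest.approx(b.as_tuple(), abs=1e-12)


def test_distance_symmetric_under_parent_swap():
    # relabeling versions 1<->2 mirrors every cell; distances are unchanged
    rates = {i: PUBLISHED_RATES[i] for i in range(1, 17)}
    table = published_rate_table()
    swapped = {}
    for cell in table.cells:
        mirror = next(
            c.study_index
            for c in table.cells
            if c.versions == tuple(3 - v for v in cell.versions)
        )
        swapped[cell.study_index] = rates[mirror]
    # the mirrored grid has its zero-convention cells at 5-8; build from raw
    # rate profiles and compare the version-mean gaps directly
    phis = np.array([rates[i] for i in range(1, 17)])
    phis_sw = np.array([swapped[i] for i in range(1, 17)])
    for role in PERMUTABLE_ROLES:
        versions = np.array([c.version_of(role) for c in table.cells])
        d = abs(phis[versions == 1].mean() - phis[versions == 2].mean())
        d_sw = abs(phis_sw[versions == 1].mean() - phis_sw[versions == 2].mean())
        assert d == pytest.approx(d_sw, abs=1e-12)


def test_shared_table_of_identical_experiments_has_zero_distance(studies):
    # with common random numbers, every cell of a self-permutation grid is the
    # same experiment fed the same stream, so the distance is exactly zero
    study1, _, result = studies
    table = build_rate_table(
        study1,
        study1.replication_of("copy"),
        result,
        60,
        master_seed=9,
        common_random_numbers=True,
    )
    assert distance_vector(table).as_tuple() == (0.0, 0.0, 0.0, 0.0)


def test_single_component_change_zeroes_other_coordinates(studies):
    # experiments differing only in data structure: under common random
    # numbers the Spre/M/Spost splits average identical sets on both sides
    from dataclasses import replace

    from repdist.growth import DataStructure

    study1, _, result = studies
    modified = replace(study1, label="bigger-n", data_structure=DataStructure(n=60))
    table = build_rate_table(
        study1, modified, result, 80, master_seed=11, common_random_numbers=True
    )
    dvec = distance_vector(table)
    assert dvec.d_spre == 0.0
    assert dvec.d_model == 0.0
    assert dvec.d_spost == 0.0


def test_incomplete_table_raises_naming_cells():
    rates = {i: 0.5 for i in range(1, 17)}
    rates.update({i: 0.0 for i in (9, 10, 11, 12)})
    table = make_rate_table(rates)
    import dataclasses
    import math

    broken = dataclasses.replace(
        table,
        estimates=tuple(
            dataclasses.replace(e, phi_hat=math.nan) if i == 2 else e
            for i, e in enumerate(table.estimates, start=1)
        ),
    )
    with pytest.raises(ValueError, match=r"\[2\]"):
        distance_vector(broken)
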