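"""Planned-modification sequences and the MVE convergence heuristic."""

from dataclasses import replace

import numpy as np
import pytest

from repdist.distance import DistanceVector
from repdist.dugong import SPRE2
from repdist.experiment import ComponentRole, PermutationError
from repdist.growth import DataStructure, NONLINEAR_MODEL
from repdist.mve import (
    ModificationStep,
    StudySequence,
    convergence_summary,
    extend_sequence,
    new_sequence,
)


def _step(i, roles):
    return ModificationStep(step_index=i, modified_components=frozenset(roles))


def test_modification_step_must_change_something():
    with pytest.raises(ValueError, match="at least one"):
        ModificationStep(step_index=1, modified_components=frozenset())


def test_identical_proposal_appends_all_zero_distance(studies):
    study1, _, result = studies
    seq = new_sequence(study1, result)
    step = _step(1, [ComponentRole.DATA_STRUCTURE])
    seq2 = extend_sequence(
        seq,
        step,
        study1.replication_of("copy"),
        n_reps=50,
        master_seed=3,
        common_random_numbers=True,
    )
    assert seq2.m == 2
    assert seq2.step_distances[-1].as_tuple() == (0.0, 0.0, 0.0, 0.0)
    assert seq2.log[-1].accepted


def test_single_component_change_localizes_distance(studies):
    study1, _, result = studies
    modified = replace(study1, label="n60", data_structure=DataStructure(n=60))
    seq = extend_sequence(
        new_sequence(study1, result),
        _step(1, [ComponentRole.DATA_STRUCTURE]),
        modified,
        n_reps=80,
        master_seed=4,
        common_random_numbers=True,
    )
    d = seq.step_distances[-1]
    assert d.d_spre == 0.0 and d.d_model == 0.0 and d.d_spost == 0.0


def test_rejected_step_keeps_sequence_and_logs(studies):
    study1, _, result = studies
    modified = replace(study1, label="n60", data_structure=DataStructure(n=60))
    seq = extend_sequence(
        new_sequence(study1, result),
        _step(1, [ComponentRole.DATA_STRUCTURE]),
        modified,
        n_reps=50,
        master_seed=5,
        acceptance_rule=lambda phi_new, phi_head: False,
    )
    assert seq.m == 1 and not seq.step_distances
    assert len(seq.log) == 1 and not seq.log[0].accepted


def test_axiom_violation_rejects_step(studies):
    study1, _, result = studies
    impossible = replace(
        study1, label="age-only-linear", pre_data=SPRE2
    )  # age-only design with the weight-requiring model: parents both invalid
    bad_head = replace(study1, label="bad", pre_data=SPRE2)
    with pytest.raises(PermutationError):
        extend_sequence(
            new_sequence(bad_head, result),
            _step(1, [ComponentRole.PRE_DATA]),
            impossible,
            n_reps=20,
            master_seed=6,
        )


def test_distance_bookkeeping_invariant(studies):
    study1, _, result = studies
    seq = new_sequence(study1, result)
    for i in range(1, 4):
        seq = extend_sequence(
            seq,
            _step(i, [ComponentRole.DATA_STRUCTURE]),
            replace(study1, label=f"n{20+i}", data_structure=DataStructure(n=20 + i)),
            n_reps=30,
            master_seed=i,
        )
    assert len(seq.step_distances) == seq.m - 1
    with pytest.raises(ValueError, match="m-1"):
        StudySequence(experiments=seq.experiments, result=result, step_distances=())


def _fake_sequence(distances, result):
    from repdist import build_studies

    study1, _, _ = build_studies()
    exps = tuple(study1.replication_of(f"e{i}") for i in range(len(distances) + 1))
    return StudySequence(
        experiments=exps, result=result, step_distances=tuple(distances)
    )


def test_convergence_flag_on_all_zero_sequence(studies):
    result = studies[2]
    zeros = [DistanceVector(0, 0, 0, 0)] * 4
    summary = convergence_summary(_fake_sequence(zeros, result))
    assert summary["converged"]
    assert all(max(r) == 0 for r in summary["rolling_range"].values())


def test_convergence_flag_false_for_growing_fluctuations(studies):
    result = studies[2]
    growing = [DistanceVector(v, 0, 0, 0) for v in (0.0, 0.5, 0.0, 0.9, 0.0, 1.0)]
    summary = convergence_summary(_fake_sequence(growing, result))
    assert not summary["converged"]


def test_convergence_needs_three_experiments(studies):
    result = studies[2]
    with pytest.raises(ValueError, match="at least 3"):
        convergence_summary(_fake_sequence([DistanceVector(0, 0, 0, 0)], result))


def test_dugong_mve_path_settles(studies):
    """Dropping weight and fixing the age-only model converges toward an MVE.

    Start from study 1 (linear model, weight measured, biased n=20), switch
    the model to the asymptotic-growth form, then drop weight from the
    design, then repeat the head unchanged: the final steps should have
    (near-)zero distances and a non-increasing rolling range.
    """
    from repdist.growth import PredictorDesign

    study1, study2, result = studies
    seq = new_sequence(study1, result)
    proposals = [
        (replace(study1, label="m2", model=NONLINEAR_MODEL), [ComponentRole.MODEL]),
        (
            replace(
                study1,
                label="m2-age-only",
                model=NONLINEAR_MODEL,
                pre_data=PredictorDesign(provides=frozenset({"age"})),
            ),
            [ComponentRole.PRE_DATA],
        ),
    ]
    for i, (prop, roles) in enumerate(proposals, start=1):
        seq = extend_sequence(
            seq, _step(i, roles), prop, n_reps=120, master_seed=40 + i,
            common_random_numbers=True,
            acceptance_rule=lambda new, head: True,
        )
    # repeat the head twice: a converged tail
    for i in (3, 4):
        seq = extend_sequence(
            seq, _step(i, [ComponentRole.MODEL]), seq.head.replication_of(f"r{i}"),
            n_reps=120, master_seed=40 + i, common_random_numbers=True,
        )
    summary = convergence_summary(seq, k=2)
    assert seq.step_distances[-1].as_tuple() == (0.0, 0.0, 0.0, 0.0)
    for ranges in summary["rolling_range"].values():
        assert ranges[-1] <= ranges[0] + 1e-12
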