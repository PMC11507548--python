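"""Planned-modification study sequences toward a Minimum Viable Experiment.

Instead of replicating an original study exactly, a planned-modification
sequence swaps study components in a controlled manner — canonically one
component per step — keeping modifications that preserve or improve the
result of interest and discarding the rest.  Each accepted step contributes
one four-coordinate distance vector between consecutive experiments; as the
sequence approaches a Minimum Viable Experiment (MVE, the minimal study that
still produces the result and is simple enough for near-exact replication)
the fluctuations of these distances should settle, and at an acceptable MVE
all distances are zero.

There is no published stopping rule for "acceptable"; the converged flag
reported here (a non-increasing rolling range of step distances) is a
labeled heuristic, not a theorem.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .distance import DistanceVector, distance_vector
from .experiment import ExperimentSpec, PermutationError, ResultSpec
from .rates import build_rate_table

__all__ = [
    "ModificationStep",
    "StepOutcome",
    "StudySequence",
    "new_sequence",
    "extend_sequence",
    "convergence_summary",
]


@dataclass(frozen=True)
class ModificationStep:
    """One proposed modification: which components change, plus new background K+."""

    step_index: int
    modified_components: frozenset
    added_background: str = ""

    def __post_init__(self):
        if self.step_index < 1:
            raise ValueError("step_index starts at 1")
        if not self.modified_components:
            raise ValueError("a planned modification alters at least one component")


@dataclass(frozen=True)
class StepOutcome:
    step: ModificationStep
    accepted: bool
    distance: DistanceVector
    phi_head: float
    phi_proposed: float


@dataclass(frozen=True)
class StudySequence:
    """An ordered chain of accepted experiments under planned modification."""

    experiments: tuple[ExperimentSpec, ...]
    result: ResultSpec
    step_distances: tuple[DistanceVector, ...] = ()
    head_rates: tuple[float, ...] = ()
    log: tuple[StepOutcome, ...] = ()

    def __post_init__(self):
        if not self.experiments:
            raise ValueError("a sequence starts from at least one experiment")
        if len(self.step_distances) != len(self.experiments) - 1:
            raise ValueError("need exactly (m-1) step distances for m experiments")

    @property
    def head(self) -> ExperimentSpec:
        return self.experiments[-1]

    @property
    def m(self) -> int:
        return len(self.experiments)


def new_sequence(original: ExperimentSpec, result: ResultSpec) -> StudySequence:
    return StudySequence(experiments=(original,), result=result)


def _default_acceptance(phi_proposed: float, phi_head: float) -> bool:
    # "yield or improve the desired result": the proposal's own rate must not drop
    return phi_proposed >= phi_head


def extend_sequence(
    seq: StudySequence,
    step: ModificationStep,
    new_spec: ExperimentSpec,
    n_reps: int,
    master_seed: int,
    acceptance_rule=None,
    common_random_numbers: bool = False,
) -> StudySequence:
    """Evaluate one proposed modification against the sequence head.

    Builds the head-vs-proposal rate table (raising
    :class:`~repdist.experiment.PermutationError` if the permutation axiom
    fails), computes the step's distance vector and both experiments' own
    reproducibility rates, and appends the proposal iff the acceptance rule
    — default: the proposal's rate does not decrease — says so.  Earlier
    distances are never mutated; rejected proposals are recorded in the log
    only.
    """
    rule = acceptance_rule or _default_acceptance
    table = build_rate_table(
        seq.head,
        new_spec,
        seq.result,
        n_reps,
        master_seed,
        common_random_numbers=common_random_numbers,
    )
    dvec = distance_vector(table)
    phi_head = table.phi(1)  # cell (1,1,1,1): the head itself
    phi_prop = table.phi(16)  # cell (2,2,2,2): the proposal itself
    accepted = bool(rule(phi_prop, phi_head))
    outcome = StepOutcome(step, accepted, dvec, phi_head, phi_prop)
    if not accepted:
        return replace(seq, log=seq.log + (outcome,))
    return StudySequence(
        experiments=seq.experiments + (new_spec,),
        result=seq.result,
        step_distances=seq.step_distances + (dvec,),
        head_rates=seq.head_rates + (phi_prop,),
        log=seq.log + (outcome,),
    )


def convergence_summary(seq: StudySequence, k: int = 3) -> dict:
    """Per-coordinate distance series with a rolling-range convergence heuristic.

    For each coordinate the rolling range (max minus min over a window of
    ``k`` consecutive step distances) is computed; the sequence is flagged
    converged when every coordinate's rolling range is non-increasing over
    its last ``k`` entries.  Requires at least three experiments.
    """
    if seq.m < 3:
        raise ValueError("convergence summary needs at least 3 experiments")
    coords = {
        "spre": [d.d_spre for d in seq.step_distances],
        "model": [d.d_model for d in seq.step_distances],
        "spost": [d.d_spost for d in seq.step_distances],
        "dstruct": [d.d_dstruct for d in seq.step_distances],
    }
    summary: dict = {"series": coords, "rolling_range": {}, "k": k}
    converged = True
    for name, series in coords.items():
        arr = np.asarray(series)
        w = min(k, len(arr))
        ranges = [
            float(arr[i - w + 1 : i + 1].max() - arr[i - w + 1 : i + 1].min())
            for i in range(w - 1, len(arr))
        ]
        summary["rolling_range"][name] = ranges
        tail = ranges[-k:]
        if any(b > a for a, b in zip(tail, tail[1:])):
            converged = False
    summary["converged"] = converged
    return summary
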