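"""Idealized-experiment data model and the component-permutation engine.

An idealized experiment is the ordered tuple

    (K < Spre < M < Spost < D)

of background knowledge, pre-data methods (design / measured variables),
generative model, post-data methods (the statistical analysis), and data
structure, ordered by epistemic precedence.  Two experiments that agree in
every component except the realized data values are exact replications of
one another; swapping components between an original experiment and a
replication produces the grid of hybrid experiments over which replication
distances are defined.

Background knowledge K is carried as free-text annotation only and is never
permuted: the distance implemented downstream is four-dimensional.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Callable, Sequence

__all__ = [
    "ComponentRole",
    "PERMUTABLE_ROLES",
    "ExperimentSpec",
    "ResultSpec",
    "PermutationCell",
    "PermutationError",
    "assemble",
    "is_permutable",
    "enumerate_permutations",
]


class ComponentRole(IntEnum):
    """The five experiment components, ordered by epistemic precedence."""

    BACKGROUND_K = 0
    PRE_DATA = 1
    MODEL = 2
    POST_DATA = 3
    DATA_STRUCTURE = 4


#: The four roles that participate in permutations (K is excluded).
PERMUTABLE_ROLES: tuple[ComponentRole, ...] = (
    ComponentRole.PRE_DATA,
    ComponentRole.MODEL,
    ComponentRole.POST_DATA,
    ComponentRole.DATA_STRUCTURE,
)

# attribute name on ExperimentSpec for each permutable role
_ROLE_ATTR = {
    ComponentRole.PRE_DATA: "pre_data",
    ComponentRole.MODEL: "model",
    ComponentRole.POST_DATA: "post_data",
    ComponentRole.DATA_STRUCTURE: "data_structure",
}


class PermutationError(ValueError):
    """Raised when the permutation axiom or an enumeration contract is violated."""


@dataclass(frozen=True)
class ExperimentSpec:
    """One fully specified idealized experiment.

    Components are duck-typed: ``pre_data`` must expose ``provides`` (a set of
    variable names), ``model`` must expose ``requires`` and ``parameters``,
    and ``post_data`` must expose ``family`` plus, for Bayesian methods,
    ``priors_assignable(model)``.  The concrete dugong components live in
    :mod:`repdist.growth` and :mod:`repdist.estimators`.
    """

    label: str
    pre_data: object
    model: object
    post_data: object
    data_structure: object
    background_k: str = ""

    def component(self, role: ComponentRole):
        if role == ComponentRole.BACKGROUND_K:
            return self.background_k
        return getattr(self, _ROLE_ATTR[role])

    def replication_of(self, label: str, background_k: str = "") -> "ExperimentSpec":
        """An exact replication: same four permutable components, fresh K.

        The replication's background knowledge is whatever it needs to repeat
        the original (its components and the result of interest), never the
        original's own K text.
        """
        return replace(self, label=label, background_k=background_k)

    def same_components(self, other: "ExperimentSpec") -> bool:
        """Exact-replication equivalence: all four permutable components equal."""
        return all(
            self.component(r) == other.component(r) for r in PERMUTABLE_ROLES
        )


@dataclass(frozen=True)
class ResultSpec:
    """A result type R, target value r, and the predicate deciding I{R=r}.

    ``predicate`` maps (true-model summary, fitted summary) -> bool and must
    be deterministic in its two arguments.  ``query`` is the covariate point
    at which both summaries are evaluated; it travels with the result because
    the result, not the experiment, fixes the scientific question.
    """

    result_type: str
    target_value: str
    query: object
    predicate: Callable[[float, float], bool]

    def evaluate(self, true_summary: float, fitted_summary: float) -> int:
        return int(bool(self.predicate(true_summary, fitted_summary)))

    def complement(self) -> "ResultSpec":
        """The complement result (not-r); I{r} + I{not-r} = 1 on every replicate."""
        inner = self.predicate
        return ResultSpec(
            result_type=self.result_type,
            target_value=f"not[{self.target_value}]",
            query=self.query,
            predicate=lambda t, f: not inner(t, f),
        )


@dataclass(frozen=True)
class PermutationCell:
    """One cell of the 2^4 permutation grid between two experiments."""

    study_index: int
    spre_version: int
    model_version: int
    spost_version: int
    dstruct_version: int
    valid: bool
    reason: str = ""

    @property
    def versions(self) -> tuple[int, int, int, int]:
        return (
            self.spre_version,
            self.model_version,
            self.spost_version,
            self.dstruct_version,
        )

    def version_of(self, role: ComponentRole) -> int:
        return {
            ComponentRole.PRE_DATA: self.spre_version,
            ComponentRole.MODEL: self.model_version,
            ComponentRole.POST_DATA: self.spost_version,
            ComponentRole.DATA_STRUCTURE: self.dstruct_version,
        }[role]


def _pick(version: int, original, replication):
    if version == 1:
        return original
    if version == 2:
        return replication
    raise ValueError(f"unknown component version {version!r}; expected 1 or 2")


def assemble(
    spre_version: int,
    model_version: int,
    spost_version: int,
    dstruct_version: int,
    original: ExperimentSpec,
    replication: ExperimentSpec,
) -> ExperimentSpec:
    """Assemble the hybrid experiment taking each component from the indicated parent.

    Version 1 selects the original's component, version 2 the replication's.
    Background knowledge is not permuted; the hybrid carries an annotation
    naming its parentage instead.
    """
    versions = (spre_version, model_version, spost_version, dstruct_version)
    label = "S(" + ",".join(map(str, versions)) + ")"
    return ExperimentSpec(
        label=label,
        pre_data=_pick(spre_version, original.pre_data, replication.pre_data),
        model=_pick(model_version, original.model, replication.model),
        post_data=_pick(spost_version, original.post_data, replication.post_data),
        data_structure=_pick(
            dstruct_version, original.data_structure, replication.data_structure
        ),
        background_k=f"hybrid of {original.label!r} and {replication.label!r}",
    )


def is_permutable(spec: ExperimentSpec) -> tuple[bool, str]:
    """Whether the assembled experiment is performable, with a reason when not.

    Non-permutable iff (a) the model requires a predictor variable the
    pre-data component does not provide, or (b) the post-data method is
    Bayesian and some model parameter cannot be assigned a declared or vague
    prior.  Total function: never raises on an assembled spec.
    """
    required = set(getattr(spec.model, "requires", ()))
    provided = set(getattr(spec.pre_data, "provides", ()))
    missing = sorted(required - provided)
    if missing:
        return False, (
            f"model requires {', '.join(missing)}; "
            f"pre-data provides {', '.join(sorted(provided)) or 'nothing'} only"
        )
    check = getattr(spec.post_data, "priors_assignable", None)
    if check is not None:
        ok, why = check(spec.model)
        if not ok:
            return False, why
    return True, ""


def enumerate_permutations(
    original: ExperimentSpec, replication: ExperimentSpec
) -> list[PermutationCell]:
    """All 2^4 component permutations of two experiments, in canonical order.

    Cells are enumerated with Spre slowest-varying, then M, then Spost, then
    Ds, and numbered 1..16; each carries a validity flag from
    :func:`is_permutable`.  Raises :class:`PermutationError` if fewer than two
    cells are valid (the permutation axiom requires at least the two parent
    experiments to be performable, and the distance is undefined otherwise).
    """
    cells: list[PermutationCell] = []
    for idx, versions in enumerate(itertools.product((1, 2), repeat=4), start=1):
        spec = assemble(*versions, original=original, replication=replication)
        ok, why = is_permutable(spec)
        cells.append(PermutationCell(idx, *versions, valid=ok, reason=why))
    if sum(c.valid for c in cells) < 2:
        raise PermutationError(
            "permutation axiom violated: fewer than two valid permutations "
            "between the two experiments"
        )
    return cells
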