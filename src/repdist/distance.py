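"""Component-wise replication distances from a reproducibility-rate table.

The distance between two experiments with respect to one component (say the
model M) is the absolute difference between the mean reproducibility rate of
the 8 permutation cells holding M at its original version and the mean of
the 8 cells holding M at the replication's version, the average in each case
running over all permutations of the remaining three components.  Rates of
non-permutable cells enter the means as 0 by convention — dropping them
would shrink the denominator, inflate one side's mean, and understate the
distance.  Because rates live in [0, 1], so does each distance coordinate,
and using rates (not the experiments themselves) as the currency makes the
distance symmetric with d = 0 for exact replications.

The distance is a four-coordinate vector (Spre, M, Spost, Ds); background
knowledge K is carried as annotation only and gets no coordinate.  It is
deliberately not collapsed to a single number: the component spaces are not
commensurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .experiment import ComponentRole, PERMUTABLE_ROLES
from .rates import RateTable

__all__ = ["DistanceVector", "component_distance", "distance_vector"]


@dataclass(frozen=True)
class DistanceVector:
    """The four component-wise distances between two experiments."""

    d_spre: float
    d_model: float
    d_spost: float
    d_dstruct: float
    n_permutations_per_side: int = 8

    def as_dict(self) -> dict[str, float]:
        return {
            "spre": self.d_spre,
            "model": self.d_model,
            "spost": self.d_spost,
            "dstruct": self.d_dstruct,
        }

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.d_spre, self.d_model, self.d_spost, self.d_dstruct)

    def max_coordinate(self) -> float:
        return max(self.as_tuple())


def _check_complete(table: RateTable) -> None:
    bad = [
        cell.study_index
        for cell, est in zip(table.cells, table.estimates)
        if not math.isfinite(est.phi_hat)
    ]
    if bad:
        raise ValueError(
            f"rate table incomplete: cells {bad} have no usable rate "
            "(all-failed cells cannot enter a distance)"
        )


def component_distance(table: RateTable, component: ComponentRole) -> float:
    """|mean phi over version-1 cells - mean phi over version-2 cells| for one role."""
    if component not in PERMUTABLE_ROLES:
        raise ValueError(f"no distance coordinate for component {component!r}")
    _check_complete(table)
    side1 = table.rates_for(component, 1)
    side2 = table.rates_for(component, 2)
    if not side1 or not side2:
        raise ValueError(f"rate table has no cells for one version of {component!r}")
    mean1 = sum(side1) / len(side1)
    mean2 = sum(side2) / len(side2)
    return abs(mean1 - mean2)


def distance_vector(table: RateTable) -> DistanceVector:
    """All four component distances from one complete rate table."""
    return DistanceVector(
        d_spre=component_distance(table, ComponentRole.PRE_DATA),
        d_model=component_distance(table, ComponentRole.MODEL),
        d_spost=component_distance(table, ComponentRole.POST_DATA),
        d_dstruct=component_distance(table, ComponentRole.DATA_STRUCTURE),
        n_permutations_per_side=len(table) // 2,
    )
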