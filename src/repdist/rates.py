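"""Monte Carlo estimation of reproducibility rates over permutation grids.

The reproducibility rate phi of a result r for an experiment is the limiting
fraction of exact replications (components identical, data values redrawn)
whose result equals r; the natural estimator is the agreement fraction over
N simulated replicates, with the usual Bernoulli Monte Carlo standard error.
Non-performable (non-permutable) permutations receive rate 0 by convention
so that component-wise averages are not unduly inflated; a cell whose fits
all fail is a distinct, flagged state — never silently zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .experiment import (
    ComponentRole,
    ExperimentSpec,
    PermutationCell,
    ResultSpec,
    assemble,
    enumerate_permutations,
    is_permutable,
)
from .growth import simulate_dataset

__all__ = ["RateEstimate", "RateTable", "estimate_rate", "build_rate_table", "mean_rate"]

log = logging.getLogger(__name__)

#: warn when more than this fraction of fits fail in one cell
FAILURE_WARN_FRACTION = 0.05


@dataclass(frozen=True)
class RateEstimate:
    """Estimated reproducibility rate for one (possibly hybrid) experiment.

    ``phi_hat`` is NaN when the permutation is valid but every fit failed
    (``all_failed``); it is exactly 0.0 with ``valid_permutation=False`` for
    the non-permutable convention.  The two states must not be conflated.
    """

    phi_hat: float
    n_requested: int
    n_valid: int
    n_failed: int
    mc_se: float
    valid_permutation: bool
    reason: str = ""

    @property
    def all_failed(self) -> bool:
        return self.valid_permutation and self.n_requested > 0 and self.n_valid == 0

    def __post_init__(self):
        if not self.valid_permutation:
            assert self.phi_hat == 0.0 and self.n_valid == 0
        elif self.n_valid + self.n_failed != self.n_requested:
            raise ValueError("fit bookkeeping does not add up")


def _zero_by_convention(n_requested: int, reason: str) -> RateEstimate:
    return RateEstimate(
        phi_hat=0.0,
        n_requested=n_requested,
        n_valid=0,
        n_failed=0,
        mc_se=0.0,
        valid_permutation=False,
        reason=reason,
    )


def estimate_rate(
    spec: ExperimentSpec,
    result: ResultSpec,
    n_reps: int,
    rng: np.random.Generator,
) -> RateEstimate:
    """Monte Carlo estimate of the reproducibility rate of ``result`` under ``spec``.

    Each replicate draws a fresh true parameter set from the model's
    plausibility box, simulates a dataset under the experiment's design and
    data structure, analyzes it with the post-data method, and scores the
    result predicate on (true summary, fitted summary).  Failed fits are
    excluded from the denominator.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    ok, why = is_permutable(spec)
    if not ok:
        return _zero_by_convention(n_reps, why)

    model = spec.model
    successes = 0
    n_failed = 0
    for _ in range(n_reps):
        params = model.draw_params(rng)
        dataset = simulate_dataset(
            model.version, params, spec.pre_data, spec.data_structure, rng
        )
        fit = spec.post_data.fit(dataset, model, result.query, rng)
        if not fit.success:
            n_failed += 1
            continue
        true_summary = model.mean_at(params, result.query)
        successes += result.evaluate(true_summary, fit.predicted_length)

    n_valid = n_reps - n_failed
    if n_failed > FAILURE_WARN_FRACTION * n_reps:
        log.warning(
            "%s: %d/%d fits failed (>%.0f%%) — the post-data method may not be "
            "appropriate for the model",
            spec.label,
            n_failed,
            n_reps,
            100 * FAILURE_WARN_FRACTION,
        )
    if n_valid == 0:
        log.error("%s: all %d fits failed; rate is undefined", spec.label, n_reps)
        return RateEstimate(
            phi_hat=math.nan,
            n_requested=n_reps,
            n_valid=0,
            n_failed=n_failed,
            mc_se=math.nan,
            valid_permutation=True,
            reason="all fits failed",
        )
    phi = successes / n_valid
    return RateEstimate(
        phi_hat=phi,
        n_requested=n_reps,
        n_valid=n_valid,
        n_failed=n_failed,
        mc_se=math.sqrt(phi * (1.0 - phi) / n_valid),
        valid_permutation=True,
    )


@dataclass(frozen=True)
class RateTable:
    """Reproducibility-rate estimates for all 16 cells of a permutation grid."""

    cells: tuple[PermutationCell, ...]
    estimates: tuple[RateEstimate, ...]

    def __post_init__(self):
        if len(self.cells) != len(self.estimates):
            raise ValueError("one estimate per cell required")
        indices = [c.study_index for c in self.cells]
        if sorted(indices) != list(range(1, len(indices) + 1)):
            raise ValueError("study indices must enumerate 1..n exactly once")

    def __len__(self) -> int:
        return len(self.cells)

    def estimate(self, study_index: int) -> RateEstimate:
        return self.estimates[study_index - 1]

    def phi(self, study_index: int) -> float:
        return self.estimate(study_index).phi_hat

    def rates_for(self, role: ComponentRole, version: int) -> list[float]:
        """phi values of the cells holding ``role`` at ``version`` (8 of 16)."""
        return [
            est.phi_hat
            for cell, est in zip(self.cells, self.estimates)
            if cell.version_of(role) == version
        ]

    def to_records(self) -> list[dict]:
        out = []
        for cell, est in zip(self.cells, self.estimates):
            out.append(
                {
                    "study": cell.study_index,
                    "spre": cell.spre_version,
                    "model": cell.model_version,
                    "spost": cell.spost_version,
                    "dstruct": cell.dstruct_version,
                    "phi": est.phi_hat,
                    "n_valid": est.n_valid,
                    "n_failed": est.n_failed,
                    "mc_se": est.mc_se,
                }
            )
        return out


def build_rate_table(
    original: ExperimentSpec,
    replication: ExperimentSpec,
    result: ResultSpec,
    n_reps: int | Callable[[PermutationCell, ExperimentSpec], int],
    master_seed: int,
    common_random_numbers: bool = False,
) -> RateTable:
    """Estimate the rate of every permutation cell, deterministically in the seed.

    Each cell gets an independent RNG sub-stream derived from ``master_seed``
    and its study index, so the table is reproducible and cells are mutually
    independent.  With ``common_random_numbers=True`` every cell reuses the
    same sub-stream instead (a variance-reduction option for distances; off
    by default, matching the independent-simulation reading).  ``n_reps`` may
    be a callable for per-cell replicate counts (e.g. fewer replicates for
    expensive Bayesian cells).
    """
    cells = enumerate_permutations(original, replication)
    estimates = []
    for cell in cells:
        spec = assemble(*cell.versions, original=original, replication=replication)
        reps = n_reps(cell, spec) if callable(n_reps) else n_reps
        key = 0 if common_random_numbers else cell.study_index
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=master_seed, spawn_key=(key,))
        )
        try:
            est = estimate_rate(spec, result, reps, rng)
        except Exception as exc:  # keep the rest of the table alive
            log.error("cell %d (%s) errored: %s", cell.study_index, spec.label, exc)
            est = RateEstimate(
                phi_hat=math.nan,
                n_requested=reps,
                n_valid=0,
                n_failed=reps,
                mc_se=math.nan,
                valid_permutation=True,
                reason=str(exc),
            )
        estimates.append(est)
    return RateTable(cells=tuple(cells), estimates=tuple(estimates))


def mean_rate(table: RateTable, study_indices: Iterable[int] | None = None) -> float:
    """Arithmetic mean of phi over the given cells (zero-convention cells included)."""
    indices = list(study_indices) if study_indices is not None else [
        c.study_index for c in table.cells
    ]
    if not indices:
        raise ValueError("mean_rate over an empty subset is undefined")
    return float(np.mean([table.phi(i) for i in indices]))
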