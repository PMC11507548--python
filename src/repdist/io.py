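"""CSV and config plumbing: rate tables, distance reports, run manifests.

All tabular interchange is plain comma-separated text with a header row and
'.' decimals: machine files keep full precision, report files format phi and
distances at 3 decimals.  Randomness is always derived from a single master
seed recorded in the run manifest (per-cell sub-streams use the cell's study
index as spawn key), so a manifest determines the simulated outputs exactly.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .distance import DistanceVector
from .estimators import bayesian_method, least_squares_method
from .experiment import ExperimentSpec, PermutationCell, ResultSpec
from .growth import DEFAULT_QUERY, DataStructure, PredictorDesign, growth_model
from .rates import RateEstimate, RateTable

__all__ = [
    "read_rate_table",
    "write_rate_table",
    "write_distance_csv",
    "RunManifest",
    "load_config",
    "experiment_from_block",
]

REQUIRED_COLUMNS = ("study", "spre", "model", "spost", "dstruct", "phi")


def write_rate_table(table: RateTable, path, report: bool = False) -> None:
    """Write a rate table as CSV; ``report=True`` rounds phi to 3 decimals."""
    frame = pd.DataFrame(table.to_records())
    if report:
        frame["phi"] = frame["phi"].round(3)
        frame["mc_se"] = frame["mc_se"].round(4)
    frame.to_csv(path, index=False)


def read_rate_table(path) -> RateTable:
    """Read and validate a rate-table CSV.

    The bookkeeping columns (n_valid, n_failed, mc_se) are optional so that
    published-rate fixtures can be read; phi must lie in [0, 1] in every row.
    """
    frame = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"rate table {path} is missing required columns {missing}")
    if frame["study"].duplicated().any():
        dup = sorted(frame.loc[frame["study"].duplicated(), "study"])
        raise ValueError(f"duplicate study indices in {path}: {dup}")
    bad = frame[(frame["phi"] < 0) | (frame["phi"] > 1) | frame["phi"].isna()]
    if not bad.empty:
        row = bad.iloc[0]
        raise ValueError(
            f"phi outside [0, 1] at study {int(row['study'])} in {path}: {row['phi']}"
        )
    frame = frame.sort_values("study")
    cells, estimates = [], []
    for _, row in frame.iterrows():
        phi = float(row["phi"])
        valid = bool(row["valid"]) if "valid" in frame.columns else True
        if not valid and phi != 0.0:
            raise ValueError(
                f"study {int(row['study'])}: non-permutable rows must have phi=0"
            )
        n_valid = int(row["n_valid"]) if "n_valid" in frame.columns else 0
        n_failed = int(row["n_failed"]) if "n_failed" in frame.columns else 0
        mc_se = float(row["mc_se"]) if "mc_se" in frame.columns else 0.0
        if not valid:
            n_valid = n_failed = 0
            mc_se = 0.0
        cells.append(
            PermutationCell(
                study_index=int(row["study"]),
                spre_version=int(row["spre"]),
                model_version=int(row["model"]),
                spost_version=int(row["spost"]),
                dstruct_version=int(row["dstruct"]),
                valid=valid,
            )
        )
        estimates.append(
            RateEstimate(
                phi_hat=phi,
                n_requested=n_valid + n_failed,
                n_valid=n_valid,
                n_failed=n_failed,
                mc_se=mc_se,
                valid_permutation=valid,
            )
        )
    return RateTable(cells=tuple(cells), estimates=tuple(estimates))


def write_distance_csv(
    dvec: DistanceVector,
    path,
    version1_label: str = "original",
    version2_label: str = "replication",
) -> None:
    """Distance report CSV: component, version labels, distance at 3 decimals."""
    rows = [
        {"component": name, "version1_label": version1_label,
         "version2_label": version2_label, "distance": round(value, 3)}
        for name, value in dvec.as_dict().items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to re-run a simulation bit-for-bit (minus timestamps)."""

    master_seed: int
    config: dict = field(default_factory=dict)
    software_version: str = ""
    created: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )

    @staticmethod
    def cell_seed_sequence(master_seed: int, study_index: int) -> np.random.SeedSequence:
        """The sub-stream scheme used for every per-cell simulation."""
        return np.random.SeedSequence(entropy=master_seed, spawn_key=(study_index,))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# declarative experiment configs

_PRE_DATA_VERSIONS = {
    1: frozenset({"age", "weight"}),
    2: frozenset({"age"}),
}
_DSTRUCT_VERSIONS = {
    1: dict(n=20, age_bias_factor=0.8, weight_bias_factor=1.2),
    2: dict(n=100, age_bias_factor=1.0, weight_bias_factor=1.0),
}


def experiment_from_block(block: dict, label: str) -> ExperimentSpec:
    """Build an experiment from one declarative config block.

    Component values may be the canonical version numbers (1 or 2) or
    explicit parameter mappings, e.g.::

        pre_data: 1                    # or {provides: [age, weight]}
        model: 2
        post_data: bayesian            # or least_squares
        data_structure: {n: 50, age_bias: 1.0, weight_bias: 1.0}
    """
    pre = block.get("pre_data", 1)
    if isinstance(pre, dict):
        pre_data = PredictorDesign(provides=frozenset(pre["provides"]))
    else:
        pre_data = PredictorDesign(provides=_PRE_DATA_VERSIONS[int(pre)])
    model = growth_model(int(block.get("model", 1)))
    post = str(block.get("post_data", "least_squares")).lower()
    if post in ("least_squares", "ols", "nls"):
        post_data = least_squares_method()
    elif post in ("bayesian", "bayes"):
        post_data = bayesian_method()
    else:
        raise ValueError(f"unknown post_data method {post!r}")
    ds = block.get("data_structure", 2)
    if isinstance(ds, dict):
        dstruct = DataStructure(
            n=int(ds["n"]),
            age_bias_factor=float(ds.get("age_bias", 1.0)),
            weight_bias_factor=float(ds.get("weight_bias", 1.0)),
        )
    else:
        dstruct = DataStructure(**_DSTRUCT_VERSIONS[int(ds)])
    return ExperimentSpec(
        label=label,
        pre_data=pre_data,
        model=model,
        post_data=post_data,
        data_structure=dstruct,
        background_k=str(block.get("background_k", "")),
    )


def load_config(path) -> dict:
    """Parse a declarative YAML config into experiments and a result spec.

    Returns a dict with keys ``experiments`` (label -> ExperimentSpec, in
    file order) and ``result`` (a breeding-status-match ResultSpec; the only
    result type currently supported in configs).
    """
    from .dugong import _status_match

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "experiments" not in raw:
        raise ValueError(f"config {path} must contain an 'experiments' mapping")
    experiments = {
        label: experiment_from_block(block, label)
        for label, block in raw["experiments"].items()
    }
    result = ResultSpec(
        result_type="breeding_status_match",
        target_value="match",
        query=DEFAULT_QUERY,
        predicate=_status_match,
    )
    return {"experiments": experiments, "result": result}
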