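"""Run configuration, JSON reports and the two diagnostic figures.

The report file is the auditable record of a run: it echoes the full
configuration (the machine-readable analysis plan), every per-split p
value and seed, the aggregate p value and the stabilisation trace, so a
run is reproducible from (input file, report) alone.  Any numbers derived
after the formal test (post-hoc exploration) do not belong in it.

Figures are rendered deterministically (fixed style, no timestamps): the
p-value ECDF against the adaptive-rule rejection boundary, and the
aggregate-p traceplot in K.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import yaml

from .aggregation import (
    AggregateResult,
    aggregate_adaptive,
    aggregate_fixed_gamma,
    boundary_curve,
)

plt.rcParams["svg.hashsalt"] = "teh"

SCHEMA_VERSION = "1.0"

REQUIRED_REPORT_FIELDS = (
    "schema_version",
    "test",
    "master_seed",
    "alpha",
    "method",
    "p_values",
    "p_aggregate",
    "trace",
)

__all__ = [
    "RunConfig",
    "plot_pvalue_ecdf",
    "plot_trace",
    "write_report",
    "load_report",
    "validate_report",
    "reaggregate_report",
]


@dataclass
class RunConfig:
    """Serialisable analysis plan for one run."""

    outcome: str = "outcome"
    treatment: str = "treatment"
    covariates: tuple = ()
    soc_label: object = 0
    subject_id: str | None = None
    delimiter: str = ","
    predictor: str = "random_forest"
    predictor_hyperparameters: dict = field(default_factory=dict)
    test_statistic: str = "fisher_exact_one_sided"
    K: int = 1000
    alpha: float = 0.05
    gamma: float | None = None
    epsilon: float = 1e-3
    master_seed: int = 0
    include_intercept: bool = True  # stacked model; False = replication mode

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f: raw[f] for f in cls.__dataclass_fields__ if f in raw}
        cfg = cls(**known)
        if cfg.covariates:
            cfg.covariates = tuple(cfg.covariates)
        return cfg

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _finalise(fig, path):
    path = Path(path)
    kwargs = {}
    if path.suffix == ".svg":
        kwargs["metadata"] = {"Date": None}
    fig.savefig(path, **kwargs)
    plt.close(fig)
    return path


def plot_pvalue_ecdf(p_values, alpha: float, path):
    """ECDF of the per-split p values with the rejection boundary.

    Significance at level alpha is read off as the ECDF step curve
    touching or crossing above the boundary segment.
    """
    p = np.sort(np.asarray(p_values, dtype=float))
    k = p.size
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.step(np.concatenate([[0.0], p]), np.arange(k + 1) / k, where="post",
            color="black", label="p-value ECDF")
    b = boundary_curve(alpha)
    ax.plot(b[:, 0], b[:, 1], color="red", label=f"rejection boundary (alpha={alpha:g})")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("p value")
    ax.set_ylabel("cumulative fraction of splits")
    ax.legend(loc="lower right", frameon=False)
    fig.tight_layout()
    return _finalise(fig, path)


def plot_trace(trace, alpha: float, path):
    """Aggregate p value recomputed on the first k splits, k = 1..K."""
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("trace must be non-empty")
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(np.arange(1, trace.size + 1), trace, color="black")
    ax.axhline(alpha, color="red", linestyle="--", label=f"alpha = {alpha:g}")
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("number of splits k")
    ax.set_ylabel("aggregate p value")
    ax.legend(loc="best", frameon=False)
    fig.tight_layout()
    return _finalise(fig, path)


def _report_payload(test_name, aggregate: AggregateResult, config, master_seed):
    cfg = config.to_dict() if isinstance(config, RunConfig) else dict(config or {})
    return {
        "schema_version": SCHEMA_VERSION,
        "test": test_name,
        "config": cfg,
        "master_seed": int(master_seed),
        "alpha": aggregate.alpha,
        "gamma": aggregate.gamma,
        "method": aggregate.method,
        "p_values": aggregate.p_values.tolist(),
        "p_aggregate": float(aggregate.p_aggregate),
        "trace": aggregate.trace.tolist(),
    }


def write_report(path, test_name, result, config=None, master_seed=0):
    """Serialise a crossover or added-benefit result to versioned JSON."""
    payload = _report_payload(test_name, result.aggregate, config, master_seed)
    payload["warnings"] = list(getattr(result, "warnings", []))
    if hasattr(result, "prevalence_estimate"):
        payload["prevalence_estimate"] = float(result.prevalence_estimate)
    if hasattr(result, "splits"):
        payload["splits"] = [s.to_dict() for s in result.splits]
    validate_report(payload)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
    return path


def validate_report(report: dict):
    """Check the report against the versioned schema; raise on violation."""
    missing = [f for f in REQUIRED_REPORT_FIELDS if f not in report]
    if missing:
        raise ValueError(f"report is missing required fields: {missing}")
    if report["schema_version"] != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported schema version {report['schema_version']!r}"
        )
    p = np.asarray(report["p_values"], dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("stored p values outside [0, 1]")
    return report


def load_report(path) -> dict:
    with open(path) as fh:
        return validate_report(json.load(fh))


def reaggregate_report(report: dict) -> float:
    """Recompute the aggregate p from a report's stored p values; equals
    the stored ``p_aggregate`` for an untampered report."""
    p = report["p_values"]
    if report["method"] == "fixed_gamma":
        return aggregate_fixed_gamma(p, report["gamma"]).p_aggregate
    return aggregate_adaptive(p, report["alpha"]).p_aggregate
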