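"""Run configuration and machine-readable stage reports for the CLI.

Every CLI invocation resolves a RunConfig (YAML file merged with
command-line overrides, all defaults materialised) and writes exactly
one RunReport JSON next to its outputs, recording the stage, the
parameters used, input/output file digests, timing and warnings —
enough to replay the stage byte-identically from the saved config.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .hapmap_io import BreedkitError

__all__ = ["RunConfig", "RunReport", "stage_timer"]

# every stage parameter with its default; unknown keys are rejected
CONFIG_DEFAULTS: dict = {
    "genotypes": None,
    "breeds": None,
    "geo": None,
    "outdir": "breedkit_out",
    "seed": 1,
    "log_level": "INFO",
    # power / balance
    "delta": 0.2,
    "alpha_test": 0.05,
    "power": 0.8,
    "p_base": 0.5,
    "strategy": "down",
    # dimred
    "method": "pca",
    "k": 2,
    "missing_policy": "mean",
    "standardize": False,
    "drop": [],
    "n_neighbors": 15,
    # tree
    "tree_method": "nj",
    "bootstrap": 0,
    # structure
    "k_min": 2,
    "k_max": 5,
    "reps": 3,
    "mask_fraction": 0.1,
    "restarts": 5,
    "max_iter": 500,
    "tol": 1e-6,
    # selection
    "score_method": "chi2",
    "r2_threshold": 0.9,
    "top_fraction": None,
    "top_count": None,
    # training / prediction
    "panel": None,
    "algorithm": "rf",
    "cv_scheme": "kfold:5",
    "alpha": 2.0,
    "model": None,
    # simulation
    "n_breeds": 10,
    "n_per_breed": 20,
    "n_snps": 2000,
    "fst": 0.15,
    "missing_rate": 0.0,
}


@dataclass
class RunConfig:
    values: dict = field(default_factory=dict)

    @classmethod
    def load(cls, config_path: str | None = None, **overrides) -> "RunConfig":
        values = dict(CONFIG_DEFAULTS)
        if config_path:
            raw = yaml.safe_load(Path(config_path).read_text()) or {}
            unknown = set(raw) - set(CONFIG_DEFAULTS)
            if unknown:
                raise BreedkitError(f"unknown config keys: {sorted(unknown)}")
            values.update(raw)
        for key, val in overrides.items():
            if key not in CONFIG_DEFAULTS:
                raise BreedkitError(f"unknown config key: {key}")
            if val is not None:
                values[key] = val
        return cls(values)

    def __getitem__(self, key: str):
        return self.values[key]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.values, sort_keys=True))


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


@dataclass
class RunReport:
    stage: str
    parameters: dict
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    seconds: float = 0.0
    warnings: list = field(default_factory=list)

    def add_input(self, name: str, path) -> None:
        p = Path(path)
        self.inputs[name] = {"path": str(p), "sha256": _digest(p)}

    def add_output(self, name: str, path) -> None:
        p = Path(path)
        self.outputs[name] = {"path": str(p), "sha256": _digest(p)}

    def write(self, outdir) -> Path:
        out = Path(outdir) / f"report_{self.stage}.json"
        out.write_text(
            json.dumps(
                {
                    "stage": self.stage,
                    "parameters": self.parameters,
                    "inputs": self.inputs,
                    "outputs": self.outputs,
                    "seconds": round(self.seconds, 3),
                    "warnings": self.warnings,
                },
                indent=2,
                default=str,
            )
            + "\n"
        )
        return out


class stage_timer:
    """Context manager stamping elapsed wall time onto a RunReport."""

    def __init__(self, report: RunReport):
        self.report = report

    def __enter__(self):
        self._t0 = time.perf_counter()
        return self.report

    def __exit__(self, *exc):
        self.report.seconds = time.perf_counter() - self._t0
        return False


def export_run_summary(reports: list[RunReport], config: RunConfig) -> dict:
    """Ordered stage reports with the resolved configuration embedded."""
    if not reports:
        raise BreedkitError("need at least one report")
    return {
        "config": dict(config.values),
        "stages": [
            {
                "stage": r.stage,
                "parameters": r.parameters,
                "inputs": r.inputs,
                "outputs": r.outputs,
                "seconds": round(r.seconds, 3),
                "warnings": r.warnings,
            }
            for r in reports
        ],
    }
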