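"""Run configuration: one seed, one block of knobs per pipeline stage."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .synthetic import SimulationConfig


def _default_discovery() -> dict:
    return {
        "top_n_cpgs": 30,
        "window_bp": 500,
        "min_cpgs": 3,
        "immune_cap": 0.2,
        "control_cap": 0.2,
        "top_k": 3,
    }


def _default_scoring() -> dict:
    return {
        "efficiency": 2.0,
        "max_ref_ct": 38.0,
        "ct_noise_sd": 0.25,
        "ref_ct_range": [24.0, 32.0],
        "dropout_rate": 0.0,
    }


def _default_thresholds() -> dict:
    return {
        "target_sensitivity": 0.95,
        "target_specificity": 0.95,
        "n_dev_cases": 20,
        "n_dev_controls": 20,
    }


def _default_evaluation() -> dict:
    return {
        "prevalence": 0.09,
        "conf": 0.95,
        "cutpoint_months": 12.0,
        "ultrasound_cutoff_mm": 5.0,
        "mutation_cutoff": 1,
    }


@dataclass
class RunConfig:
    """Everything a full pipeline run needs, reproducible from one seed."""

    seed: int = 0
    predictive: bool = False
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    discovery: dict = field(default_factory=_default_discovery)
    scoring: dict = field(default_factory=_default_scoring)
    thresholds: dict = field(default_factory=_default_thresholds)
    evaluation: dict = field(default_factory=_default_evaluation)

    def stage_seeds(self) -> dict:
        """Derive one independent sub-seed (< 2^31) per stochastic stage."""
        state = np.random.SeedSequence(self.seed).generate_state(4, dtype=np.uint64)
        names = ["simulate", "comparators", "plate", "spare"]
        return {name: int(s % (2**31)) for name, s in zip(names, state)}

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"]["immune_fraction_distribution"] = list(
            d["simulation"]["immune_fraction_distribution"]
        )
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sim = data.pop("simulation", {})
        if isinstance(sim, dict):
            base = SimulationConfig()
            merged = {**asdict(base), **sim}
            merged["immune_fraction_distribution"] = tuple(
                merged["immune_fraction_distribution"]
            )
            sim = SimulationConfig(**merged)
        cfg = cls(
            seed=int(data.get("seed", 0)),
            predictive=bool(data.get("predictive", False)),
            simulation=sim,
        )
        for block in ("discovery", "scoring", "thresholds", "evaluation"):
            defaults = getattr(cfg, block)
            defaults.update(data.get(block, {}))
        cfg.validate()
        return cfg

    def validate(self) -> None:
        d, s, t, e = self.discovery, self.scoring, self.thresholds, self.evaluation
        if d["window_bp"] <= 0 or d["min_cpgs"] < 1 or d["top_k"] < 1:
            raise ValueError("discovery parameters out of range")
        if not s["efficiency"] > 1:
            raise ValueError("scoring efficiency must exceed 1")
        if not (0 <= s["dropout_rate"] < 1):
            raise ValueError("dropout_rate must lie in [0, 1)")
        for key in ("target_sensitivity", "target_specificity"):
            if not (0 < t[key] <= 1):
                raise ValueError(f"{key} must lie in (0, 1]")
        if not (0 < e["prevalence"] < 1):
            raise ValueError("prevalence must lie in (0, 1)")


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return RunConfig.from_dict(data or {})


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
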