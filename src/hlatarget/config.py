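"""Run configuration: one YAML file fixes every stage's parameters and seed."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["RunConfig", "load_config", "config_hash"]

_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "paths": {},
    "filter": {"fdr_cutoff": 0.05, "length_min": 8, "length_max": 12, "drop_modified": True},
    "restriction": {"sb_only": False},
    "validation": {"r_min": 0.9, "rt_window_min": 3.0, "rt_rule_enabled": False, "tol_da": 0.02},
    "imputation": {"width": 0.3, "downshift": 1.8},
    "de": {"fc_cutoff": 1.0, "alpha": 0.05, "equal_var": True},
    "surfaceome": {"min_helices": 3, "top_k": 50, "min_replicates": 1},
    "motif": {"pseudocount": 0.0, "alpha": 0.05},
    "simulate": {
        "n_true_peptides": 400,
        "n_decoy": 80,
        "n_irt": 5,
        "n_blank": 10,
        "n_modified": 20,
        "length_dist": {9: 0.65, 10: 0.2, 11: 0.1, 8: 0.03, 12: 0.02},
        "n_validation_pairs": 12,
        "noise_cv": 0.1,
        "n_noise_peaks": 10,
        "lfq": {
            "n_proteins": 2000,
            "n_per_group": 3,
            "frac_de": 0.05,
            "log2_effect": 2.0,
            "within_sd": 0.5,
        },
        "overlap_fractions": {
            "HBPA": 0.1,
            "TANTIGEN": 0.05,
            "CTA": 0.02,
            "IEDB": 0.1,
            "CSPA": 0.15,
            "DRUGGABLE": 0.05,
        },
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


@dataclass
class RunConfig:
    """Validated run configuration with defaults for every knob."""

    raw: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.raw = _merge(_DEFAULTS, self.raw)

    def __getitem__(self, key: str) -> Any:
        return self.raw[key]

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    def path(self, name: str) -> Path:
        try:
            return Path(self.raw["paths"][name])
        except KeyError:
            raise KeyError(f"config has no path entry {name!r}") from None

    def check_paths_exist(self, names: list[str]) -> None:
        missing = [n for n in names if not self.path(n).exists()]
        if missing:
            raise FileNotFoundError(
                "missing input files: "
                + ", ".join(f"{n} ({self.path(n)})" for n in missing)
            )


def load_config(path: str | Path, seed_override: int | None = None) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if seed_override is not None:
        raw["seed"] = seed_override
    return RunConfig(raw=raw)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the full (merged) configuration."""
    blob = yaml.safe_dump(config.raw, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
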