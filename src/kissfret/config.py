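"""Flat key-value run configuration with schema validation."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .kinetics import KineticModel, RATE_KEYS
from .synth import PhotophysicsParams

__all__ = ["RunConfig", "ConfigError", "parse_config", "load_config"]


class ConfigError(ValueError):
    pass


def _bool(v: str) -> bool:
    if v.lower() in ("true", "1", "yes"):
        return True
    if v.lower() in ("false", "0", "no"):
        return False
    raise ValueError(v)


# key -> (type, default); required keys have default None
SCHEMA: dict[str, tuple[Any, Any]] = {
    "condition": (str, "default"),
    # kinetic scheme (s^-1), all six required
    **{k: (float, None) for k in RATE_KEYS},
    # photophysics
    "frame_time": (float, 0.1),
    "total_intensity": (float, 1000.0),
    "noise_sigma": (float, -1.0),  # -1 -> total_intensity / 12
    "e_U": (float, 0.38),
    "e_K": (float, 0.69),
    "e_M": (float, 0.86),
    "sigma_e": (float, 0.08),
    "donor_bleach_lifetime": (float, 60.0),
    "acceptor_bleach_lifetime": (float, 40.0),
    "donor_only_fraction": (float, 0.1),
    # cohort
    "n_molecules": (int, 200),
    "movie_frames": (int, 600),
    "static_fraction": (float, 0.0),
    # analysis thresholds
    "donor_only_cut": (float, 0.25),
    "histogram_frames": (int, 20),
    "min_n": (int, 30),
    "stitch_cap": (int, 50_000),
    "hmm_tol": (float, 1e-6),
    "hmm_max_iter": (int, 500),
    # reproducibility
    "seed": (int, 0),
}


@dataclass
class RunConfig:
    values: dict[str, Any] = field(default_factory=dict)
    source_text: str = ""

    def __getattr__(self, key: str) -> Any:
        values = object.__getattribute__(self, "values")
        if key in values:
            return values[key]
        raise AttributeError(key)

    def kinetic_model(self) -> KineticModel:
        return KineticModel.from_config({k: self.values[k] for k in RATE_KEYS})

    def photophysics(self) -> PhotophysicsParams:
        v = self.values
        return PhotophysicsParams(
            frame_time=v["frame_time"],
            total_intensity=v["total_intensity"],
            noise_sigma=None if v["noise_sigma"] < 0 else v["noise_sigma"],
            state_efficiencies={"U": v["e_U"], "K": v["e_K"], "M": v["e_M"]},
            state_sigma_e=v["sigma_e"],
            donor_bleach_lifetime=v["donor_bleach_lifetime"],
            acceptor_bleach_lifetime=v["acceptor_bleach_lifetime"],
            donor_only_fraction=v["donor_only_fraction"],
        )

    def digest(self) -> str:
        canonical = "\n".join(f"{k}={self.values[k]}" for k in sorted(self.values))
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def parse_config(text: str) -> RunConfig:
    """Parse ``key = value`` lines; '#' starts a comment.

    Unknown keys are rejected; the six rate keys are required.
    """
    values: dict[str, Any] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key not in SCHEMA:
            raise ConfigError(f"line {lineno}: unknown key {key!r}")
        typ, _ = SCHEMA[key]
        try:
            values[key] = _bool(val) if typ is bool else typ(val)
        except ValueError:
            raise ConfigError(
                f"line {lineno}: cannot parse {key} value {val!r} as {typ.__name__}")
    for key, (typ, default) in SCHEMA.items():
        if key not in values:
            if default is None:
                raise ConfigError(f"missing required key {key!r}")
            values[key] = default
    return RunConfig(values=values, source_text=text)


def load_config(path: str | Path) -> RunConfig:
    return parse_config(Path(path).read_text())
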