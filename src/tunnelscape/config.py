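"""Run configuration: defaults, file loading, flag overrides, provenance.

A bare invocation reproduces the production regime on the synthetic fixtures:
pocket-frequency cutoff 0.2, RMSF threshold 1.0 Å, the standard well-tempered
metadynamics setting (H = 0.1 kcal/mol, δ = 0.05 Å, ΔT = 4500 K,
τ_G = 1000 fs), walls of K = 40 kcal/(mol·Å²), and T = 298 K.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["DEFAULTS", "RunConfig", "parse_config"]

DEFAULTS: dict[str, object] = {
    # grid thresholding
    "cutoff": 0.2,
    # reference-frame fitting
    "rmsf_threshold": 1.0,
    # well-tempered metadynamics (production setting)
    "H": 0.1,
    "delta": 0.05,
    "deltaT": 4500.0,
    "tauG": 1000.0,
    "T": 298.0,
    # confining walls: longitudinal on CV1, radial upper bound on CV2
    "wall_K": 40.0,
    "cv1_wall_lo": -20.0,
    "cv1_wall_hi": 12.5,
    "cv2_wall_hi": 9.0,
    # integrator
    "dt": 0.5,
    "diffusion_coeff": 0.1,
    "n_steps": 1_000_000,
    # contact analysis
    "contact_d0": 4.5,
    "contact_lam": 1.0,
    "contact_cutoff": 4.5,
    "n_clusters": 4,
    # entropy estimator
    "entropy_components": 10,
    "entropy_bins": 30,
    # misc
    "seed": 0,
}


@dataclass
class RunConfig:
    """Resolved configuration values plus the provenance of each one
    (``default`` | ``file`` | ``flag``)."""

    values: dict = field(default_factory=lambda: dict(DEFAULTS))
    provenance: dict = field(default_factory=lambda: {k: "default" for k in DEFAULTS})

    def __getitem__(self, key: str):
        return self.values[key]

    def write(self, path) -> None:
        """Write the fully resolved config (with provenance) as JSON."""
        with open(path, "w") as fh:
            json.dump(
                {k: {"value": self.values[k], "source": self.provenance[k]}
                 for k in sorted(self.values)},
                fh, indent=2,
            )
            fh.write("\n")


def _check_types(updates: dict, source: str) -> None:
    unknown = sorted(set(updates) - set(DEFAULTS))
    if unknown:
        raise ValueError(f"unknown configuration key(s) from {source}: {', '.join(unknown)}")
    for k, v in updates.items():
        want = type(DEFAULTS[k])
        if want is float and isinstance(v, int) and not isinstance(v, bool):
            continue
        if not isinstance(v, want) or isinstance(v, bool) is not isinstance(DEFAULTS[k], bool):
            raise ValueError(
                f"configuration key {k!r} from {source}: expected {want.__name__}, "
                f"got {type(v).__name__} ({v!r})"
            )


def parse_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Resolve a configuration from defaults, an optional JSON/YAML file, and
    flag overrides (flags win over file values, which win over defaults)."""
    cfg = RunConfig()
    if path is not None:
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            data = yaml.safe_load(text) or {}
        else:
            try:
                data = json.loads(text) if text.strip() else {}
            except json.JSONDecodeError:
                data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"configuration file {path} must hold a mapping")
        _check_types(data, f"file {path}")
        for k, v in data.items():
            cfg.values[k] = float(v) if type(DEFAULTS[k]) is float else v
            cfg.provenance[k] = "file"
    if overrides:
        overrides = {k: v for k, v in overrides.items() if v is not None}
        _check_types(overrides, "flags")
        for k, v in overrides.items():
            cfg.values[k] = float(v) if type(DEFAULTS[k]) is float else v
            cfg.provenance[k] = "flag"
    return cfg
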