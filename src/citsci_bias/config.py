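"""YAML run configuration: schema, defaults and validation.

A near-empty config reproduces the standard settings: complete checklists
only, no incidental/historical protocols, <= 5 km, 5-240 min, 1%
prevalence cutoff (swept over 0/0.5/1/1.5%), zero policy "drop", REML
estimation with Wald 95% intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .io_filtering import FilterConfig
from .representation import ZERO_POLICIES
from .synthetic import EventGenConfig, PlantedEffects, TraitGenConfig
from .trait_models import ModelSpec
from .traits import ColorConfig

_TOP_KEYS = {
    "mode", "seed", "output_dir", "log_level", "filter", "prevalence_cutoffs",
    "zero_policy", "color", "model", "synthetic", "files",
}
_FILTER_KEYS = {
    "max_distance_km", "min_duration_min", "max_duration_min",
    "require_complete", "exclude_protocols", "prevalence_cutoff",
}
_COLOR_KEYS = {"reference", "space", "weights"}
_MODEL_KEYS = {"predictors", "estimation", "ci_level"}
_SYNTH_KEYS = {
    "n_states", "n_species", "checklists_per_state", "contamination",
    "boundary_fraction", "x_count_rate", "truth",
}
_TRUTH_KEYS = {
    "slope_b", "state_intercepts", "gamma_body", "gamma_flock",
    "gamma_color", "gamma_iucn", "noise_sd",
}
_FILES_KEYS = {"checklists", "ebird_obs", "inat_obs", "traits"}


@dataclass
class RunConfig:
    """Validated end-to-end run settings."""

    mode: str = "synthetic"
    seed: int = 0
    output_dir: str = "citsci_bias_out"
    log_level: str = "INFO"
    filter: FilterConfig = field(default_factory=FilterConfig)
    prevalence_cutoffs: tuple = (0.0, 0.005, 0.01, 0.015)
    zero_policy: str = "drop"
    color: ColorConfig = field(default_factory=ColorConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    synthetic: EventGenConfig | None = None
    files: dict | None = None
    raw: dict = field(default_factory=dict)


def _check_unknown(section: dict, allowed: set, where: str, problems: list) -> None:
    for key in section:
        if key not in allowed:
            problems.append(f"unknown key {key!r} in {where} (allowed: {sorted(allowed)})")


def validate_raw(raw: dict) -> list:
    """Collect every schema problem in a raw config dict (no exceptions)."""
    problems: list = []
    if not isinstance(raw, dict):
        return [f"config root must be a mapping, got {type(raw).__name__}"]
    _check_unknown(raw, _TOP_KEYS, "top level", problems)

    mode = raw.get("mode", "synthetic")
    if mode not in ("synthetic", "files"):
        problems.append(f"mode must be 'synthetic' or 'files', got {mode!r}")
    if mode == "files":
        files = raw.get("files")
        if not isinstance(files, dict):
            problems.append("files mode requires a 'files' section with input paths")
        else:
            _check_unknown(files, _FILES_KEYS, "files", problems)
            for key in _FILES_KEYS:
                if key not in files:
                    problems.append(f"files section is missing required path {key!r}")
                elif not Path(str(files[key])).exists():
                    problems.append(f"files.{key} does not exist: {files[key]}")

    _check_unknown(raw.get("filter", {}) or {}, _FILTER_KEYS, "filter", problems)
    _check_unknown(raw.get("color", {}) or {}, _COLOR_KEYS, "color", problems)
    _check_unknown(raw.get("model", {}) or {}, _MODEL_KEYS, "model", problems)
    synth = raw.get("synthetic", {}) or {}
    _check_unknown(synth, _SYNTH_KEYS, "synthetic", problems)
    _check_unknown(synth.get("truth", {}) or {}, _TRUTH_KEYS, "synthetic.truth", problems)

    zp = raw.get("zero_policy", "drop")
    if zp not in ZERO_POLICIES:
        problems.append(f"zero_policy must be one of {ZERO_POLICIES}, got {zp!r}")
    cutoffs = raw.get("prevalence_cutoffs", (0.0, 0.005, 0.01, 0.015))
    if not isinstance(cutoffs, (list, tuple)) or not cutoffs:
        problems.append("prevalence_cutoffs must be a non-empty list")
    else:
        for c in cutoffs:
            if not isinstance(c, (int, float)) or not 0 <= c <= 1:
                problems.append(f"prevalence cutoff out of range [0, 1]: {c!r}")
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        problems.append(f"seed must be an integer, got {seed!r}")

    # Section constructors perform the remaining range checks.
    if not problems:
        try:
            _build(raw)
        except ConfigError as exc:
            problems.append(str(exc))
    return problems


def _build(raw: dict) -> RunConfig:
    filt = FilterConfig(**(raw.get("filter", {}) or {}))
    color_raw = dict(raw.get("color", {}) or {})
    if "reference" in color_raw:
        color_raw["reference"] = tuple(color_raw["reference"])
    if "weights" in color_raw:
        color_raw["weights"] = tuple(color_raw["weights"])
    color = ColorConfig(**color_raw)
    model_raw = dict(raw.get("model", {}) or {})
    if "predictors" in model_raw:
        model_raw["predictors"] = tuple(model_raw["predictors"])
    model = ModelSpec(**model_raw)

    synth_cfg = None
    if raw.get("mode", "synthetic") == "synthetic":
        s = dict(raw.get("synthetic", {}) or {})
        truth_raw = s.pop("truth", None)
        n_states = int(s.pop("n_states", 5))
        n_species = int(s.pop("n_species", 50))
        states = tuple(f"S{i:02d}" for i in range(n_states))
        truth = None
        if truth_raw:
            truth_raw = dict(truth_raw)
            intercepts = truth_raw.pop(
                "state_intercepts", {st: -2.3 for st in states}
            )
            truth = PlantedEffects(
                slope_b=float(truth_raw.pop("slope_b", 1.0)),
                state_intercepts={str(k): float(v) for k, v in intercepts.items()},
                **{k: float(v) for k, v in truth_raw.items()},
            )
        synth_cfg = EventGenConfig(
            states=states,
            trait_cfg=TraitGenConfig(n_species=n_species, seed=int(raw.get("seed", 0))),
            truth=truth,
            seed=int(raw.get("seed", 0)),
            **s,
        )
        synth_cfg.validate()

    return RunConfig(
        mode=raw.get("mode", "synthetic"),
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", "citsci_bias_out")),
        log_level=str(raw.get("log_level", "INFO")),
        filter=filt,
        prevalence_cutoffs=tuple(raw.get("prevalence_cutoffs", (0.0, 0.005, 0.01, 0.015))),
        zero_policy=raw.get("zero_policy", "drop"),
        color=color,
        model=model,
        synthetic=synth_cfg,
        files=raw.get("files"),
        raw=raw,
    )


def load_config(path) -> RunConfig:
    """Load + validate a YAML config; raises ConfigError listing all problems."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    problems = validate_raw(raw)
    if problems:
        raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(problems))
    return _build(raw)
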