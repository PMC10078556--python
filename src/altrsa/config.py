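"""Configuration files for the model and the simulator.

Both JSON and YAML are accepted (JSON is tried first; YAML is a superset,
so either dialect parses).  Unknown keys are rejected, defaults are filled,
and every invariant violation names the offending key.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .core import AlternativeMixture, ModelConfig, WorldPrior
from .simulate import CELLS, DesignSpec, GenParams

__all__ = ["ConfigError", "load_raw", "load_model_config", "load_sim_config"]

_MODEL_KEYS = {"N", "prior", "alpha", "access_partial", "access_full", "p_with_numerals"}
_DESIGN_KEYS = {
    "n_participants",
    "n_target",
    "n_exposure",
    "first_trial_exposure",
    "no_adjacent_targets",
}
_GEN_KEYS = {
    "cell_means_not_all",
    "sd_total",
    "sd_participant",
    "sd_item",
    "sd_resid",
    "exposure_mean_all",
    "comprehension_error_rate",
}
_CELL_NAMES = {
    "partial_no_num": ("partial", "no_numerals"),
    "partial_with_num": ("partial", "with_numerals"),
    "full_no_num": ("full", "no_numerals"),
    "full_with_num": ("full", "with_numerals"),
}


class ConfigError(ValueError):
    """A configuration file failed to parse or validate."""


def load_raw(path) -> dict:
    """Parse a JSON or YAML mapping from disk."""
    text = Path(path).read_text()
    try:
        raw = json.loads(text)
    except json.JSONDecodeError:
        try:
            raw = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: cannot parse as JSON or YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping, got {type(raw).__name__}")
    return raw


def _check_keys(raw: dict, allowed: set, path) -> None:
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")


def load_model_config(path, alpha_override: float | None = None) -> ModelConfig:
    """Read and validate a scenario config into a ModelConfig."""
    raw = load_raw(path)
    _check_keys(raw, _MODEL_KEYS, path)
    n = raw.get("N", 3)
    if not isinstance(n, int) or n < 1:
        raise ConfigError(f"{path}: N must be a positive integer")
    prior_raw = raw.get("prior", "uniform")
    try:
        if prior_raw == "uniform":
            prior = WorldPrior.uniform(n)
        else:
            prior = WorldPrior(tuple(float(x) for x in prior_raw))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: prior: {exc}") from exc
    alpha = alpha_override if alpha_override is not None else raw.get("alpha", 1.0)
    try:
        return ModelConfig(
            n=n,
            prior=prior,
            alpha=float(alpha),
            access_partial=raw.get("access_partial", min(2, n - 1) if n > 1 else 1),
            access_full=raw.get("access_full", n),
            mixture=AlternativeMixture(float(raw.get("p_with_numerals", 0.0))),
        )
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def load_sim_config(path, n_override: int | None = None):
    """Read and validate a simulator config into (DesignSpec, GenParams)."""
    raw = load_raw(path)
    _check_keys(raw, _DESIGN_KEYS | _GEN_KEYS, path)
    design_kwargs = {k: raw[k] for k in _DESIGN_KEYS if k in raw}
    if n_override is not None:
        design_kwargs["n_participants"] = n_override
    try:
        spec = DesignSpec(**design_kwargs)
    except ValueError as exc:
        raise ConfigError(f"{path}: design: {exc}") from exc

    gen_kwargs = {}
    if "cell_means_not_all" in raw:
        means = raw["cell_means_not_all"]
        if not isinstance(means, dict):
            raise ConfigError(f"{path}: cell_means_not_all must be a mapping")
        unknown = set(means) - set(_CELL_NAMES)
        if unknown:
            raise ConfigError(
                f"{path}: cell_means_not_all: unknown cells {sorted(unknown)} "
                f"(expected {sorted(_CELL_NAMES)})"
            )
        missing = set(_CELL_NAMES) - set(means)
        if missing:
            raise ConfigError(
                f"{path}: cell_means_not_all: missing cells {sorted(missing)}"
            )
        gen_kwargs["cell_means_not_all"] = {
            _CELL_NAMES[k]: float(v) for k, v in means.items()
        }
    for key in ("sd_participant", "sd_item", "sd_resid",
                "exposure_mean_all", "comprehension_error_rate"):
        if key in raw:
            gen_kwargs[key] = float(raw[key])
    try:
        if "sd_total" in raw:
            if {"sd_participant", "sd_item", "sd_resid"} & set(raw):
                raise ConfigError(
                    f"{path}: give either sd_total or the three components, not both"
                )
            means = gen_kwargs.pop("cell_means_not_all", None)
            params = (
                GenParams.from_cell_means(means, sd_total=float(raw["sd_total"]),
                                          **gen_kwargs)
                if means is not None
                else GenParams.from_cell_means(
                    GenParams().cell_means_not_all,
                    sd_total=float(raw["sd_total"]), **gen_kwargs
                )
            )
        else:
            params = GenParams(**gen_kwargs)
    except ValueError as exc:
        raise ConfigError(f"{path}: params: {exc}") from exc
    return spec, params
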