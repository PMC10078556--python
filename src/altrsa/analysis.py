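"""Contrast estimation, bootstrap inference and Monte-Carlo power analysis.

The estimand is the 2×2 fixed-effect structure of the rating studies:
intercept (grand mean), knowledgeability main effect (full − partial),
exposure main effect (with − without numerals), and their interaction, on
the 0–100 "probability not all" scale with ±0.5 contrast coding.

The estimator aggregates target trials to per-participant cell means first
(each participant contributes one partial and one full mean), averages
those within exposure group, and combines the four cell averages with the
standard contrast algebra.  On balanced data these are exactly the
fixed-effect quantities a mixed-effects contrast regression targets;
uncertainty comes from a nonparametric bootstrap that resamples
participants within exposure group (exposure is between-subject).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import CELLS, DesignSpec, GenParams, generate_dataset, transform_responses

__all__ = [
    "FitResult",
    "SimpleEffectResult",
    "PowerResult",
    "contrast_code",
    "estimate_effects",
    "simple_effects",
    "power_analysis",
]

_KNOW_CODE = {"partial": -0.5, "full": 0.5}
_EXPO_CODE = {"no_numerals": -0.5, "with_numerals": 0.5}

EFFECTS = ("intercept", "knowledgeability", "exposure", "interaction")


def contrast_code(dataset: pd.DataFrame) -> pd.DataFrame:
    """Add ±0.5 contrast columns k, e and their product k_x_e."""
    know = dataset["knowledgeability"]
    expo = dataset["exposure_condition"]
    bad_k = set(know.dropna().unique()) - set(_KNOW_CODE)
    bad_e = set(expo.dropna().unique()) - set(_EXPO_CODE)
    if bad_k or bad_e:
        raise ValueError(f"unknown factor levels: {sorted(bad_k | bad_e)}")
    out = dataset.copy()
    out["k"] = know.map(_KNOW_CODE)
    out["e"] = expo.map(_EXPO_CODE)
    out["k_x_e"] = out["k"] * out["e"]
    return out


@dataclass(frozen=True)
class FitResult:
    intercept: float
    effect_knowledgeability: float
    effect_exposure: float
    effect_interaction: float
    ci: dict  # effect name -> (lo, hi) percentile bootstrap interval
    se: dict  # effect name -> bootstrap standard error
    n_participants: int
    n_missing_cells: int
    n_boot: int
    ci_level: float

    def effect(self, name: str) -> float:
        return {
            "intercept": self.intercept,
            "knowledgeability": self.effect_knowledgeability,
            "exposure": self.effect_exposure,
            "interaction": self.effect_interaction,
        }[name]

    def to_dict(self) -> dict:
        return {
            "estimates": {name: self.effect(name) for name in EFFECTS},
            "ci": {k: list(v) for k, v in self.ci.items()},
            "se": dict(self.se),
            "n_participants": self.n_participants,
            "n_missing_cells": self.n_missing_cells,
            "n_boot": self.n_boot,
            "ci_level": self.ci_level,
            "estimator": "participant-cell-mean contrasts, "
            "participant-level bootstrap within exposure group",
        }


def _participant_cell_matrix(dataset: pd.DataFrame):
    """Per-participant (partial, full) means of not_all_rating, by group.

    Returns {exposure: (n_g, 2) array with NaN for missing cells} and the
    count of missing participant×knowledgeability cells.
    """
    targets = dataset[dataset["trial_type"] == "target"]
    if "not_all_rating" not in targets.columns:
        raise ValueError("dataset lacks not_all_rating; run transform_responses first")
    cell = (
        targets.groupby(["exposure_condition", "participant", "knowledgeability"],
                        observed=True)["not_all_rating"]
        .mean()
        .unstack("knowledgeability")
    )
    for level in ("partial", "full"):
        if level not in cell.columns:
            cell[level] = np.nan
    groups = {}
    n_missing = 0
    for expo in ("no_numerals", "with_numerals"):
        if expo not in cell.index.get_level_values(0):
            raise ValueError(f"exposure group {expo!r} absent from dataset")
        mat = cell.loc[expo][["partial", "full"]].to_numpy(dtype=float)
        n_missing += int(np.isnan(mat).sum())
        groups[expo] = mat
    return groups, n_missing


def _effects_from_cells(no_num: np.ndarray, with_num: np.ndarray) -> np.ndarray:
    """Contrast algebra on cell averages.

    Inputs are (..., 2) arrays of (partial, full) group means; returns
    (..., 4): intercept, knowledgeability, exposure, interaction.
    """
    a, c = no_num[..., 0], no_num[..., 1]      # partial/no, full/no
    b, d = with_num[..., 0], with_num[..., 1]  # partial/with, full/with
    return np.stack(
        [
            (a + b + c + d) / 4.0,
            (c + d) / 2.0 - (a + b) / 2.0,
            (b + d) / 2.0 - (a + c) / 2.0,
            (d - b) - (c - a),
        ],
        axis=-1,
    )


def _bootstrap_effects(groups, n_boot: int, rng) -> np.ndarray:
    """(n_boot, 4) bootstrap replicates, resampling within exposure group."""
    means = {}
    for expo, mat in groups.items():
        n_g = mat.shape[0]
        idx = rng.integers(0, n_g, size=(n_boot, n_g))
        with np.errstate(invalid="ignore"):
            means[expo] = np.nanmean(mat[idx], axis=1)  # (n_boot, 2)
    return _effects_from_cells(means["no_numerals"], means["with_numerals"])


def estimate_effects(
    dataset: pd.DataFrame,
    n_boot: int = 2000,
    ci_level: float = 0.95,
    seed: int | None = None,
) -> FitResult:
    """Point estimates plus percentile-bootstrap intervals for the 2×2 effects.

    Participants missing one knowledgeability cell (e.g., after trial-level
    exclusions) contribute only their available cell; the count of such
    missing cells is reported in the result.
    """
    groups, n_missing = _participant_cell_matrix(dataset)
    for expo, mat in groups.items():
        if mat.shape[0] < 2:
            raise ValueError(f"need >= 2 participants in exposure group {expo!r}")
    with np.errstate(invalid="ignore"):
        point = _effects_from_cells(
            np.nanmean(groups["no_numerals"], axis=0),
            np.nanmean(groups["with_numerals"], axis=0),
        )
    rng = np.random.default_rng(seed)
    boot = _bootstrap_effects(groups, n_boot, rng)
    lo_q, hi_q = (1 - ci_level) / 2, 1 - (1 - ci_level) / 2
    ci = {}
    se = {}
    for j, name in enumerate(EFFECTS):
        lo, hi = np.nanquantile(boot[:, j], [lo_q, hi_q])
        ci[name] = (float(lo), float(hi))
        se[name] = float(np.nanstd(boot[:, j], ddof=1))
    n_participants = sum(mat.shape[0] for mat in groups.values())
    return FitResult(
        intercept=float(point[0]),
        effect_knowledgeability=float(point[1]),
        effect_exposure=float(point[2]),
        effect_interaction=float(point[3]),
        ci=ci,
        se=se,
        n_participants=n_participants,
        n_missing_cells=n_missing,
        n_boot=n_boot,
        ci_level=ci_level,
    )


@dataclass(frozen=True)
class SimpleEffectResult:
    knowledgeability: str
    estimate: float  # with_numerals minus no_numerals group means
    ci: tuple
    se: float
    n_boot: int
    ci_level: float

    def to_dict(self) -> dict:
        return {
            "knowledgeability": self.knowledgeability,
            "estimate": self.estimate,
            "ci": list(self.ci),
            "se": self.se,
            "n_boot": self.n_boot,
            "ci_level": self.ci_level,
        }


def simple_effects(
    dataset: pd.DataFrame,
    within: str,
    n_boot: int = 2000,
    ci_level: float = 0.95,
    seed: int | None = None,
) -> SimpleEffectResult:
    """Exposure effect (with − without numerals) at one knowledgeability level."""
    if within not in _KNOW_CODE:
        raise ValueError(f"unknown knowledgeability level {within!r}")
    groups, _ = _participant_cell_matrix(dataset)
    col = 0 if within == "partial" else 1
    rng = np.random.default_rng(seed)
    vals = {}
    boots = {}
    for expo, mat in groups.items():
        v = mat[:, col]
        v = v[~np.isnan(v)]
        if v.size < 2:
            raise ValueError(f"need >= 2 participants with {within!r} data in {expo!r}")
        vals[expo] = v.mean()
        idx = rng.integers(0, v.size, size=(n_boot, v.size))
        boots[expo] = v[idx].mean(axis=1)
    est = vals["with_numerals"] - vals["no_numerals"]
    diff = boots["with_numerals"] - boots["no_numerals"]
    lo_q, hi_q = (1 - ci_level) / 2, 1 - (1 - ci_level) / 2
    lo, hi = np.quantile(diff, [lo_q, hi_q])
    return SimpleEffectResult(
        knowledgeability=within,
        estimate=float(est),
        ci=(float(lo), float(hi)),
        se=float(diff.std(ddof=1)),
        n_boot=n_boot,
        ci_level=ci_level,
    )


@dataclass(frozen=True)
class PowerResult:
    n_participants: int
    n_sims: int
    alpha_level: float
    power: float
    mc_se: float

    def to_dict(self) -> dict:
        return {
            "n_participants": self.n_participants,
            "n_sims": self.n_sims,
            "alpha_level": self.alpha_level,
            "power": self.power,
            "mc_se": self.mc_se,
        }


def power_analysis(
    params: GenParams,
    spec: DesignSpec,
    n_grid,
    n_sims: int,
    alpha_level: float = 0.05,
    seed: int = 0,
    n_boot: int = 1000,
) -> list:
    """Monte-Carlo power of the bootstrap interaction test per sample size.

    For each n in the grid, simulates ``n_sims`` experiments from the
    generator, fits each with :func:`estimate_effects`, and records the
    fraction of runs whose (1 − alpha_level) interaction CI excludes zero.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100 for a usable power estimate")
    results = []
    root = np.random.SeedSequence(seed)
    for n in n_grid:
        sim_spec = DesignSpec(
            n_participants=int(n),
            n_target=spec.n_target,
            n_exposure=spec.n_exposure,
            first_trial_exposure=spec.first_trial_exposure,
            no_adjacent_targets=spec.no_adjacent_targets,
        )
        streams = root.spawn(n_sims)
        n_reject = 0
        for ss in streams:
            data_seed, boot_seed = ss.generate_state(2) >> 1  # keep < 2**31
            data = transform_responses(
                generate_dataset(sim_spec, params, int(data_seed))
            )
            fit = estimate_effects(
                data, n_boot=n_boot, ci_level=1 - alpha_level, seed=int(boot_seed)
            )
            lo, hi = fit.ci["interaction"]
            if lo > 0 or hi < 0:
                n_reject += 1
        power = n_reject / n_sims
        results.append(
            PowerResult(
                n_participants=int(n),
                n_sims=n_sims,
                alpha_level=alpha_level,
                power=power,
                mc_se=float(np.sqrt(power * (1 - power) / n_sims)),
            )
        )
    return results
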