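"""Synthetic rating-experiment generator for the 2×2 implicature design.

Emulates the structure of the rating studies the model targets: a
between-subject exposure factor (whether the speaker habitually uses
numerals in filler trials), a within-subject knowledgeability factor
(speaker examined 2 of 3 vs. 3 of 3 objects), 8 target trials (4 partial /
4 full) interleaved with 24 exposure trials per participant, and a 0–100
"probability that all objects have the property" rating per trial.

Ratings are generated as a cell mean plus Gaussian participant, item and
residual components, clipped to the closed response scale [0, 100] —
bounded-scale responses pile up at the endpoints rather than being
resampled.  ``expected_cell_means`` gives the exact expected value of the
generated ratings (censored-normal mean), which is what any consistent
estimator of the cell means converges to.

The ordering constraints of the real studies are enforced per participant:
the first trial is an exposure trial and no two target trials are adjacent.
Target positions are drawn uniformly over the layouts satisfying both
constraints via the classic non-adjacent-combination bijection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "DesignSpec",
    "GenParams",
    "ExclusionPolicy",
    "ExclusionReport",
    "CELLS",
    "build_design",
    "generate_dataset",
    "transform_responses",
    "exclusion_filter",
    "expected_cell_means",
    "expected_effects",
]

KNOWLEDGEABILITY = ("partial", "full")
EXPOSURE = ("no_numerals", "with_numerals")
#: the 2×2 design cells in canonical order
CELLS = (
    ("partial", "no_numerals"),
    ("partial", "with_numerals"),
    ("full", "no_numerals"),
    ("full", "with_numerals"),
)

#: columns of a dataset CSV, in fixed order
DATASET_COLUMNS = [
    "participant",
    "item",
    "position",
    "trial_type",
    "knowledgeability",
    "exposure_condition",
    "rating",
    "comp1_correct",
    "comp2_correct",
]


@dataclass(frozen=True)
class DesignSpec:
    """Factorial layout of one simulated experiment."""

    n_participants: int = 240
    n_target: int = 8
    n_exposure: int = 24
    first_trial_exposure: bool = True
    no_adjacent_targets: bool = True

    def __post_init__(self) -> None:
        if self.n_participants < 2 or self.n_participants % 2:
            raise ValueError(
                "n_participants must be even and >= 2 (exposure condition is "
                "assigned between subjects in equal halves)"
            )
        if self.n_target < 2 or self.n_target % 2:
            raise ValueError("n_target must be even (balanced knowledgeability)")
        if self.n_exposure < 0:
            raise ValueError("n_exposure must be >= 0")

    @property
    def n_trials(self) -> int:
        return self.n_target + self.n_exposure


@dataclass(frozen=True)
class GenParams:
    """Response-generation parameters.

    ``cell_means_not_all`` are mean ratings per design cell on the
    transformed 0–100 "probability not all" scale; generation converts them
    back to the probability-of-all scale the question actually asks.  The
    default means/SD reproduce the second rating study's observed cells;
    the total variance is split 40% participant / 10% item / 50% residual.
    """

    cell_means_not_all: dict = field(
        default_factory=lambda: {
            ("partial", "no_numerals"): 45.4,
            ("partial", "with_numerals"): 52.3,
            ("full", "no_numerals"): 64.7,
            ("full", "with_numerals"): 62.0,
        }
    )
    # default SDs: total SD 33.375 split as 40/10/50% of variance
    sd_participant: float = 21.108
    sd_item: float = 10.554
    sd_resid: float = 23.600
    #: mean probability-of-all rating for (never-analyzed) exposure trials
    exposure_mean_all: float = 80.0
    comprehension_error_rate: float = 0.0

    def __post_init__(self) -> None:
        for cell in CELLS:
            if cell not in self.cell_means_not_all:
                raise ValueError(f"cell_means_not_all missing cell {cell}")
            m = self.cell_means_not_all[cell]
            if not 0.0 <= m <= 100.0:
                raise ValueError(f"cell mean for {cell} outside [0, 100]: {m}")
        for name in ("sd_participant", "sd_item", "sd_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.comprehension_error_rate <= 1.0:
            raise ValueError("comprehension_error_rate must lie in [0, 1]")

    @property
    def sd_total(self) -> float:
        return float(
            np.sqrt(self.sd_participant**2 + self.sd_item**2 + self.sd_resid**2)
        )

    @classmethod
    def from_cell_means(cls, means_not_all, sd_total=33.375, **kwargs) -> "GenParams":
        """Build params from not-all cell means and a total SD (40/10/50 split)."""
        return cls(
            cell_means_not_all=dict(means_not_all),
            sd_participant=sd_total * np.sqrt(0.4),
            sd_item=sd_total * np.sqrt(0.1),
            sd_resid=sd_total * np.sqrt(0.5),
            **kwargs,
        )

    @classmethod
    def from_prediction_table(cls, table, sd_total=33.375, **kwargs) -> "GenParams":
        """Link cell means to a core-model PredictionTable (percent scale)."""
        means = {
            (k, a): 100.0 * p for (k, a), p in table.cells.items()
        }
        return cls.from_cell_means(means, sd_total=sd_total, **kwargs)


def _non_adjacent_positions(rng, n_slots: int, k: int) -> np.ndarray:
    """Uniform sample of k pairwise non-adjacent indices from 0..n_slots-1.

    Bijection: sorted draws y_1 < ... < y_k from {0..n_slots-k} map to
    positions y_i + (i-1), which are pairwise non-adjacent.
    """
    if n_slots - k + 1 < k:
        raise ValueError("not enough slots for non-adjacent placement")
    y = np.sort(rng.choice(n_slots - k + 1, size=k, replace=False))
    return y + np.arange(k)


def _participant_order(rng, spec: DesignSpec):
    """Trial ordering for one participant, honoring the layout constraints."""
    m, k = spec.n_trials, spec.n_target
    is_target = np.zeros(m, dtype=bool)
    if spec.first_trial_exposure:
        if spec.n_exposure < 1:
            raise ValueError(
                "constraint violated: first trial must be an exposure trial "
                "but n_exposure = 0"
            )
        if spec.no_adjacent_targets:
            pos = 1 + _non_adjacent_positions(rng, m - 1, k)
        else:
            pos = 1 + rng.choice(m - 1, size=k, replace=False)
    else:
        if spec.no_adjacent_targets:
            pos = _non_adjacent_positions(rng, m, k)
        else:
            pos = rng.choice(m, size=k, replace=False)
    is_target[pos] = True

    half = k // 2
    know_targets = np.array(["partial"] * half + ["full"] * half, dtype=object)
    rng.shuffle(know_targets)
    # exposure trials also alternate speaker knowledgeability, half and half
    n_exp = spec.n_exposure
    know_exposure = np.array(
        ["partial"] * (n_exp // 2) + ["full"] * (n_exp - n_exp // 2), dtype=object
    )
    rng.shuffle(know_exposure)

    target_items = np.array([f"T{i + 1}" for i in range(k)], dtype=object)
    rng.shuffle(target_items)
    exposure_items = np.array([f"E{i + 1}" for i in range(n_exp)], dtype=object)
    rng.shuffle(exposure_items)

    trial_type = np.where(is_target, "target", "exposure")
    items = np.empty(m, dtype=object)
    know = np.empty(m, dtype=object)
    items[is_target] = target_items
    items[~is_target] = exposure_items
    know[is_target] = know_targets
    know[~is_target] = know_exposure
    return trial_type, items, know


def build_design(spec: DesignSpec, seed: int) -> pd.DataFrame:
    """Ordered trial lists for all participants; deterministic given seed.

    Raises a ValueError naming the violated constraint when the layout is
    unsatisfiable (e.g., no exposure trial available for position 1, or too
    few exposure trials to separate the targets).
    """
    if spec.no_adjacent_targets and (spec.n_trials - spec.n_target + 1 <
                                     spec.n_target + int(spec.first_trial_exposure)):
        raise ValueError(
            "constraint violated: too few exposure trials to keep target "
            "trials non-adjacent"
        )
    streams = np.random.SeedSequence(seed).spawn(spec.n_participants)
    frames = []
    for pid, ss in enumerate(streams, start=1):
        rng = np.random.default_rng(ss)
        trial_type, items, know = _participant_order(rng, spec)
        frames.append(
            pd.DataFrame(
                {
                    "participant": pid,
                    "item": items,
                    "position": np.arange(1, spec.n_trials + 1),
                    "trial_type": trial_type,
                    "knowledgeability": know,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_dataset(spec: DesignSpec, params: GenParams, seed: int) -> pd.DataFrame:
    """Simulate one full experiment; returns one row per trial.

    Ratings answer "how likely is it that ALL objects have the property"
    (0–100); the analysis-side complement is added by
    :func:`transform_responses`.  The exposure condition is assigned between
    subjects in equal halves.  One master seed drives per-participant
    streams (via ``SeedSequence.spawn``) plus a shared item-effect stream,
    so regeneration with the same seed is bit-reproducible.
    """
    root = np.random.SeedSequence(seed)
    item_ss, assign_ss, *participant_ss = root.spawn(spec.n_participants + 2)

    item_rng = np.random.default_rng(item_ss)
    item_labels = [f"T{i + 1}" for i in range(spec.n_target)] + [
        f"E{i + 1}" for i in range(spec.n_exposure)
    ]
    item_effects = dict(
        zip(item_labels, params.sd_item * item_rng.standard_normal(len(item_labels)))
    )

    assign_rng = np.random.default_rng(assign_ss)
    half = spec.n_participants // 2
    exposure_assignment = np.array(
        ["no_numerals"] * half + ["with_numerals"] * half, dtype=object
    )
    assign_rng.shuffle(exposure_assignment)

    # mean of the raw probability-of-all rating per (trial_type, knowledgeability)
    mean_all = {
        ("target", k, e): 100.0 - params.cell_means_not_all[(k, e)]
        for k, e in CELLS
    }

    m = spec.n_trials
    cols: dict = {
        "participant": [],
        "item": [],
        "trial_type": [],
        "knowledgeability": [],
        "exposure_condition": [],
        "rating": [],
        "comp1_correct": [],
        "comp2_correct": [],
    }
    for pid, ss in enumerate(participant_ss, start=1):
        rng = np.random.default_rng(ss)
        trial_type, items, know = _participant_order(rng, spec)
        exposure = exposure_assignment[pid - 1]
        mu = np.array(
            [
                mean_all[("target", k, exposure)]
                if t == "target"
                else params.exposure_mean_all
                for t, k in zip(trial_type, know)
            ]
        )
        v_item = np.array([item_effects[i] for i in items])
        u_participant = params.sd_participant * rng.standard_normal()
        eps = params.sd_resid * rng.standard_normal(m)
        rating = np.clip(mu + u_participant + v_item + eps, 0.0, 100.0)
        comp = rng.random((m, 2)) >= params.comprehension_error_rate
        cols["participant"].append(np.full(m, pid))
        cols["item"].append(items)
        cols["trial_type"].append(trial_type)
        cols["knowledgeability"].append(know)
        cols["exposure_condition"].append(np.full(m, exposure, dtype=object))
        cols["rating"].append(rating)
        cols["comp1_correct"].append(comp[:, 0])
        cols["comp2_correct"].append(comp[:, 1])
    data = {name: np.concatenate(parts) for name, parts in cols.items()}
    data["position"] = np.tile(np.arange(1, m + 1), spec.n_participants)
    return pd.DataFrame(data)[DATASET_COLUMNS]


def transform_responses(dataset: pd.DataFrame) -> pd.DataFrame:
    """Add ``not_all_rating`` = 100 − rating; the original column is kept."""
    ratings = dataset["rating"].to_numpy(dtype=float)
    if np.any(ratings < 0) or np.any(ratings > 100) or np.any(~np.isfinite(ratings)):
        raise ValueError("ratings must lie in [0, 100]")
    out = dataset.copy()
    out["not_all_rating"] = 100.0 - out["rating"]
    return out


@dataclass(frozen=True)
class ExclusionPolicy:
    """Participant- and trial-level comprehension-based exclusion rules.

    ``accuracy_threshold`` applies to a participant's accuracy over all
    comprehension answers; ``drop_bad_trials`` additionally removes target
    trials with any wrong comprehension answer.
    """

    accuracy_threshold: float = 1.0
    drop_bad_trials: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy_threshold <= 1.0:
            raise ValueError("accuracy_threshold must lie in [0, 1]")


@dataclass(frozen=True)
class ExclusionReport:
    n_participants_before: int
    n_participants_dropped: int
    n_trials_dropped: int


def exclusion_filter(dataset: pd.DataFrame, policy: ExclusionPolicy | None = None):
    """Apply the exclusion policy; returns (filtered dataset, report)."""
    if policy is None:
        policy = ExclusionPolicy()
    correct = dataset[["comp1_correct", "comp2_correct"]].to_numpy(dtype=float)
    acc = (
        pd.DataFrame(
            {"participant": dataset["participant"], "acc": correct.mean(axis=1)}
        )
        .groupby("participant")["acc"]
        .mean()
    )
    keep_participants = acc[acc >= policy.accuracy_threshold].index
    n_before = acc.size
    out = dataset[dataset["participant"].isin(keep_participants)]
    n_trials_dropped = 0
    if policy.drop_bad_trials:
        bad = (
            (out["trial_type"] == "target")
            & ~(out["comp1_correct"] & out["comp2_correct"])
        )
        n_trials_dropped = int(bad.sum())
        out = out[~bad]
    report = ExclusionReport(
        n_participants_before=int(n_before),
        n_participants_dropped=int(n_before - len(keep_participants)),
        n_trials_dropped=n_trials_dropped,
    )
    return out.reset_index(drop=True), report


# ---------------------------------------------------------------------------
# analytic moments of the generator (independent of the sampling code path)
# ---------------------------------------------------------------------------

def _censored_normal_mean(mu: float, sigma: float, lo=0.0, hi=100.0) -> float:
    """E[clip(X, lo, hi)] for X ~ N(mu, sigma^2), in closed form."""
    if sigma == 0:
        return float(np.clip(mu, lo, hi))
    a = (lo - mu) / sigma
    b = (hi - mu) / sigma
    return float(
        lo * norm.cdf(a)
        + hi * norm.sf(b)
        + mu * (norm.cdf(b) - norm.cdf(a))
        + sigma * (norm.pdf(a) - norm.pdf(b))
    )


def expected_cell_means(params: GenParams) -> dict:
    """Expected *not-all* rating per cell under the generator.

    Clipping acts on the total trial value, whose marginal law is Gaussian
    with the combined SD, so the expectation is the censored-normal mean;
    the not-all transform is affine and commutes with the expectation.
    """
    sd = params.sd_total
    return {
        cell: 100.0 - _censored_normal_mean(100.0 - m, sd)
        for cell, m in params.cell_means_not_all.items()
    }


def expected_effects(params: GenParams) -> dict:
    """Generator's true intercept/main-effect/interaction values (not-all scale)."""
    m = expected_cell_means(params)
    a = m[("partial", "no_numerals")]
    b = m[("partial", "with_numerals")]
    c = m[("full", "no_numerals")]
    d = m[("full", "with_numerals")]
    return {
        "intercept": (a + b + c + d) / 4.0,
        "knowledgeability": (c + d) / 2.0 - (a + b) / 2.0,
        "exposure": (b + d) / 2.0 - (a + c) / 2.0,
        "interaction": (d - b) - (c - a),
    }
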