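"""Epistemic Rational Speech Acts model with uncertainty over alternative sets.

The model concerns scenarios in which a speaker has examined ``a`` of ``N``
objects (e.g., letters that may contain checks) and utters a quantifier such
as "some".  A pragmatic listener infers how many of the N objects have the
target property, jointly reasoning about

* the speaker's *knowledge state* — which complete worlds are consistent
  with having observed ``o`` property-bearing objects among the ``a``
  examined — and
* the *alternative set* the speaker chooses among: the core quantifiers
  {none, some, all}, optionally augmented with lower-bounded numerals
  ("two" = at least two).

The recursion is the standard RSA ladder.  A literal listener restricts the
world prior to the utterance's literal meaning::

    L0(w | u)  ∝  P(w) · 1[w ∈ ⟦u⟧]

A speaker with knowledge state s values utterances by the expected log
probability the literal listener assigns to the worlds the speaker believes
in, and softmaxes that utility with rationality alpha::

    U1(u | s)       =  Σ_w P(w | s) · log L0(w | u)
    S1(u | s, A)    ∝  exp(alpha · U1(u | s)),   u ∈ A

The pragmatic listener marginalizes over the speaker's possible
observations and over which alternative set A the speaker was using::

    L1(w | u)  ∝  Σ_A P(A) Σ_o P(w) · P(o | w, a) · S1(u | s(a, o), A)

All products are accumulated in log space and normalized with log-sum-exp.
A knowledge state in which *no* alternative is assertable (every utterance
is false in some belief-supported world) is "mute" and contributes zero
probability mass to the L1 sum.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom

__all__ = [
    "WorldPrior",
    "Utterance",
    "AlternativeSet",
    "AlternativeMixture",
    "KnowledgeState",
    "ModelConfig",
    "PredictionTable",
    "UninterpretableUtteranceError",
    "UnproducibleUtteranceError",
    "core_alternatives",
    "numeral_alternatives",
    "literal_listener",
    "speaker_utility",
    "speaker_distribution",
    "observation_model",
    "knowledge_state",
    "pragmatic_listener",
    "prob_not_all",
    "predict_condition_table",
    "sweep",
]

_ATOL = 1e-12

_NUMERAL_WORDS = [
    "zero", "one", "two", "three", "four", "five",
    "six", "seven", "eight", "nine", "ten",
]


class UninterpretableUtteranceError(ValueError):
    """The utterance's meaning has no overlap with the prior's support."""


class UnproducibleUtteranceError(ValueError):
    """No reachable knowledge state would ever produce the utterance."""


@dataclass(frozen=True)
class WorldPrior:
    """Prior distribution over the number of property-bearing objects.

    ``weights[w]`` is the prior probability that exactly ``w`` of the ``N``
    objects have the property, for w = 0..N.
    """

    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size < 2:
            raise ValueError("prior needs weights for at least worlds {0, 1}")
        if np.any(w < 0):
            raise ValueError("prior weights must be nonnegative")
        if abs(w.sum() - 1.0) > _ATOL:
            raise ValueError(f"prior weights must sum to 1 (got {w.sum()!r})")
        object.__setattr__(self, "weights", tuple(float(x) for x in w))

    @property
    def n(self) -> int:
        """Scenario size N (worlds are counts 0..N)."""
        return len(self.weights) - 1

    @classmethod
    def uniform(cls, n: int) -> "WorldPrior":
        return cls(tuple([1.0 / (n + 1)] * (n + 1)))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)


@dataclass(frozen=True)
class Utterance:
    """A label together with its literal meaning (set of true world counts)."""

    label: str
    meaning: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "meaning", frozenset(int(w) for w in self.meaning))
        if not self.meaning:
            raise ValueError(f"utterance {self.label!r} has empty meaning")
        if any(w < 0 for w in self.meaning):
            raise ValueError(f"utterance {self.label!r} has negative world counts")


@dataclass(frozen=True)
class AlternativeSet:
    """An ordered inventory of utterances the speaker chooses among."""

    utterances: tuple
    tag: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "utterances", tuple(self.utterances))
        labels = [u.label for u in self.utterances]
        if len(set(labels)) != len(labels):
            raise ValueError("alternative set has duplicate utterance labels")

    def __iter__(self):
        return iter(self.utterances)

    def __len__(self) -> int:
        return len(self.utterances)

    def __getitem__(self, label: str) -> Utterance:
        for u in self.utterances:
            if u.label == label:
                return u
        raise KeyError(label)

    def __contains__(self, label: str) -> bool:
        return any(u.label == label for u in self.utterances)


def core_alternatives(n: int) -> AlternativeSet:
    """The quantifier inventory {none, some, all} for a scenario of size N."""
    return AlternativeSet(
        (
            Utterance("none", frozenset({0})),
            Utterance("some", frozenset(range(1, n + 1))),
            Utterance("all", frozenset({n})),
        ),
        tag="no_numerals",
    )


def numeral_alternatives(n: int) -> AlternativeSet:
    """{none, some, all} plus lower-bounded numerals one..N ("two" = ≥ 2)."""
    base = core_alternatives(n)
    numerals = tuple(
        Utterance(_numeral_word(k), frozenset(range(k, n + 1)))
        for k in range(1, n + 1)
    )
    return AlternativeSet(base.utterances + numerals, tag="with_numerals")


def _numeral_word(k: int) -> str:
    return _NUMERAL_WORDS[k] if k < len(_NUMERAL_WORDS) else str(k)


@dataclass(frozen=True)
class AlternativeMixture:
    """Listener's probability that the speaker uses the with-numerals set."""

    p_with_numerals: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_with_numerals <= 1.0:
            raise ValueError("p_with_numerals must lie in [0, 1]")


@dataclass(frozen=True)
class KnowledgeState:
    """What the speaker knows after examining ``access`` of the N objects.

    ``support`` lists the world counts consistent with observing
    ``observed`` property-bearing objects; ``belief`` is the posterior over
    those worlds given the prior and the sampling law.
    """

    access: int
    observed: int
    n: int
    support: tuple
    belief: tuple

    @property
    def full(self) -> bool:
        return self.access == self.n


@dataclass(frozen=True)
class ModelConfig:
    """Scenario parameters for condition-table prediction.

    alpha is the softmax rationality: 0 yields a speaker indifferent among
    assertable utterances, large values approach utility maximization.  The
    base recursion corresponds to alpha = 1.
    """

    n: int = 3
    prior: WorldPrior | None = None
    alpha: float = 1.0
    access_partial: int = 2
    access_full: int | None = None
    mixture: AlternativeMixture = field(default_factory=lambda: AlternativeMixture(0.0))

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("scenario size N must be >= 1")
        if self.prior is None:
            object.__setattr__(self, "prior", WorldPrior.uniform(self.n))
        if self.prior.n != self.n:
            raise ValueError("prior is defined over a different scenario size")
        if self.access_full is None:
            object.__setattr__(self, "access_full", self.n)
        if self.access_full != self.n:
            raise ValueError("full access must equal N")
        # N = 1 has no strictly partial access level; allow a = N there
        if self.n == 1:
            if self.access_partial != 1:
                raise ValueError("for N = 1 the only access level is 1")
        elif not 1 <= self.access_partial < self.access_full:
            raise ValueError("partial access must satisfy 1 <= a < N")
        if not (self.alpha >= 0 and math.isfinite(self.alpha)):
            raise ValueError("rationality alpha must be finite and >= 0")

    def to_dict(self) -> dict:
        return {
            "N": self.n,
            "prior": list(self.prior.weights),
            "alpha": self.alpha,
            "access_partial": self.access_partial,
            "access_full": self.access_full,
            "p_with_numerals": self.mixture.p_with_numerals,
        }


# ---------------------------------------------------------------------------
# the RSA ladder
# ---------------------------------------------------------------------------

def _log_literal_listener(u: Utterance, prior: WorldPrior) -> np.ndarray:
    logp = np.full(prior.n + 1, -np.inf)
    for w in u.meaning:
        if w <= prior.n and prior.weights[w] > 0:
            logp[w] = math.log(prior.weights[w])
    total = logsumexp(logp)
    if total == -np.inf:
        raise UninterpretableUtteranceError(
            f"utterance {u.label!r} is incompatible with the entire prior"
        )
    return logp - total


def literal_listener(u: Utterance, prior: WorldPrior) -> np.ndarray:
    """Posterior of the literal listener: prior restricted to ⟦u⟧, renormalized.

    Returns an array over world counts 0..N; zero outside the meaning.
    """
    return np.exp(_log_literal_listener(u, prior))


def speaker_utility(state: KnowledgeState, u: Utterance, prior: WorldPrior) -> float:
    """Expected log L0 of the speaker's believed worlds (nats).

    Returns ``-inf`` exactly when the utterance is false in some world the
    speaker assigns positive belief to — the utterance is not assertable.
    """
    log_l0 = _log_literal_listener(u, prior)
    total = 0.0
    for w, b in zip(state.support, state.belief):
        if b <= 0:
            continue
        if log_l0[w] == -np.inf:
            return -np.inf
        total += b * log_l0[w]
    return total


def speaker_distribution(
    state: KnowledgeState,
    alternatives: AlternativeSet,
    alpha: float,
    prior: WorldPrior,
) -> np.ndarray:
    """Softmax speaker: probabilities ∝ exp(alpha · U1) over the alternative set.

    Utterances with utility ``-inf`` receive probability 0 regardless of
    alpha (at alpha = 0 the speaker is uniform over the *assertable*
    utterances).  A mute state — no assertable alternative at all — is
    returned as an all-zero vector.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    utilities = np.array(
        [speaker_utility(state, u, prior) for u in alternatives], dtype=float
    )
    finite = np.isfinite(utilities)
    probs = np.zeros(len(alternatives))
    if not finite.any():
        return probs  # mute state
    logw = alpha * utilities[finite]
    probs[finite] = np.exp(logw - logsumexp(logw))
    return probs


def is_mute(speaker_probs: np.ndarray) -> bool:
    """True when a speaker_distribution output marks a mute knowledge state."""
    return not np.any(speaker_probs)


def observation_model(w: int, access: int, n: int) -> np.ndarray:
    """P(o | w, a): hypergeometric law for examining ``a`` of N objects.

    The examined objects are a uniformly random subset without replacement,
    so the number ``o`` of property-bearing objects among them follows
    Hypergeometric(N, w, a).  Returns an array over o = 0..access.
    """
    if not 0 <= w <= n:
        raise ValueError("world count w must lie in 0..N")
    if not 1 <= access <= n:
        raise ValueError("access a must lie in 1..N")
    o = np.arange(access + 1)
    return hypergeom.pmf(o, n, w, access)


def knowledge_state(
    access: int, observed: int, n: int, prior: WorldPrior
) -> KnowledgeState:
    """Bayesian knowledge state after observing ``o`` of ``a`` examined objects.

    Support is {o, ..., o + (N − a)} ∩ {0..N}; belief is the prior times the
    hypergeometric observation likelihood, renormalized.
    """
    if not 0 <= observed <= access:
        raise ValueError("observed count must lie in 0..access")
    if not 1 <= access <= n:
        raise ValueError("access must lie in 1..N")
    support = tuple(range(observed, min(observed + n - access, n) + 1))
    lik = np.array(
        [prior.weights[w] * observation_model(w, access, n)[observed] for w in support]
    )
    total = lik.sum()
    if total <= 0:
        raise ValueError(
            f"observation (a={access}, o={observed}) has zero probability "
            "under the prior"
        )
    return KnowledgeState(
        access=access,
        observed=observed,
        n=n,
        support=support,
        belief=tuple(lik / total),
    )


def pragmatic_listener(
    utterance_label: str,
    access: int,
    mixture: AlternativeMixture,
    config: ModelConfig,
) -> np.ndarray:
    """L1 posterior over world counts given an utterance and speaker access.

    Marginalizes over the speaker's possible observations o (weighted by the
    prior and the hypergeometric sampling law) and over the two alternative
    sets (weighted by the mixture).  Mute states contribute nothing.
    """
    prior = config.prior
    n = config.n
    sets = [
        (1.0 - mixture.p_with_numerals, core_alternatives(n)),
        (mixture.p_with_numerals, numeral_alternatives(n)),
    ]
    for p_a, alts in sets:
        if p_a > 0 and utterance_label not in alts:
            raise ValueError(
                f"utterance {utterance_label!r} missing from alternative set "
                f"{alts.tag!r} with positive mixture weight"
            )

    log_score = np.full(n + 1, -np.inf)
    for p_a, alts in sets:
        if p_a <= 0:
            continue
        idx = next(i for i, u in enumerate(alts) if u.label == utterance_label)
        for o in range(access + 1):
            try:
                state = knowledge_state(access, o, n, prior)
            except ValueError:
                continue  # observation unreachable under this prior
            s1 = speaker_distribution(state, alts, config.alpha, prior)[idx]
            if s1 <= 0:
                continue
            for w in range(n + 1):
                pw = prior.weights[w]
                if pw <= 0:
                    continue
                p_obs = observation_model(w, access, n)[o]
                if p_obs <= 0:
                    continue
                term = math.log(p_a) + math.log(pw) + math.log(p_obs) + math.log(s1)
                log_score[w] = np.logaddexp(log_score[w], term)

    total = logsumexp(log_score)
    if total == -np.inf:
        raise UnproducibleUtteranceError(
            f"no reachable knowledge state produces {utterance_label!r}"
        )
    return np.exp(log_score - total)


def prob_not_all(posterior: np.ndarray, n: int) -> float:
    """Probability that fewer than all N objects have the property."""
    return float(1.0 - posterior[n])


@dataclass(frozen=True)
class PredictionTable:
    """Pragmatic-listener "not all" probabilities for the 2×2 design cells.

    Keys are (knowledgeability, alternatives) with knowledgeability in
    {partial, full} and alternatives in {no_numerals, with_numerals}.
    """

    cells: dict
    config: ModelConfig

    def percent(self, knowledgeability: str, alternatives: str) -> float:
        return 100.0 * self.cells[(knowledgeability, alternatives)]

    @property
    def percent_rounded(self) -> dict:
        """Cells as whole percents, the convention used for table display."""
        return {
            f"{k}_{'with_num' if a == 'with_numerals' else 'no_num'}":
                int(round(100.0 * v))
            for (k, a), v in self.cells.items()
        }

    def knowledgeability_effect(self, alternatives: str) -> float:
        return (
            self.cells[("full", alternatives)] - self.cells[("partial", alternatives)]
        )

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "cells": {
                f"{k}_{'with_num' if a == 'with_numerals' else 'no_num'}": v
                for (k, a), v in self.cells.items()
            },
            "percent_rounded": self.percent_rounded,
        }


def predict_condition_table(config: ModelConfig) -> PredictionTable:
    """All four knowledgeability × alternatives cells of P(not all | "some").

    The alternatives factor pins the mixture at its extremes (0 = core set
    only, 1 = numerals certainly available); knowledgeability contrasts
    partial against full access.
    """
    cells = {}
    for know, access in (("partial", config.access_partial), ("full", config.access_full)):
        for alts, p in (("no_numerals", 0.0), ("with_numerals", 1.0)):
            post = pragmatic_listener(
                "some", access, AlternativeMixture(p), config
            )
            cells[(know, alts)] = prob_not_all(post, config.n)
    return PredictionTable(cells=cells, config=config)


def sweep(
    alphas,
    p_with_numerals_grid,
    config: ModelConfig | None = None,
):
    """Grid of partial/full "not all" probabilities over alpha and P(A).

    Returns a pandas DataFrame with one row per (alpha, p_with_numerals)
    grid point, in deterministic row order (alpha-major).
    """
    import pandas as pd

    if config is None:
        config = ModelConfig()
    alphas = list(alphas)
    p_with_numerals_grid = list(p_with_numerals_grid)
    if not alphas or not p_with_numerals_grid:
        raise ValueError("sweep grids must be nonempty")
    rows = []
    for alpha in alphas:
        cfg = replace(config, alpha=float(alpha))
        for p in p_with_numerals_grid:
            mix = AlternativeMixture(float(p))
            row = {"alpha": float(alpha), "p_with_numerals": float(p)}
            for know, access in (
                ("partial", cfg.access_partial),
                ("full", cfg.access_full),
            ):
                post = pragmatic_listener("some", access, mix, cfg)
                row[f"p_not_all_{know}"] = prob_not_all(post, cfg.n)
            rows.append(row)
    return pd.DataFrame(rows)
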