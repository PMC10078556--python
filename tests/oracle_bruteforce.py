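"""Brute-force enumeration oracle for the pragmatic-listener recursion.

Deliberately shares no code with the package: plain Python loops, explicit
subset enumeration for the observation law, and linear-space arithmetic
(products and divisions, no logs).  Used only to cross-check the log-space
implementation on small scenarios.
"""

import itertools
import math


def bf_meanings(n, with_numerals):
    """label -> set of true world counts, lower-bounded numerals."""
    meanings = {
        "none": {0},
        "some": set(range(1, n + 1)),
        "all": {n},
    }
    if with_numerals:
        words = ["zero", "one", "two", "three", "four", "five",
                 "six", "seven", "eight", "nine", "ten"]
        for k in range(1, n + 1):
            label = words[k] if k < len(words) else str(k)
            meanings[label] = set(range(k, n + 1))
    return meanings


def bf_observation(w, a, n):
    """P(o | w, a) by enumerating every a-subset of n labeled objects."""
    has_property = [i < w for i in range(n)]
    counts = {}
    total = 0
    for subset in itertools.combinations(range(n), a):
        o = sum(1 for i in subset if has_property[i])
        counts[o] = counts.get(o, 0) + 1
        total += 1
    return {o: c / total for o, c in counts.items()}


def bf_literal_listener(meaning, prior):
    """prior restricted to the meaning, renormalized; {} if empty overlap."""
    total = sum(prior[w] for w in meaning if 0 <= w < len(prior))
    if total == 0:
        return {}
    return {w: prior[w] / total for w in meaning if prior[w] > 0}


def bf_belief(a, o, n, prior):
    """Speaker's posterior over worlds after seeing o of a examined objects."""
    scores = {}
    for w in range(n + 1):
        p_obs = bf_observation(w, a, n).get(o, 0.0)
        if prior[w] > 0 and p_obs > 0:
            scores[w] = prior[w] * p_obs
    total = sum(scores.values())
    return {w: s / total for w, s in scores.items()} if total > 0 else {}


def bf_speaker(a, o, n, prior, alpha, with_numerals):
    """S1(u | state): weight(u) = prod_w L0(w|u)^(alpha * belief(w))."""
    belief = bf_belief(a, o, n, prior)
    if not belief:
        return None  # unreachable observation
    weights = {}
    for label, meaning in bf_meanings(n, with_numerals).items():
        l0 = bf_literal_listener(meaning, prior)
        weight = 1.0
        for w, b in belief.items():
            if w not in l0:
                weight = 0.0
                break
            weight *= math.pow(l0[w], alpha * b)
        weights[label] = weight
    total = sum(weights.values())
    if total == 0:
        return {}  # mute state
    return {label: wt / total for label, wt in weights.items()}


def bf_pragmatic_listener(label, a, n, prior, alpha, p_with_numerals):
    """L1(w | u) by direct triple enumeration; {} if u is never produced."""
    score = {w: 0.0 for w in range(n + 1)}
    for p_set, with_num in ((1.0 - p_with_numerals, False),
                            (p_with_numerals, True)):
        if p_set == 0.0:
            continue
        for o in range(a + 1):
            s1 = bf_speaker(a, o, n, prior, alpha, with_num)
            if s1 is None or not s1:
                continue
            p_u = s1.get(label, 0.0)
            if p_u == 0.0:
                continue
            for w in range(n + 1):
                p_obs = bf_observation(w, a, n).get(o, 0.0)
                score[w] += p_set * prior[w] * p_obs * p_u
    total = sum(score.values())
    if total == 0:
        return {}
    return {w: s / total for w, s in score.items()}
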