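# altrsa

Epistemic Rational Speech Acts (RSA) modeling of scalar implicature with
**uncertainty over the speaker's alternative utterances**, together with a
synthetic-experiment generator and an analysis pipeline for the 2×2
(knowledgeability × contextual-numerals) rating design used to test the
model.

## The problem

When a speaker says *"some of the letters have checks inside"*, listeners
often infer *not all* of them do — a scalar implicature.  Two contextual
factors modulate this inference:

1. **Speaker knowledge.** If the speaker has only examined 2 of the 3
   letters, "some" is weaker evidence against "all": the implicature is
   partly canceled.
2. **Available alternatives.** If the speaker habitually uses numerals
   ("2 of today's rooms…"), then saying "some" instead of "two" is itself
   informative, and the implicature strengthens — but only when the speaker
   has partial knowledge.

`altrsa` implements a pragmatic listener who reasons jointly about both.

## The model

Worlds are counts `w ∈ {0..N}` of property-bearing objects (`N = 3` by
default).  A literal listener restricts a world prior to the utterance's
literal meaning ⟦u⟧ (lower-bounded numerals: ⟦two⟧ = {2, 3}):

    L0(w | u) ∝ P(w) · 1[w ∈ ⟦u⟧]

A speaker who has examined `a` of the `N` objects and seen `o` with the
property holds a hypergeometric-Bayes posterior `P(w | s)` over worlds, and
chooses utterances by softmax over the expected informativity utility:

    U1(u | s)    = Σ_w P(w | s) · log L0(w | u)
    S1(u | s, A) ∝ exp(α · U1(u | s)),   u ∈ A

where `A` is the alternative set — either {none, some, all} or that set
plus the lower-bounded numerals {one..N} — and α ≥ 0 is the rationality.
The pragmatic listener inverts the speaker, marginalizing over what the
speaker may have observed and over which alternative set is in play:

    L1(w | u) ∝ Σ_A P(A) Σ_o P(w) · P(o | w, a) · S1(u | s(a, o), A)

The headline summary statistic is `P(not all | "some") = 1 − L1(N | "some")`
for the four knowledgeability (partial vs. full access) × alternatives
(without vs. with numerals) cells.

## Worked example

```
$ printf 'N: 3\nprior: uniform\nalpha: 3.0\n' > scenario.yaml
$ altrsa predict --config scenario.yaml --out pred.json
INFO altrsa: prediction cells (percent, rounded): {'partial_no_num': 62,
'partial_with_num': 80, 'full_no_num': 98, 'full_with_num': 98}
```

`pred.json` holds the exact probabilities:

```json
"cells": {
  "partial_no_num": 0.625,
  "partial_with_num": 0.7966101694915255,
  "full_no_num": 0.9824561403508771,
  "full_with_num": 0.9760387281022533
}
```

Reading the cells: a fully knowledgeable speaker who still says "some"
almost certainly did not see the all-world (both full cells ≈ 98%,
regardless of alternatives).  A partially knowledgeable speaker licenses a
much weaker implicature (62%), *unless* numerals were available — then
declining to say "two" raises the listener's confidence to 80%.  The
knowledgeability effect is therefore much larger without numerals
(0.982 − 0.625 = 0.357) than with them (0.976 − 0.797 = 0.179): a
knowledgeability × alternatives interaction.

The same pipeline simulates and analyzes a rating experiment (240
participants, 8 target + 24 exposure trials each, 0–100 ratings):

```
$ altrsa simulate --n 240 --seed 7 --out data.csv
$ altrsa analyze --data data.csv --seed 1 --out fit.json
```

which printed, for this seed,

```
estimates:  knowledgeability 13.18   exposure -0.34   interaction -5.18
95% CI:     [10.78, 15.59]           [-4.97, 4.50]    [-9.78, -0.52]
```

i.e., a strong knowledgeability main effect, no exposure main effect, and
a negative interaction (the knowledgeability effect shrinks when numerals
are in the context) — the qualitative signature the model predicts, here
recovered from the generator's default cell means.  `altrsa power` runs a
Monte-Carlo power analysis of the interaction test over a grid of sample
sizes, and `altrsa sweep` maps the predictions over α and the
alternative-set mixture weight P(A).

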