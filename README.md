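# meloinfo

Information dynamics of melodic corpora: nth-order Markov statistics of
relative-interval patterns, corpus-wide "familiar phrase" tracking, and
lifetime-period analysis of how a composer's statistical style changes.

## The problem

Statistical-learning accounts of music cognition model a listener (and,
symmetrically, a composer) as an agent that internalizes the transition
statistics of the music it is exposed to. Under that view a score corpus is
data about the composer's probabilistic model: how predictable the next
note is given its context, how uncertain melodic continuation is overall,
and how deep the sequential dependencies run. This package measures those
quantities across a corpus of symbolic scores and tests how they differ
between periods of a composer's lifetime — the design used for Beethoven's
32 piano sonatas, whose conventional early / middle / late split and
published inventory of ubiquitous interval patterns ship with the package.

## The model

For every movement, the highest sounding pitch at each onset forms the
melody line (grace notes excluded, tied/slurred repetitions counted once).
An order-*n* pattern spans *n*+2 consecutive notes, each note after the
first encoded as its signed semitone offset from the window's first note —
a key-invariant representation under which a descending scale run becomes,
e.g., `[-2,-3,-5,-7]`. From the resulting (context, next-offset) streams:

- **transitional probability** TP = P(e_{n+1} | e_n), the maximum-likelihood
  ratio count(context, next)/count(context);
- **information content** IC = −log₂ TP (bits), the surprisal of one
  transition;
- **conditional entropy** H(B|A) = −Σᵢ P(aᵢ) Σⱼ P(bⱼ|aᵢ) log₂ P(bⱼ|aᵢ)
  (bits), the model's residual uncertainty;
- **mutual information** MI = H(Y) − H(Y|X) (bits), the uncertainty
  reduction the context affords (orders ≥ 1).

"Familiar phrases" are the patterns occurring at least once in *every*
piece of the corpus; their per-piece TPs are movement-weighted averages.
Pieces are then the experimental units in a mixed ANOVA (within: Markov
order 0–3; between: lifetime period) with Greenhouse–Geisser correction
when sphericity fails, Bonferroni post-hocs, and a Pearson correlation of
familiar-phrase TP against entropy per order.

Because the real sonata corpus is external, the package includes a
first-class synthetic-corpus generator: per-piece transition tables drawn
from per-period Dirichlet parameters, planted familiar phrases with exact
target TPs, and controllable row entropy — so every pipeline stage is
testable against known ground truth.

## Worked example

```python
from meloinfo.pipeline import analyze_corpus
from meloinfo.simulate import beethoven_like, build_scenario

corpus = build_scenario(beethoven_like(seed=3, notes_per_movement=800))
result = analyze_corpus(corpus.movements, corpus.periods)
```

The scenario plants a late-period shift (familiar TP 0.6 → 0.3, flatter
transition rows). Printing the period main effects (`examples/05_lifetime_anova.py`):

```
familiar_tp  period effect: F(2,29) =   97.35, p = 1.36e-13, partial eta2 = 0.87 | early 0.437 vs late 0.358
entropy      period effect: F(2,29) =  109.67, p = 3.00e-14, partial eta2 = 0.88 | early 2.040 vs late 2.405
mi           period effect: F(2,29) =   74.39, p = 3.81e-12, partial eta2 = 0.84 | early 1.964 vs late 1.519
```

Familiar phrases are less probable and continuation is more uncertain in
the late period — exactly the planted structure — and the Bonferroni
post-hocs localize the difference to late vs the other periods while
early vs middle stays null (adjusted p = 1). The `examples/` directory has
one short script per capability (extraction, encoding, information
profiles, phrase mining, the ANOVA, parameter recovery).

A thin CLI mirrors the library: `meloinfo simulate | extract | encode |
stats | familiar | anova | run` (see `meloinfo --help`).

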