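# Methods

## Melody extraction

The unit of analysis is the movement-level melody line: the highest pitch
sounding at each onset. Extraction rules, in order:

1. grace notes are removed before anything else (they are ornaments outside
   the metrical grid and carry no duration);
2. at each distinct onset the maximum pitch across all staves and voices is
   kept — voice crossings are resolved by pitch, not voice identity,
   because "the highest pitch playable at a point in time" is a property of
   the sounding texture, not of any one voice;
3. a note repeating the previous line pitch is merged into it only when it
   is marked as a tie or slur *continuation*. Slurs across different
   pitches keep every note: merging them would delete melody tones, and
   legato scale runs must survive extraction. This is a deliberate reading
   of an ambiguous convention ("slurred pitches counted as one"); the
   conservative same-pitch-only merge changes nothing for melodies without
   repeated notes under slurs.

Onsets and durations are exact rationals in quarter-note units, so tuplets
compare exactly. Repeat and da-capo markings are not expanded: the score
is analyzed in notated order once, since no expansion convention is
implied by the data and expansion would double-weight repeated sections.

The MusicXML reader is intentionally minimal: score-partwise documents,
pitches/chords/rests, `divisions` changes, `backup`/`forward`, grace
marks, ties and slurs, and the compressed `.mxl` container. Everything the
extraction contract needs, nothing more; a plain-text one-pitch-per-token
format serves as the internal interchange and fixture format.

## Encoding

An order-n pattern covers n+2 consecutive notes. Notes 2…n+2 are encoded
as signed semitone offsets from the window's **first** note (not as
successive intervals): a five-note descent C–B♭–A–G–F is `[-2,-3,-5,-7]`.
The first `n` offsets are the context, the last is the predicted symbol.
The representation is invariant under transposition of the window, which
is the point: statistics describe interval shape independent of key.
Octave is preserved (−12 ≠ 0). Windows slide by one note and never cross
movement boundaries.

## Information measures

Transition probabilities are plain maximum-likelihood ratios with **no
smoothing**. This is deliberate: familiar phrases occur in every piece by
definition, so their TPs are never zero, and for everything else an
unobserved transition is reported as *absent* rather than as a
zero-probability event (IC would be infinite; it is signalled, never
returned as a number). All logarithms are base 2; results are bits.

Conditional entropy weights each context row by its empirical frequency
(0·log 0 := 0); at order 0 it reduces to the marginal entropy of the
offset alphabet. Mutual information is computed as H(Y) − H(Y|X); the
algebraically identical joint-sum form is kept as an independent oracle in
the tests, not collapsed into the implementation.

Movement-to-piece aggregation: each phrase's per-piece TP is the average
of its movement TPs weighted by the phrase's occurrence count in that
movement. Entropy and MI are computed from the piece-level *pooled*
counts, the count-level analogue of the same weighting — this keeps TP,
entropy, and MI on one table per piece, at the cost of assuming movements
are exchangeable samples of the piece's statistics.

## Familiar phrases

A phrase is familiar at order n if its (context, next) count is positive
in **every** piece — ubiquity at piece (sonata) level, so one occurrence
in any movement counts. The per-piece summary is the unweighted mean over
the familiar set of each phrase's weighted TP: phrases contribute equally,
weighting having already been applied inside each phrase.

The package ships the published 32-sonata inventory as a TSV fixture
(20 / 13 / 12 / 3 patterns at orders 0–3). The source analysis states 37
first-order phrases while listing 13; the fixture preserves the listed
patterns and surfaces the discrepancy as a validation note instead of
resolving it either way.

## Lifetime statistics

Pieces are the experimental units (n = 32 in the reference design; the
conventional period split early = 1–12, 19, 20; middle = 13–18, 21–27;
late = 28–32 is the default mapping). The design is a mixed ANOVA with
Markov order within (0–3; 1–3 for MI, which has no order-0 value) and
period between, run per measure. Sphericity of the within effect is tested
with Mauchly's W; when rejected at p < 0.05 the Greenhouse–Geisser ε
scales the within dfs (fractional dfs, corrected p). The correction is
applied to the within main effect only — the interaction is reported with
integer dfs. Effect sizes are partial η².

Post-hoc scheme (the conventional reading, since none is forced by the
design): pairwise two-sample t-tests on piece-level means — between-factor
comparisons average over orders; interaction follow-ups compare periods
within each order, Bonferroni-corrected over every pair tested in the
family (exact multiplication, capped at 1). Familiar-TP vs entropy
relations are two-sided Pearson correlations across pieces, per order,
α = 0.05.

The ANOVA itself is delegated to `pingouin.mixed_anova`; an explicit
sums-of-squares decomposition written independently in the test suite
checks F, dfs, and partial η² to 1e-8.

## Synthetic corpora

The generator emulates the statistical structure the analysis assumes,
not music. Tables are defined directly in the encoder's offset space:
contexts are cumulative sums of interval n-tuples over a fixed interval
alphabet (default {−3,−2,−1,1,2,3}), successors are `last offset +
interval`. That context space is closed under window rebasing, so chain
walks never leave the table and planted offset patterns map one-to-one
onto encoder outputs. Each context row is a symmetric Dirichlet draw;
the concentration parameter controls expected row entropy (small → peaked,
large → near-uniform, log₂ 6 ≈ 2.585 bits ceiling). Planted phrase entries
are overwritten to exact target TPs and the remaining mass renormalized.

Every **piece** draws its own table from its period's parameters. This
within-period variability is what gives the between-period F-test an
honest error term; a single shared table per period would make the null
scenario miscalibrated. Each planted phrase is additionally spliced once
into the piece's first movement (insertion points indexed into the
original melody so runs cannot break each other), guaranteeing ubiquity
even in very short corpora. Absolute pitch is anchored at middle C and is
cosmetic — encoding removes it.

Default scenario ("beethoven-like"): 14/13/5 pieces in early/middle/late,
3 movements per piece, 2000 notes per movement, order-2 generator; planted
familiar TP 0.6/0.6/0.3 and concentration 0.5/0.5/5.0, i.e. the late
period avoids familiar phrases and spreads its transition mass. The
planted order-2 and order-3 patterns are the published descent patterns,
which chain under rebasing (each pattern's rebased context is another's
context), so familiar structure propagates to neighboring orders the way
scale runs do in real music. The null scenario is identical with all
periods at early-period parameters.

What the generator does **not** emulate: rhythm, phrase boundaries, meter,
harmony, voice leading, or any key-dependent structure. Passing tests
therefore show that the pipeline measures what it claims on data matching
its model assumptions — they do not validate musicological conclusions
about real corpora.

## Problem sizes and numerical choices

- Parameter-recovery checks run the default 32 × 3 × 2000-note scenario:
  planted TPs are recovered within ±0.03 (period means) and row entropy
  within ±0.1 bits per piece (measured pooled entropy vs generator rows
  weighted by the empirically visited contexts, isolating row-estimation
  error).
- The power and calibration sweeps use 100 seeded corpora each with
  400-note movements — the package's chosen sweep size, large enough that
  the planted effect is unmistakable and the null rate is a meaningful
  binomial estimate.
- Estimator consistency is asserted in the context-frequency-weighted L1
  sense; rarely visited contexts are estimated to proportionally lower
  accuracy, which no estimator avoids.
- Probability rows are validated to sum to 1 within 1e-12; entropy and MI
  are clamped at 0 against −1e-16-scale float residue; degenerate requests
  (empty tables, zero-probability IC, zero-variance correlations, single
  periods) raise typed signals rather than returning numbers.

## Known limitations

- Ubiquity is exact (support = 100%); no frequent-pattern mining with
  thresholds below that.
- No smoothing or back-off: the statistics describe the corpus, they are
  not a predictive language model.
- The MusicXML reader does not interpret repeats, transposing instruments,
  or percussion notation; scores outside the piano-solo shape it targets
  should be converted to the plain-text format upstream.
- Mixed ANOVA assumes piece-level normality and between-group variance
  homogeneity; with 5 late-period pieces the late-group error estimate is
  coarse, exactly as in the reference design.
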