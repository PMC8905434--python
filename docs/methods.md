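# Methods

## Text model

Raw text is lowercased; diacritics are removed by canonical decomposition
followed by dropping combining marks (ë → e).  Every punctuation character is
a *sequence divider* — punctuation ends an input sequence rather than joining
one — with a single exception: an apostrophe flanked by word characters on
both sides (possessives, contractions) stays inside its word.  A leading
apostrophe therefore divides; this is the package's resolution of the tension
between "keep the possessive apostrophe" and "a word never starts with an
apostrophe", and it means clitics written with a leading apostrophe (Dutch
*'t*) lose it.  Hyphens are punctuation, so a hyphenated source token is
processed as multiple model words; when scoring against a reference that
counts it as one word, `fixation_link.align_reference_words` sums the model
words' counts onto the reference word.  Digits are kept as ordinary symbols.
Line breaks in display-formatted material always divide sequences (words on
different display lines are too far apart to be read as one unit).

Every sequence is rendered with a single space after every word, including
the last.  Spaces are boundary markers, never free-standing symbols: a unit
that ends at a word boundary owns the following space in its span and its
stored form, so word-final units (`"do "`) are distinct from word prefixes
(`"do"` inside `"down"`), and concatenating the tokens of any segmentation
reproduces the rendered sequence exactly, character by character.

## The LiB learner

The lexicon is an ordered list of unit types; rank encodes confidence that a
type is a cognitive unit.  No frequency counts are kept.

**Selection.** At each position the longest matching lexicon form is
provisionally selected (larger-first).  When at least two forms match, the
largest is evaluated counterfactually: both the largest and the
second-largest candidate are extended by plain greedy larger-first
segmentation until their token boundaries first reach a common character
offset (capped at the sequence end), and their token counts up to that
horizon are compared.  Strictly more tokens for the largest ⇒ it is marked
*Bad* and the runner-up is selected; ties or fewer tokens ⇒ *Good* and it is
kept.  The horizon choice is the package's own: beyond the resynchronization
offset both continuations are identical, so comparing further adds cost but
no information.  No nested counterfactuals are evaluated inside the
lookahead.  Out-of-lexicon symbols are emitted as singleton tokens.

**Memorizing.** After segmenting a sequence, each adjacent token pair is
concatenated and appended at the lowest rank with probability `p_memorize`
(default 0.1); novel symbols are always appended.  New types are usable
immediately (online learning).  Pairs never span sequence dividers.

**Re-ranking.** Verdicts collected during an epoch are applied in order
after the batch: a Good form at rank r moves to ceil(r·`promote_factor`)
(default 0.5), a Bad form to min(|L|, ceil(r·`demote_factor`)) (default
2.0), with the relative order of untouched entries preserved.
Multiplicative moves keep the front of the lexicon — where established units
live — stable, while junk drifts quickly to the tail.

**Forgetting.** After re-ranking, entries in the tail `probation_zone`
fraction of the lexicon (default 0.2) age by one epoch; an entry reaching
`probation_period` epochs (default 3) without a Good verdict is removed.  A
Good verdict cancels probation.  Two package choices: single-symbol types
are never removed, so the alphabet always remains segmentable; and an entry
protected by an old Good verdict re-enters a fresh probation if it stays in
the tail, rather than being immune forever.

**Training loop and stopping.** Each epoch samples a `batch_size` (default
200) batch of sequences with replacement, segments it with evaluation and
online memorizing, re-ranks, forgets, and records the batch's Shannon code
length under its empirical token frequencies, −Σ log2(f(token)/N).  Training
stops when this quantity has not reached a new minimum for `stop_patience`
(default 3) consecutive epochs, or at `max_epochs` (default 200, a safety
net).  In large-corpus mode batches are drawn without replacement from one
shuffled pass and training ends when the material is exhausted.  All
randomness flows from one seed through independent spawned streams (batch
sampling, pair sampling), so a run is exactly reproducible and two runs with
the same seed write byte-identical lexicon files.

`p_memorize`, the re-rank factors, the probation parameters, and the
stopping patience are free hyperparameters of this implementation, declared
as defaults rather than fitted; all are exposed on `LiBConfig`.

`max_unit_len` bounds a unit's *effective length* — characters including
internal spaces but excluding the trailing boundary space — and models a
perceptual-span-like limit.  The sweep utility retrains a fresh lexicon per
limit (rather than post-filtering one lexicon), the stronger reading of
"limiting the unit length in the model".

## The CBL comparator

CBL operates on words.  Counts of chunks and adjacent chunk pairs are
updated incrementally; when the backward transitional probability
count(left, right)/count(right) of the current pair exceeds the running
average of all BTPs evaluated so far, the pair becomes a new chunk that
replaces the pair in further processing (so chunks grow hierarchically).
The running average includes every evaluation event, repeated pairs
included; before the first evaluation it is undefined and the comparison is
treated as "not above" (a conservative cold start — the model has no
hyperparameters to tune).  Training is a single incremental pass by default
(`passes` is configurable).  At test time the inventory is frozen and
sequences are segmented by greedy left-to-right longest match over whole
words; the greedy order at test time is a package decision, as is the
single-pass default.  CBL never produces subword units.

## Linking segmentations to fixations

A unit's center is the middle character of its effective span for odd
lengths, or the boundary between the two middle characters for even lengths.
Each unit contributes exactly one first-pass fixation, credited to the word
containing its center, so predicted counts conserve the token count exactly.
When the center falls on an inter-word space or on a boundary straddling two
words, the fixation goes to the word contributing more characters to the
unit, ties broken toward the right-hand word (a forward-saccade bias).  This
tie-break is under-determined by the phenomenon being modeled and is flagged
as a deviation risk; it affects only units whose two halves split exactly at
a word boundary.

Observed unit lengths are inferred from counts alone: assuming each fixation
sits at the center of the unit it reveals, a sequence's mean unit length is
its rendered length divided by its total fixation count, and the corpus
value is the fixation-count-weighted mean over sequences (zero-fixation
sequences excluded).  A secondary estimator that reconstructs explicit unit
boundaries midway between consecutive inferred fixation positions is
provided (`infer_fixation_unit_lengths`) for comparison; the ratio is the
package's primary operationalization.

Perceptual-span asymmetry, refixation correction, and predictability effects
are deliberately not modeled: the prediction task is meant to evaluate
segmentations free of prior oculomotor knowledge.

## Evaluation

Labels are the distinct observed count values; per-label binary F1 is
averaged with weights equal to each label's true-instance count and reported
in percent to two decimals.  A label that is predicted but never observed
has weight zero and enters only as false positives on observed labels; under
this construction a label with TP+FP+FN = 0 cannot occur, and `binary_f1`
returns 0 for an all-zero triple by convention.  The 3-label (Skip = 0,
One = 1, More > 1) confusion matrix and marginal distributions accompany the
score.  Because Only-Length is stochastic, the evaluator reports the mean
weighted F1 over R shuffles (default R = 100) with its spread; R = 1
reproduces a single-shuffle protocol.

## Synthetic data

The generator emulates what the models assume about text: a fixed inventory
of chunk types — plain words, multiword collocations built from 2-3
inventory words, and composite words made of two subword pieces — sampled
i.i.d. with Zipfian weights (exponent s) into sequences of 4-12 chunks.
Defaults (40 words, 20 multiword chunks, 6 composites, s = 1, 2,000
sequences, 12-letter alphabet, word lengths 2-7) constitute the package's
study conditions for parameter recovery: multiword and composite chunks are
interleaved among the top Zipf ranks, the way frequent collocations sit at
the top of natural frequency spectra, so supra-word and subword structure is
learnable at this corpus size.  "Observed" fixation tables are generated
from the true segmentation by the same center rule the predictor uses, which
yields the closure property weighted_f1 = 100 exactly at zero noise; noise
perturbs each word's count by ±1 with the given probability (reflected at
zero so the nominal rate is exact).

What the generator does **not** emulate — and therefore what passing tests
cannot show: natural-language morphology and syntax (chunks are sampled
independently, with no sequential dependencies for CBL to exploit beyond
chunk identity), participant variability, re-reading, launch-site and
word-length effects on skipping, or any semantic modulation of fixations.
Scores on synthetic corpora validate the machinery, not the cognitive claim;
on this clean word-level-compositional data CBL can score above LiB even
though both beat the word-based baselines.

## Numerical and interface choices

- Encoding bits use exact log2 arithmetic on batch token counts; the
  plateau test uses a 1e-9 absolute tolerance against the running minimum.
- Re-rank moves are applied sequentially in verdict order within an epoch;
  whether re-ranking is immediate or batched is under-determined, and the
  batched reading was chosen.
- Lexicon files store one form per rank-ordered line with spaces shown as
  `␣` plus a config echo; segmentation files are pipe-delimited in the
  standard example style; fixation tables are four-column TSV.
- Seeds derived internally (per-limit sweep streams, Only-Length shuffle
  seeds) are reduced modulo 2^31.

## Known limitations

- The counterfactual compares only the top two candidates, as specified;
  a third, shorter candidate could in principle be better still.
- Greedy-plus-counterfactual segmentation does not guarantee the global
  minimum token count (an exact dynamic program would, but that is not the
  mechanism being modeled).
- The apostrophe rule trades Dutch leading-apostrophe clitics for the
  no-tagger constraint; see the text-model section.
- Absolute scores on real eye-tracking corpora depend on those corpora and
  are out of scope here; the package's numbers are all computed on its own
  synthetic study.
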