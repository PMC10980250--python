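# Methods

## The model

The package studies audio-visual spoken-word recognition (lip-reading) with
a two-layer lexical network, the **AV-net**:

* **Audio layer.** One node per phonological word-form, written in a
  case-sensitive, one-character-per-phoneme computer-readable alphabet
  (24 consonants, 15 vowels). An edge joins two word-forms at phoneme edit
  distance 1 — a single addition, deletion, or substitution (the classic
  one-phoneme neighbor metric; a word's degree here is its *neighborhood
  density*).
* **Visual layer.** Phonemes that look alike on the lips and jaw fall into
  one *viseme* class (9 consonant classes `b f T w r C s k n`, 4 vowel
  classes `e o a W`; the mapping is position-wise and idempotent on class
  representatives; note that `d` patterns with the palato-alveolars in
  class `C`, and both `i` and `I` sit in class `e`). Words whose viseme
  transcriptions coincide form a *lexical equivalence class* (LEC) and map
  to a single visual node. Visual edges join viseme strings of equal length
  differing in exactly one position (single-viseme substitution). A node's
  within-layer degree is its **LEC degree** — how many other LECs it can be
  confused with by one viseme.
* **Interlayer edges.** Each word connects to the viseme node of its own
  transcription; exactly one per word.

The **V-net** is the ablation that deletes the audio layer and the
interlayer edges, modelling a viewer with no access to the phonology of the
language being lip-read.

All edges are undirected and unweighted; node ids carry an `A`/`V` suffix so
word strings and viseme strings that collide remain distinct.

For an all-CVC lexicon every audio string has length 3 and only substitution
neighbors can occur; the builders nevertheless implement the general
one-edit rule on the audio layer (additions/deletions across lengths) and
reject unequal-length pairs on the visual layer, where the substitution
wording is the precise one.

## Diffusion of activation

Word identification is simulated as linear diffusion on the flat graph
(edge types ignored). Per synchronous step, a node keeps a fraction *r*
(retention) of its activation; of the remainder, a fraction 1 − *d* (decay)
is split equally among its neighbors; afterwards any node strictly below the
suppress threshold *s* is zeroed. Isolated nodes keep everything, so with
*d* = *s* = 0 total activation is conserved exactly and the process is
linear (superposition holds). Defaults, used everywhere: 20 units of seed
activation per stimulus node, *r* = 0.5, *d* = 0, *s* = 0, *T* = 5 steps
(activation is near its asymptote by then). There are no inhibitory links,
thresholds, or resting levels — this is diffusion in the physics sense, an
exploration of how network structure shapes function, not a process model
of lexical access.

The reference engine is the per-node synchronous update; a batched fast
path multiplies stacked seed vectors by the sparse one-step operator
M = r·I + (1 − r)(1 − d)·A·D⁻¹ (isolates mapped to themselves) and is
tested equal to the reference to 1e−10 against an independently built dense
matrix power. The fast path is used only when *s* = 0, where it is exact.

## Simulated identification conditions

Each stimulus word is presented in isolation (activation reset between
trials); the readout is the final activation of one node at *T* = 5, higher
meaning more accurate identification:

| condition | network | seeded (20 units each)  | readout |
|-----------|---------|-------------------------|---------|
| sim1      | AV-net  | word node + viseme node | word node |
| sim2      | AV-net  | word node               | word node |
| sim3      | AV-net  | viseme node             | word node |
| sim4_av   | AV-net  | viseme node             | viseme node |
| sim4_v    | V-net   | viseme node             | viseme node |

sim1/sim2/sim3 model audio-visual, audio-only, and visual-only
presentation; in sim3 the readout stays on the word node because the task
response is a word. The sim4 pair probes what access to phonology
contributes to purely visual identification. In sim1 both seeds receive the
full 20 units (total 40), and by linearity sim1 = sim2 + sim3 per word
exactly — the audio-visual "boost" is the sim3 term.

## Statistics

Group comparisons are pooled-variance Student t-tests (df = n₁ + n₂ − 2),
one-tailed with the a-priori direction easy > hard; the audio-visual boost
is a two-tailed paired t (df = n − 1). Correlations are Pearson
product-moment. Error-pattern tests are Pearson chi-squares with **no
continuity correction** (goodness of fit against equal expecteds, df = k − 1;
2×2 independence from margin expecteds, df = 1) — the uncorrected form is
what reproduces the published statistics from the published counts. No
multiple-testing correction is applied. Degenerate inputs (zero pooled
variance, zero-variance differences, constant correlates, empty margins)
raise rather than returning NaN.

## Error classification

For each stimulus and its modal (most frequent) incorrect response:
same-LEC ⇔ identical viseme strings; phonological neighbor ⇔ phoneme edit
distance 1; for different-LEC errors the unique single-viseme edit is
classified as addition / deletion / substitution with a position label
(onset = first symbol, final = last, vowel = interior; for CVC strings this
is exactly onset/medial-vowel/final), and anything involving more than one
viseme is "other". Addition/deletion positions are labelled by the position
of the inserted/removed viseme in the longer string. Responses outside the
lexicon are transcribed from their supplied phonemic form — human responses
are unconstrained. Ties in the modal response are resolved upstream by the
data supplier; the table format carries one response per stimulus.

## Synthetic study materials

The generators produce data with the structure the analyses assume, so the
whole pipeline runs without any external corpus:

* **Lexicon.** `n_words` (default 1,000) distinct CVC strings. Phoneme
  choice is Zipf-weighted (1/rank) over an English-like frequency ranking
  of the alphabet. This skew is load-bearing: it is what couples a word's
  neighborhood density to the size and degree of its LEC, as in real
  lexicons — with uniform phoneme use, density decouples from viseme-layer
  confusability and the easy/hard activation contrast collapses. Word
  frequency is log-normal (ln-mean 1.0, ln-sd 1.5, i.e. a median of ~2.7
  occurrences per million with a heavy tail); familiarity is uniform on
  [5, 7] (the "known word" range).
* **Easy/hard stimuli.** Easy candidates are the high-frequency,
  low-density corner of the lexicon; hard candidates the low-frequency,
  high-density corner. Pools start at the quartile cuts and relax in 0.05
  steps (never past the median) until `k_per_group` (default 38) pairs with
  *identical initial-consonant multisets* can be formed; within a pool the
  most extreme items are preferred, and selection is deterministic given
  the seed. The relaxation exists because strict quartile pools over a
  1,000-word lexicon often cannot supply 38 onset-matched pairs; it
  preserves the intent (extreme corners first) while making the selection
  well-defined at realistic sizes.
* **Visual-only behavior.** Per-word accuracy follows a logistic model,
  logit(p) = logit(p_base) + β_size·z(LEC size) + β_deg·z(LEC degree) with
  p_base = 0.15 (visual-only identification is hard; observed means land
  near the ~15%-correct regime) and negative slopes (−0.4, −0.6), observed
  as a binomial proportion over 20 simulated viewers. The modal error is
  drawn from the stimulus's own LEC with probability 0.35 (roughly the
  same-LEC share of published error tables), from anywhere in the lexicon
  with probability 0.15 (gross misperceptions, needed for the multi-viseme
  "other" category to exist at its observed ~1/6 share), and otherwise from
  LECs one viseme substitution away — always frequency-weighted, never the
  stimulus itself.

What the generator does **not** emulate: real phonotactics (strings are
position-independent draws), the correlation between word frequency and
phonological form, perceptual asymmetries between particular viseme pairs,
and response perseveration across viewers. Passing the end-to-end recovery
checks therefore shows that the pipeline is sensitive to the structural
relationships it claims to measure, not that the generator is a model of
human lip-reading.

## Design choices that were genuinely open

* The viseme map follows the published equivalence table verbatim even
  where phonetically surprising (`d` in class `C` while `t` is in class
  `s`); the duplicated first-vowel-class entry is read as the two codes
  `i` and `I`.
* Unknown phonemes are a hard validation error, never silently dropped —
  a silent gap would corrupt the LEC partition.
* The familiarity ≥ 5 filter is a loader-side selection rule, applied only
  when a familiarity column is present.
* Trials are independent (state reset between words); per-word readouts of
  ~0.2–1.6 units out of 20 seeded are only consistent with isolated trials.
* The V-net attenuation check asks for a smaller easy/hard effect size in
  the V-net than in the AV-net viseme readout (mean Cohen's d over seeds),
  not for a strict null: with the skewed generator the easy/hard groups
  still differ somewhat in LEC degree, which the V-net retains, so the
  ablation shrinks rather than erases the contrast.

## Problem sizes

Default analyses use a 1,000-word lexicon (~1,200 network nodes), 38 + 38
stimuli, and 5 diffusion steps; the multi-seed recovery checks use 20
replicate lexicons. These sizes keep every stage well-resolved (all
qualitative patterns are stable across seeds) while the full test suite and
analysis pipeline run in well under a minute.

## Known limitations

* The replication-scale quantities that depend on the exact published
  1,070-word lexicon and 76 stimuli (group means such as 1.49 vs 1.37
  units, the specific r values, the 195-node visual layer) are not
  reproducible from synthetic data; the pipeline reproduces the qualitative
  result set and the exactly-checkable worked examples and test statistics.
* Viseme-layer edges are substitution-only; for non-CVC lexicons the
  treatment of unequal-length viseme strings (no edge) is one defensible
  reading of the construction, not the only one.
* The suppress parameter is implemented (strict `<` threshold after each
  step) but all reported analyses use s = 0, where it is a no-op.
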