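# Methods

## Instrument model

A test instantiation is a seeded draw from a word-frequency corpus. The
filtered vocabulary is sorted by count (descending, alphabetical
tie-break for determinism) and cut into `n_tiers = 10` contiguous bands
whose sizes differ by at most one (earlier tiers absorb the remainder).
Per tier, 5 true words are sampled uniformly without replacement and 2
pseudowords are generated from distinct template words of the same tier;
templates are kept disjoint from the selected true words so a foil is
never visually paired with a presented word. The default design therefore
yields 50 true words + 20 pseudowords = 70 items, presented in a single
seeded global shuffle without tier labels.

Responses use a 4-level ordered scale (1 = never seen the word, 4 = sure
of its meaning). The master key is category 4 on every true word and 1 on
every pseudoword.

## Item weights

Word counts are log-transformed (natural log; the base is immaterial
after standardisation), z-scored over the **full filtered vocabulary**
(not the sampled items, so weights are stable across instantiations from
the same corpus), and passed through a logistic
`w = 1 / (1 + exp(-slope * (z - center)))` with defaults `slope = 1`,
`center = 0`, both config-exposed. This gives high-frequency words weight
near 1 and rare words weight near 0: failure to recognise a common word
is strong evidence of limited literacy, whereas rare words barely
discriminate. Each pseudoword receives the arithmetic mean of the
instrument's 50 pre-normalisation true-word weights; all 70 weights are
then jointly normalised to sum to 1. Averaging before joint normalisation
is a deliberate order-of-operations choice (the two orders give the same
normalised weights here, since normalisation is a single global
rescaling).

## Scoring

`kappa = 1 - q_o / q_e`, with

- `q_o = Σ_n u_n v(k_n, l_n)` — item-weighted observed disagreement;
- `q_e = Σ_i Σ_j p1(i) p2(j) v(i, j)` where `p1, p2` are the two raters'
  item-weighted marginal category distributions
  (`p1(i) = Σ_n u_n [k_n = i]`).

`v` is linear `|i - j|` by default (quadratic `(i - j)^2` optional); any
positive rescaling of `v` cancels in the ratio. At uniform item weights
the statistic reduces exactly to textbook weighted Cohen's kappa computed
from the 4×4 contingency table; the test suite asserts agreement with
scikit-learn's independent implementation to 1e-10 over 1,000 random
instances, and checks the marginal-product chance term against explicit
double summation over all 16 category pairs.

Numerical/degenerate choices:

- The raw kappa can be negative (anti-key responding); the reported
  literacy score is the raw value clamped to [0, 1], with both retained
  in the output so no information is discarded.
- `q_e = 0` occurs only when both raters are the same constant; agreement
  is then perfect and kappa is defined as 1 with a `degenerate` flag.
  `q_e = 0` with `q_o > 0` is impossible for symmetric `v` with zero
  diagonal and is guarded as an internal error.
- Item weights must be nonnegative and sum to 1 within 1e-9; sheets whose
  item ids do not exactly match the key are rejected rather than imputed,
  since no missing-data rule is part of the scoring model.

## Pseudoword generation

Lexicon words are segmented deterministically into per-syllable
(onset, nucleus, coda) triples: maximal runs of vowel letters (`aeiou`;
`y` acts as a vowel only in words containing no other vowel letter) form
the nuclei, word-initial consonants the first onset, medial consonant
clusters attach wholly to the following onset (maximal-onset convention),
and trailing consonants form the final coda. Concatenating any
segmentation reproduces the word (a property test over random strings).

Transition counts between consecutive non-empty elements across the
lexicon form a first-order chain. A pseudoword for a template is built by
a seeded random walk that fills the template's element slots with
same-role elements, requiring every adjacent pair to be an observed
transition, and rejecting candidates that equal the template, appear in
the lexicon, or fail to re-segment to the template's syllable pattern.
The search is capped (default 1,000 attempts); instrument assembly
retries failing templates against the remaining tier words. On a small
closed lexicon the outputs provably lie within the brute-force enumeration
of chain-consistent strings — note that very small lexicons can admit
*no* chain-consistent nonword, in which case generation correctly fails.

## Synthetic data

The vocabulary generator emulates the heavy-tailed frequency profile of a
natural corpus: counts follow `top_count · rank^(-s)` (default exponent
`s = 1`, `top_count = 10^7`, floored at 1) over unique pronounceable
strings of 1–3 consonant-vowel syllables drawn from fixed English-like
onset/nucleus/coda inventories. It reproduces the *shape* a tiered,
frequency-weighted instrument needs; it does not model morphology,
polysemy, part-of-speech mixtures, or the correlation between frequency
and word length found in real corpora, so passing tests demonstrate the
machinery, not lexical realism.

Respondents are simulated under a graded-response model: ability
`theta ~ N(0, 1)`; for a true word with difficulty `b` (the item's
standardised *negative* log frequency, so rare words are hard), latent
familiarity `x = a(theta - b) + e` with standard-logistic `e`, and the
response is 1 plus the number of thresholds `tau = (-1, 0, 1)` below `x`.
Pseudowords follow a false-alarm model: category 3 or 4 (equally likely)
with probability `pseudo_base · (1 - expit(pseudo_slope · theta))`
(defaults 0.3 and 1), else category 1 — false alarms vanish with ability,
the calibration logic of the Yes-No paradigm. Defaults `a = 1.5` and the
above are simulation fixtures chosen to give realistic ordinal response
spread; they are config-exposed and are **not** claims about human
respondents. Consequently any simulated reliability or validity
correlation (e.g. the ≈0.93 parallel-form r at defaults) characterises
the fixture, not people; only the experimental *designs* — disjoint
parallel forms with shared respondents, scores against a noisy external
criterion, ceiling-rate comparison — mirror field practice.

Experiment harnesses use `numpy.random.SeedSequence` spawning so every
stage (form building, ability draw, response noise, criterion noise) is
independently and reproducibly seeded from one master seed; correlation
CIs use the Fisher z-transform.

## Problem sizes

Default analyses use a 1,000-word synthetic corpus, 70-item instruments,
and 200 simulated respondents (1,000 sheets for the chance-correction
check); each runs in seconds on a laptop.

## Known limitations

- The syllabifier is a deterministic heuristic, not a dictionary-based
  one; unusual orthography (e.g. vowel-less loanwords) is skipped when
  building the chain and rejected as a template.
- Single-language (English-like orthography) only.
- No confidence intervals on individual kappa scores and no grade-level
  cutpoints; the score is a relative, corpus-anchored measure.
- Quality-control item count (default 3) and required answers are
  administrator-supplied; the package only applies the filter.
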