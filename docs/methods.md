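# Methods

## The model

`ndra` simulates response times and pronunciations in the reading aloud
task with a single lexical route built from two-layer discriminative
(Rescorla-Wagner) networks. There is no direct orthography-to-phonology
conversion rule system: non-words are read through the same lexical
architecture as words, via the co-activation of orthographically similar
lexemes.

Processing stages:

1. **Visual input.** Each letter has a complexity value: the square
   root of the summed city-block distance between its 20×20 binary
   bitmap and the bitmaps of all 26 letters. Word `Complexity` is the
   sum over letter tokens. Letters that look like many others (o, c)
   are cheap; distinctive letters (w, y) are expensive.
2. **Orthography → lexemes.** Cues are the word's letters plus its
   boundary-marked letter bigrams (`bear` → b, e, a, r, #b, be, ea, ar,
   r#; binary presence, set semantics). Outcomes are lexemes (uppercase
   word types). Association strengths are the equilibrium
   Rescorla-Wagner weights (below). The target's summed activation plus
   a back-off constant b = 0.01 is `ActLexeme`; for items without a
   lexeme, `ActLexeme` = b exactly. The `n_neighbors` = 20
   highest-activated other lexemes are the item's co-activated
   orthographic neighborhood; their raw activations (floored at 0) are
   the neighbor weights w_i.
3. **Lexemes → phonology.** Phonology is coded as two demi-syllables
   (onset+nucleus, nucleus+coda; the nucleus appears in both halves,
   `b8R` → b8, 8R). The network is trained in the perception direction
   (demi-syllable cues → lexeme outcomes), and production reads the
   transpose. Demi-syllable activation is
   `ActPhon_k = w_lex·a_t + Σ_i w_i·a_i + b`, with a_t the
   target-lexeme weight (omitted for non-words), a_i the neighbor
   weights, and w_lex = 4.7 the top-down advantage of the verified
   target lexeme. Selection difficulty is the Shannon entropy H over
   the two activations normalized to probabilities.
4. **Latency.** Multiplicative integration, then a linear map to ms:

       Act = Complexity^w1 · H^w5 / (ActLexeme^w2 · ActPhon1^w3 · ActPhon2^w4)
       RT  = w6 · Act + w7

   with (w1..w7) = (1.270, 0.200, 0.050, 0.098, 0.152, 0.055, 450).
   The division form makes lexical and phonological support
   facilitatory and visual complexity and selection uncertainty
   inhibitory; the back-off constant keeps every factor positive. All
   ten free parameters (w1..w7, w_lex, b, n_neighbors) live in
   `ModelParams` with these defaults.
5. **Pronunciation (checking mechanism).** For a word, only
   demi-syllables weighted by its own lexeme compete; the top
   word-initial and word-final units are articulated. For a non-word,
   word-initial candidates are voted on by lexemes sharing the
   orthographic onset + vowel (onset-only as fallback), word-final
   candidates by lexemes sharing the orthographic rhyme (coda-only as
   fallback); votes are weighted by each lexeme's orthographic
   activation. Nucleus disagreements between the winning halves are
   resolved in favour of the second demi-syllable's vowel (re-selecting
   or, if no candidate matches, synthesizing the first half — the
   synthesis is flagged in the result trace). Exact ties are re-voted
   by onset-only/coda-only sharing lexemes over the tied candidates,
   then broken lexicographically. Only attested demi-syllables can win
   a vote, so non-word pronunciations are recombinations of learned
   units.

An optional sub-lexical network (orthographic cues → demi-syllables)
provides `ActPhonSub_1`, `ActPhonSub_2` and `HSub` for dual-route
comparisons; these are reported alongside but never enter `Act`, since
adding them does not improve the lexical-route model.

## Equilibrium solver

Learning events pair a cue set with an outcome set, one event per word
type, weighted by token frequency. The asymptotic ("adult state")
weights solve, per outcome k,

    Pr(O_k | C_i) = Σ_j Pr(C_j | C_i) V_jk,

the normal equations of the frequency-weighted least-squares problem
over events. We solve the normalized Gram system G V = T through its
symmetric eigendecomposition, truncating eigenvalues below 1e-9 of the
largest. Design rationale:

* Lexical event tables are routinely rank-deficient (perfectly
  correlated cues). Among the solution manifold, the eigenvalue-
  truncated pseudo-inverse returns the minimum-norm solution, which is
  the fixed point gradient-flow learning reaches from zero initial
  weights — the answer the iterative delta rule itself would give.
* Cues that never co-occur with an outcome's cue cluster must carry
  zero weight (they were never informative about it). The cue
  co-occurrence matrix is block-diagonal over connected components, and
  eigenspace projectors preserve that structure, so this holds to
  numerical precision. Generic SVD least-squares routines do not
  guarantee this: their rank truncation can split a near-degenerate
  eigenvalue cluster across blocks and leak weight between unrelated
  cue clusters, which we observed as wrong-vowel pronunciations before
  adopting the eigendecomposition route.
* The iterative learner (`simulate_learning`) is retained as an
  independent slow-route oracle; with a constant learning rate its
  trajectory fluctuates around the fixed point, so comparisons use a
  tail (Polyak) average of the final trajectory segment, which
  estimates the same fixed point with lower variance than the final
  snapshot.

On full-rank systems the solver verifies the equilibrium residual to
1e-8 and raises otherwise.

## Glyph fixture

Letter bitmaps are packaged as text (one 20×20 bit block per letter),
rasterized once from a monospaced bitmap font and frozen, because live
font rendering is platform-dependent and would break bit-level
determinism of the complexity table. The loader verifies a SHA-256
checksum. Only ordering properties of the complexity values (e.g.
C(o) < C(w)) are meaningful; absolute values depend on the font.
`letter_complexity(use_sqrt=False)` gives the bare summed distance.

## Synthetic data

The generator (`fixtures`) emulates the structure of a monosyllabic
training lexicon without external resources: entries are built from
paired orthographic/DISC onset, nucleus and coda inventories, so
orthography and phonology are jointly plausible; words cluster into
body families sharing vowel + coda; token frequencies are Zipf
(exponent 1.0, maximum 100,000, floored at 1); a configurable fraction
of bodies is inconsistent, assigning an alternative nucleus
pronunciation to a frequency-weighted half of the family. Non-words
recombine attested onsets with attested bodies, constrained so both
candidate demi-syllables are attested.

What the generator does **not** emulate: English letter and phoneme
statistics, polysyllables, morphology, length variation beyond the
inventories, homophony rates, and the 10^5-word scale of real training
corpora. Passing tests therefore demonstrate the mechanisms of the
architecture — cue competition, neighbor co-activation, frequency
weighting — at desk scale, not quantitative fits to human data.

### Factorial design fixtures

Two matched factorial designs probe directional effects. Both went
through the same design discipline an experimenter would apply —
isolate the manipulated variable, match everything else:

* **Matched rime sharing.** A target whose phonological rime is rare
  gets concentrated equilibrium credit (a large target term and low H),
  which at small scale swamps the neighbor channel. Both designs
  therefore hold each target's rime-sharer count constant across cells,
  using homophone spellings (a 'y' nucleus plus variant codas drawn
  from letters the normal codas never use) that share the rime without
  sharing orthography.
* **Background vocabulary.** In a large lexicon every bigram is shared
  by many words, so lexeme self-activation is comparably diluted for
  everyone; a design-only lexicon concentrates cue ownership. A
  background vocabulary shares the designs' onset, nucleus-transition
  and coda bigrams (never a design rime) to globalize cue sharing.
* **Low-frequency targets** (frequency 50, matched across cells).
  Neighborhood and consistency effects are carried by neighbor
  co-activation relative to the target's own support and are strongest
  for low-frequency words, experimentally and in this architecture;
  for high-frequency targets at desk scale the self-activation and
  entropy channels dominate and the contrasts shrink toward zero.

The neighborhood design contrasts 6 vs 0 orthographic body sharers; the
consistency design contrasts all-friend vs all-enemy (exception word)
body families of equal size. The non-word frequency design retrains the
network with non-words added to the lexicon at two frequency tiers
(20,000 vs 20), pronouncing each non-word with the base model to supply
its phonology.

## Numerical and procedural choices

* Activations entering H and the latency formula are floored at b
  (equilibrium weights can be negative); neighbor weights are floored
  at 0 and carry no back-off.
* Ties anywhere in pronunciation are resolved deterministically
  (coarser orthographic vote, then lexicographic order); identical
  inputs give identical outputs, including traces.
* Demi-syllable splitting requires exactly one nucleus run; an
  onset-less or coda-less syllable yields a bare-nucleus half. The DISC
  nucleus inventory is an editable package data table
  (`data/disc_nuclei.tsv`); syllabic consonants are excluded by
  default. Orthographic 'y' counts as a vowel letter only when no
  other vowel letter is present.
* Lexemes are identified with uppercase orthography, so homographs
  collapse — acceptable for monomorphemic monosyllables.
* For items without a lexeme, the demi-syllable pair entering the
  latency computation is the pair selected by the checking mechanism
  (the pronounced pair), not a canonical transcription.
* Standardization uses the sample (n−1) standard deviation; principal
  components fix their sign by making the largest-magnitude loading
  positive; model evaluation transforms latencies by −1000/RT before
  z-scoring.
* Problem sizes in the test and acceptance runs: lexica of 300-500
  words for pronunciation and round-trip checks, 400 words + 200
  non-words for the word/non-word contrast, 100 targets per cell
  (≈2,100-word lexica including fixtures and background) for the
  factorial designs, 50 random event tables for the equilibrium
  residual and 8-20 for the iterative-oracle comparison.

## Known limitations

* The checking mechanism can only output attested demi-syllables;
  pronunciations requiring novel units fail explicitly rather than
  being patched.
* Equilibrium weights assume a stationary adult state; no
  developmental trajectory or time-varying salience is modeled.
* The visual front end is a letter-prototypicality proxy, not a model
  of early vision; complexity is independent of retinal position,
  crowding and familiarity.
* Effect magnitudes at desk scale are not comparable to full-scale
  training; only signs and mechanism-level properties are asserted.
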