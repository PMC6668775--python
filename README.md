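# ndra

A single-route discriminative-learning simulator of reading aloud.
`ndra` models response times and pronunciations for printed words *and*
non-words with one lexical architecture: equilibrium Rescorla-Wagner
networks map letters and letter bigrams onto lexemes, and lexemes onto
demi-syllables, with no separate grapheme-to-phoneme conversion route.
It is aimed at psycholinguists studying visual word recognition and
speech production who want an interpretable, parameter-sparse
alternative to dual-route architectures.

## The model in brief

For an item the simulator computes five bottom-up support measures and
integrates them into simulated naming latencies:

* `Complexity` — summed visual complexity of the letters, where a
  letter's complexity is √(Σ city-block distance of its 20×20 bitmap to
  all 26 letters);
* `ActLexeme` — activation of the item's lexeme, a_k = Σ_{j∈cues} V_jk
  plus a back-off b = 0.01 (exactly b for items without a lexeme);
* `ActPhon_1`, `ActPhon_2` — activations of its two demi-syllables
  (onset+nucleus, nucleus+coda; DISC notation, nucleus repeated):
  ActPhon_k = w_lex·a_t + Σ_i w_i·a_i + b, combining the target lexeme
  (w_lex = 4.7) with the 20 most co-activated orthographic neighbors;
* `H` — Shannon entropy over the two demi-syllable activations
  (response-selection uncertainty);

combined multiplicatively and mapped linearly to milliseconds:

    Act = Complexity^1.270 · H^0.152 / (ActLexeme^0.200 · ActPhon_1^0.050 · ActPhon_2^0.098)
    RT  = 0.055 · Act + 450

Association strengths V are the parameter-free equilibrium solution of
the Rescorla-Wagner learning rule over frequency-weighted events,
Pr(O_k|C_i) = Σ_j Pr(C_j|C_i)·V_jk. A top-down checking mechanism turns
activations into pronunciations: for words only the target lexeme's
demi-syllables compete; for non-words, demi-syllables are elected by
activation-weighted votes of lexemes sharing the orthographic
onset+vowel (first half) or rhyme (second half). See
[docs/methods.md](docs/methods.md) for the full account.

## Worked example

The package ships a synthetic-lexicon generator, so nothing needs to be
downloaded. Build a 200-word lexicon with 50 matched non-words, train
the networks, and simulate a mixed item list:

```sh
ndra fixtures --seed 42 --n-words 200 --n-bodies 40 --out lex.tsv \
              --nonwords 50 --nonwords-out nw.txt
ndra train --lexicon lex.tsv --out model/
ndra simulate --model model/ --items items.txt --out profiles.tsv
ndra pronounce --model model/ --items items.txt --out pron.tsv
```

With `items.txt` holding three non-words and three words, the profile
table reads:

```
  item  is_nonword  Complexity  ActLexeme  ActPhon1  ActPhon2     H      RT
 blain        True     176.806      0.010     0.185     0.353 0.928 567.685
 blesk        True     177.600      0.010     0.378     0.216 0.946 570.172
bloast        True     208.803      0.010     0.365     0.180 0.916 599.747
braift       False     212.716      0.374     4.333     0.387 0.409 503.896
flaift       False     214.847      0.528     2.131     1.049 0.915 504.121
traift       False     212.070      0.572     4.401     0.319 0.357 499.199
```

Words are named faster than non-words (≈500 vs ≈570 ms) because their
lexemes are activated (ActLexeme ≫ b) and their own lexeme feeds the
demi-syllables (large ActPhon_1). The pronunciation table shows the
checking mechanism assembling each item from one word-initial and one
word-final demi-syllable — via the target lexeme for words, via
orthographic neighbors for non-words:

```
  item first second assembled             route
 blain   bl1     1n      bl1n nonword-neighbors
 blesk   blE    Esk     blEsk nonword-neighbors
bloast   bl5    5st     bl5st nonword-neighbors
braift   br1    1ft     br1ft       word-target
flaift   fl1    1ft     fl1ft       word-target
traift   tr1    1ft     tr1ft       word-target
```

All words are pronounced exactly as transcribed in the lexicon, and the
non-word pronunciations recombine attested demi-syllables.

The same functionality is available as a library
(`ndra.train_model`, `ndra.batch_simulate`, `ndra.pronounce`, ...); an
`ndra evaluate` command correlates simulated with observed latencies
(−1000/RT transform, z-scoring, standardized effect sizes).

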