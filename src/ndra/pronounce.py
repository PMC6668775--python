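"""Top-down checking mechanism: turning activations into pronunciations.

The discriminative core produces graded activations over demi-syllables;
actual articulation requires picking exactly one word-initial and one
word-final demi-syllable.  The checking mechanism filters which lexemes
may contribute:

* For a word, only the target lexeme votes: each candidate demi-syllable
  is scored by its production-direction weight from the target lexeme.
* For a non-word, the lexemes sharing the orthographic onset + vowel
  with the input vote for the first demi-syllable, and those sharing the
  orthographic rhyme vote for the second, each weighted by its own
  orthographic activation.

Vowel conflicts between the winning halves are resolved in favour of the
second demi-syllable's nucleus; exact ties are re-voted by onset-only
(or coda-only) sharing lexemes, with lexicographic order as the final,
deterministic tie-break.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from ndra.lexicon import demi_parts, orthographic_parts
from ndra.networks import TrainedModel

_REL_TOL = 1e-9
_ABS_TOL = 1e-12


class PronunciationError(RuntimeError):
    """Raised when no pronounceable candidate survives the checking stages."""


@dataclass
class PronunciationResult:
    """Selected demi-syllables, the assembled DISC string, and a trace."""

    item: str
    first: str
    second: str
    assembled: str
    route: str  # word-target | nonword-neighbors | fallback-onset | fallback-coda
    trace: list[str] = field(default_factory=list)


def assemble(first: str, second: str) -> str:
    """Join two demi-syllables into a DISC string (nucleus spelled once)."""
    _, n1, coda1 = demi_parts(first)
    if coda1:
        raise ValueError(f"{first!r} is not a word-initial demi-syllable")
    onset2, n2, _ = demi_parts(second)
    if onset2:
        raise ValueError(f"{second!r} is not a word-final demi-syllable")
    if n1 != n2:
        raise ValueError(f"nucleus mismatch: {first!r} vs {second!r}")
    return first + second[len(n2):]


def _ties(scores: dict[str, float]) -> list[str]:
    """Candidates within floating-point tolerance of the best score."""
    best = max(scores.values())
    return sorted(
        d
        for d, s in scores.items()
        if math.isclose(s, best, rel_tol=_REL_TOL, abs_tol=_ABS_TOL)
    )


def _vote(model: TrainedModel, demis, lexeme_weights: dict[str, float]) -> dict[str, float]:
    """Activation-weighted vote of a lexeme set over candidate demi-syllables."""
    return {
        d: sum(w * model.lexeme_to_demi(d, lex) for lex, w in lexeme_weights.items())
        for d in demis
    }


def _positive_candidates(model: TrainedModel, demis, lexemes) -> set[str]:
    """Demi-syllables receiving positive weight from at least one lexeme."""
    return {
        d
        for d in demis
        if any(model.lexeme_to_demi(d, lex) > 0 for lex in lexemes)
    }


def tie_fallback(
    model: TrainedModel,
    orthography: str,
    tied: list[str],
    position: str,
    lexeme_activations: dict[str, float],
) -> str:
    """Resolve an exact tie by a coarser orthographic vote.

    The re-vote uses lexemes sharing only the orthographic onset (first
    position) or only the orthographic coda (second position) with the
    item, cast over the demi-syllables involved in the tie (every tied
    candidate shares its phonological coda with a tied candidate, so
    the coda filter keeps the tied set).  A residual tie falls back to
    lexicographic order.
    """
    if len(tied) == 1:
        return tied[0]
    onset, _, coda = orthographic_parts(orthography)
    part_index = 0 if position == "first" else 2
    shared = onset if position == "first" else coda
    sharers = {
        e.lexeme: lexeme_activations.get(e.lexeme, 0.0)
        for e in model.lexicon
        if (model.include_nonwords or not e.is_nonword)
        and orthographic_parts(e.orthography)[part_index] == shared
    }
    tied_codas = {demi_parts(d)[2] for d in tied}
    pool = [d for d in tied if demi_parts(d)[2] in tied_codas]
    if not sharers or not pool:
        return tied[0]
    scores = _vote(model, pool, sharers)
    return _ties(scores)[0]


def resolve_vowel_conflict(
    first_scores: dict[str, float], first: str, second: str
) -> tuple[str, bool]:
    """Force nucleus agreement, preferring the second demi-syllable's vowel.

    Re-selects the highest-scoring word-initial candidate whose nucleus
    matches the second demi-syllable's; if none exists, a demi-syllable
    is synthesized from the winning onset plus the second's nucleus.
    Returns (first demi, synthesized?).
    """
    n1 = demi_parts(first)[1]
    n2 = demi_parts(second)[1]
    if n1 == n2:
        return first, False
    matching = {
        d: s for d, s in first_scores.items() if demi_parts(d)[1] == n2
    }
    if matching:
        return _ties(matching)[0], False
    onset = demi_parts(first)[0]
    return onset + n2, True


def _select(
    model: TrainedModel,
    orthography: str,
    scores: dict[str, float],
    position: str,
    lexeme_activations: dict[str, float],
    trace: list[str],
) -> tuple[str, dict[str, float]]:
    positive = {d: s for d, s in scores.items() if s > 0}
    if not positive:
        raise PronunciationError(
            f"{orthography!r}: no positively activated {position} demi-syllable"
        )
    tied = _ties(positive)
    if len(tied) > 1:
        trace.append(f"{position}: tie among {tied}")
        winner = tie_fallback(model, orthography, tied, position, lexeme_activations)
        trace.append(f"{position}: tie resolved to {winner}")
    else:
        winner = tied[0]
    return winner, positive


def pronounce_word(
    model: TrainedModel, word: str, params=None
) -> PronunciationResult:
    """Pronounce a word via its own lexeme's demi-syllable weights.

    Only demi-syllables activated by the target lexeme are considered:
    the first demi-syllable is the most strongly connected word-initial
    unit, the second the most strongly connected word-final unit.
    """
    from ndra.simulate import ModelParams, lexeme_activations as _lex_acts

    params = params or ModelParams()
    entry = model.entry(word)
    if entry is None:
        raise PronunciationError(f"{word!r} has no lexeme in the model")
    lexeme = entry.lexeme
    acts, _ = _lex_acts(model, word, params)
    act_map = {lex: max(float(a), 0.0) for lex, a in acts.items()}
    trace: list[str] = []
    first_scores = {
        d: model.lexeme_to_demi(d, lexeme) for d in model.initial_demis
    }
    second_scores = {
        d: model.lexeme_to_demi(d, lexeme) for d in model.final_demis
    }
    first, first_pos = _select(model, word, first_scores, "first", act_map, trace)
    second, _ = _select(model, word, second_scores, "second", act_map, trace)
    first, synthesized = resolve_vowel_conflict(first_pos, first, second)
    if synthesized:
        trace.append(f"first: synthesized {first} for vowel agreement")
    return PronunciationResult(
        item=word,
        first=first,
        second=second,
        assembled=assemble(first, second),
        route="word-target",
        trace=trace,
    )


def _nonword_candidate_lexemes(
    model: TrainedModel, orthography: str, position: str
) -> tuple[list, str]:
    """Lexemes orthographically licensed to vote, plus the route taken.

    First position: lexemes sharing the orthographic onset + vowel; if
    none exist, fall back to onset-only sharing.  Second position:
    lexemes sharing the orthographic rhyme (vowel + coda); fallback is
    coda-only sharing.
    """
    onset, vowel, coda = orthographic_parts(orthography)
    entries = [
        e for e in model.lexicon if model.include_nonwords or not e.is_nonword
    ]

    def parts(e):
        return orthographic_parts(e.orthography)

    if position == "first":
        strict = [e for e in entries if parts(e)[0] == onset and parts(e)[1] == vowel]
        if strict:
            return strict, "nonword-neighbors"
        return [e for e in entries if parts(e)[0] == onset], "fallback-onset"
    strict = [e for e in entries if parts(e)[1] == vowel and parts(e)[2] == coda]
    if strict:
        return strict, "nonword-neighbors"
    return [e for e in entries if parts(e)[2] == coda], "fallback-coda"


def pronounce_nonword(
    model: TrainedModel, orthography: str, params=None
) -> PronunciationResult:
    """Pronounce a non-word by activation-weighted votes of neighbors.

    Word-initial candidates are the demi-syllables positively activated
    by lexemes sharing the orthographic onset + vowel with the input;
    word-final candidates come from rhyme-sharing lexemes.  Each lexeme's
    vote is weighted by the activation it receives from the non-word's
    orthographic cues, so only attested demi-syllables can be produced.
    """
    from ndra.simulate import ModelParams, lexeme_activations as _lex_acts

    params = params or ModelParams()
    acts, _ = _lex_acts(model, orthography, params)
    act_map = {lex: max(float(a), 0.0) for lex, a in acts.items()}
    trace: list[str] = []
    route = "nonword-neighbors"

    selections: dict[str, str] = {}
    positives: dict[str, dict[str, float]] = {}
    for position, pool in (
        ("first", model.initial_demis),
        ("second", model.final_demis),
    ):
        lexemes, pos_route = _nonword_candidate_lexemes(model, orthography, position)
        if pos_route != "nonword-neighbors":
            route = pos_route
            trace.append(f"{position}: {pos_route} (no strict orthographic match)")
        if not lexemes:
            raise PronunciationError(
                f"{orthography!r}: no candidate lexemes for {position} demi-syllable"
            )
        weights = {e.lexeme: act_map.get(e.lexeme, 0.0) for e in lexemes}
        candidates = _positive_candidates(model, pool, weights)
        if not candidates:
            raise PronunciationError(
                f"{orthography!r}: empty candidate set for {position} demi-syllable"
            )
        scores = _vote(model, candidates, weights)
        if all(s <= 0 for s in scores.values()):
            # zero-activation voters: treat every candidate as tied
            tied = sorted(candidates)
            trace.append(f"{position}: zero-weight vote, tie among {tied}")
            winner = tie_fallback(model, orthography, tied, position, act_map)
            positives[position] = dict.fromkeys(candidates, 0.0)
        else:
            winner, positives[position] = _select(
                model, orthography, scores, position, act_map, trace
            )
        selections[position] = winner

    first, second = selections["first"], selections["second"]
    first, synthesized = resolve_vowel_conflict(positives["first"], first, second)
    if synthesized:
        trace.append(f"first: synthesized {first} for vowel agreement")
    return PronunciationResult(
        item=orthography,
        first=first,
        second=second,
        assembled=assemble(first, second),
        route=route,
        trace=trace,
    )


def pronounce(model: TrainedModel, item: str, params=None) -> PronunciationResult:
    """Pronounce ``item`` as a word if it has a lexeme, else as a non-word."""
    if model.entry(item) is not None:
        return pronounce_word(model, item, params)
    return pronounce_nonword(model, item, params)
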