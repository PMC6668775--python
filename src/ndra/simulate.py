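"""Per-item activation profiles and simulated naming latencies.

For an item the model computes five bottom-up support measures —
visual Complexity, the activation of the item's lexeme (ActLexeme), the
activations of its first and second demi-syllable (ActPhon_1, ActPhon_2)
and the Shannon entropy H over the two demi-syllable activations — and
integrates them multiplicatively into total activation units::

    Act = Complexity^w1 * H^w5 / (ActLexeme^w2 * ActPhon1^w3 * ActPhon2^w4)

which a linear transform maps to milliseconds: RT = w6 * Act + w7.
Visual complexity and selection uncertainty slow naming; lexical and
phonological support speed it up.  Non-words have no lexeme, so their
ActLexeme is exactly the back-off constant, and the target-lexeme term
is dropped from their demi-syllable activations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from ndra.networks import TrainedModel
from ndra.rw_core import activation as _activation
from ndra.visual import default_complexity_table, word_complexity
from ndra.lexicon import extract_cues, split_demisyllables


@dataclass(frozen=True)
class ModelParams:
    """The model's 10 free parameters.

    w1..w5 are the integration exponents for Complexity, ActLexeme,
    ActPhon_1, ActPhon_2 and H; w6 (slope) and w7 (intercept, ms) map
    activation units to latencies; w_lex weights the target lexeme's
    contribution to demi-syllable activation against that of co-activated
    neighbors; b is the additive back-off; n_neighbors the number of
    co-activated orthographic neighbors taken into account.
    """

    w1: float = 1.270
    w2: float = 0.200
    w3: float = 0.050
    w4: float = 0.098
    w5: float = 0.152
    w6: float = 0.055
    w7: float = 450.0
    w_lex: float = 4.700
    b: float = 0.01
    n_neighbors: int = 20

    def __post_init__(self) -> None:
        for name in ("w1", "w2", "w3", "w4", "w5", "w6", "w7", "w_lex", "b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")


def lexeme_activations(
    model: TrainedModel, orthography: str, params: ModelParams = ModelParams()
) -> tuple[pd.Series, float]:
    """All lexeme activations for an orthographic input, plus ActLexeme.

    ActLexeme is the target lexeme's activation (back-off included) when
    the item has a lexeme in the model; items without a lexical
    representation get exactly the back-off constant.
    """
    acts = _activation(model.o2l, extract_cues(orthography), backoff=params.b)
    lexeme = orthography.upper()
    if model.has_lexeme(lexeme) and lexeme in acts.index:
        act_lexeme = float(acts[lexeme])
    else:
        act_lexeme = params.b
    return acts, act_lexeme


def top_neighbors(
    acts: pd.Series, target_lexeme: str | None, n: int = 20
) -> list[tuple[str, float]]:
    """The n highest-activated lexemes excluding the target.

    Neighbor weights are the raw orthographic activations floored at
    zero (no back-off).  Ties are broken lexicographically so rankings
    are stable across runs.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    items = [
        (lex, float(a)) for lex, a in acts.items() if lex != target_lexeme
    ]
    items.sort(key=lambda kv: (-kv[1], kv[0]))
    return [(lex, max(a, 0.0)) for lex, a in items[:n]]


def demisyllable_activations(
    model: TrainedModel,
    demis: tuple[str, str],
    neighbors: list[tuple[str, float]],
    target_lexeme: str | None,
    params: ModelParams = ModelParams(),
) -> tuple[float, float]:
    """(ActPhon_1, ActPhon_2) for a supplied demi-syllable pair.

    Each activation is w_lex * a_t + sum_i w_i * a_i + b, where a_t is
    the production-direction weight from the target lexeme to the
    demi-syllable (dropped for items without a lexeme), a_i the weight
    from neighbor i, and w_i neighbor i's orthographic activation.
    """
    out = []
    for demi in demis:
        total = params.b
        if target_lexeme is not None:
            total += params.w_lex * model.lexeme_to_demi(demi, target_lexeme)
        for lex, w_i in neighbors:
            total += w_i * model.lexeme_to_demi(demi, lex)
        out.append(total)
    return out[0], out[1]


def demi_entropy(act_phon_1: float, act_phon_2: float) -> float:
    """Shannon entropy over the two demi-syllable activations, in bits.

    Activations are turned into probabilities by normalization; equal
    activations give the 1-bit maximum.
    """
    if act_phon_1 <= 0 or act_phon_2 <= 0:
        raise ValueError("demi-syllable activations must be positive")
    total = act_phon_1 + act_phon_2
    h = 0.0
    for a in (act_phon_1, act_phon_2):
        p = a / total
        h -= p * math.log2(p)
    return h


def total_activation(
    complexity: float,
    act_lexeme: float,
    act_phon_1: float,
    act_phon_2: float,
    h: float,
    params: ModelParams = ModelParams(),
) -> float:
    """Multiplicative integration of the support measures into Act units.

    Inhibitory measures (Complexity, H) sit in the numerator,
    facilitatory ones (ActLexeme, ActPhon_1, ActPhon_2) in the
    denominator; the back-off floor keeps the denominator positive.
    """
    act_lexeme = max(act_lexeme, params.b)
    act_phon_1 = max(act_phon_1, params.b)
    act_phon_2 = max(act_phon_2, params.b)
    h = max(h, params.b)
    return (
        complexity**params.w1
        * h**params.w5
        / (act_lexeme**params.w2 * act_phon_1**params.w3 * act_phon_2**params.w4)
    )


def simulate_rt(act: float, params: ModelParams = ModelParams()) -> float:
    """Linear transform of activation units into milliseconds."""
    if not math.isfinite(act):
        raise ValueError("Act must be finite")
    return params.w6 * act + params.w7


def simulate_item(
    model: TrainedModel,
    orthography: str,
    params: ModelParams = ModelParams(),
    complexity_table: dict[str, float] | None = None,
    include_sublexical: bool = False,
) -> dict:
    """Full activation profile for one item.

    Items whose lexeme is in the model are simulated as words (target
    demi-syllables from their own phonology); anything else is simulated
    as a non-word, with the pronounced demi-syllable pair selected by the
    top-down checking mechanism.
    """
    from ndra.pronounce import pronounce_nonword

    if complexity_table is None:
        complexity_table = default_complexity_table()
    acts, act_lexeme = lexeme_activations(model, orthography, params)
    lexeme = orthography.upper()
    is_word = model.has_lexeme(lexeme)
    neighbors = top_neighbors(acts, lexeme if is_word else None, params.n_neighbors)

    if is_word:
        entry = model.entry(orthography)
        pair = split_demisyllables(entry.phonology)
        demis = (pair.first, pair.second)
        target = lexeme
    else:
        result = pronounce_nonword(model, orthography, params)
        demis = (result.first, result.second)
        target = None

    ap1, ap2 = demisyllable_activations(model, demis, neighbors, target, params)
    ap1_f, ap2_f = max(ap1, params.b), max(ap2, params.b)
    h = demi_entropy(ap1_f, ap2_f)
    complexity = word_complexity(orthography, complexity_table)
    act = total_activation(complexity, act_lexeme, ap1_f, ap2_f, h, params)
    profile = {
        "item": orthography,
        "is_nonword": not is_word,
        "demi1": demis[0],
        "demi2": demis[1],
        "Complexity": complexity,
        "ActLexeme": act_lexeme,
        "ActPhon1": ap1_f,
        "ActPhon2": ap2_f,
        "H": h,
        "Act": act,
        "RT": simulate_rt(act, params),
    }
    if include_sublexical:
        profile.update(sublexical_measures(model, orthography, demis, params))
    return profile


def sublexical_measures(
    model: TrainedModel,
    orthography: str,
    demis: tuple[str, str],
    params: ModelParams = ModelParams(),
) -> dict:
    """Sub-lexical route measures (ActPhonSub_1, ActPhonSub_2, HSub).

    Computed from the direct orthography-to-demi-syllable network;
    reported alongside the lexical measures but never integrated into
    Act — the dual-route comparison found them non-contributory.
    """
    if model.sublex is None:
        raise ValueError("model was trained without a sub-lexical network")
    acts = _activation(model.sublex, extract_cues(orthography), backoff=params.b)
    sub = [
        float(acts[d]) if d in acts.index else params.b for d in demis
    ]
    sub = [max(a, params.b) for a in sub]
    return {
        "ActPhonSub1": sub[0],
        "ActPhonSub2": sub[1],
        "HSub": demi_entropy(sub[0], sub[1]),
    }


def batch_simulate(
    model: TrainedModel,
    items: list[str],
    params: ModelParams = ModelParams(),
    include_sublexical: bool = False,
) -> pd.DataFrame:
    """Activation profiles for a list of items, one row per item.

    Items that cannot be simulated (e.g. unsplittable phonology) are
    recorded as failed rows with an ``error`` message rather than
    aborting the batch.
    """
    table = default_complexity_table()
    rows = []
    for item in items:
        try:
            rows.append(
                simulate_item(
                    model,
                    item,
                    params,
                    complexity_table=table,
                    include_sublexical=include_sublexical,
                )
            )
        except Exception as exc:  # noqa: BLE001 - failures become rows
            rows.append({"item": item, "error": str(exc)})
    return pd.DataFrame(rows)
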