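"""Synthetic lexica and non-words for training and testing the model.

The generator emulates the structure of a monosyllabic training lexicon:
CVC-style monomorphemic entries built from paired orthographic/DISC
onset, nucleus and coda inventories, Zipf-distributed token frequencies,
orthographic body families (words sharing vowel + coda), and a
controllable fraction of *inconsistent* bodies whose members split
between two rime pronunciations.  Non-words recombine attested onsets
and bodies, so their candidate demi-syllables are attested in the
lexicon's phonology.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from ndra.lexicon import LexiconEntry, orthographic_parts

logger = logging.getLogger(__name__)

#: paired (orthography, DISC) onset inventory
ONSETS: tuple[tuple[str, str], ...] = (
    ("b", "b"), ("d", "d"), ("f", "f"), ("g", "g"), ("h", "h"),
    ("k", "k"), ("l", "l"), ("m", "m"), ("n", "n"), ("p", "p"),
    ("r", "r"), ("s", "s"), ("t", "t"), ("v", "v"), ("w", "w"),
    ("z", "z"), ("st", "st"), ("tr", "tr"), ("sk", "sk"), ("bl", "bl"),
    ("gr", "gr"), ("sn", "sn"), ("sl", "sl"), ("pl", "pl"), ("fl", "fl"),
    ("br", "br"), ("dr", "dr"), ("cl", "kl"), ("cr", "kr"), ("sw", "sw"),
)

#: paired (orthography, regular DISC, alternative DISC) nucleus inventory;
#: the alternative supplies the second pronunciation of inconsistent bodies
NUCLEI: tuple[tuple[str, str, str], ...] = (
    ("a", "{", "#"), ("e", "E", "i"), ("i", "I", "2"), ("o", "Q", "5"),
    ("u", "V", "U"), ("ee", "i", "E"), ("oo", "u", "U"), ("ai", "1", "2"),
    ("oa", "5", "$"), ("ea", "8", "i"),
)

#: paired (orthography, DISC) coda inventory
CODAS: tuple[tuple[str, str], ...] = (
    ("b", "b"), ("d", "d"), ("g", "g"), ("k", "k"), ("l", "l"),
    ("m", "m"), ("n", "n"), ("p", "p"), ("t", "t"), ("s", "s"),
    ("f", "f"), ("z", "z"), ("nd", "nd"), ("st", "st"), ("mp", "mp"),
    ("nt", "nt"), ("sk", "sk"), ("ft", "ft"), ("lk", "lk"), ("sp", "sp"),
    ("ls", "lz"), ("rn", "n"),
)


@dataclass(frozen=True)
class FixtureConfig:
    """Parameters of the synthetic-lexicon generator."""

    seed: int = 0
    n_words: int = 300
    zipf_exponent: float = 1.0
    n_bodies: int = 60
    consistency_mix: float = 0.0
    max_frequency: int = 100_000
    onsets: tuple = ONSETS
    nuclei: tuple = NUCLEI
    codas: tuple = CODAS

    def __post_init__(self) -> None:
        if not 0 <= self.consistency_mix <= 1:
            raise ValueError("consistency_mix must be in [0, 1]")
        if not (self.onsets and self.nuclei and self.codas):
            raise ValueError("inventories must be non-empty")
        if self.n_words < 1 or self.n_bodies < 1:
            raise ValueError("n_words and n_bodies must be positive")


def zipf_frequencies(
    n: int, exponent: float, max_frequency: int, rng: np.random.Generator
) -> np.ndarray:
    """Zipf token frequencies: rank r gets max_frequency * r^-exponent.

    Ranks are shuffled so frequency is independent of generation order;
    all frequencies are floored at 1.
    """
    ranks = rng.permutation(n) + 1
    freqs = np.maximum(1, np.round(max_frequency * ranks.astype(float) ** -exponent))
    return freqs.astype(int)


def generate_lexicon(config: FixtureConfig) -> list[LexiconEntry]:
    """Generate a synthetic monosyllabic lexicon.

    Words are distributed as evenly as possible over ``n_bodies`` body
    families (shared vowel + coda); family members get distinct onsets.
    A ``consistency_mix`` fraction of bodies is inconsistent: a
    frequency-weighted subset of the family receives an alternative
    nucleus pronunciation.
    """
    rng = np.random.default_rng(config.seed)
    all_bodies = list(itertools.product(range(len(config.nuclei)), range(len(config.codas))))
    if config.n_bodies > len(all_bodies):
        raise ValueError(
            f"n_bodies={config.n_bodies} exceeds the {len(all_bodies)} "
            "possible nucleus x coda combinations"
        )
    max_family = len(config.onsets)
    if config.n_words > config.n_bodies * max_family:
        raise ValueError(
            f"inventory too small: {config.n_words} words over "
            f"{config.n_bodies} bodies with at most {max_family} onsets each"
        )
    body_ids = [
        all_bodies[i] for i in rng.choice(len(all_bodies), config.n_bodies, replace=False)
    ]
    base, extra = divmod(config.n_words, config.n_bodies)
    sizes = [base + (1 if i < extra else 0) for i in range(config.n_bodies)]

    words: list[tuple[str, str, str, int]] = []  # orth, regular disc, alt disc, body
    for b, ((nuc_i, coda_i), size) in enumerate(zip(body_ids, sizes)):
        if size == 0:
            continue
        nuc_orth, nuc_disc, nuc_alt = config.nuclei[nuc_i]
        coda_orth, coda_disc = config.codas[coda_i]
        onset_ids = rng.choice(len(config.onsets), size, replace=False)
        for o in onset_ids:
            onset_orth, onset_disc = config.onsets[o]
            words.append(
                (
                    onset_orth + nuc_orth + coda_orth,
                    onset_disc + nuc_disc + coda_disc,
                    onset_disc + nuc_alt + coda_disc,
                    b,
                )
            )
    orths = [w[0] for w in words]
    if len(set(orths)) != len(orths):
        raise RuntimeError("generator produced duplicate orthographies")

    freqs = zipf_frequencies(len(words), config.zipf_exponent, config.max_frequency, rng)

    n_inconsistent = round(config.consistency_mix * config.n_bodies)
    inconsistent = set(
        rng.choice(config.n_bodies, n_inconsistent, replace=False).tolist()
    )
    alternative: set[int] = set()
    for b in inconsistent:
        members = [i for i, w in enumerate(words) if w[3] == b]
        if len(members) < 2:
            continue
        k = len(members) // 2
        weights = freqs[members].astype(float)
        chosen = rng.choice(
            members, size=k, replace=False, p=weights / weights.sum()
        )
        alternative.update(int(i) for i in chosen)

    entries = []
    for i, (orth, disc, alt, _b) in enumerate(words):
        entries.append(
            LexiconEntry(
                orthography=orth,
                phonology=alt if i in alternative else disc,
                frequency=int(freqs[i]),
            )
        )
    return entries


def generate_nonwords(
    lexicon: list[LexiconEntry], seed: int = 0, n: int = 100
) -> list[str]:
    """Novel onset x body recombinations absent from the lexicon.

    Every returned item has an attested orthographic onset and an
    attested body, and its onset + vowel combination occurs in some
    entry, so both candidate demi-syllables are attested in the
    lexicon's phonology.  Returns fewer than ``n`` (with a warning) when
    the combinatorics are exhausted.
    """
    if not lexicon:
        raise ValueError("lexicon is empty")
    rng = np.random.default_rng(seed)
    existing = {e.orthography for e in lexicon}
    onsets, bodies, onset_vowels = set(), set(), set()
    for e in lexicon:
        onset, vowel, coda = orthographic_parts(e.orthography)
        onsets.add(onset)
        bodies.add((vowel, coda))
        onset_vowels.add((onset, vowel))
    candidates = []
    for onset in sorted(onsets):
        for vowel, coda in sorted(bodies):
            orth = onset + vowel + coda
            if orth in existing:
                continue
            if (onset, vowel) not in onset_vowels:
                continue
            candidates.append(orth)
    if len(candidates) < n:
        logger.warning(
            "only %d of %d requested non-words could be generated",
            len(candidates),
            n,
        )
        n = len(candidates)
    picked = rng.choice(len(candidates), size=n, replace=False)
    return [candidates[i] for i in sorted(picked)]


def label_pseudohomophones(model, nonwords: list[str]) -> dict[str, bool]:
    """Flag non-words whose generated pronunciation matches a real word."""
    from ndra.pronounce import pronounce_nonword, PronunciationError

    word_phons = {
        e.phonology for e in model.lexicon if not e.is_nonword
    }
    labels = {}
    for nw in nonwords:
        try:
            labels[nw] = pronounce_nonword(model, nw).assembled in word_phons
        except PronunciationError:
            labels[nw] = False
    return labels


# -- factorial design fixtures ----------------------------------------------

#: 2-letter coda inventory of the factorial designs (orthography == DISC)
DESIGN_CODAS: tuple[str, ...] = (
    "nd", "st", "mp", "nt", "sk", "ft", "lk", "sp", "ld", "lf",
    "lp", "lt", "ns", "nk", "ps", "pt", "rd", "rk", "rm", "rp",
    "rt", "sm", "sn", "ts", "bs", "dz", "gz", "kt", "lm", "ln",
    "md", "mf", "ng", "nz", "pk", "rb", "rf", "rg", "rl", "rs",
)

#: same-length variant coda spellings built from letters the normal codas
#: never use; a variant coda maps to the DISC of its normal counterpart,
#: giving rime homophones with minimal orthographic overlap
VARIANT_CODAS: tuple[str, ...] = tuple(
    a + b for a in "cjqx" for b in "cjqxhwvzbd"
)[: len(DESIGN_CODAS)]

#: single-letter nuclei used by the designs; 'y' serves as the variant
#: vowel spelling (it only counts as a vowel when no other vowel letter
#: is present, which holds for the variant-coda words)
_DESIGN_NUCLEI = tuple(n for n in NUCLEI if len(n[0]) == 1)
_VARIANT_NUCLEUS = "y"


@dataclass
class DesignFixture:
    """A lexicon plus the matched target groups of a factorial contrast."""

    lexicon: list[LexiconEntry]
    groups: dict[str, list[str]]


def _background_entries(rng: np.random.Generator) -> list[LexiconEntry]:
    """Background vocabulary that globalizes orthographic cue sharing.

    In a large lexicon every letter and bigram is shared by many words,
    so the self-activation of a lexeme is comparably diluted for all
    words; a design-only lexicon concentrates cue ownership and
    confounds the factorial contrasts.  The background words share the
    designs' onset, nucleus-transition and coda bigrams but never a
    design rime, leaving rime-sharing counts untouched.
    """
    entries = []
    long_nuclei = [n for n in NUCLEI if len(n[0]) == 2]
    # 2-letter-nucleus words sharing the design codas
    for nuc_orth, nuc_disc, _ in long_nuclei:
        for j, coda in enumerate(DESIGN_CODAS):
            for o in rng.choice(len(ONSETS), 2, replace=False):
                onset_orth, onset_disc = ONSETS[o]
                entries.append(
                    LexiconEntry(
                        orthography=onset_orth + nuc_orth + coda,
                        phonology=onset_disc + nuc_disc + coda,
                        frequency=int(rng.integers(50, 5_000)),
                    )
                )
    # 1-letter-nucleus words with 1-letter codas sharing the
    # nucleus-to-coda bigrams of the design bodies
    short_codas = sorted({c[0] for c in DESIGN_CODAS})
    for nuc_orth, nuc_disc, _ in _DESIGN_NUCLEI:
        for coda in short_codas:
            for o in rng.choice(len(ONSETS), 2, replace=False):
                onset_orth, onset_disc = ONSETS[o]
                entries.append(
                    LexiconEntry(
                        orthography=onset_orth + nuc_orth + coda,
                        phonology=onset_disc + nuc_disc + coda,
                        frequency=int(rng.integers(50, 5_000)),
                    )
                )
    return entries


def _design_grid(rng: np.random.Generator):
    """Body grid (5 single-letter nuclei x 40 codas) with per-coda
    stratified assignment to the two design cells (100 bodies each)."""
    n_codas = len(DESIGN_CODAS)
    three = set(rng.choice(n_codas, size=n_codas // 2, replace=False).tolist())
    cells = {}
    for j in range(n_codas):
        k = 3 if j in three else 2
        cell_a = set(rng.choice(len(_DESIGN_NUCLEI), size=k, replace=False).tolist())
        for i in range(len(_DESIGN_NUCLEI)):
            cells[(i, j)] = "A" if i in cell_a else "B"
    return cells


class _RemoteOnsets:
    """Allocates distinct onsets to the rime-homophone words of each
    variant coda so their orthographies stay unique."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.used: dict[int, set[int]] = {}

    def take(self, coda_j: int) -> tuple[str, str]:
        used = self.used.setdefault(coda_j, set())
        free = [o for o in range(len(ONSETS)) if o not in used]
        if not free:
            raise ValueError("onset inventory exhausted for variant coda")
        o = int(self.rng.choice(free))
        used.add(o)
        return ONSETS[o]


def _remote_entry(
    remotes: _RemoteOnsets,
    coda_j: int,
    nuc_disc: str,
    rng: np.random.Generator,
) -> LexiconEntry:
    """A rime homophone spelled with 'y' + a variant coda: shares the
    phonological rime of body (nucleus, coda_j) but almost no
    orthography with its normally-spelled members."""
    onset_orth, onset_disc = remotes.take(coda_j)
    return LexiconEntry(
        orthography=onset_orth + _VARIANT_NUCLEUS + VARIANT_CODAS[coda_j],
        phonology=onset_disc + nuc_disc + DESIGN_CODAS[coda_j],
        frequency=int(rng.integers(50, 5_000)),
    )


def neighborhood_design(
    seed: int = 0,
    n_per_cell: int = 100,
    n_friends: int = 6,
    target_frequency: int = 50,
) -> DesignFixture:
    """Dense vs. sparse orthographic neighborhoods, frequency matched.

    Every target's phonological rime is shared by the same number of
    words (``n_friends + 1``) in both cells, so equilibrium credit
    assignment over demi-syllables is matched; the cells differ only in
    how many of those rime-sharers are *orthographic* neighbors (body
    sharers): ``n_friends`` for dense targets, none for sparse targets,
    whose rime-sharers are homophonously spelled.  Targets are
    normally-spelled words of identical token frequency and length.

    Targets are low-frequency by default: neighborhood effects are
    carried by the co-activation of neighbors relative to the target's
    own lexical support, and the experimental literature locates them
    primarily in low-frequency words.
    """
    rng = np.random.default_rng(seed)
    cells = _design_grid(rng)
    if n_per_cell > sum(1 for c in cells.values() if c == "A"):
        raise ValueError("n_per_cell exceeds the design grid capacity")
    remotes = _RemoteOnsets(rng)
    target_onsets = [o for o in ONSETS if len(o[0]) == 1]
    entries, dense, sparse = [], [], []
    n_a = n_b = 0
    for (i, j), cell in sorted(cells.items()):
        nuc_orth, nuc_disc, _ = _DESIGN_NUCLEI[i]
        coda = DESIGN_CODAS[j]
        is_dense = cell == "A"
        if is_dense and n_a >= n_per_cell or not is_dense and n_b >= n_per_cell:
            continue
        n_normal = 1 + (n_friends if is_dense else 0)
        n_remote = 1 + (0 if is_dense else n_friends)
        t = int(rng.choice(len(target_onsets)))
        onset_orth, onset_disc = target_onsets[t]
        entries.append(
            LexiconEntry(
                orthography=onset_orth + nuc_orth + coda,
                phonology=onset_disc + nuc_disc + coda,
                frequency=target_frequency,
            )
        )
        (dense if is_dense else sparse).append(entries[-1].orthography)
        friends = [o for o in range(len(ONSETS)) if ONSETS[o][0] != onset_orth]
        for o in rng.choice(friends, size=n_normal - 1, replace=False):
            f_orth, f_disc = ONSETS[o]
            entries.append(
                LexiconEntry(
                    orthography=f_orth + nuc_orth + coda,
                    phonology=f_disc + nuc_disc + coda,
                    frequency=int(rng.integers(50, 5_000)),
                )
            )
        for _ in range(n_remote):
            entries.append(_remote_entry(remotes, j, nuc_disc, rng))
        if is_dense:
            n_a += 1
        else:
            n_b += 1
    entries.extend(_background_entries(rng))
    return DesignFixture(lexicon=entries, groups={"dense": dense, "sparse": sparse})


def consistency_design(
    seed: int = 0,
    n_per_cell: int = 100,
    family_size: int = 6,
    target_frequency: int = 50,
) -> DesignFixture:
    """Consistent vs. inconsistent body families, frequency matched.

    Both cells have orthographic body families of ``family_size`` and
    targets whose phonological rime is shared by the same total number
    of words.  In consistent families all members share the rime; in
    inconsistent families the target is an exception word — every body
    neighbor is an enemy carrying an alternative nucleus pronunciation
    — and homophonously spelled rime-sharers restore the target's
    global rime count, so the cells differ only in whether the
    orthographic neighbors are friends or enemies.  Targets are
    low-frequency by default, the regime in which consistency effects
    are strongest experimentally.
    """
    rng = np.random.default_rng(seed)
    cells = _design_grid(rng)
    remotes = _RemoteOnsets(rng)
    target_onsets = [o for o in ONSETS if len(o[0]) == 1]
    n_enemies = family_size - 1
    entries, consistent, inconsistent = [], [], []
    n_a = n_b = 0
    for (i, j), cell in sorted(cells.items()):
        nuc_orth, nuc_disc, nuc_alt = _DESIGN_NUCLEI[i]
        coda = DESIGN_CODAS[j]
        is_consistent = cell == "A"
        if (
            is_consistent
            and n_a >= n_per_cell
            or not is_consistent
            and n_b >= n_per_cell
        ):
            continue
        t = int(rng.choice(len(target_onsets)))
        onset_orth, onset_disc = target_onsets[t]
        entries.append(
            LexiconEntry(
                orthography=onset_orth + nuc_orth + coda,
                phonology=onset_disc + nuc_disc + coda,
                frequency=target_frequency,
            )
        )
        (consistent if is_consistent else inconsistent).append(
            entries[-1].orthography
        )
        others = [o for o in range(len(ONSETS)) if ONSETS[o][0] != onset_orth]
        member_onsets = rng.choice(others, size=family_size - 1, replace=False)
        for rank, o in enumerate(member_onsets):
            f_orth, f_disc = ONSETS[o]
            enemy = not is_consistent and rank < n_enemies
            entries.append(
                LexiconEntry(
                    orthography=f_orth + nuc_orth + coda,
                    phonology=f_disc + (nuc_alt if enemy else nuc_disc) + coda,
                    frequency=int(rng.integers(50, 5_000)),
                )
            )
        # homophone rime-sharers equalize each target's rime count
        n_remote = 1 + (n_enemies if not is_consistent else 0)
        for _ in range(n_remote):
            entries.append(_remote_entry(remotes, j, nuc_disc, rng))
        if is_consistent:
            n_a += 1
        else:
            n_b += 1
    entries.extend(_background_entries(rng))
    return DesignFixture(
        lexicon=entries,
        groups={"consistent": consistent, "inconsistent": inconsistent},
    )


def nonword_frequency_design(
    seed: int = 0,
    n_per_cell: int = 100,
    high_frequency: int = 20_000,
    low_frequency: int = 20,
    base_config: FixtureConfig | None = None,
) -> DesignFixture:
    """Non-words at two frequency tiers, ready for lexicon retraining.

    Generates a base word lexicon, derives non-words from it, assigns
    the model-generated pronunciation to each non-word, and returns the
    combined lexicon with non-word entries flagged; retraining with
    ``include_nonwords=True`` probes the non-word frequency effect.
    """
    from ndra.networks import train_model
    from ndra.pronounce import pronounce_nonword

    config = base_config or FixtureConfig(
        seed=seed, n_words=300, n_bodies=75, consistency_mix=0.0
    )
    lexicon = generate_lexicon(config)
    nonwords = generate_nonwords(lexicon, seed=seed + 1, n=2 * n_per_cell)
    if len(nonwords) < 2 * n_per_cell:
        raise ValueError("could not generate enough non-words for the design")
    base_model = train_model(lexicon)
    rng = np.random.default_rng(seed + 2)
    order = rng.permutation(len(nonwords))
    high = sorted(nonwords[i] for i in order[:n_per_cell])
    low = sorted(nonwords[i] for i in order[n_per_cell:])
    combined = list(lexicon)
    for tier, freq in ((high, high_frequency), (low, low_frequency)):
        for nw in tier:
            phon = pronounce_nonword(base_model, nw).assembled
            combined.append(
                LexiconEntry(
                    orthography=nw, phonology=phon, frequency=freq, is_nonword=True
                )
            )
    return DesignFixture(lexicon=combined, groups={"high": high, "low": low})
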