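"""Lexicon I/O, orthographic cue extraction and demi-syllable decomposition.

Orthography is coded as lowercase letters a-z.  Phonology is coded in the
single-character DISC notation of the CELEX lexical database; a monosyllable
decomposes into two demi-syllables (onset + nucleus, nucleus + coda) with
the nucleus repeated in both halves, e.g. /b8R/ ("bear") -> b8 and 8R.
"""

from __future__ import annotations

import csv
import importlib.resources
import logging
import re
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

BOUNDARY = "#"

_ORTH_RE = re.compile(r"^[a-z]+$")
_ORTH_VOWELS = frozenset("aeiou")


def _load_disc_nuclei() -> frozenset[str]:
    ref = importlib.resources.files("ndra.data").joinpath("disc_nuclei.tsv")
    symbols = []
    with ref.open("r", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            symbols.append(row["symbol"])
    return frozenset(symbols)


#: DISC symbols counted as syllable nuclei.  Shipped as an editable config
#: table (``data/disc_nuclei.tsv``); syllabic consonants are excluded by
#: default.
DISC_NUCLEI: frozenset[str] = _load_disc_nuclei()


class LexiconError(ValueError):
    """Raised for malformed lexicon entries or files."""


@dataclass(frozen=True)
class LexiconEntry:
    """One word (or non-word) of the training lexicon.

    Training entries must have at least 3 letters; 1- and 2-letter words
    are excluded from training data so that bigram coding is not trivially
    favoured.  Phonology must contain exactly one nucleus run.
    """

    orthography: str
    phonology: str
    frequency: int
    is_nonword: bool = False

    def __post_init__(self) -> None:
        if not _ORTH_RE.match(self.orthography):
            raise LexiconError(
                f"orthography must be lowercase a-z, got {self.orthography!r}"
            )
        if self.frequency < 1:
            raise LexiconError(
                f"{self.orthography!r}: frequency must be >= 1, got {self.frequency}"
            )
        if not self.is_nonword and len(self.orthography) < 3:
            raise LexiconError(
                f"{self.orthography!r}: training entries must have >= 3 letters"
            )
        # Validates the single-nucleus invariant as a side effect.
        split_demisyllables(self.phonology)

    @property
    def lexeme(self) -> str:
        """Lexical identifier: the uppercase orthography."""
        return self.orthography.upper()


@dataclass(frozen=True)
class DemiSyllablePair:
    """The two demi-syllables of a monosyllable; the nucleus is repeated."""

    first: str
    second: str

    def __iter__(self):
        return iter((self.first, self.second))


def is_vowel(symbol: str, nuclei: frozenset[str] = DISC_NUCLEI) -> bool:
    """True iff ``symbol`` is a DISC nucleus symbol."""
    if len(symbol) != 1:
        raise ValueError(f"expected a single DISC symbol, got {symbol!r}")
    return symbol in nuclei


def extract_cues(orthography: str) -> frozenset[str]:
    """Orthographic cues of a word: letters plus boundary-marked bigrams.

    For "bear" the cues are the letters b, e, a, r and the bigrams
    #b, be, ea, ar, r#.  Cue presence is binary: repeated letters or
    bigrams contribute a single cue (set semantics).
    """
    if not _ORTH_RE.match(orthography):
        raise LexiconError(
            f"orthography must be non-empty lowercase a-z, got {orthography!r}"
        )
    padded = BOUNDARY + orthography + BOUNDARY
    bigrams = {padded[i : i + 2] for i in range(len(padded) - 1)}
    return frozenset(set(orthography) | bigrams)


def split_demisyllables(
    phonology: str, nuclei: frozenset[str] = DISC_NUCLEI
) -> DemiSyllablePair:
    """Split a DISC monosyllable into (onset+nucleus, nucleus+coda).

    The nucleus (the unique maximal run of vowel symbols) is repeated in
    both halves.  A syllable without onset or coda yields a bare-nucleus
    half, e.g. /8R/ -> (8, 8R).
    """
    if not phonology:
        raise LexiconError("empty phonology")
    runs = list(re.finditer(f"[{re.escape(''.join(sorted(nuclei)))}]+", phonology))
    if len(runs) != 1:
        raise LexiconError(
            f"{phonology!r}: expected exactly one nucleus run, found {len(runs)}"
        )
    run = runs[0]
    onset, nucleus, coda = (
        phonology[: run.start()],
        run.group(),
        phonology[run.end() :],
    )
    return DemiSyllablePair(first=onset + nucleus, second=nucleus + coda)


def demi_parts(
    demi: str, nuclei: frozenset[str] = DISC_NUCLEI
) -> tuple[str, str, str]:
    """Decompose a demi-syllable into (onset, nucleus, coda).

    A word-initial demi-syllable has an empty coda; a word-final one has
    an empty onset.
    """
    runs = list(re.finditer(f"[{re.escape(''.join(sorted(nuclei)))}]+", demi))
    if len(runs) != 1:
        raise LexiconError(f"{demi!r}: not a well-formed demi-syllable")
    run = runs[0]
    return demi[: run.start()], run.group(), demi[run.end() :]


def orthographic_parts(orthography: str) -> tuple[str, str, str]:
    """Split an orthographic string into (onset, vowel cluster, coda).

    The onset is everything before the first vowel letter, the vowel
    cluster is the maximal run of vowel letters starting there, and the
    coda is the remainder.  'y' counts as a vowel letter only when the
    string contains no other vowel letter (covers forms like "sky").
    """
    if not _ORTH_RE.match(orthography):
        raise LexiconError(f"invalid orthography {orthography!r}")
    vowels = _ORTH_VOWELS
    if not any(ch in vowels for ch in orthography):
        if "y" in orthography:
            vowels = frozenset("y")
        else:
            raise LexiconError(f"{orthography!r}: no vowel letter")
    i = next(k for k, ch in enumerate(orthography) if ch in vowels)
    j = i
    while j < len(orthography) and orthography[j] in vowels:
        j += 1
    return orthography[:i], orthography[i:j], orthography[j:]


def orthographic_rhyme(orthography: str) -> str:
    """Vowel cluster + coda (the orthographic body)."""
    _, vowel, coda = orthographic_parts(orthography)
    return vowel + coda


_COLUMNS = ("orthography", "disc", "frequency")


def read_lexicon(path, delimiter: str = "\t") -> list[LexiconEntry]:
    """Read a lexicon from delimited text.

    Required columns: ``orthography``, ``disc``, ``frequency``; optional
    ``is_nonword`` (0/1).  Rows are validated against the entry
    invariants; duplicate orthographies and malformed rows raise
    :class:`LexiconError` with the offending line number.
    """
    entries: list[LexiconEntry] = []
    seen: set[str] = set()
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            logger.warning("empty lexicon file %s", path)
            return entries
        missing = set(_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise LexiconError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                entry = LexiconEntry(
                    orthography=row["orthography"],
                    phonology=row["disc"],
                    frequency=int(row["frequency"]),
                    is_nonword=bool(int(row.get("is_nonword") or 0)),
                )
            except (LexiconError, TypeError, ValueError) as exc:
                raise LexiconError(f"{path}, line {lineno}: {exc}") from exc
            if entry.orthography in seen:
                raise LexiconError(
                    f"{path}, line {lineno}: duplicate orthography "
                    f"{entry.orthography!r}"
                )
            seen.add(entry.orthography)
            entries.append(entry)
    if not entries:
        logger.warning("lexicon file %s contains no entries", path)
    return entries


def write_lexicon(entries: list[LexiconEntry], path, delimiter: str = "\t") -> None:
    """Write a lexicon as delimited text (round-trips with read_lexicon)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow([*_COLUMNS, "is_nonword"])
        for e in entries:
            writer.writerow(
                [e.orthography, e.phonology, e.frequency, int(e.is_nonword)]
            )
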