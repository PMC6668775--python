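"""Construction of the model's trained equilibrium networks from a lexicon.

Three networks are derived from the same frequency-weighted event tables:

* ``o2l`` — orthography to lexemes: letters and letter bigrams as cues,
  lexemes (uppercase orthographies) as outcomes.
* ``p2l`` — demi-syllables as cues, lexemes as outcomes.  Activation in
  the running model flows the other way (lexeme -> demi-syllable), read
  off the *transpose* of this matrix; training in the perception
  direction uses the one-to-many mapping that discriminative learning
  favours.
* ``sublex`` (optional) — a sub-lexical route mapping letters and
  bigrams straight onto demi-syllables, used only for the dual-route
  comparison measures.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ndra.lexicon import LexiconEntry, extract_cues, split_demisyllables
from ndra.rw_core import EventTable, solve_equilibrium


def _training_entries(
    lexicon: list[LexiconEntry], include_nonwords: bool
) -> list[LexiconEntry]:
    entries = [e for e in lexicon if include_nonwords or not e.is_nonword]
    if not entries:
        raise ValueError("no training entries in lexicon")
    return entries


def build_o2l(
    lexicon: list[LexiconEntry], include_nonwords: bool = False
) -> pd.DataFrame:
    """Equilibrium orthography-to-lexeme network (one event per entry)."""
    entries = _training_entries(lexicon, include_nonwords)
    events = EventTable(
        [
            (extract_cues(e.orthography), frozenset({e.lexeme}), e.frequency)
            for e in entries
        ]
    )
    return solve_equilibrium(events)


def build_p2l(
    lexicon: list[LexiconEntry], include_nonwords: bool = False
) -> pd.DataFrame:
    """Equilibrium demi-syllable-to-lexeme network.

    Cues are the entry's two demi-syllables; production reads the
    transpose of the returned matrix.
    """
    entries = _training_entries(lexicon, include_nonwords)
    events = []
    for e in entries:
        pair = split_demisyllables(e.phonology)
        events.append(
            (frozenset({pair.first, pair.second}), frozenset({e.lexeme}), e.frequency)
        )
    return solve_equilibrium(EventTable(events))


def build_sublexical(
    lexicon: list[LexiconEntry], include_nonwords: bool = False
) -> pd.DataFrame:
    """Equilibrium sub-lexical network: orthographic cues -> demi-syllables."""
    entries = _training_entries(lexicon, include_nonwords)
    events = []
    for e in entries:
        pair = split_demisyllables(e.phonology)
        events.append(
            (
                extract_cues(e.orthography),
                frozenset({pair.first, pair.second}),
                e.frequency,
            )
        )
    return solve_equilibrium(EventTable(events))


@dataclass
class TrainedModel:
    """The trained networks plus the lexicon they were trained on."""

    o2l: pd.DataFrame
    p2l: pd.DataFrame
    lexicon: list[LexiconEntry]
    sublex: pd.DataFrame | None = None
    include_nonwords: bool = False
    #: demi-syllables attested word-initially / word-finally in training
    initial_demis: frozenset[str] = field(init=False)
    final_demis: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        trained = [
            e for e in self.lexicon if self.include_nonwords or not e.is_nonword
        ]
        first, second = set(), set()
        for e in trained:
            pair = split_demisyllables(e.phonology)
            first.add(pair.first)
            second.add(pair.second)
        self.initial_demis = frozenset(first)
        self.final_demis = frozenset(second)
        self._entries_by_orth = {e.orthography: e for e in trained}
        self._lexemes = frozenset(e.lexeme for e in trained)

    def entry(self, orthography: str) -> LexiconEntry | None:
        return self._entries_by_orth.get(orthography)

    def has_lexeme(self, lexeme: str) -> bool:
        return lexeme in self._lexemes

    def lexeme_to_demi(self, demi: str, lexeme: str) -> float:
        """Production-direction weight: trained V[demi-syllable, lexeme]."""
        if demi in self.p2l.index and lexeme in self.p2l.columns:
            return float(self.p2l.at[demi, lexeme])
        return 0.0


def train_model(
    lexicon: list[LexiconEntry],
    sublexical: bool = False,
    include_nonwords: bool = False,
) -> TrainedModel:
    """Train all networks from a lexicon.

    Non-word entries join the training events only when
    ``include_nonwords`` is set (the retraining regime used to probe
    non-word frequency effects).
    """
    return TrainedModel(
        o2l=build_o2l(lexicon, include_nonwords),
        p2l=build_p2l(lexicon, include_nonwords),
        sublex=build_sublexical(lexicon, include_nonwords) if sublexical else None,
        lexicon=list(lexicon),
        include_nonwords=include_nonwords,
    )


# -- serialization -----------------------------------------------------------

def _label_checksum(df: pd.DataFrame) -> str:
    payload = "\x00".join(list(df.index) + ["|"] + list(df.columns))
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()


def save_model(model: TrainedModel, directory) -> None:
    """Serialize a trained model to a directory of TSV files + manifest."""
    from ndra.lexicon import write_lexicon

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest = {
        "include_nonwords": model.include_nonwords,
        "matrices": {},
    }
    matrices = {"o2l": model.o2l, "p2l": model.p2l}
    if model.sublex is not None:
        matrices["sublex"] = model.sublex
    for name, df in matrices.items():
        df.to_csv(d / f"{name}.tsv", sep="\t", float_format="%.17g")
        manifest["matrices"][name] = {
            "shape": list(df.shape),
            "labels_sha256": _label_checksum(df),
        }
    write_lexicon(model.lexicon, d / "lexicon.tsv")
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_model(directory) -> TrainedModel:
    """Load a model saved by :func:`save_model`; verifies label checksums."""
    from ndra.lexicon import read_lexicon

    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    matrices = {}
    for name, meta in manifest["matrices"].items():
        df = pd.read_csv(d / f"{name}.tsv", sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if _label_checksum(df) != meta["labels_sha256"]:
            raise ValueError(f"label checksum mismatch for matrix {name!r}")
        matrices[name] = df
    return TrainedModel(
        o2l=matrices["o2l"],
        p2l=matrices["p2l"],
        sublex=matrices.get("sublex"),
        lexicon=read_lexicon(d / "lexicon.tsv"),
        include_nonwords=manifest["include_nonwords"],
    )
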