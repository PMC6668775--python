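"""Letter-complexity quantification from glyph bitmaps.

Visual decoding cost is approximated by how *atypical* a letter's shape
is: the summed Manhattan (city-block) distance between a letter's 20x20
binary bitmap and the bitmaps of all 26 letters, square-rooted by
default.  Letters similar to many others (o, c) come out low; visually
distinctive letters (w, y) come out high.  Word complexity is the sum of
its letters' complexities, one term per occurrence.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import string

import numpy as np

GLYPH_SIZE = 20
_FIXTURE_NAME = "glyphs_20x20.txt"
_FIXTURE_SHA256 = "dc7eef205dc74ef1c49a760191a271c6ec26f5d5d0a5c7521a9340e2d0420f14"


class GlyphError(ValueError):
    """Raised for malformed or corrupted glyph data."""


def load_fixture_glyphs() -> dict[str, np.ndarray]:
    """Load the packaged deterministic 20x20 monospaced glyph bitmaps.

    The bitmaps were rasterized once from a monospaced bitmap font and
    frozen as text so that complexity values are identical across
    platforms.  The file is checksum-verified on load.
    """
    ref = importlib.resources.files("ndra.data").joinpath(_FIXTURE_NAME)
    text = ref.read_text(encoding="utf-8")
    digest = hashlib.sha256(text.encode("utf-8")).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise GlyphError(f"glyph fixture checksum mismatch ({digest})")
    return parse_glyphs(text)


def parse_glyphs(text: str) -> dict[str, np.ndarray]:
    """Parse PBM-style text blocks (``glyph <letter>`` + 20 bit rows)."""
    glyphs: dict[str, np.ndarray] = {}
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("glyph "):
            letter = line.split()[1]
            rows = lines[i + 1 : i + 1 + GLYPH_SIZE]
            bitmap = np.array([[int(c) for c in r.strip()] for r in rows])
            if bitmap.shape != (GLYPH_SIZE, GLYPH_SIZE):
                raise GlyphError(f"glyph {letter!r}: bad shape {bitmap.shape}")
            if not np.isin(bitmap, (0, 1)).all():
                raise GlyphError(f"glyph {letter!r}: non-binary values")
            glyphs[letter] = bitmap
            i += 1 + GLYPH_SIZE
        else:
            i += 1
    missing = set(string.ascii_lowercase) - set(glyphs)
    if missing:
        raise GlyphError(f"missing glyphs: {sorted(missing)}")
    return glyphs


def glyph_distance(a: np.ndarray, b: np.ndarray) -> int:
    """City-block distance between two binary bitmaps (pixels differing)."""
    return int(np.abs(a.astype(int) - b.astype(int)).sum())


def letter_complexity(
    glyphs: dict[str, np.ndarray], use_sqrt: bool = True
) -> dict[str, float]:
    """Per-letter complexity: (sqrt of) summed pixel distance to all letters.

    The self-term contributes zero either way.  ``use_sqrt=False`` gives
    the bare sum.
    """
    letters = sorted(glyphs)
    stack = np.stack([glyphs[ch].astype(int).ravel() for ch in letters])
    dist = np.abs(stack[:, None, :] - stack[None, :, :]).sum(axis=2)
    totals = dist.sum(axis=1).astype(float)
    if use_sqrt:
        totals = np.sqrt(totals)
    return dict(zip(letters, totals))


def word_complexity(word: str, table: dict[str, float]) -> float:
    """Summed letter complexity of a word; repeats count per occurrence."""
    unknown = set(word) - set(table)
    if unknown:
        raise KeyError(f"letters without complexity values: {sorted(unknown)}")
    return float(sum(table[ch] for ch in word))


def default_complexity_table(use_sqrt: bool = True) -> dict[str, float]:
    """Complexity table computed from the packaged glyph fixture."""
    return letter_complexity(load_fixture_glyphs(), use_sqrt=use_sqrt)
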