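"""Alphabet encoding, substitution matrices and gap penalties.

Everything downstream of this module works on integer residue codes. The
alphabet is taken from the substitution matrix itself (the 20 standard amino
acids plus whatever extra rows the matrix carries, e.g. B, Z, X). One extra
*dummy* code is reserved past the end of the alphabet: it scores 0 against
every residue and is used to pad queries to lane/partition boundaries, so
padding can never change an alignment score.

Gap model: a gap of length k costs ``open + k * extend`` (the first gapped
cell costs ``open + extend``). The shorthand ``"10-2k"`` used throughout
protein-search tooling means open=10, extend=2. ``extend >= 1`` is enforced
globally: the vectorized engines rely on strictly decaying vertical-gap
scores for their fill-value safety argument.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

__all__ = [
    "Alphabet",
    "SubstitutionMatrix",
    "GapPenalty",
    "ScoringScheme",
    "MatrixFormatError",
    "GapSpecError",
    "EncodingError",
    "load_matrix",
    "parse_gap_spec",
    "encode_sequence",
    "BUILTIN_MATRICES",
]

BUILTIN_MATRICES = ("BLOSUM62", "BLOSUM50")

#: characters silently removed from sequence text before encoding
_STRIP_RE = re.compile(r"[\s\*]+")


class MatrixFormatError(ValueError):
    """Raised for unknown matrix names or malformed/asymmetric score tables."""


class GapSpecError(ValueError):
    """Raised for malformed gap-penalty strings or a zero extension penalty."""


class EncodingError(ValueError):
    """Raised in strict mode when a sequence contains out-of-alphabet residues."""


@dataclass(frozen=True)
class Alphabet:
    """Ordered residue alphabet with a reserved zero-scoring dummy code.

    ``symbols`` are the residue characters in matrix order; codes are their
    positions. The dummy code is ``len(symbols)`` and is deliberately *not*
    a symbol: it only ever arises from padding, never from input text.
    """

    symbols: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        object.__setattr__(
            self, "_index", {c: i for i, c in enumerate(self.symbols)}
        )

    @property
    def size(self) -> int:
        """Number of codes including the dummy."""
        return len(self.symbols) + 1

    @property
    def dummy_code(self) -> int:
        return len(self.symbols)

    def code(self, ch: str) -> int:
        return self._index[ch]

    def __contains__(self, ch: str) -> bool:
        return ch in self._index

    def encode(self, text: str, strict: bool = False) -> np.ndarray:
        """Encode residue text to int64 codes.

        Whitespace and ``'*'`` are stripped and case is folded. Unknown
        characters map to ``X`` when the alphabet has an X row, else to the
        dummy code; with ``strict=True`` they raise :class:`EncodingError`.
        """
        clean = _STRIP_RE.sub("", text).upper()
        unknown = self._index.get("X", self.dummy_code)
        codes = np.empty(len(clean), dtype=np.int64)
        get = self._index.get
        for i, ch in enumerate(clean):
            c = get(ch)
            if c is None:
                if strict:
                    raise EncodingError(
                        f"residue {ch!r} at position {i} is not in the alphabet"
                    )
                c = unknown
            codes[i] = c
        return codes

    def decode(self, codes) -> str:
        return "".join(self.symbols[int(c)] for c in codes)


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric integer substitution score table over an :class:`Alphabet`.

    ``scores`` has shape ``(alphabet.size, alphabet.size)`` — i.e. it includes
    the dummy row/column, which is identically zero.
    """

    name: str
    alphabet: Alphabet
    scores: np.ndarray

    def __post_init__(self) -> None:
        n = self.alphabet.size
        if self.scores.shape != (n, n):
            raise MatrixFormatError(
                f"score table shape {self.scores.shape} does not cover the "
                f"{n}-code alphabet"
            )
        _check_symmetric(self.scores, self.alphabet)
        d = self.alphabet.dummy_code
        if self.scores[d, :].any() or self.scores[:, d].any():
            raise MatrixFormatError("dummy residue must score 0 against everything")

    def score(self, a: int, b: int) -> int:
        return int(self.scores[a, b])

    def __getitem__(self, pair: tuple[str, str]) -> int:
        a, b = pair
        return int(self.scores[self.alphabet.code(a), self.alphabet.code(b)])

    @property
    def max_score(self) -> int:
        return int(self.scores.max())


@dataclass(frozen=True)
class GapPenalty:
    """Affine gap parameters: gap of length k costs ``open + k * extend``."""

    open: int
    extend: int

    def __post_init__(self) -> None:
        if self.open < 0:
            raise GapSpecError(f"gap open penalty must be >= 0, got {self.open}")
        if self.extend < 1:
            raise GapSpecError(
                f"gap extension penalty must be >= 1, got {self.extend}"
            )

    @property
    def first(self) -> int:
        """Cost of the first gapped cell (open + extend)."""
        return self.open + self.extend

    def cost(self, k: int) -> int:
        return self.open + k * self.extend

    def __str__(self) -> str:
        return f"{self.open}-{self.extend}k"


@dataclass(frozen=True)
class ScoringScheme:
    """A substitution matrix plus gap penalties; shared by every engine."""

    matrix: SubstitutionMatrix
    gap: GapPenalty

    @property
    def alphabet(self) -> Alphabet:
        return self.matrix.alphabet

    @classmethod
    def default(cls) -> "ScoringScheme":
        return cls(load_matrix("BLOSUM62"), GapPenalty(10, 2))


def _check_symmetric(scores: np.ndarray, alphabet: Alphabet) -> None:
    bad = np.argwhere(scores != scores.T)
    if bad.size:
        i, j = (int(x) for x in bad[0])
        sym = list(alphabet.symbols) + ["<dummy>"]
        raise MatrixFormatError(
            f"asymmetric score table: ({sym[i]},{sym[j]}) = {scores[i, j]} "
            f"but ({sym[j]},{sym[i]}) = {scores[j, i]}"
        )


def _from_bio_array(arr, name: str) -> SubstitutionMatrix:
    """Convert a Bio.Align substitution_matrices Array, dropping any '*' row."""
    letters = [c for c in arr.alphabet if c != "*"]
    if not letters:
        raise MatrixFormatError(f"matrix {name!r} has an empty alphabet")
    alphabet = Alphabet(tuple(letters))
    n = alphabet.size
    scores = np.zeros((n, n), dtype=np.int64)
    for i, a in enumerate(letters):
        for j, b in enumerate(letters):
            v = float(arr[a, b])
            if v != round(v):
                raise MatrixFormatError(
                    f"matrix {name!r} entry ({a},{b}) = {v} is not an integer"
                )
            scores[i, j] = int(round(v))
    _check_symmetric(scores, alphabet)
    return SubstitutionMatrix(name=name, alphabet=alphabet, scores=scores)


def load_matrix(name_or_path: str | Path) -> SubstitutionMatrix:
    """Load a built-in BLOSUM matrix or an NCBI-format score-table file.

    Built-ins carry the standard published integer scores. Files follow the
    NCBI text layout: '#' comment lines, then a column-alphabet line, then one
    row per residue (row label + integers). Non-square or asymmetric tables
    are rejected with an error naming the offending pair.
    """
    key = str(name_or_path).upper()
    if key in BUILTIN_MATRICES:
        return _from_bio_array(substitution_matrices.load(key), key)
    path = Path(name_or_path)
    if not path.is_file():
        raise MatrixFormatError(
            f"{name_or_path!r} is neither a built-in matrix "
            f"{BUILTIN_MATRICES} nor a readable file"
        )
    try:
        arr = substitution_matrices.read(str(path))
    except Exception as exc:  # malformed table, ragged rows, ...
        raise MatrixFormatError(f"cannot parse matrix file {path}: {exc}") from exc
    return _from_bio_array(arr, path.stem)


_GAP_QRK = re.compile(r"^\s*(\d+)\s*-\s*(\d+)\s*k\s*$", re.IGNORECASE)
_GAP_SLASH = re.compile(r"^\s*(\d+)\s*/\s*(\d+)\s*$")


def parse_gap_spec(spec: str) -> GapPenalty:
    """Parse the ``"<q>-<r>k"`` shorthand (or explicit ``"<q>/<r>"``).

    ``"10-2k"`` means open=10, extend=2, so a length-k gap costs 10 + 2k.
    """
    m = _GAP_QRK.match(spec) or _GAP_SLASH.match(spec)
    if m is None:
        raise GapSpecError(
            f"cannot parse gap penalty {spec!r}; expected e.g. '10-2k' or '10/2'"
        )
    q, r = int(m.group(1)), int(m.group(2))
    if r == 0:
        raise GapSpecError(f"gap extension must be >= 1 in {spec!r}")
    return GapPenalty(open=q, extend=r)


def encode_sequence(
    text: str, alphabet: Alphabet, strict: bool = False
) -> np.ndarray:
    """Encode residue text with :meth:`Alphabet.encode` (lenient by default)."""
    return alphabet.encode(text, strict=strict)
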