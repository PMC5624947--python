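"""Substitution matrices and the affine gap model.

Three matrices are available: PHAT (transmembrane-specific, the default for
TM regions), BLOSUM62 (the default for loop regions) and GONNET250.
BLOSUM62 and GONNET250 come from Bio.Align.substitution_matrices; GONNET250
entries are scaled x10 and rounded so that all dynamic programming is
integer-exact.  PHAT ships as a packaged data file.  The unknown residue X
scores 0 against everything.

Gap cost convention: a gap of length L costs ``gap_open + (L-1)*gap_extend``
(the opening column is charged ``gap_open``; each further column
``gap_extend``).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from Bio.Align import substitution_matrices

#: Scoring alphabet: the 20 amino acids plus X, in this fixed order.
ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_INDEX = {c: i for i, c in enumerate(ALPHABET)}

MATRIX_NAMES = ("PHAT", "BLOSUM62", "GONNET250")


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric integer scores over the 21-letter alphabet (20 AAs + X)."""

    name: str
    scores: np.ndarray  # (21, 21) int array in ALPHABET order

    def __post_init__(self) -> None:
        if self.scores.shape != (len(ALPHABET), len(ALPHABET)):
            raise ValueError("score matrix must be 21x21")
        if not np.array_equal(self.scores, self.scores.T):
            raise ValueError(f"matrix {self.name} is not symmetric")

    def score(self, a: str, b: str) -> int:
        return int(self.scores[_INDEX[a], _INDEX[b]])


@dataclass(frozen=True)
class GapModel:
    """Affine gap penalties (both non-negative, open >= extend)."""

    gap_open: int = 8
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if not self.gap_open >= self.gap_extend >= 0:
            raise ValueError("need gap_open >= gap_extend >= 0")

    def cost(self, length: int) -> int:
        """Total penalty of one gap of the given length."""
        if length < 1:
            raise ValueError("gap length must be >= 1")
        return self.gap_open + (length - 1) * self.gap_extend


def gap_cost(model: GapModel, length: int) -> int:
    return model.cost(length)


def parse_matrix_file(text: str, name: str) -> SubstitutionMatrix:
    """Parse the packaged square-matrix format.

    First non-comment line: the residue alphabet (whitespace-separated
    letters); following lines: a full square of integer scores in that
    order.  Letters missing from the file (X in particular) score 0.
    """
    lines = [
        ln for ln in (raw.strip() for raw in text.splitlines())
        if ln and not ln.startswith("#")
    ]
    letters = lines[0].split()
    rows = [ln.split() for ln in lines[1:]]
    if len(rows) != len(letters) or any(len(r) != len(letters) for r in rows):
        raise ValueError(f"matrix file for {name} is not square")
    scores = np.zeros((len(ALPHABET), len(ALPHABET)), dtype=np.int64)
    for i, a in enumerate(letters):
        for j, b in enumerate(letters):
            scores[_INDEX[a], _INDEX[b]] = int(rows[i][j])
    return SubstitutionMatrix(name, scores)


def _from_biopython(bp_name: str, name: str, scale: float = 1.0) -> SubstitutionMatrix:
    table = substitution_matrices.load(bp_name)
    scores = np.zeros((len(ALPHABET), len(ALPHABET)), dtype=np.int64)
    for a in ALPHABET[:-1]:  # X handled below: 0 against everything
        for b in ALPHABET[:-1]:
            scores[_INDEX[a], _INDEX[b]] = round(float(table[a, b]) * scale)
    return SubstitutionMatrix(name, scores)


def load_matrix(name: str) -> SubstitutionMatrix:
    """Load PHAT, BLOSUM62 or GONNET250 (case-insensitive)."""
    key = name.upper()
    if key == "PHAT":
        text = (
            resources.files("memsa").joinpath("data/phat_75_73.txt").read_text()
        )
        return parse_matrix_file(text, "PHAT")
    if key == "BLOSUM62":
        return _from_biopython("BLOSUM62", "BLOSUM62")
    if key == "GONNET250":
        # Gonnet PAM250 log-odds are real-valued; store x10 rounded to keep
        # the DP integer-exact.
        return _from_biopython("GONNET1992", "GONNET250", scale=10.0)
    raise ValueError(
        f"unknown matrix {name!r}; valid names: {', '.join(MATRIX_NAMES)}"
    )
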