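"""Hydrophobicity substitution matrix and length-normalized global alignment.

The comparison score between two amino acids is derived from the Eisenberg
consensus hydrophobicity scale: with Δ(a, b) = |h_a − h_b| and Δmax the largest
difference over all residue pairs,

    score(a, b) = round(20 · (1 − Δ(a, b) / Δmax)),

so identical residues score 20 and the most dissimilar pair scores 0.  Two
subsequences are compared by affine-gap global alignment (gap open 10, gap
extend 0.5, end gaps free — the EMBOSS needle defaults) under this matrix, and
the optimal raw score is divided by the number of alignment columns.  Two
identical sequences therefore always score exactly 20, the scale maximum.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

#: Canonical residue order of the substitution matrix.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_NEG = -1e30  # effectively -inf for the DP; finite to keep arithmetic simple


def load_scale(source=None) -> dict[str, float]:
    """Load a hydrophobicity scale (residue → kcal/mol).

    Without arguments the packaged Eisenberg consensus scale is returned.
    ``source`` may be a path to a two-column TSV (residue, value) to use any
    other 20-entry scale.
    """
    if source is None:
        text = (
            resources.files("colnet").joinpath("data/eisenberg_consensus.tsv").read_text()
        )
    elif isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    values: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        residue, value = line.split("\t")
        values[residue.strip().upper()] = float(value)
    _check_scale(values)
    return values


def _check_scale(values: Mapping[str, float]) -> None:
    missing = set(ALPHABET) - set(values)
    extra = set(values) - set(ALPHABET)
    if missing or extra:
        raise ValueError(
            f"hydrophobicity scale must cover exactly the 20 amino acids "
            f"(missing: {sorted(missing)}, unexpected: {sorted(extra)})"
        )
    if not all(np.isfinite(v) for v in values.values()):
        raise ValueError("hydrophobicity scale contains non-finite values")


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric 20×20 integer similarity table with entries in [0, 20]."""

    alphabet: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores)
        n = len(self.alphabet)
        if scores.shape != (n, n):
            raise ValueError(f"score table must be {n}x{n}")
        if not np.array_equal(scores, scores.T):
            raise ValueError("substitution matrix must be symmetric")
        if not np.issubdtype(scores.dtype, np.integer):
            raise ValueError("substitution scores must be integers")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(
            self, "_index", {aa: i for i, aa in enumerate(self.alphabet)}
        )

    def score(self, a: str, b: str) -> int:
        try:
            return int(self.scores[self._index[a], self._index[b]])
        except KeyError as exc:
            raise KeyError(f"residue {exc.args[0]!r} not in matrix alphabet") from None

    def to_tsv(self, destination) -> None:
        frame = pd.DataFrame(
            self.scores, index=list(self.alphabet), columns=list(self.alphabet)
        )
        frame.to_csv(destination, sep="\t")

    @classmethod
    def from_tsv(cls, source) -> "SubstitutionMatrix":
        frame = pd.read_csv(source, sep="\t", index_col=0)
        alphabet = "".join(frame.index)
        if list(frame.columns) != list(frame.index):
            raise ValueError("matrix TSV row and column labels differ")
        return cls(alphabet=alphabet, scores=frame.to_numpy(dtype=int))


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # "rounded to the next integer": half values round away from zero.
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def build_substitution_matrix(
    scale: Mapping[str, float], max_score: int = 20
) -> SubstitutionMatrix:
    """Turn a hydrophobicity scale into the pipeline's substitution matrix.

    The pairwise hydrophobicity differences are inverted and min-max scaled so
    that a zero difference (identical residues) maps to ``max_score`` and the
    largest difference maps to 0, then rounded to integers.
    """
    _check_scale(scale)
    h = np.array([scale[aa] for aa in ALPHABET], dtype=float)
    delta = np.abs(h[:, None] - h[None, :])
    dmax = delta.max()
    if dmax == 0:
        raise ValueError("degenerate scale: all hydrophobicity values are equal")
    scores = _round_half_away(max_score * (1.0 - delta / dmax)).astype(int)
    return SubstitutionMatrix(alphabet=ALPHABET, scores=scores)


@dataclass(frozen=True)
class GapParams:
    """Affine gap model of the global alignment.

    A gap of length k costs ``open + (k−1)·extend`` by default; setting
    ``extend_on_open`` charges ``open + k·extend`` instead (both conventions
    are in circulation for the EMBOSS parameterisation).  With
    ``end_gaps_penalized`` False, leading and trailing gaps are free but still
    appear as columns of the reported alignment.
    """

    open: float = 10.0
    extend: float = 0.5
    end_gaps_penalized: bool = False
    extend_on_open: bool = False

    def __post_init__(self) -> None:
        if self.open < 0 or self.extend < 0:
            raise ValueError("gap costs must be non-negative")

    @property
    def first_residue_cost(self) -> float:
        return self.open + (self.extend if self.extend_on_open else 0.0)


@dataclass(frozen=True)
class AlignmentResult:
    """A global alignment and its length-normalized similarity."""

    aligned_a: str
    aligned_b: str
    raw_score: float
    n_columns: int
    normalized_similarity: float


def global_align(
    a: str, b: str, m: SubstitutionMatrix, g: GapParams = GapParams()
) -> AlignmentResult:
    """Score-maximal affine-gap global alignment of two residue strings.

    Gotoh three-state dynamic programming with deterministic traceback
    (preference on ties: diagonal > up > left).  The normalized similarity is
    the raw optimum divided by the number of alignment columns, end-gap
    columns included.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    try:
        ai = [m._index[c] for c in a]
        bi = [m._index[c] for c in b]
    except KeyError as exc:
        raise KeyError(f"residue {exc.args[0]!r} not in matrix alphabet") from None

    sub = m.scores
    la, lb = len(a), len(b)
    go = g.first_residue_cost
    ge = g.extend
    free_ends = not g.end_gaps_penalized

    # S_M: a[i-1] aligned to b[j-1]; S_X: gap in b (consumes a, "up");
    # S_Y: gap in a (consumes b, "left").
    SM = np.full((la + 1, lb + 1), _NEG)
    SX = np.full((la + 1, lb + 1), _NEG)
    SY = np.full((la + 1, lb + 1), _NEG)
    SM[0, 0] = 0.0
    for i in range(1, la + 1):
        SX[i, 0] = 0.0 if free_ends else -(go + (i - 1) * ge)
    for j in range(1, lb + 1):
        SY[0, j] = 0.0 if free_ends else -(go + (j - 1) * ge)

    for i in range(1, la + 1):
        smrow, sxrow, syrow = SM[i], SX[i], SY[i]
        smprev, sxprev, syprev = SM[i - 1], SX[i - 1], SY[i - 1]
        subrow = sub[ai[i - 1]]
        for j in range(1, lb + 1):
            smrow[j] = subrow[bi[j - 1]] + max(
                smprev[j - 1], sxprev[j - 1], syprev[j - 1]
            )
            sxrow[j] = max(smprev[j] - go, sxprev[j] - ge, syprev[j] - go)
            syrow[j] = max(smrow[j - 1] - go, sxrow[j - 1] - go, syrow[j - 1] - ge)

    if free_ends:
        # Trailing gaps are free: finish anywhere on the last row/column and
        # pad the remainder with gap columns.  Candidate order fixes ties:
        # the corner first, then the last row right-to-left, then the last
        # column bottom-to-top.
        candidates = [(la, lb)]
        candidates += [(la, j) for j in range(lb - 1, -1, -1)]
        candidates += [(i, lb) for i in range(la - 1, -1, -1)]
        best_val = _NEG
        end = (la, lb)
        for i, j in candidates:
            val = max(SM[i, j], SX[i, j], SY[i, j])
            if val > best_val:
                best_val, end = val, (i, j)
        raw = best_val
    else:
        end = (la, lb)
        raw = max(SM[la, lb], SX[la, lb], SY[la, lb])

    cols_a: list[str] = []
    cols_b: list[str] = []
    i, j = end
    # trailing free gap columns
    for k in range(lb - 1, j - 1, -1):
        cols_a.append("-")
        cols_b.append(b[k])
    for k in range(la - 1, i - 1, -1):
        cols_a.append(a[k])
        cols_b.append("-")

    # choose the state at the end cell: diagonal > up > left
    here = max(SM[i, j], SX[i, j], SY[i, j])
    for state, val in (("M", SM[i, j]), ("X", SX[i, j]), ("Y", SY[i, j])):
        if val == here:
            break

    while i > 0 or j > 0:
        if state == "M":
            cols_a.append(a[i - 1])
            cols_b.append(b[j - 1])
            target = SM[i, j] - sub[ai[i - 1], bi[j - 1]]
            i, j = i - 1, j - 1
            for state, val in (("M", SM[i, j]), ("X", SX[i, j]), ("Y", SY[i, j])):
                if val == target:
                    break
        elif state == "X":
            cols_a.append(a[i - 1])
            cols_b.append("-")
            if j == 0:
                i -= 1  # leading/boundary gap run in b
                continue
            target = SX[i, j]
            i -= 1
            for state, val in (
                ("M", SM[i, j] - go),
                ("X", SX[i, j] - ge),
                ("Y", SY[i, j] - go),
            ):
                if val == target:
                    break
        else:  # "Y"
            cols_a.append("-")
            cols_b.append(b[j - 1])
            if i == 0:
                j -= 1
                continue
            target = SY[i, j]
            j -= 1
            for state, val in (
                ("M", SM[i, j] - go),
                ("X", SX[i, j] - go),
                ("Y", SY[i, j] - ge),
            ):
                if val == target:
                    break

    aligned_a = "".join(reversed(cols_a))
    aligned_b = "".join(reversed(cols_b))
    n_columns = len(aligned_a)
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        raw_score=float(raw),
        n_columns=n_columns,
        normalized_similarity=float(raw) / n_columns,
    )


def similarity(
    a: str, b: str, m: SubstitutionMatrix, g: GapParams = GapParams()
) -> float:
    """Length-normalized global-alignment similarity of two residue strings."""
    return global_align(a, b, m, g).normalized_similarity
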