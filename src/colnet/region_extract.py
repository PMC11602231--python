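"""Greedy extraction of fixed-length high-confidence subsequences.

Repetitive (Gly-X-Y)ₙ collagen cores receive very low model confidence while
terminal domains are predicted well; extracting only high-confidence windows
therefore focuses the comparison on the informative parts of each α-chain.

The extraction is greedy with sentinel masking: the length-L window with the
highest mean confidence is emitted, its confidence values are overwritten with
a large negative sentinel so no overlapping window can be selected again, and
the search repeats until no window reaches the confidence threshold.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .seq_io import MASK_SENTINEL, Condition, ConfidenceSequence, subsequence_header


class Orientation(str, Enum):
    FORWARD = "fwd"
    REVERSED = "rev"


@dataclass(frozen=True)
class Subsequence:
    """A fixed-length subsequence extracted from one α-chain.

    ``start``/``end`` index the condition-applied parent sequence (0-based,
    half-open).  A REVERSED record holds the exact reversal of its FORWARD
    twin's residues; interval and provenance are shared between the twins.
    """

    parent_id: str
    start: int
    end: int
    residues: str
    mean_confidence: float
    orientation: Orientation
    condition: Condition
    length_param: int
    conf_threshold: float

    def __post_init__(self) -> None:
        if self.end - self.start != self.length_param:
            raise ValueError(
                f"{self.parent_id}: interval [{self.start},{self.end}) does not "
                f"match length parameter {self.length_param}"
            )
        if len(self.residues) != self.length_param:
            raise ValueError(f"{self.parent_id}: residues length mismatch")

    @property
    def header(self) -> str:
        return subsequence_header(self)


@dataclass(frozen=True)
class ExtractionParams:
    """Window length L and mean-confidence threshold of one extraction run."""

    length: int
    conf_threshold: float
    mask_sentinel: float = MASK_SENTINEL

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"window length must be >= 1, got {self.length}")
        if not 0.0 <= self.conf_threshold <= 100.0:
            raise ValueError(
                f"confidence threshold must be in [0, 100], got {self.conf_threshold}"
            )


def extract_regions(
    seq: ConfidenceSequence,
    params: ExtractionParams,
    position_sort: bool = False,
) -> list[Subsequence]:
    """Greedily extract non-overlapping high-confidence windows of length L.

    Each round selects the window with the maximal mean confidence (leftmost on
    ties), emits it if that mean is >= the threshold, and masks its positions
    with the sentinel so overlapping windows can never be re-selected.  The
    result is in extraction order (descending emission-time mean) unless
    ``position_sort`` is set.

    Windows containing ``'X'`` residues are ineligible: hydrophobicity is
    undefined for unknown residues, so their positions are treated as
    sentinel-confidence.
    """
    L = params.length
    n = len(seq)
    if n < L:
        return []

    work = np.asarray(seq.confidence, dtype=float).copy()
    for i, aa in enumerate(seq.residues):
        if aa == "X":
            work[i] = params.mask_sentinel

    out: list[Subsequence] = []
    window = np.ones(L)
    while True:
        means = np.convolve(work, window, mode="valid") / L
        best = int(np.argmax(means))  # argmax is leftmost on ties
        best_mean = float(means[best])
        if best_mean < params.conf_threshold:
            break
        out.append(
            Subsequence(
                parent_id=seq.chain_id,
                start=best,
                end=best + L,
                residues=seq.residues[best : best + L],
                mean_confidence=best_mean,
                orientation=Orientation.FORWARD,
                condition=seq.condition,
                length_param=L,
                conf_threshold=params.conf_threshold,
            )
        )
        work[best : best + L] = params.mask_sentinel

    if position_sort:
        out.sort(key=lambda s: s.start)
    return out


def add_reversed(subs: Sequence[Subsequence]) -> list[Subsequence]:
    """Return each FORWARD record followed by its REVERSED twin.

    Proteins have no complement, so "reversed" means plain string reversal;
    reversed records are marked ``rev`` in their FASTA name.  Passing an
    already-REVERSED record is an error (no double reversal).
    """
    out: list[Subsequence] = []
    for sub in subs:
        if sub.orientation is not Orientation.FORWARD:
            raise ValueError(f"cannot reverse an already-reversed record: {sub.header}")
        out.append(sub)
        out.append(replace(sub, residues=sub.residues[::-1], orientation=Orientation.REVERSED))
    return out


def surviving_chains(
    all_chains: Iterable[ConfidenceSequence], params: ExtractionParams
) -> set[str]:
    """Chain ids for which extraction yields at least one subsequence.

    The complement of this set is the excluded-chain list for the parameter
    pair (L, confidence threshold).
    """
    return {
        seq.chain_id for seq in all_chains if extract_regions(seq, params)
    }


def extraction_table(subs: Sequence[Subsequence]) -> pd.DataFrame:
    """Extraction log: one row per subsequence, in the given order."""
    return pd.DataFrame(
        {
            "chain_id": [s.parent_id for s in subs],
            "start": [s.start for s in subs],
            "end": [s.end for s in subs],
            "orientation": [s.orientation.value for s in subs],
            "mean_confidence": [s.mean_confidence for s in subs],
        }
    )


def read_fasta(source) -> list[Subsequence]:
    """Read subsequences back from a FASTA file written by seq_io.write_fasta.

    Provenance is recovered from the header grammar; the emission-time mean
    confidence is not encoded in the header and is restored as NaN.
    """
    if isinstance(source, (str, Path)):
        handle = open(source)
        close = True
    elif isinstance(source, str):  # pragma: no cover - unreachable, kept explicit
        handle = io.StringIO(source)
        close = False
    else:
        handle = source
        close = False
    try:
        out = []
        for record in SeqIO.parse(handle, "fasta"):
            parts = record.id.split("|")
            if len(parts) != 6:
                raise ValueError(f"unparseable subsequence header: {record.id}")
            parent, span, orient, cond, lpart, cpart = parts
            start, end = (int(x) for x in span.split("-"))
            out.append(
                Subsequence(
                    parent_id=parent,
                    start=start,
                    end=end,
                    residues=str(record.seq),
                    mean_confidence=float("nan"),
                    orientation=Orientation(orient),
                    condition=Condition(cond),
                    length_param=int(lpart[1:]),
                    conf_threshold=float(cpart[1:]),
                )
            )
        return out
    finally:
        if close:
            handle.close()
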