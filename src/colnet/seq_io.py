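"""Input/output of confidence-annotated collagen α-chain sequences.

Structure-prediction model files for collagen α-chains store the predicted
per-residue confidence (pLDDT, 0–100) in the B-factor column of a PDB file.
This module reads such files into :class:`ConfidenceSequence` objects, attaches
UniProt-style region features (signal peptide, propeptides, mature chain),
applies the three sequence conditions used throughout the pipeline, and writes
extracted subsequences to FASTA.

Coordinate conventions
----------------------
Internally every interval is 0-based, half-open.  Annotation tables arrive in
the UniProt convention (1-based, inclusive); the conversion happens once, in
:func:`read_annotations`, and nowhere else.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data.IUPACData import protein_letters_3to1
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .region_extract import Subsequence

logger = logging.getLogger(__name__)

#: Sentinel written into the confidence track to mask already-extracted regions.
MASK_SENTINEL = -1e9

_THREE_TO_ONE: dict[str, str] = {k.upper(): v for k, v in protein_letters_3to1.items()}

#: Residue-level feature types that may appear in annotation tables but play
#: no role in region selection; they are accepted and ignored.
IGNORED_FEATURE_TYPES = frozenset(
    {"mod_res", "modified_residue", "carbohyd", "disulfid", "crosslnk", "lipid"}
)


class PDBFormatError(ValueError):
    """Raised for model files the parser cannot interpret."""


class AnnotationError(ValueError):
    """Raised for invalid feature-annotation or family tables."""


class Condition(str, Enum):
    """The three sequence conditions an α-chain is analysed under."""

    WHOLE_SEQUENCE = "whole_sequence"
    WITHOUT_SIGNAL = "without_signal"
    ONLY_CHAIN = "only_chain"


@dataclass
class FeatureAnnotation:
    """Region features of one α-chain (0-based, half-open intervals).

    ``signal`` is the signal peptide at the N-terminus, ``propeptides`` the
    N-/C-terminal propeptides cleaved during maturation, and ``chain`` the
    mature chain region (UniProt "Chain" feature).
    """

    signal: tuple[int, int] | None = None
    propeptides: list[tuple[int, int]] = field(default_factory=list)
    chain: tuple[int, int] | None = None

    def validate(self, seq_len: int | None = None, chain_id: str = "?") -> None:
        intervals = list(self.propeptides)
        if self.signal is not None:
            intervals.append(self.signal)
        if self.chain is not None:
            intervals.append(self.chain)
        for start, end in intervals:
            if start < 0 or end <= start:
                raise AnnotationError(
                    f"{chain_id}: invalid interval [{start}, {end})"
                )
            if seq_len is not None and end > seq_len:
                raise AnnotationError(
                    f"{chain_id}: interval [{start}, {end}) exceeds sequence "
                    f"length {seq_len}"
                )
        if self.signal is not None and self.signal[0] != 0:
            raise AnnotationError(
                f"{chain_id}: signal peptide must start at the N-terminus"
            )
        ordered = sorted(self.propeptides)
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if s2 < e1:
                raise AnnotationError(
                    f"{chain_id}: overlapping propeptides [{s1},{e1}) and [{s2},{e2})"
                )
        if self.signal is not None and self.chain is not None:
            if _overlaps(self.signal, self.chain):
                raise AnnotationError(
                    f"{chain_id}: chain feature overlaps the signal peptide"
                )


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


@dataclass
class ConfidenceSequence:
    """One α-chain: residues plus a per-residue model-confidence track.

    ``confidence[i]`` is the predicted confidence (0–100) of ``residues[i]``,
    or :data:`MASK_SENTINEL` once the position has been masked by extraction.
    """

    chain_id: str
    residues: str
    confidence: list[float]
    features: FeatureAnnotation | None = None
    family: str = ""
    condition: Condition = Condition.WHOLE_SEQUENCE

    def __post_init__(self) -> None:
        if not self.chain_id:
            raise ValueError("chain_id must be non-empty")
        if len(self.residues) != len(self.confidence):
            raise ValueError(
                f"{self.chain_id}: residues ({len(self.residues)}) and confidence "
                f"({len(self.confidence)}) lengths differ"
            )
        for value in self.confidence:
            if value != MASK_SENTINEL and not 0.0 <= value <= 100.0:
                raise ValueError(
                    f"{self.chain_id}: confidence {value!r} outside [0, 100]"
                )

    def __len__(self) -> int:
        return len(self.residues)


def three_to_one(residue_name: str) -> str:
    """Map an uppercase 3-letter residue name to its 1-letter IUPAC code.

    Total function: the 20 standard amino acids map to their codes, everything
    else (including modified and unknown residues) maps to ``'X'``.
    """
    return _THREE_TO_ONE.get(residue_name.upper(), "X")


def parse_model_pdb(pdb_text: str, chain_id: str | None = None) -> ConfidenceSequence:
    """Parse a single-model, single-chain PDB file into a ConfidenceSequence.

    The per-residue confidence is taken from the B-factor of the residue's
    first atom (structure predictors write the same value on every atom of a
    residue, so the first atom is a robust choice even for truncated records).

    Parameters
    ----------
    pdb_text:
        Contents of the PDB file.
    chain_id:
        Identifier for the resulting sequence; defaults to the PDB chain name.
    """
    structure = gemmi.read_pdb_string(pdb_text)
    if len(structure) == 0:
        raise PDBFormatError("no ATOM records found")
    if len(structure) > 1:
        raise PDBFormatError(
            f"expected a single model, found {len(structure)}"
        )
    model = structure[0]
    chains = [ch for ch in model if len(ch) > 0]
    if not chains:
        raise PDBFormatError("no ATOM records found")
    if len(chains) > 1:
        names = ", ".join(ch.name for ch in chains)
        raise PDBFormatError(f"expected a single chain, found: {names}")
    chain = chains[0]

    by_number: dict[int, tuple[str, float]] = {}
    for residue in chain:
        num = residue.seqid.num
        name = residue.name.upper()
        # B-factor column carries two decimals; rounding removes the
        # single-precision noise of the parser's float storage.
        bfac = round(float(residue[0].b_iso), 2)
        if num in by_number:
            if by_number[num][0] != name:
                raise PDBFormatError(
                    f"residue {num} named both {by_number[num][0]} and {name}"
                )
            continue
        by_number[num] = (name, bfac)

    numbers = sorted(by_number)
    residues = "".join(three_to_one(by_number[n][0]) for n in numbers)
    confidence = [by_number[n][1] for n in numbers]
    return ConfidenceSequence(
        chain_id=chain_id or chain.name or "A",
        residues=residues,
        confidence=confidence,
    )


def read_annotations(
    table_text: str,
    seq_lengths: Mapping[str, int] | None = None,
) -> dict[str, FeatureAnnotation]:
    """Read a feature-annotation table into per-chain FeatureAnnotations.

    The table is TSV with columns ``chain_id, feature_type, start, end`` where
    ``feature_type`` is one of ``signal``, ``propeptide`` or ``chain`` and
    coordinates are 1-based inclusive (UniProt convention).  Residue-level PTM
    feature types (:data:`IGNORED_FEATURE_TYPES`) are accepted and ignored.

    When ``seq_lengths`` is supplied, intervals are range-checked against it.
    """
    frame = pd.read_csv(io.StringIO(table_text), sep="\t", comment="#", dtype=str)
    required = {"chain_id", "feature_type", "start", "end"}
    missing = required - set(frame.columns)
    if missing:
        raise AnnotationError(f"annotation table lacks columns: {sorted(missing)}")

    annotations: dict[str, FeatureAnnotation] = {}
    for row_idx, row in frame.iterrows():
        cid = str(row["chain_id"])
        ftype = str(row["feature_type"]).strip().lower()
        if ftype in IGNORED_FEATURE_TYPES:
            continue
        if ftype not in {"signal", "propeptide", "chain"}:
            raise AnnotationError(
                f"chain {cid}, row {row_idx}: unknown feature_type {ftype!r}"
            )
        try:
            start1, end1 = int(row["start"]), int(row["end"])
        except (TypeError, ValueError) as exc:
            raise AnnotationError(
                f"chain {cid}, row {row_idx}: non-integer coordinates"
            ) from exc
        if start1 < 1 or end1 < start1:
            raise AnnotationError(
                f"chain {cid}, row {row_idx}: invalid range {start1}..{end1}"
            )
        interval = (start1 - 1, end1)  # 1-based inclusive -> 0-based half-open
        ann = annotations.setdefault(cid, FeatureAnnotation())
        if ftype == "signal":
            if ann.signal is not None:
                raise AnnotationError(f"chain {cid}, row {row_idx}: duplicate signal")
            ann.signal = interval
        elif ftype == "chain":
            if ann.chain is not None:
                raise AnnotationError(
                    f"chain {cid}, row {row_idx}: duplicate chain feature"
                )
            ann.chain = interval
        else:
            ann.propeptides.append(interval)

    for cid, ann in annotations.items():
        seq_len = seq_lengths.get(cid) if seq_lengths is not None else None
        ann.validate(seq_len=seq_len, chain_id=cid)
    return annotations


def read_family_table(table_text: str) -> pd.DataFrame:
    """Read the chain → (collagen, family, colour) classification table.

    TSV columns: ``chain_id, collagen_id, family, color`` with one row per
    α-chain; ``color`` is a ``#RRGGBB`` hex string used for network nodes.
    """
    frame = pd.read_csv(io.StringIO(table_text), sep="\t", comment="#", dtype=str)
    required = {"chain_id", "collagen_id", "family", "color"}
    missing = required - set(frame.columns)
    if missing:
        raise AnnotationError(f"family table lacks columns: {sorted(missing)}")
    if frame["chain_id"].duplicated().any():
        dupes = frame.loc[frame["chain_id"].duplicated(), "chain_id"].tolist()
        raise AnnotationError(f"duplicate chain ids in family table: {dupes}")
    return frame.reset_index(drop=True)


def apply_condition(seq: ConfidenceSequence, condition: Condition) -> ConfidenceSequence:
    """Apply one of the three sequence conditions to an α-chain.

    WHOLE_SEQUENCE returns the sequence unchanged; WITHOUT_SIGNAL removes the
    signal-peptide interval; ONLY_CHAIN removes the signal and every
    propeptide.  Removal drops both residues and their confidence values and
    concatenates the remainder in the original order.  Feature coordinates are
    no longer valid on the shortened sequence and are cleared in the output.

    Chains lacking a required annotation (e.g. transmembrane collagens have no
    signal peptide) pass through unchanged with a logged warning.
    """
    if condition == Condition.WHOLE_SEQUENCE:
        return replace(seq, condition=condition)

    features = seq.features
    if features is None:
        logger.warning(
            "%s: no feature annotation; %s leaves the sequence unchanged",
            seq.chain_id,
            condition.value,
        )
        return replace(seq, features=None, condition=condition)

    remove: list[tuple[int, int]] = []
    if features.signal is not None:
        remove.append(features.signal)
    elif condition in (Condition.WITHOUT_SIGNAL, Condition.ONLY_CHAIN):
        logger.warning(
            "%s: no signal annotation; nothing removed for the signal",
            seq.chain_id,
        )
    if condition == Condition.ONLY_CHAIN:
        if features.propeptides:
            remove.extend(features.propeptides)
        else:
            logger.warning(
                "%s: no propeptide annotations; nothing removed for propeptides",
                seq.chain_id,
            )

    keep = np.ones(len(seq), dtype=bool)
    for start, end in remove:
        keep[start:end] = False
    residues = "".join(np.array(list(seq.residues))[keep])
    confidence = [c for c, k in zip(seq.confidence, keep) if k]
    return ConfidenceSequence(
        chain_id=seq.chain_id,
        residues=residues,
        confidence=confidence,
        features=None,
        family=seq.family,
        condition=condition,
    )


def load_dataset(
    models_dir,
    annotations_path=None,
    families_path=None,
) -> tuple[list[ConfidenceSequence], pd.DataFrame | None]:
    """Load a directory of PDB model files plus annotation/family tables.

    Every ``*.pdb`` file in ``models_dir`` becomes one ConfidenceSequence whose
    chain id is the file's stem.  Returns the sequences (annotated and
    family-labelled where tables are given) and the family table.
    """
    models_dir = Path(models_dir)
    paths = sorted(models_dir.glob("*.pdb"))
    if not paths:
        raise FileNotFoundError(f"no .pdb files in {models_dir}")
    sequences = [parse_model_pdb(p.read_text(), chain_id=p.stem) for p in paths]

    if annotations_path is not None:
        lengths = {s.chain_id: len(s) for s in sequences}
        annotations = read_annotations(Path(annotations_path).read_text(), lengths)
        for seq in sequences:
            seq.features = annotations.get(seq.chain_id)

    family_map = None
    if families_path is not None:
        family_map = read_family_table(Path(families_path).read_text())
        fam_of = dict(zip(family_map["chain_id"], family_map["family"]))
        for seq in sequences:
            seq.family = fam_of.get(seq.chain_id, "")
    return sequences, family_map


def subsequence_header(sub: "Subsequence") -> str:
    """FASTA header for a subsequence record.

    Grammar: ``{chain_id}|{start}-{end}|{orientation}|{condition}|L{length}|C{conf}``
    with orientation ``fwd`` or ``rev`` (reversed records are marked ``rev``).
    """
    return (
        f"{sub.parent_id}|{sub.start}-{sub.end}|{sub.orientation.value}|"
        f"{sub.condition.value}|L{sub.length_param}|C{sub.conf_threshold:g}"
    )


def write_fasta(subsequences: Iterable["Subsequence"], destination) -> None:
    """Write subsequences to FASTA using the header grammar above.

    ``destination`` may be a path or a text file object.  Duplicate headers
    (identical provenance) are an error.
    """
    records = []
    seen: set[str] = set()
    for sub in subsequences:
        header = subsequence_header(sub)
        if header in seen:
            raise ValueError(f"duplicate FASTA header: {header}")
        seen.add(header)
        records.append(SeqRecord(Seq(sub.residues), id=header, description=""))
    if isinstance(destination, (str, Path)):
        with open(destination, "w") as handle:
            SeqIO.write(records, handle, "fasta")
    else:
        SeqIO.write(records, destination, "fasta")
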