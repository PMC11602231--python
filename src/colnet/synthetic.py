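"""Collagen-like synthetic datasets for exercising the whole pipeline.

Real collagen α-chains have a repetitive (Gly-X-Y)ₙ core that structure
predictors assign very low confidence, flanked by well-predicted terminal
domains, and family membership shows up as conserved terminal motifs.  The
generator emulates exactly that statistical structure: each family owns an
ancestor motif drawn from a family-specific hydrophobicity band, every chain
carries a lightly mutated copy of it embedded in a high-confidence region,
and the core confidences are drawn from a low-confidence distribution.

The hydrophobicity bands are spaced so that, under the packaged substitution
matrix, within-family motif similarity sits near the scale maximum (≈ 19–20)
while motifs from different bands align at ≈ 16.5 or below; a network
threshold of 17.5 therefore separates the planted families.

The first family mirrors fibrillar collagens: its motif lives in the
N-propeptide, so the ONLY_CHAIN condition (which removes propeptides) leaves
those chains without any high-confidence window.  One family mirrors
transmembrane collagens and carries no signal peptide.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import protein_letters_1to3

from .hydro_align import ALPHABET
from .litnet import HitCountMatrix
from .seq_io import MASK_SENTINEL, ConfidenceSequence, FeatureAnnotation

_ONE_TO_THREE = {k.upper(): v.upper() for k, v in protein_letters_1to3.items()}
_ONE_TO_THREE["X"] = "UNK"


@dataclass(frozen=True)
class FamilySpec:
    name: str
    color: str
    pool: str  # residues of the family's hydrophobicity band
    motif_in_propeptide: bool = False
    has_signal: bool = True


#: Six families patterned on the six collagen groups.  Pools are bands of the
#: Eisenberg scale with inter-band gaps large enough to keep cross-family
#: alignment similarity below the within-family level.
FAMILY_SPECS: tuple[FamilySpec, ...] = (
    FamilySpec("fibrillar", "#800080", "IF", motif_in_propeptide=True),
    FamilySpec("facit", "#00FFFF", "MA"),
    FamilySpec("network", "#008000", "TS"),
    FamilySpec("transmembrane", "#FFFF00", "K", has_signal=False),
    FamilySpec("endostatin", "#FFA500", "EQND"),
    FamilySpec("other", "#FF0000", "R"),
)

_CORE_XY = "PAQS"  # X/Y positions of the (Gly-X-Y)n repeat


@dataclass
class SynthParams:
    """Geometry, noise and reproducibility knobs of the generator.

    Defaults mirror the real dataset's scale: 6 families totalling 44
    α-chains, 30-residue family motifs (matching the default subsequence
    length), high-confidence motifs (mean 90) against low-confidence cores
    (mean 30) so the default confidence threshold of 70 selects exactly the
    motif windows.
    """

    n_families: int = 6
    chains_per_family: tuple[int, ...] = (11, 9, 8, 7, 5, 4)
    signal_len: int = 20
    propeptide_len: int = 30
    core_repeats: int = 80
    motif_len: int = 30
    high_conf_mean: float = 90.0
    high_conf_sd: float = 3.0
    low_conf_mean: float = 30.0
    low_conf_sd: float = 8.0
    within_family_mutation_rate: float = 0.02
    between_family_divergence: float = 1.0
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_families <= len(FAMILY_SPECS):
            raise ValueError(
                f"n_families must be in [1, {len(FAMILY_SPECS)}]"
            )
        if len(self.chains_per_family) != self.n_families:
            raise ValueError("chains_per_family must have n_families entries")
        for name in ("signal_len", "propeptide_len", "core_repeats", "motif_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.motif_len > self.propeptide_len:
            raise ValueError(
                "impossible geometry: motif_len exceeds propeptide_len "
                "(the motif must fit inside its flank)"
            )
        for name in (
            "within_family_mutation_rate",
            "between_family_divergence",
            "indel_rate",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("high_conf_mean", "low_conf_mean"):
            if not 0.0 <= getattr(self, name) <= 100.0:
                raise ValueError(f"{name} must be in [0, 100]")


def _random_residues(rng: np.random.Generator, n: int, pool: str = ALPHABET) -> str:
    return "".join(rng.choice(list(pool), size=n)) if n else ""


def _mutate(rng: np.random.Generator, residues: str, rate: float) -> str:
    out = list(residues)
    hits = rng.random(len(out)) < rate
    for i in np.flatnonzero(hits):
        out[i] = rng.choice(list(ALPHABET))
    return "".join(out)


def _indel(rng: np.random.Generator, residues: str, rate: float) -> str:
    if rate <= 0:
        return residues
    out: list[str] = []
    for aa in residues:
        r = rng.random()
        if r < rate / 2:
            continue  # deletion
        out.append(aa)
        if r > 1 - rate / 2:
            out.append(aa)  # duplication
    return "".join(out)


def _confidence(
    rng: np.random.Generator, n: int, mean: float, sd: float
) -> list[float]:
    values = np.clip(rng.normal(mean, sd, size=n), 0.0, 100.0)
    # two decimals: the resolution of the PDB B-factor column, so confidence
    # tracks survive a PDB round trip bit-exactly
    return [round(float(v), 2) for v in values]


def _collagen_sizes(n_chains: int) -> list[int]:
    sizes = []
    remaining = n_chains
    while remaining > 0:
        take = min(3, remaining)
        sizes.append(take)
        remaining -= take
    return sizes


def generate_dataset(
    p: SynthParams,
) -> tuple[list[ConfidenceSequence], dict[str, FeatureAnnotation], pd.DataFrame]:
    """Generate (sequences, annotations, family_map) for one parameter set.

    Fully reproducible from ``p.seed``.  Every chain is
    ``[signal][flank+motif][(G-X-Y)n core][tail]``; for the fibrillar-like
    family the motif-bearing flank and the tail are annotated as propeptides
    and only the core is the UniProt-style "Chain", while for the other
    families the motif is part of the chain region.
    """
    rng = np.random.default_rng(p.seed)
    sequences: list[ConfidenceSequence] = []
    annotations: dict[str, FeatureAnnotation] = {}
    family_rows = []
    collagen_counter = 0

    for f in range(p.n_families):
        spec = FAMILY_SPECS[f]
        ancestor = "".join(
            rng.choice(list(spec.pool))
            if rng.random() < p.between_family_divergence
            else rng.choice(list(ALPHABET))
            for _ in range(p.motif_len)
        )
        chain_ids: list[str] = []
        for size in _collagen_sizes(p.chains_per_family[f]):
            collagen_counter += 1
            collagen_id = f"SCOL{collagen_counter}"
            for k in range(1, size + 1):
                chain_ids.append(f"{collagen_id}a{k}")
                family_rows.append(
                    {
                        "chain_id": f"{collagen_id}a{k}",
                        "collagen_id": collagen_id,
                        "family": spec.name,
                        "color": spec.color,
                    }
                )

        for cid in chain_ids:
            motif = _indel(
                rng,
                _mutate(rng, ancestor, p.within_family_mutation_rate),
                p.indel_rate,
            )
            signal = _random_residues(rng, p.signal_len if spec.has_signal else 0)
            pad = p.propeptide_len - len(ancestor)
            offset = int(rng.integers(0, pad + 1)) if pad > 0 else 0
            flank_pre = _random_residues(rng, offset)
            flank_post = _random_residues(rng, max(pad - offset, 0))
            core = "".join(
                "G" + _random_residues(rng, 2, _CORE_XY)
                for _ in range(p.core_repeats)
            )
            core = _mutate(rng, core, p.within_family_mutation_rate)
            tail = _random_residues(rng, p.motif_len)

            residues = signal + flank_pre + motif + flank_post + core + tail
            conf: list[float] = []
            conf += _confidence(rng, len(signal), p.low_conf_mean, p.low_conf_sd)
            conf += _confidence(rng, len(flank_pre), p.low_conf_mean, p.low_conf_sd)
            conf += _confidence(rng, len(motif), p.high_conf_mean, p.high_conf_sd)
            conf += _confidence(rng, len(flank_post), p.low_conf_mean, p.low_conf_sd)
            conf += _confidence(rng, len(core), p.low_conf_mean, p.low_conf_sd)
            conf += _confidence(rng, len(tail), p.low_conf_mean, p.low_conf_sd)

            sig_end = len(signal)
            flank_end = sig_end + len(flank_pre) + len(motif) + len(flank_post)
            core_end = flank_end + len(core)
            total = len(residues)
            if spec.motif_in_propeptide:
                ann = FeatureAnnotation(
                    signal=(0, sig_end) if sig_end else None,
                    propeptides=[(sig_end, flank_end), (core_end, total)],
                    chain=(flank_end, core_end),
                )
            else:
                ann = FeatureAnnotation(
                    signal=(0, sig_end) if sig_end else None,
                    propeptides=[],
                    chain=(sig_end, total),
                )
            ann.validate(seq_len=total, chain_id=cid)
            annotations[cid] = ann
            sequences.append(
                ConfidenceSequence(
                    chain_id=cid,
                    residues=residues,
                    confidence=conf,
                    features=ann,
                    family=spec.name,
                )
            )

    family_map = pd.DataFrame(
        family_rows, columns=["chain_id", "collagen_id", "family", "color"]
    )
    return sequences, annotations, family_map


def annotations_table_text(annotations: dict[str, FeatureAnnotation]) -> str:
    """Render annotations as the TSV read by ``seq_io.read_annotations``.

    Coordinates are converted back to the 1-based inclusive input convention.
    """
    lines = ["chain_id\tfeature_type\tstart\tend"]
    for cid in sorted(annotations):
        ann = annotations[cid]
        if ann.signal is not None:
            lines.append(f"{cid}\tsignal\t{ann.signal[0] + 1}\t{ann.signal[1]}")
        for start, end in ann.propeptides:
            lines.append(f"{cid}\tpropeptide\t{start + 1}\t{end}")
        if ann.chain is not None:
            lines.append(f"{cid}\tchain\t{ann.chain[0] + 1}\t{ann.chain[1]}")
    return "\n".join(lines) + "\n"


def write_model_pdb(seq: ConfidenceSequence, destination) -> None:
    """Write a sequence as a minimal single-chain PDB model.

    One CA atom per residue with the confidence in the B-factor column;
    ``seq_io.parse_model_pdb`` inverts this exactly.  Masked (sentinel)
    confidences cannot be serialized.
    """
    lines = []
    for i, (aa, conf) in enumerate(zip(seq.residues, seq.confidence), start=1):
        if conf == MASK_SENTINEL:
            raise ValueError(
                f"{seq.chain_id}: masked confidence at residue {i} is not serializable"
            )
        res3 = _ONE_TO_THREE.get(aa, "UNK")
        x = 3.8 * i
        lines.append(
            f"ATOM  {i:5d}  CA  {res3:3s} A{i:4d}    "
            f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}{1.0:6.2f}{conf:6.2f}          "
            f" C"
        )
    lines.append("TER")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if isinstance(destination, (str, Path)):
        Path(destination).write_text(text)
    else:
        destination.write(text)


def write_dataset(
    sequences: list[ConfidenceSequence],
    annotations: dict[str, FeatureAnnotation],
    family_map: pd.DataFrame,
    out_dir,
) -> None:
    """Write a generated dataset in the formats the pipeline reads.

    ``<out_dir>/models/<chain_id>.pdb`` per chain, plus ``annotations.tsv``
    and ``families.tsv``.
    """
    out_dir = Path(out_dir)
    models = out_dir / "models"
    models.mkdir(parents=True, exist_ok=True)
    for seq in sequences:
        write_model_pdb(seq, models / f"{seq.chain_id}.pdb")
    (out_dir / "annotations.tsv").write_text(annotations_table_text(annotations))
    family_map.to_csv(out_dir / "families.tsv", sep="\t", index=False)


def generate_hit_counts(
    family_map: pd.DataFrame,
    base_hits: int = 20,
    within_boost: float = 10.0,
    seed: int = 0,
) -> HitCountMatrix:
    """Synthetic literature hit counts concentrated within families.

    Off-diagonal counts are Poisson: mean ``base_hits`` between families and
    ``base_hits × within_boost`` within a family (chains of one family are
    co-cited far more often).  Diagonal (single-term) counts exceed every
    off-diagonal count, as single keywords always return the most hits.
    """
    if within_boost <= 1:
        raise ValueError("within_boost must be > 1")
    rng = np.random.default_rng(seed)
    labels = list(family_map["chain_id"])
    fam = dict(zip(family_map["chain_id"], family_map["family"]))
    n = len(labels)
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            mean = base_hits * (within_boost if fam[labels[i]] == fam[labels[j]] else 1)
            counts[i, j] = counts[j, i] = rng.poisson(mean)
    top = counts.max()
    for i in range(n):
        counts[i, i] = top + 1 + rng.poisson(base_hits * within_boost)
    return HitCountMatrix(labels=labels, counts=counts)
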