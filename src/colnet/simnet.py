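"""All-vs-all similarity, matrix compression, networks and the parameter sweep.

The subsequence-level similarity table is compressed with the max rule: the
similarity between two α-chains (or two collagen types) is the maximum
similarity over all comparisons between their subsequences.  Thresholding the
compressed matrix yields weighted networks whose connected components are the
subnetworks discussed throughout the analysis.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .hydro_align import GapParams, SubstitutionMatrix, similarity
from .region_extract import (
    ExtractionParams,
    Orientation,
    Subsequence,
    add_reversed,
    extract_regions,
)
from .seq_io import Condition, ConfidenceSequence, apply_condition

logger = logging.getLogger(__name__)

#: Node colour for chains absent from the family table.
DEFAULT_FAMILY = "other"
DEFAULT_COLOR = "#FF0000"


def default_network_thresholds(inclusive: bool = False) -> np.ndarray:
    """The network-threshold grid: 12 to 20 in steps of 0.25.

    By default the grid is half-open ([12, 20), 32 values), which matches the
    published network count; ``inclusive`` adds the endpoint 20 (33 values).
    """
    stop = 20.25 if inclusive else 20.0
    return np.arange(12.0, stop, 0.25)


def pairwise_similarities(
    subs: Sequence[Subsequence],
    m: SubstitutionMatrix,
    g: GapParams = GapParams(),
) -> pd.DataFrame:
    """Similarity for every scored unordered pair of subsequence records.

    All records of one (condition, L, confidence) set — FORWARD and REVERSED —
    are compared, except a record against itself and REVERSED-vs-REVERSED
    pairs: by reversal invariance those equal the corresponding
    FORWARD-vs-FORWARD score and are skipped.  A record against its own
    reversed twin IS scored.
    """
    rows = []
    for sa, sb in itertools.combinations(subs, 2):
        if sa.orientation is Orientation.REVERSED and sb.orientation is Orientation.REVERSED:
            continue
        rows.append(
            {
                "id_a": sa.header,
                "id_b": sb.header,
                "parent_a": sa.parent_id,
                "parent_b": sb.parent_id,
                "similarity": similarity(sa.residues, sb.residues, m, g),
            }
        )
    return pd.DataFrame(
        rows, columns=["id_a", "id_b", "parent_a", "parent_b", "similarity"]
    )


@dataclass
class SimilarityMatrix:
    """Symmetric compressed similarity matrix at chain or collagen level."""

    level: str  # "chain" | "collagen"
    labels: list[str]
    values: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if len(set(self.labels)) != n:
            raise ValueError("matrix labels must be unique")
        if not np.allclose(values, values.T, equal_nan=True):
            raise ValueError("similarity matrix must be symmetric")
        self.values = values

    def entry(self, a: str, b: str) -> float:
        ia, ib = self.labels.index(a), self.labels.index(b)
        return float(self.values[ia, ib])

    def to_tsv(self, destination) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            destination, sep="\t"
        )

    @classmethod
    def from_tsv(cls, source, level: str = "chain") -> "SimilarityMatrix":
        frame = pd.read_csv(source, sep="\t", index_col=0)
        return cls(level=level, labels=[str(c) for c in frame.columns],
                   values=frame.to_numpy(dtype=float))


def _compress(
    table: pd.DataFrame,
    group_of: Callable[[str], str],
    level: str,
    params: dict | None = None,
) -> SimilarityMatrix:
    groups_a = table["parent_a"].map(group_of)
    groups_b = table["parent_b"].map(group_of)
    labels = sorted(set(groups_a) | set(groups_b))
    index = {g: i for i, g in enumerate(labels)}
    n = len(labels)
    values = np.full((n, n), np.nan)
    for ga, gb, sim in zip(groups_a, groups_b, table["similarity"]):
        ia, ib = index[ga], index[gb]
        if np.isnan(values[ia, ib]) or sim > values[ia, ib]:
            values[ia, ib] = values[ib, ia] = sim
    # Self-similarity defaults to the scale maximum when a group has no scored
    # same-group pair; the diagonal never produces edges either way.
    for i in range(n):
        if np.isnan(values[i, i]):
            values[i, i] = 20.0
    return SimilarityMatrix(level=level, labels=labels, values=values,
                            params=dict(params or {}))


def compress_chain_level(
    table: pd.DataFrame,
    chain_of: Callable[[str], str] | Mapping[str, str] | None = None,
    params: dict | None = None,
) -> SimilarityMatrix:
    """Max-rule compression of the pair table to an α-chain matrix.

    entry(c1, c2) is the maximum similarity over all scored record pairs with
    one record from chain c1 and one from c2.  ``chain_of`` maps a record's
    parent id to its chain id; by default the parent id is the chain id.
    """
    if table.empty:
        return SimilarityMatrix(level="chain", labels=[], values=np.empty((0, 0)),
                                params=dict(params or {}))
    fn = _as_callable(chain_of)
    return _compress(table, fn, "chain", params)


def compress_collagen_level(
    table: pd.DataFrame,
    collagen_of: Callable[[str], str] | Mapping[str, str],
    params: dict | None = None,
) -> SimilarityMatrix:
    """Max-rule compression to collagen types.

    entry(t1, t2) is the maximum similarity over the subsequences of all
    α-chains belonging to the compared collagen types; ``collagen_of`` maps a
    chain id to its collagen id.
    """
    if table.empty:
        return SimilarityMatrix(level="collagen", labels=[], values=np.empty((0, 0)),
                                params=dict(params or {}))
    fn = _as_callable(collagen_of)
    return _compress(table, fn, "collagen", params)


def _as_callable(mapping) -> Callable[[str], str]:
    if mapping is None:
        return lambda x: x
    if callable(mapping):
        return mapping
    return lambda x: mapping[x]


def compress_matrix(
    sm: SimilarityMatrix,
    group_of: Callable[[str], str] | Mapping[str, str],
    level: str,
) -> SimilarityMatrix:
    """Group an existing similarity matrix by taking entrywise group maxima.

    Compressing a chain-level matrix by the identity grouping is the identity;
    grouping it by collagen type equals collagen-level compression of the raw
    pair table (max of maxima).
    """
    fn = _as_callable(group_of)
    groups = [fn(lbl) for lbl in sm.labels]
    labels = sorted(set(groups))
    index = {g: i for i, g in enumerate(labels)}
    n = len(labels)
    values = np.full((n, n), np.nan)
    for i, gi in enumerate(groups):
        for j, gj in enumerate(groups):
            if i == j:
                continue
            a, b = index[gi], index[gj]
            v = sm.values[i, j]
            if np.isnan(values[a, b]) or v > values[a, b]:
                values[a, b] = values[b, a] = v
    for g, i in index.items():
        members = [k for k, gk in enumerate(groups) if gk == g]
        diag = sm.values[np.ix_(members, members)]
        values[i, i] = np.nanmax(diag) if diag.size else 20.0
    return SimilarityMatrix(level=level, labels=labels, values=values,
                            params=dict(sm.params))


def count_pairings(
    matrix: SimilarityMatrix, thresholds: Iterable[float] | None = None
) -> pd.DataFrame:
    """Number of unordered off-diagonal pairs with similarity >= τ, per τ.

    Default τ grid: 12 to 20 in steps of 0.25.  Counts are non-increasing in τ
    and bounded by C(n, 2).
    """
    if thresholds is None:
        thresholds = default_network_thresholds()
    taus = np.asarray(list(thresholds), dtype=float)
    iu = np.triu_indices(len(matrix.labels), k=1)
    upper = matrix.values[iu]
    counts = [int(np.sum(upper >= tau)) for tau in taus]
    return pd.DataFrame({"threshold": taus, "n_pairs": counts})


def _node_attrs(label: str, level: str, family_map: pd.DataFrame | None) -> dict:
    if family_map is not None:
        key = "chain_id" if level == "chain" else "collagen_id"
        rows = family_map[family_map[key] == label]
        if len(rows):
            row = rows.iloc[0]
            return {
                "collagen": str(row["collagen_id"]),
                "family": str(row["family"]),
                "color": str(row["color"]),
                "graphics": {"fill": str(row["color"])},
            }
    logger.warning("label %s missing from family table; assigned family 'other'", label)
    return {
        "collagen": label,
        "family": DEFAULT_FAMILY,
        "color": DEFAULT_COLOR,
        "graphics": {"fill": DEFAULT_COLOR},
    }


def build_network(
    matrix: SimilarityMatrix,
    threshold: float,
    family_map: pd.DataFrame | None = None,
) -> nx.Graph:
    """Threshold a similarity matrix into a weighted, family-coloured network.

    Every matrix label becomes a node (isolated nodes are retained); an edge
    joins two labels iff their off-diagonal similarity is >= the threshold,
    weighted by that similarity.  Self-edges are never created.
    """
    net = nx.Graph(level=matrix.level, threshold=float(threshold))
    for key, value in matrix.params.items():
        net.graph[str(key)] = value
    for label in matrix.labels:
        net.add_node(label, **_node_attrs(label, matrix.level, family_map))
    n = len(matrix.labels)
    for i in range(n):
        for j in range(i + 1, n):
            v = matrix.values[i, j]
            if not np.isnan(v) and v >= threshold:
                net.add_edge(matrix.labels[i], matrix.labels[j], weight=float(v))
    return net


def connected_components(net: nx.Graph) -> tuple[list[set[str]], int]:
    """Partition into connected components and count the subnetworks.

    A subnetwork is a component with at least two nodes; isolated nodes are
    part of the partition but not of the subnetwork count (they are reported
    apart, as unconnected chains).
    """
    parts = [set(c) for c in nx.connected_components(net)]
    parts.sort(key=lambda c: (-len(c), min(c)))
    return parts, sum(1 for c in parts if len(c) >= 2)


def write_gml(net: nx.Graph, destination) -> None:
    """Serialize a network to GML 1.0 (yEd-readable, hex fill colours)."""
    text = "\n".join(nx.generate_gml(net)) + "\n"
    if isinstance(destination, (str, Path)):
        Path(destination).write_text(text)
    else:
        destination.write(text)


def read_gml(source) -> nx.Graph:
    """Read a GML network back; inverse of :func:`write_gml`."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    return nx.parse_gml(text)


@dataclass(frozen=True)
class SweepGrid:
    """The full parameter grid of the analysis.

    Three sequence conditions × 50 subsequence lengths (10..500 step 10) ×
    20 confidence thresholds (0..95 step 5) × 32 network thresholds
    (12..20 step 0.25, half-open) × 2 levels (chains, collagens).
    """

    conditions: tuple[Condition, ...] = tuple(Condition)
    lengths: tuple[int, ...] = tuple(range(10, 501, 10))
    conf_thresholds: tuple[float, ...] = tuple(float(c) for c in range(0, 100, 5))
    net_thresholds: tuple[float, ...] = tuple(default_network_thresholds())
    levels: tuple[str, ...] = ("chain", "collagen")

    @property
    def n_networks(self) -> int:
        return (
            len(self.conditions)
            * len(self.lengths)
            * len(self.conf_thresholds)
            * len(self.net_thresholds)
            * len(self.levels)
        )

    def cells(self):
        return itertools.product(self.conditions, self.lengths, self.conf_thresholds)


def _network_path(cond: Condition, L: int, conf: float, level: str, tau: float) -> str:
    return f"{cond.value}/L{L:03d}_C{conf:g}/{level}_T{tau:.2f}.gml"


def run_sweep(
    sequences: Sequence[ConfidenceSequence],
    family_map: pd.DataFrame,
    grid: SweepGrid,
    out_dir,
    matrix: SubstitutionMatrix | None = None,
    gaps: GapParams = GapParams(),
    dry_run: bool = False,
) -> pd.DataFrame:
    """Run extraction → alignment → compression → networks over a grid.

    One GML file is written per (condition, L, confidence, network threshold,
    level); the returned manifest (also written as ``manifest.tsv``) lists one
    row per network with its grid coordinates, so its row count equals the
    grid product.  With ``dry_run`` the grid is enumerated and the manifest
    written, but no extraction, alignment or network files are produced.

    Chains with zero extracted subsequences in a cell are dropped from that
    cell's matrices (and so from its networks) but listed in the manifest's
    ``excluded_chains`` column.
    """
    if matrix is None and not dry_run:
        from .hydro_align import build_substitution_matrix, load_scale

        matrix = build_substitution_matrix(load_scale())
    out_dir = Path(out_dir)
    collagen_of = dict(zip(family_map["chain_id"], family_map["collagen_id"]))

    rows = []
    for cond, L, conf in grid.cells():
        if dry_run:
            for level in grid.levels:
                for tau in grid.net_thresholds:
                    rows.append(
                        {
                            "condition": cond.value,
                            "length": L,
                            "conf_threshold": conf,
                            "level": level,
                            "net_threshold": tau,
                            "path": _network_path(cond, L, conf, level, tau),
                            "n_nodes": "",
                            "n_edges": "",
                            "excluded_chains": "",
                        }
                    )
            continue

        params = ExtractionParams(length=L, conf_threshold=conf)
        subs: list[Subsequence] = []
        excluded: list[str] = []
        for seq in sequences:
            conditioned = apply_condition(seq, cond)
            found = extract_regions(conditioned, params)
            if found:
                subs.extend(found)
            else:
                excluded.append(seq.chain_id)
        subs = add_reversed(subs)
        table = pairwise_similarities(subs, matrix, gaps)
        cell_params = {"condition": cond.value, "length": L, "conf_threshold": conf}
        matrices = {
            "chain": compress_chain_level(table, params=cell_params),
            "collagen": compress_collagen_level(
                table, lambda c: collagen_of.get(c, c), params=cell_params
            ),
        }
        logger.info(
            "cell %s L=%d conf=%g: %d subsequences, %d chains excluded",
            cond.value, L, conf, len(subs), len(excluded),
        )
        for level in grid.levels:
            sm = matrices[level]
            for tau in grid.net_thresholds:
                net = build_network(sm, tau, family_map)
                rel = _network_path(cond, L, conf, level, tau)
                path = out_dir / rel
                path.parent.mkdir(parents=True, exist_ok=True)
                write_gml(net, path)
                rows.append(
                    {
                        "condition": cond.value,
                        "length": L,
                        "conf_threshold": conf,
                        "level": level,
                        "net_threshold": tau,
                        "path": rel,
                        "n_nodes": net.number_of_nodes(),
                        "n_edges": net.number_of_edges(),
                        "excluded_chains": ",".join(sorted(excluded)),
                    }
                )

    manifest = pd.DataFrame(rows)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest


def grid_statistics(
    sequences: Sequence[ConfidenceSequence],
    grid: SweepGrid,
    matrix: SubstitutionMatrix,
    gaps: GapParams = GapParams(),
) -> pd.DataFrame:
    """Per-cell subsequence counts and similarity-score spread.

    For every (condition, L, confidence) cell: the number of extracted
    subsequences (FORWARD + REVERSED) and the population standard deviation of
    all pairwise similarities (NaN when fewer than two similarities exist).
    Used to locate an operating point; no selection rule is hard-coded — see
    :func:`pareto_front`.
    """
    rows = []
    for cond, L, conf in grid.cells():
        params = ExtractionParams(length=L, conf_threshold=conf)
        subs: list[Subsequence] = []
        for seq in sequences:
            subs.extend(extract_regions(apply_condition(seq, cond), params))
        subs = add_reversed(subs)
        table = pairwise_similarities(subs, matrix, gaps)
        sims = table["similarity"].to_numpy()
        sd = float(np.std(sims)) if len(sims) >= 2 else float("nan")
        rows.append(
            {
                "condition": cond.value,
                "length": L,
                "conf_threshold": conf,
                "n_subsequences": len(subs),
                "similarity_sd": sd,
            }
        )
    return pd.DataFrame(rows)


def pareto_front(stats: pd.DataFrame) -> pd.DataFrame:
    """Mark cells on the Pareto front of (n_subsequences, similarity_sd).

    Both quantities are maximized: many subsequences mean broad chain coverage
    and a large similarity spread means discriminative scores.  A cell is on
    the front when no other cell is at least as good on both and strictly
    better on one.  Cells with undefined spread are never on the front.
    """
    stats = stats.copy()
    n = stats["n_subsequences"].to_numpy(dtype=float)
    sd = stats["similarity_sd"].to_numpy(dtype=float)
    on_front = np.zeros(len(stats), dtype=bool)
    for i in range(len(stats)):
        if np.isnan(sd[i]):
            continue
        dominated = np.any(
            (n >= n[i]) & (sd >= sd[i]) & ((n > n[i]) | (sd > sd[i])) & ~np.isnan(sd)
        )
        on_front[i] = not dominated
    stats["pareto"] = on_front
    return stats
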