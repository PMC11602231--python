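"""Literature co-occurrence matrix transform and reference networks.

Hit counts from querying pairs of collagens (or α-chains) in literature
databases arrive as a symmetric integer matrix; the diagonal holds the
single-term hit counts.  To avoid a bias towards heavily studied collagens the
counts are transformed logarithmically (base 100) and normalised, producing a
distance-like matrix: more hits ⇒ lower value, zero hits ⇒ the fixed maximal
value 10.  Networks then connect pairs whose distance is at or below a
threshold — the opposite edge direction to the similarity networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .simnet import _node_attrs


@dataclass
class HitCountMatrix:
    """Symmetric non-negative integer co-occurrence counts."""

    labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        n = len(self.labels)
        if counts.shape != (n, n):
            raise ValueError("count matrix shape does not match labels")
        if not np.issubdtype(counts.dtype, np.integer):
            raise ValueError("hit counts must be integers")
        if (counts < 0).any():
            raise ValueError("hit counts must be non-negative")
        if not np.array_equal(counts, counts.T):
            raise ValueError("hit-count matrix must be symmetric")
        self.counts = counts

    def to_tsv(self, destination) -> None:
        pd.DataFrame(self.counts, index=self.labels, columns=self.labels).to_csv(
            destination, sep="\t"
        )

    @classmethod
    def from_tsv(cls, source) -> "HitCountMatrix":
        frame = pd.read_csv(source, sep="\t", index_col=0)
        return cls(labels=[str(c) for c in frame.columns],
                   counts=frame.to_numpy(dtype=int))


@dataclass
class LiteratureMatrix:
    """Distance-like transform of a hit-count matrix (lower = more hits)."""

    labels: list[str]
    distances: np.ndarray
    zero_hit_value: float = 10.0

    def __post_init__(self) -> None:
        distances = np.asarray(self.distances, dtype=float)
        n = len(self.labels)
        if distances.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(distances, distances.T):
            raise ValueError("distance matrix must be symmetric")
        self.distances = distances

    def to_tsv(self, destination) -> None:
        pd.DataFrame(self.distances, index=self.labels, columns=self.labels).to_csv(
            destination, sep="\t"
        )


def transform_hits(
    hits: HitCountMatrix,
    zero_hit_value: float = 10.0,
    scale: float = 10.0,
    log_base: float = 100.0,
) -> LiteratureMatrix:
    """Transform hit counts into the normalised literature distance matrix.

    Zero counts map to ``zero_hit_value`` (10, the published convention for an
    occurrence of zero).  A positive count h maps to

        scale · (1 − log_b(h) / log_b(h_max)),

    with h_max the largest count in the matrix, so the best-studied pair maps
    to 0 and the transform is strictly decreasing in h.  The base (default
    100) cancels in the ratio and is kept as an explicit, documented knob.
    An all-zero matrix has no h_max and is an error.
    """
    counts = hits.counts
    h_max = int(counts.max())
    if h_max == 0:
        raise ValueError("all hit counts are zero; h_max is undefined")
    distances = np.full(counts.shape, float(zero_hit_value))
    nz = counts > 0
    if h_max == 1:
        distances[nz] = 0.0  # the endpoint rule h = h_max -> 0 takes precedence
    else:
        logs = np.log(counts[nz].astype(float)) / np.log(log_base)
        log_max = np.log(float(h_max)) / np.log(log_base)
        distances[nz] = scale * (1.0 - logs / log_max)
    return LiteratureMatrix(
        labels=list(hits.labels),
        distances=distances,
        zero_hit_value=float(zero_hit_value),
    )


def build_literature_networks(
    lit: LiteratureMatrix,
    thresholds: Iterable[float] | None = None,
    family_map: pd.DataFrame | None = None,
    level: str = "chain",
) -> list[nx.Graph]:
    """Thresholded reference networks from a literature distance matrix.

    For each threshold τ (default 1..20 in steps of one) an edge joins two
    labels iff their off-diagonal distance is <= τ — smaller distance means a
    stronger literature link, so the edge rule is the mirror image of the
    similarity networks.  Nodes without qualifying edges are retained as
    isolated nodes.
    """
    if thresholds is None:
        thresholds = range(1, 21)
    nets = []
    labels = lit.labels
    n = len(labels)
    for tau in thresholds:
        net = nx.Graph(level=level, threshold=float(tau), kind="literature")
        for label in labels:
            net.add_node(label, **_node_attrs(label, level, family_map))
        for i in range(n):
            for j in range(i + 1, n):
                d = lit.distances[i, j]
                if d <= tau:
                    net.add_edge(labels[i], labels[j], weight=float(d))
        nets.append(net)
    return nets
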