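"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's dynamic-programming / vectorised code
paths: alignments are enumerated explicitly, extraction re-scans every window
with plain Python arithmetic, and components come from union-find.
"""

from __future__ import annotations

from typing import Iterator


def enumerate_alignments(a: str, b: str) -> Iterator[list[tuple[str, str]]]:
    """Yield every global alignment of a and b as a list of columns."""
    if not a and not b:
        yield []
        return
    if a:
        for rest in enumerate_alignments(a[1:], b):
            yield [(a[0], "-")] + rest
    if b:
        for rest in enumerate_alignments(a, b[1:]):
            yield [("-", b[0])] + rest
    if a and b:
        for rest in enumerate_alignments(a[1:], b[1:]):
            yield [(a[0], b[0])] + rest


def score_alignment(
    columns: list[tuple[str, str]],
    score_of,
    gap_open: float,
    gap_extend: float,
    free_end_gaps: bool,
    extend_on_open: bool = False,
) -> float:
    """Affine-gap score of one explicit alignment.

    A maximal gap run of length k costs open + (k-1)*extend (or open+k*extend
    with ``extend_on_open``); runs touching either end of the alignment are
    free when ``free_end_gaps``.
    """
    first = gap_open + (gap_extend if extend_on_open else 0.0)
    total = 0.0
    n = len(columns)
    for side in (0, 1):
        run_start = None
        for i in range(n + 1):
            gap = i < n and columns[i][side] == "-"
            if gap and run_start is None:
                run_start = i
            elif not gap and run_start is not None:
                length = i - run_start
                if free_end_gaps and (run_start == 0 or i == n):
                    cost = 0.0
                else:
                    cost = first + (length - 1) * gap_extend
                total -= cost
                run_start = None
    for ca, cb in columns:
        if ca != "-" and cb != "-":
            total += score_of(ca, cb)
    return total


def best_alignment_score(
    a: str,
    b: str,
    score_of,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    free_end_gaps: bool = True,
) -> float:
    """Optimal global-alignment score by exhaustive enumeration."""
    return max(
        score_alignment(cols, score_of, gap_open, gap_extend, free_end_gaps)
        for cols in enumerate_alignments(a, b)
    )


def greedy_extract(
    residues: str, confidence: list[float], length: int, threshold: float,
    sentinel: float = -1e9,
) -> list[tuple[int, float]]:
    """Greedy high-confidence window extraction, re-scanned in plain Python.

    Returns (start, mean) tuples in extraction order.  Positions holding 'X'
    are treated as sentinel-confidence, exactly like the implementation's
    eligibility rule.
    """
    work = [
        sentinel if aa == "X" else c for aa, c in zip(residues, confidence)
    ]
    n = len(work)
    out: list[tuple[int, float]] = []
    while n >= length:
        means = [sum(work[i : i + length]) / length for i in range(n - length + 1)]
        best = max(range(len(means)), key=lambda i: (means[i], -i))
        if means[best] < threshold:
            break
        out.append((best, means[best]))
        for i in range(best, best + length):
            work[i] = sentinel
    return out


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def components(nodes, edges) -> list[set]:
    """Connected components via union-find."""
    uf = UnionFind(nodes)
    for a, b in edges:
        uf.union(a, b)
    groups: dict = {}
    for node in nodes:
        groups.setdefault(uf.find(node), set()).add(node)
    return list(groups.values())
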