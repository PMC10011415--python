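"""Hypergraph container, plain-text I/O, projection, and the per-hyperedge
threshold/rate formulas shared by every dynamics module.

A hypergraph is a node set ``{0, ..., N-1}`` together with hyperedges,
each an arbitrary-cardinality node subset.  The contagion dynamics attach
to each hyperedge ``e_j`` a critical-mass threshold
``Theta_j = ceil(theta_star * |e_j|)`` and an activation rate
``lambda_j = lam * modulation(|e_j|)``; the default modulation is the
base-2 logarithm, so the pairwise case reduces to standard SIS
(``log2(2) = 1``) while the per-member rate of very large groups
vanishes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Hashable, Iterable, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Hypergraph",
    "DynamicsParameters",
    "log2_modulation",
    "constant_modulation",
    "load_hypergraph",
    "write_hypergraph",
    "projected_adjacency",
    "giant_component",
    "hyperedge_threshold",
    "hyperedge_rate",
]


def log2_modulation(cardinality: int) -> float:
    """Default cardinality modulation ``lambda*(|e|) = log2(|e|)``."""
    return math.log2(cardinality)


def constant_modulation(cardinality: int) -> float:
    """Cardinality-independent modulation ``lambda*(|e|) = 1``."""
    return 1.0


class Hypergraph:
    """A validated hypergraph with contiguous integer node labels.

    Parameters
    ----------
    hyperedges:
        Iterable of node-index collections.  Each hyperedge is stored as a
        sorted ``numpy`` integer array.  Hyperedges with repeated members
        raise; duplicates (as sets) and cardinality < 2 are rejected here
        (the loader drops them with a logged count before construction).
    node_count:
        Number of nodes ``N``.  If omitted, inferred as ``max label + 1``.
    node_labels:
        Optional original labels, index ``i`` -> label; kept for
        round-tripping externally labelled data.
    community:
        Optional per-node integer block labels (from generators).
    """

    def __init__(
        self,
        hyperedges: Iterable[Sequence[int]],
        node_count: int | None = None,
        node_labels: Sequence[Hashable] | None = None,
        community: Sequence[int] | None = None,
    ) -> None:
        edges: list[np.ndarray] = []
        seen: set[tuple[int, ...]] = set()
        for e in hyperedges:
            arr = np.array(sorted(int(v) for v in e), dtype=np.int64)
            if arr.size < 2:
                raise ValueError(f"hyperedge of cardinality {arr.size} < 2: {arr.tolist()}")
            if np.any(arr[1:] == arr[:-1]):
                raise ValueError(f"hyperedge with repeated node: {arr.tolist()}")
            key = tuple(arr.tolist())
            if key in seen:
                raise ValueError(f"duplicate hyperedge: {arr.tolist()}")
            seen.add(key)
            edges.append(arr)
        self.hyperedges: list[np.ndarray] = edges
        max_label = max((int(e[-1]) for e in edges), default=-1)
        if node_count is None:
            node_count = max_label + 1
        if max_label >= node_count:
            raise ValueError(f"node index {max_label} out of range for N={node_count}")
        if node_count < 0:
            raise ValueError("node_count must be nonnegative")
        self.node_count: int = int(node_count)
        self.node_labels = list(node_labels) if node_labels is not None else None
        if self.node_labels is not None and len(self.node_labels) != self.node_count:
            raise ValueError("node_labels length must equal node_count")
        self.community = np.asarray(community, dtype=np.int64) if community is not None else None
        if self.community is not None and self.community.size != self.node_count:
            raise ValueError("community length must equal node_count")

    # -- basic views ---------------------------------------------------

    @property
    def n_hyperedges(self) -> int:
        return len(self.hyperedges)

    def cardinalities(self) -> np.ndarray:
        return np.array([e.size for e in self.hyperedges], dtype=np.int64)

    def incidence_lists(self) -> list[list[int]]:
        """Per-node list of incident hyperedge indices."""
        inc: list[list[int]] = [[] for _ in range(self.node_count)]
        for j, e in enumerate(self.hyperedges):
            for v in e:
                inc[v].append(j)
        return inc

    def edge_key_set(self) -> set[tuple[int, ...]]:
        return {tuple(e.tolist()) for e in self.hyperedges}

    def membership_counts(self) -> np.ndarray:
        """Per-node number of incident hyperedges (hypergraph degree)."""
        counts = np.zeros(self.node_count, dtype=np.int64)
        for e in self.hyperedges:
            counts[e] += 1
        return counts

    def restrict(self, nodes: Iterable[int]) -> "Hypergraph":
        """Sub-hypergraph induced on ``nodes`` (labels remapped, order by
        old index).  Hyperedges that lose members below cardinality 2 are
        dropped; so are induced duplicates."""
        keep = sorted(set(int(v) for v in nodes))
        remap = {v: i for i, v in enumerate(keep)}
        new_edges = []
        seen: set[tuple[int, ...]] = set()
        for e in self.hyperedges:
            sub = tuple(remap[v] for v in e.tolist() if v in remap)
            if len(sub) < 2 or sub in seen:
                continue
            seen.add(sub)
            new_edges.append(sub)
        labels = None
        if self.node_labels is not None:
            labels = [self.node_labels[v] for v in keep]
        comm = self.community[keep] if self.community is not None else None
        return Hypergraph(new_edges, node_count=len(keep), node_labels=labels, community=comm)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Hypergraph(N={self.node_count}, M={self.n_hyperedges})"


@dataclass(frozen=True)
class DynamicsParameters:
    """Rates of the contagion process.

    Attributes
    ----------
    lam:
        Free spreading parameter ``lambda >= 0``.
    delta:
        Per-node deactivation rate ``delta >= 0``.
    theta_star:
        Global critical-mass fraction in ``[0, 1]``; per-hyperedge
        threshold is ``Theta_j = ceil(theta_star * |e_j|)``.
    modulation:
        Cardinality modulation ``lambda*``; the hyperedge rate is
        ``lambda_j = lam * modulation(|e_j|)``.  Defaults to ``log2``.
    """

    lam: float
    delta: float
    theta_star: float
    modulation: Callable[[int], float] = field(default=log2_modulation)

    def __post_init__(self) -> None:
        if self.lam < 0 or self.delta < 0:
            raise ValueError("rates must be nonnegative")
        if not 0.0 <= self.theta_star <= 1.0:
            raise ValueError("theta_star must lie in [0, 1]")

    def replace(self, **kw) -> "DynamicsParameters":
        d = {
            "lam": self.lam,
            "delta": self.delta,
            "theta_star": self.theta_star,
            "modulation": self.modulation,
        }
        d.update(kw)
        return DynamicsParameters(**d)

    def thresholds(self, H: Hypergraph) -> np.ndarray:
        return np.array(
            [hyperedge_threshold(int(c), self.theta_star) for c in H.cardinalities()],
            dtype=np.int64,
        )

    def rates(self, H: Hypergraph) -> np.ndarray:
        return np.array(
            [hyperedge_rate(int(c), self) for c in H.cardinalities()], dtype=float
        )


def hyperedge_threshold(cardinality: int, theta_star: float) -> int:
    """Critical-mass threshold ``Theta_j = ceil(theta_star * |e_j|)``."""
    if not 0.0 <= theta_star <= 1.0:
        raise ValueError("theta_star must lie in [0, 1]")
    if cardinality < 2:
        raise ValueError("cardinality must be >= 2")
    return int(math.ceil(theta_star * cardinality))


def hyperedge_rate(cardinality: int, params: DynamicsParameters) -> float:
    """Hyperedge activation rate ``lambda_j = lam * modulation(|e_j|)``."""
    if cardinality < 2:
        raise ValueError("cardinality must be >= 2")
    return params.lam * params.modulation(cardinality)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _dedupe_and_filter(
    raw_edges: list[list[int]],
) -> tuple[list[tuple[int, ...]], int, int]:
    """Set-deduplicate and drop cardinality < 2; returns (edges, n_dropped_small,
    n_dropped_dup).  Within-edge repeated labels are collapsed (set identity)."""
    seen: set[tuple[int, ...]] = set()
    out: list[tuple[int, ...]] = []
    small = dup = 0
    for e in raw_edges:
        key = tuple(sorted(set(e)))
        if len(key) < 2:
            small += 1
            continue
        if key in seen:
            dup += 1
            continue
        seen.add(key)
        out.append(key)
    return out, small, dup


def _remap(edges: list[tuple[int, ...]]) -> tuple[list[tuple[int, ...]], list[int]]:
    """Remap labels to 0..N-1 in order of first appearance."""
    table: dict[int, int] = {}
    for e in edges:
        for v in e:
            if v not in table:
                table[v] = len(table)
    remapped = [tuple(table[v] for v in e) for e in edges]
    labels = [0] * len(table)
    for orig, idx in table.items():
        labels[idx] = orig
    return remapped, labels


def load_hypergraph(path: str | Path, format: str = "edge-list") -> Hypergraph:
    """Read a hypergraph from disk.

    ``edge-list``: UTF-8 text, one hyperedge per line, whitespace-separated
    integer labels, ``#`` comments allowed.

    ``simplex-pair``: ``path`` names the cardinalities file (one ``|e_j|``
    per line, conventionally ``*-nverts.txt``); the companion flattened
    member file is found by replacing ``nverts`` with ``simplices`` in the
    name, or may be passed as ``path`` being a tuple-like ``(nverts,
    simplices)`` via a two-element sequence.

    Duplicate hyperedges and hyperedges of cardinality < 2 are dropped
    with a logged count.  Node labels are remapped to ``0..N-1`` in order
    of first appearance; the original labels are retained on the result.
    """
    if format == "edge-list":
        raw = _read_edge_list(Path(path))
    elif format == "simplex-pair":
        raw = _read_simplex_pair(path)
    else:
        raise ValueError(f"unknown format: {format!r}")
    edges, small, dup = _dedupe_and_filter(raw)
    if small or dup:
        logger.info(
            "dropped %d hyperedges of cardinality < 2 and %d duplicates", small, dup
        )
    remapped, labels = _remap(edges)
    return Hypergraph(remapped, node_count=len(labels), node_labels=labels)


def _read_edge_list(path: Path) -> list[list[int]]:
    raw: list[list[int]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            try:
                raw.append([int(tok) for tok in body.split()])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer token in {body!r}") from exc
    return raw


def _read_simplex_pair(path) -> list[list[int]]:
    if isinstance(path, (tuple, list)) and len(path) == 2:
        nverts_path, members_path = Path(path[0]), Path(path[1])
    else:
        nverts_path = Path(path)
        members_path = Path(str(nverts_path).replace("nverts", "simplices"))
        if members_path == nverts_path:
            raise ValueError(
                "cannot infer member file; pass (nverts, simplices) paths explicitly"
            )
    cards = _read_int_column(nverts_path)
    members = _read_int_column(members_path)
    flat = [v for row in members for v in row]
    sizes = [v for row in cards for v in row]
    if sum(sizes) != len(flat):
        raise ValueError(
            f"simplex-pair length mismatch: sum of cardinalities {sum(sizes)} "
            f"!= member count {len(flat)}"
        )
    raw: list[list[int]] = []
    pos = 0
    for s in sizes:
        raw.append(flat[pos : pos + s])
        pos += s
    return raw


def _read_int_column(path: Path) -> list[list[int]]:
    rows: list[list[int]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            try:
                rows.append([int(tok) for tok in body.split()])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer token in {body!r}") from exc
    return rows


def write_hypergraph(H: Hypergraph, path: str | Path, original_labels: bool = False) -> None:
    """Write the canonical edge-list: sorted members, lexicographic lines."""
    lines = []
    for e in H.hyperedges:
        if original_labels and H.node_labels is not None:
            members = sorted(int(H.node_labels[v]) for v in e)
        else:
            members = e.tolist()
        lines.append(" ".join(str(v) for v in members))
    lines.sort(key=lambda s: [int(t) for t in s.split()])
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Structure
# ---------------------------------------------------------------------------


def projected_adjacency(H: Hypergraph) -> np.ndarray:
    """Weighted projected adjacency ``A_ik = sum_j 1/(|e_j|-1)`` over the
    hyperedges containing both ``i`` and ``k`` (zero diagonal)."""
    N = H.node_count
    A = np.zeros((N, N), dtype=float)
    for e in H.hyperedges:
        w = 1.0 / (e.size - 1)
        idx = np.ix_(e, e)
        A[idx] += w
        A[e, e] -= w
    return A


def giant_component(H: Hypergraph, level: str = "full") -> set[int]:
    """Largest connected component as a node set.

    ``level='pairwise-only'`` uses only cardinality-2 hyperedges;
    ``level='full'`` connects all members of every hyperedge.  Ties are
    broken by the smallest minimum node label.  Isolated nodes count as
    singleton components.
    """
    if level not in ("pairwise-only", "full"):
        raise ValueError(f"unknown level: {level!r}")
    G = nx.Graph()
    G.add_nodes_from(range(H.node_count))
    for e in H.hyperedges:
        if level == "pairwise-only" and e.size != 2:
            continue
        # star expansion within the hyperedge is enough for connectivity
        anchor = int(e[0])
        for v in e[1:]:
            G.add_edge(anchor, int(v))
    if H.node_count == 0:
        return set()
    comps = list(nx.connected_components(G))
    comps.sort(key=lambda c: (-len(c), min(c)))
    return set(comps[0])
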