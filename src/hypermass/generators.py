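"""Structured hypergraph generators.

Three constructions used to study the contagion dynamics:

- the *hyperblob*: a random k-regular pairwise graph plus one hyperedge
  containing every node — its symmetry collapses the dynamics to a 1-D
  occupancy chain (see :mod:`hypermass.blobchain`);
- a *community model*: equal-sized blocks with per-block in-community
  hyperedge counts and ``m_out`` bridge hyperedges spanning exactly two
  blocks, cardinalities drawn from a truncated exponential;
- *configuration-model rewiring*: pairwise shuffles that preserve each
  node's hyperedge-membership count and the cardinality multiset.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from hypermass.hypergraph import Hypergraph

logger = logging.getLogger(__name__)

__all__ = [
    "CommunityConfig",
    "make_hyperblob",
    "make_community_hypergraph",
    "rewire_configuration_model",
]


def make_hyperblob(N: int, k: int, seed: int) -> Hypergraph:
    """Random k-regular graph on ``N`` nodes plus one global hyperedge.

    ``k = N - 1`` yields the complete graph (homogeneous mixing), for
    which the occupancy chain of :mod:`hypermass.blobchain` is exact.
    """
    if k >= N:
        raise ValueError(f"need k < N (got k={k}, N={N})")
    if (k * N) % 2 != 0:
        raise ValueError(f"k*N must be even (got k={k}, N={N})")
    if k == N - 1:
        pair_edges = [(i, j) for i in range(N) for j in range(i + 1, N)]
    else:
        G = nx.random_regular_graph(k, N, seed=int(seed))
        pair_edges = sorted(tuple(sorted(e)) for e in G.edges())
    edges: list[tuple[int, ...]] = [tuple(e) for e in pair_edges]
    edges.append(tuple(range(N)))
    return Hypergraph(edges, node_count=N)


@dataclass(frozen=True)
class CommunityConfig:
    """Parameters of the community hypergraph model.

    ``m_in[c]`` in-community hyperedges are drawn inside block ``c``;
    ``m_out`` bridge hyperedges each span exactly two distinct blocks.
    Cardinalities are ``ceil`` of an exponential draw with mean ``mu``,
    clamped into ``[2, N / n_communities]``.
    """

    node_count: int
    m_in: tuple[int, ...]
    m_out: int
    mu: float = 8.0
    n_communities: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "m_in", tuple(int(m) for m in self.m_in))
        object.__setattr__(self, "n_communities", len(self.m_in))
        if self.n_communities < 1:
            raise ValueError("need at least one community")
        if self.node_count % self.n_communities != 0:
            raise ValueError("node_count must be divisible by the number of communities")
        if any(m < 0 for m in self.m_in) or self.m_out < 0:
            raise ValueError("hyperedge counts must be nonnegative")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.node_count // self.n_communities < 2:
            raise ValueError("blocks too small: cardinality window [2, N/n_c] is empty")

    @property
    def block_size(self) -> int:
        return self.node_count // self.n_communities

    def blocks(self) -> list[np.ndarray]:
        b = self.block_size
        return [np.arange(c * b, (c + 1) * b) for c in range(self.n_communities)]


def _draw_cardinality(rng: np.random.Generator, mu: float, cmax: int) -> int:
    c = int(np.ceil(rng.exponential(mu)))
    return min(max(c, 2), cmax)


def make_community_hypergraph(config: CommunityConfig, seed: int) -> Hypergraph:
    """Sample the community model; duplicate hyperedges are resampled.

    Returns a :class:`Hypergraph` carrying per-node ``community`` labels
    (equal-sized contiguous blocks).
    """
    rng = np.random.default_rng(int(seed))
    cmax = config.block_size
    blocks = config.blocks()
    edges: list[tuple[int, ...]] = []
    seen: set[tuple[int, ...]] = set()

    def _add(sampler) -> None:
        for _ in range(10000):
            e = sampler()
            if e not in seen:
                seen.add(e)
                edges.append(e)
                return
        raise RuntimeError("could not sample a non-duplicate hyperedge")

    for c, m in enumerate(config.m_in):
        block = blocks[c]
        for _ in range(m):
            def sample_in(block=block):
                card = _draw_cardinality(rng, config.mu, cmax)
                return tuple(sorted(rng.choice(block, size=card, replace=False).tolist()))
            _add(sample_in)
    nc = config.n_communities
    if config.m_out > 0 and nc < 2:
        raise ValueError("bridges require at least two communities")
    for _ in range(config.m_out):
        def sample_bridge():
            card = _draw_cardinality(rng, config.mu, cmax)
            a, b = rng.choice(nc, size=2, replace=False)
            ell = int(rng.integers(1, card))  # uniform on {1, ..., card-1}
            part_a = rng.choice(blocks[a], size=ell, replace=False)
            part_b = rng.choice(blocks[b], size=card - ell, replace=False)
            return tuple(sorted(np.concatenate([part_a, part_b]).tolist()))
        _add(sample_bridge)

    community = np.repeat(np.arange(nc), config.block_size)
    return Hypergraph(edges, node_count=config.node_count, community=community)


def rewire_configuration_model(H: Hypergraph, n_swaps: int, seed: int) -> Hypergraph:
    """Vertex-labeled configuration-model rewiring.

    Each step picks two hyperedges uniformly, pools their members, and
    randomly repartitions the pool into two hyperedges of the original
    cardinalities.  A proposal is rejected — both hyperedges kept, the
    step still counted — if it would repeat a node within a hyperedge or
    duplicate an existing hyperedge.  Node membership counts and the
    cardinality multiset are invariant.
    """
    if n_swaps < 0:
        raise ValueError("n_swaps must be nonnegative")
    if H.n_hyperedges < 2:
        warnings.warn("fewer than 2 hyperedges: rewiring is a no-op", stacklevel=2)
        return Hypergraph(
            [e.tolist() for e in H.hyperedges],
            node_count=H.node_count,
            node_labels=H.node_labels,
            community=H.community,
        )
    rng = np.random.default_rng(int(seed))
    edges = [tuple(e.tolist()) for e in H.hyperedges]
    seen = set(edges)
    M = len(edges)
    for _ in range(int(n_swaps)):
        a, b = rng.choice(M, size=2, replace=False)
        ea, eb = edges[a], edges[b]
        pool = list(ea) + list(eb)
        perm = rng.permutation(len(pool))
        new_a = tuple(sorted(pool[i] for i in perm[: len(ea)]))
        new_b = tuple(sorted(pool[i] for i in perm[len(ea):]))
        if len(set(new_a)) != len(ea) or len(set(new_b)) != len(eb):
            continue  # repeated node within a hyperedge
        if new_a == new_b:
            continue
        for cand in (new_a, new_b):
            if cand in seen and cand not in (ea, eb):
                break
        else:
            seen.discard(ea)
            seen.discard(eb)
            if new_a in seen or new_b in seen:
                seen.add(ea)
                seen.add(eb)
                continue
            seen.add(new_a)
            seen.add(new_b)
            edges[a], edges[b] = new_a, new_b
    return Hypergraph(
        edges, node_count=H.node_count, node_labels=H.node_labels, community=H.community
    )
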