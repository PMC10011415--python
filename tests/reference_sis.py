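"""Independent reference SIS simulator (direct Gillespie with thinning).

Used as an oracle for the pairwise reduction of the contagion model: on a
graph where every hyperedge has cardinality 2, the dynamics is exactly
the SIS model with infection rate ``lam`` per directed active-inactive
edge and recovery rate ``delta``.

This implementation deliberately takes a different algorithmic route
from the package's next-reaction engine: a single total-rate clock with
rejection (phantom) infection events, valid for *regular* graphs where
every node has the same degree.  Supports the same stored-state
quasi-stationary recycling.
"""

from __future__ import annotations

import numpy as np


def qs_sis_regular(
    adjacency: list[list[int]],
    lam: float,
    delta: float,
    t_relax: float,
    t_sample: float,
    seed: int,
    memory_size: int = 50,
    p_r: float = 0.02,
    init_active: list[int] | None = None,
):
    """QS-SIS on a k-regular graph; returns (freq over n, window rhos).

    Direct method: total event rate ``(delta + lam*k) * n``; an infection
    event picks a uniform active node and a uniform neighbor, and is a
    no-op if the neighbor is already active (thinning keeps this exact).
    """
    rng = np.random.default_rng(int(seed))
    N = len(adjacency)
    k = len(adjacency[0])
    assert all(len(nb) == k for nb in adjacency), "graph must be regular"
    Y = np.zeros(N, dtype=np.int8)
    if init_active is None:
        Y[:] = 1
    else:
        Y[np.asarray(init_active, dtype=int)] = 1
    active = [v for v in range(N) if Y[v]]
    pos = {v: i for i, v in enumerate(active)}
    states = [Y.copy() for _ in range(memory_size)]
    freq = np.zeros(N + 1)
    t = 0.0
    t_end = t_relax + t_sample

    def add(v):
        pos[v] = len(active)
        active.append(v)
        Y[v] = 1

    def remove(v):
        i = pos.pop(v)
        last = active.pop()
        if last != v:
            active[i] = last
            pos[last] = i
        Y[v] = 0

    while t < t_end:
        n = len(active)
        rate = (delta + lam * k) * n
        dt = rng.exponential(1.0 / rate)
        if t >= t_relax:
            freq[n] += min(dt, t_end - t)
        t += dt
        u = active[rng.integers(n)]
        if rng.random() < delta / (delta + lam * k):
            remove(u)
        else:
            w = adjacency[u][rng.integers(k)]
            if not Y[w]:
                add(w)
        if not active:
            pick = states[rng.integers(memory_size)]
            Y[:] = pick
            active.clear()
            pos.clear()
            for v in range(N):
                if Y[v]:
                    add(v)
        elif rng.random() < min(1.0, p_r * dt):
            states[rng.integers(memory_size)] = Y.copy()
    return freq


def sis_absorption_time(
    adjacency: list[list[int]],
    lam: float,
    delta: float,
    seed: int,
    init_active: list[int],
    t_max: float = 1e4,
) -> float:
    """Time to absorption of a plain (non-QS) SIS run; direct method."""
    rng = np.random.default_rng(int(seed))
    N = len(adjacency)
    k = len(adjacency[0])
    Y = np.zeros(N, dtype=np.int8)
    Y[np.asarray(init_active, dtype=int)] = 1
    active = [v for v in range(N) if Y[v]]
    pos = {v: i for i, v in enumerate(active)}
    t = 0.0
    while active and t < t_max:
        n = len(active)
        rate = (delta + lam * k) * n
        t += rng.exponential(1.0 / rate)
        u = active[rng.integers(n)]
        if rng.random() < delta / (delta + lam * k):
            i = pos.pop(u)
            last = active.pop()
            if last != u:
                active[i] = last
                pos[last] = i
            Y[u] = 0
        else:
            w = adjacency[u][rng.integers(k)]
            if not Y[w]:
                pos[w] = len(active)
                active.append(w)
                Y[w] = 1
    return t
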