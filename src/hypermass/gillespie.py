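"""Statistically exact continuous-time simulation of the critical-mass
contagion process.

Every live Poisson process carries its next firing time in an indexed
priority queue (next-reaction method): per-node deactivation clocks at
rate ``delta``, per-hyperedge activation clocks at rate
``lambda_j = lam * modulation(|e_j|)`` live while the active count
``T_j`` satisfies ``Theta_j <= T_j < |e_j|``, and — for every
cardinality-2 hyperedge — two directed node-to-node infection clocks,
which reproduce the standard SIS law on the pairwise subgraph.
A hyperedge firing activates *all* inactive members simultaneously.

Processes are created on threshold crossing and invalidated (version
counter) when their liveness condition breaks; exponential clocks are
sampled lazily at creation.  Because the clocks are memoryless, this is
exact in distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from heapq import heappop, heappush
from typing import Sequence

import numpy as np

from hypermass.hypergraph import DynamicsParameters, Hypergraph

__all__ = ["Trajectory", "simulate", "node_activity", "resolve_init"]


# event kind codes
DEACT = 0
GROUP = 1
PAIR = 2


class _Engine:
    """Next-reaction engine over a fixed hypergraph and parameter set.

    The mutable state (``Y``, per-hyperedge counts, the queue) is rebuilt
    by :meth:`reset`, so one engine can be reused across QS restarts.
    """

    def __init__(self, H: Hypergraph, params: DynamicsParameters, rng: np.random.Generator):
        self.N = H.node_count
        self.delta = float(params.delta)
        self.rng = rng
        # split hyperedges: every cardinality-2 hyperedge is simulated as
        # a pair of directed SIS infection clocks
        thetas = params.thresholds(H)
        rates = params.rates(H)
        g_members: list[list[int]] = []
        g_theta: list[int] = []
        g_rate: list[float] = []
        g_orig: list[int] = []
        pair_edges: list[tuple[int, int]] = []
        pair_rate: list[float] = []
        for jj, (e, th, r) in enumerate(zip(H.hyperedges, thetas, rates)):
            if e.size == 2:
                pair_edges.append((int(e[0]), int(e[1])))
                pair_rate.append(float(r))
            else:
                g_members.append([int(v) for v in e])
                g_theta.append(int(th))
                g_rate.append(float(r))
                g_orig.append(jj)
        self.g_members = g_members
        self.g_theta = g_theta
        self.g_rate = g_rate
        self.g_orig = g_orig
        self.n_groups = len(g_members)
        self.node_groups: list[list[int]] = [[] for _ in range(self.N)]
        for j, mem in enumerate(g_members):
            for v in mem:
                self.node_groups[v].append(j)
        # directed pair processes: ids 2*p (u->v) and 2*p+1 (v->u)
        self.pair_rate = pair_rate
        self.node_pairs: list[list[tuple[int, int, float]]] = [[] for _ in range(self.N)]
        # per node: (neighbor, directed-pid with node as source, rate)
        self.dir_src: list[int] = []
        self.dir_dst: list[int] = []
        self.dir_rate: list[float] = []
        for p, (u, v) in enumerate(pair_edges):
            pid_uv = len(self.dir_src)
            self.dir_src.append(u)
            self.dir_dst.append(v)
            self.dir_rate.append(pair_rate[p])
            pid_vu = len(self.dir_src)
            self.dir_src.append(v)
            self.dir_dst.append(u)
            self.dir_rate.append(pair_rate[p])
            self.node_pairs[u].append((v, pid_uv, pair_rate[p]))
            self.node_pairs[v].append((u, pid_vu, pair_rate[p]))
        # process id layout: [0, N) deactivations, [N, N+G) groups,
        # [N+G, N+G+2P) directed pairs
        self.off_g = self.N
        self.off_p = self.N + self.n_groups
        self.n_proc = self.off_p + len(self.dir_src)
        self.ver = [0] * self.n_proc
        self.live = [False] * self.n_proc
        self.heap: list[tuple[float, int, int]] = []
        self.Y: list[int] = [0] * self.N
        self.T: list[int] = [0] * self.n_groups
        self.t = 0.0
        self.n_active = 0
        self._ebuf = rng.standard_exponential(8192)
        self._epos = 0

    def _exp1(self) -> float:
        """Next unit-exponential variate (buffered for speed)."""
        i = self._epos
        if i >= self._ebuf.size:
            self._ebuf = self.rng.standard_exponential(8192)
            i = 0
        self._epos = i + 1
        return self._ebuf[i]

    # -- process bookkeeping ------------------------------------------

    def _birth(self, pid: int, rate: float) -> None:
        self.ver[pid] += 1
        self.live[pid] = True
        t_fire = self.t + self._exp1() / rate
        heappush(self.heap, (t_fire, pid, self.ver[pid]))

    def _kill(self, pid: int) -> None:
        self.ver[pid] += 1
        self.live[pid] = False

    def _update_group(self, j: int) -> None:
        pid = self.off_g + j
        want = self.g_theta[j] <= self.T[j] < len(self.g_members[j])
        if want and not self.live[pid]:
            self._birth(pid, self.g_rate[j])
        elif not want and self.live[pid]:
            self._kill(pid)

    def _activate(self, v: int) -> None:
        self.Y[v] = 1
        self.n_active += 1
        if self.delta > 0:
            self._birth(v, self.delta)
        T = self.T
        for j in self.node_groups[v]:
            T[j] += 1
            self._update_group(j)
        Y = self.Y
        off_p = self.off_p
        for (w, pid_out, rate) in self.node_pairs[v]:
            # v -> w live if w inactive
            if Y[w] == 0:
                if rate > 0:
                    self._birth(off_p + pid_out, rate)
            else:
                # w -> v dies (v now active); pid of w->v is the partner
                partner = off_p + (pid_out ^ 1)
                if self.live[partner]:
                    self._kill(partner)

    def _deactivate(self, v: int) -> None:
        self.Y[v] = 0
        self.n_active -= 1
        if self.live[v]:
            self._kill(v)
        T = self.T
        for j in self.node_groups[v]:
            T[j] -= 1
            self._update_group(j)
        Y = self.Y
        off_p = self.off_p
        for (w, pid_out, rate) in self.node_pairs[v]:
            pid_o = off_p + pid_out
            if self.live[pid_o]:
                self._kill(pid_o)  # v -> w needs v active
            if Y[w] == 1 and rate > 0:
                self._birth(off_p + (pid_out ^ 1), rate)  # w -> v now live

    def reset(self, Y0: Sequence[int], t: float | None = None) -> None:
        """Install state ``Y0``, rebuilding counts, liveness, and queue."""
        if t is not None:
            self.t = t
        self.heap.clear()
        self.ver = [v + 1 for v in self.ver]
        self.live = [False] * self.n_proc
        self.Y = [1 if y else 0 for y in Y0]
        self.n_active = sum(self.Y)
        self.T = [sum(self.Y[v] for v in mem) for mem in self.g_members]
        if self.delta > 0:
            for v in range(self.N):
                if self.Y[v]:
                    self._birth(v, self.delta)
        for j in range(self.n_groups):
            self._update_group(j)
        off_p = self.off_p
        for pid in range(len(self.dir_src)):
            u, w, rate = self.dir_src[pid], self.dir_dst[pid], self.dir_rate[pid]
            if rate > 0 and self.Y[u] == 1 and self.Y[w] == 0:
                self._birth(off_p + pid, rate)

    def step(self):
        """Execute the next event.

        Returns ``(t_event, kind, payload)`` with payload the deactivated
        node, the (hyperedge index, tuple of newly activated nodes), or
        the (source, target) pair; ``None`` if no process is live.
        """
        heap = self.heap
        ver = self.ver
        live = self.live
        while heap:
            t_fire, pid, v = heappop(heap)
            if v != ver[pid] or not live[pid]:
                continue
            self.t = t_fire
            if pid < self.off_g:
                self._kill(pid)
                self._deactivate(pid)
                return t_fire, DEACT, pid
            if pid < self.off_p:
                j = pid - self.off_g
                newly = [m for m in self.g_members[j] if self.Y[m] == 0]
                for m in newly:
                    self._activate(m)
                # group is now saturated; _update_group ran via _activate
                return t_fire, GROUP, (self.g_orig[j], tuple(newly))
            d = pid - self.off_p
            u, w = self.dir_src[d], self.dir_dst[d]
            self._kill(pid)
            self._activate(w)
            return t_fire, PAIR, (u, w)
        return None


@dataclass
class Trajectory:
    """Event-ordered record of one realization.

    ``times``/``kinds``/``payloads`` describe each executed transition;
    ``initial_state`` allows exact replay.  ``snapshots`` holds
    ``(time, state-copy)`` pairs at the configured event stride, and
    ``active_time`` the per-node cumulative time spent active.
    """

    initial_state: np.ndarray
    times: np.ndarray
    kinds: np.ndarray
    payloads: list
    t_end: float
    active_time: np.ndarray
    snapshots: list = field(default_factory=list)
    absorbed: bool = False

    @property
    def n_events(self) -> int:
        return len(self.times)

    def final_state(self) -> np.ndarray:
        Y = self.initial_state.copy()
        for kind, payload in zip(self.kinds, self.payloads):
            _apply(Y, kind, payload)
        return Y


def _apply(Y: np.ndarray, kind: int, payload) -> None:
    if kind == DEACT:
        Y[payload] = 0
    elif kind == GROUP:
        for m in payload[1]:
            Y[m] = 1
    else:
        Y[payload[1]] = 1


def resolve_init(
    init, N: int, rng: np.random.Generator
) -> np.ndarray:
    """Accept an explicit binary vector, an activation fraction ``rho0``
    (uniformly random placement, at least one node when ``rho0 > 0``), or
    an iterable node set."""
    if isinstance(init, (float, np.floating)):
        if not 0.0 <= init <= 1.0:
            raise ValueError("fraction init must lie in [0, 1]")
        n_on = int(round(init * N))
        if init > 0:
            n_on = max(n_on, 1)
        Y = np.zeros(N, dtype=np.int8)
        if n_on:
            Y[rng.choice(N, size=n_on, replace=False)] = 1
        return Y
    arr = np.asarray(list(init) if not isinstance(init, np.ndarray) else init)
    if arr.ndim == 1 and arr.size == N and set(np.unique(arr)).issubset({0, 1}):
        return arr.astype(np.int8)
    # node set
    Y = np.zeros(N, dtype=np.int8)
    idx = arr.astype(np.int64)
    if idx.size and (idx.min() < 0 or idx.max() >= N):
        raise ValueError("init node set out of range")
    Y[idx] = 1
    return Y


def simulate(
    H: Hypergraph,
    params: DynamicsParameters,
    init,
    t_max: float,
    seed: int,
    snapshot_stride: int | None = None,
    max_events: int | None = None,
) -> Trajectory:
    """Run one exact realization until absorption or ``t_max``.

    ``init`` may be a binary vector, a fraction ``rho0`` (random uniform
    placement), or a node set.  Deactivations flip one node ``1 -> 0`` at
    rate ``delta``; a hyperedge whose active count is at or above its
    critical mass flips all inactive members to ``1`` simultaneously at
    rate ``lambda_j``.
    """
    if H.node_count == 0:
        raise ValueError("empty hypergraph")
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    rng = np.random.default_rng(int(seed))
    Y0 = resolve_init(init, H.node_count, rng)
    eng = _Engine(H, params, rng)
    eng.reset(Y0, t=0.0)

    times: list[float] = []
    kinds: list[int] = []
    payloads: list = []
    snapshots: list = []
    active_time = np.zeros(H.node_count, dtype=float)
    last_t = 0.0
    Y_arr = Y0.astype(float)
    absorbed = eng.n_active == 0
    n_ev = 0
    while not absorbed:
        out = eng.step()
        if out is None:
            if eng.n_active == 0:
                absorbed = True
            else:
                eng.t = t_max  # frozen state persists to the horizon
            break
        t_ev, kind, payload = out
        if t_ev > t_max:
            eng.t = t_max
            break
        active_time += Y_arr * (t_ev - last_t)
        last_t = t_ev
        times.append(t_ev)
        kinds.append(kind)
        payloads.append(payload)
        _apply(Y_arr, kind, payload)
        n_ev += 1
        if snapshot_stride and n_ev % snapshot_stride == 0:
            snapshots.append((t_ev, Y_arr.astype(np.int8).copy()))
        if eng.n_active == 0:
            absorbed = True
            break
        if max_events is not None and n_ev >= max_events:
            break
    t_end = min(eng.t, t_max) if not absorbed else eng.t
    if not absorbed and t_end > last_t:
        active_time += Y_arr * (t_end - last_t)
    return Trajectory(
        initial_state=Y0.copy(),
        times=np.array(times, dtype=float),
        kinds=np.array(kinds, dtype=np.int8),
        payloads=payloads,
        t_end=t_end,
        active_time=active_time,
        snapshots=snapshots,
        absorbed=absorbed,
    )


def node_activity(traj: Trajectory, window: tuple[float, float]) -> np.ndarray:
    """Per-node fraction of ``window`` time spent active, replayed exactly
    from the event log."""
    t0, t1 = window
    if not (t1 > t0):
        raise ValueError("empty window")
    if t0 < 0 or t1 > traj.t_end + 1e-12:
        raise ValueError("window outside trajectory span")
    Y = traj.initial_state.astype(float).copy()
    acc = np.zeros_like(Y)
    last = t0
    for t_ev, kind, payload in zip(traj.times, traj.kinds, traj.payloads):
        if t_ev <= t0:
            _apply(Y, kind, payload)
            continue
        if t_ev >= t1:
            break
        acc += Y * (t_ev - last)
        last = t_ev
        _apply(Y, kind, payload)
    acc += Y * (t1 - last)
    return acc / (t1 - t0)
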