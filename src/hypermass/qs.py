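"""Quasi-stationary (QS) Monte-Carlo sampling.

The contagion process has a single absorbing state (all nodes inactive),
so any finite system eventually dies out; the QS method conditions on
survival.  A list of ``M`` previously visited active states is kept and
continuously refreshed (the running state overwrites a uniformly random
slot with probability ``p_r * dt`` per executed event); whenever the
absorbing state is hit, the state is replaced by a uniform draw from the
list and the run continues.  After a relaxation time ``t_relax``,
occupancy is accrued time-weighted into ``Freq(n)``; sampling proceeds
in windows of length ``t_window``, stopping when the cumulative
susceptibility changes by less than ``eps`` between consecutive windows
or after ``c_max`` windows.

Summaries follow the standard definitions ``rho = <n>/N`` and
``chi = (<n^2> - <n>^2)/<n>`` under the time-weighted distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from hypermass.gillespie import DEACT, GROUP, _Engine, resolve_init
from hypermass.hypergraph import DynamicsParameters, Hypergraph

__all__ = [
    "QSConfig",
    "StateDistribution",
    "BranchDiagram",
    "run_qs",
    "summary",
    "peaks",
    "lambda_sweep",
]


@dataclass(frozen=True)
class QSConfig:
    """Tunables of the QS sampler.

    ``memory_size`` (M) and ``replace_rate`` (p_r) control the stored-state
    list; the sampler is stable over a decade of either.  ``t_relax`` and
    ``t_window`` should grow with system size; ``eps`` and ``c_max`` are
    the adaptive stopping rule on the cumulative susceptibility.
    """

    memory_size: int = 100
    replace_rate: float = 0.02
    t_relax: float = 1e4
    t_window: float = 1e3
    eps: float = 1e-3
    c_max: int = 500

    def __post_init__(self) -> None:
        if self.memory_size < 1:
            raise ValueError("memory_size must be >= 1")
        if self.replace_rate < 0:
            raise ValueError("replace_rate must be >= 0")
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.c_max < 1:
            raise ValueError("c_max must be >= 1")


@dataclass
class StateDistribution:
    """Time-weighted occupancy over the number of active nodes.

    ``freq[n]`` is the total sampled time spent with ``n`` active nodes
    (``freq[0] == 0`` by QS construction); ``node_activity`` the per-node
    fraction of sampled time spent active; ``window_rho`` the per-window
    order-parameter estimates used for Monte-Carlo standard errors.
    """

    freq: np.ndarray
    node_activity: np.ndarray
    total_time: float
    window_rho: list[float] = field(default_factory=list)
    window_chi: list[float] = field(default_factory=list)
    converged: bool = False
    final_state: np.ndarray | None = None

    @property
    def N(self) -> int:
        return len(self.freq) - 1

    def probabilities(self) -> np.ndarray:
        tot = self.freq.sum()
        if tot <= 0:
            raise ValueError("empty distribution")
        return self.freq / tot

    def rho_se(self) -> float:
        """Block (per-window) standard error of rho."""
        return _block_se(self.window_rho)

    def chi_se(self) -> float:
        """Block (per-window) standard error of chi."""
        return _block_se(self.window_chi)


def _block_se(blocks) -> float:
    w = np.asarray(blocks, dtype=float)
    w = w[np.isfinite(w)]
    if w.size < 2:
        return np.inf
    return float(w.std(ddof=1) / np.sqrt(w.size))


def _moments(freq: np.ndarray) -> tuple[float, float]:
    tot = freq.sum()
    n = np.arange(len(freq))
    m1 = float((freq * n).sum() / tot)
    m2 = float((freq * n * n).sum() / tot)
    return m1, m2


def summary(dist: StateDistribution) -> tuple[float, float]:
    """Order parameter ``rho = <n>/N`` and susceptibility
    ``chi = (<n^2> - <n>^2)/<n>``."""
    freq = dist.freq if isinstance(dist, StateDistribution) else np.asarray(dist)
    if freq.sum() <= 0:
        raise ValueError("empty distribution")
    m1, m2 = _moments(freq)
    N = len(freq) - 1
    rho = m1 / N
    chi = (m2 - m1 * m1) / m1 if m1 > 0 else 0.0
    return rho, chi


def peaks(
    dist: StateDistribution | np.ndarray,
    smoothing_window: int = 5,
    min_prominence: float = 0.02,
) -> list[float]:
    """Positions (as fractions ``n_peak / N``) of the local maxima of the
    smoothed occupancy profile.

    The profile is moving-average smoothed over ``smoothing_window``
    consecutive bins and zero-padded so boundary modes (e.g. the QS mode
    near ``n = 1``) register; ``min_prominence`` is relative to the
    profile maximum.
    """
    freq = dist.freq if isinstance(dist, StateDistribution) else np.asarray(dist, float)
    tot = freq.sum()
    if tot <= 0:
        raise ValueError("empty distribution")
    p = freq / tot
    N = len(p) - 1
    # n = 0 is structurally empty under QS; keep it out of the smoothing
    # so the absorbing boundary does not fabricate local structure
    offset = 1 if p[0] == 0 else 0
    core = p[offset:]
    if smoothing_window > 1:
        kernel = np.ones(smoothing_window)
        # normalized moving average: edge bins average over the in-range
        # part of the kernel only, so a flat profile stays exactly flat
        smooth = np.convolve(core, kernel, mode="same") / np.convolve(
            np.ones_like(core), kernel, mode="same"
        )
    else:
        smooth = core.copy()
    prom = min_prominence * smooth.max()
    idx, _ = find_peaks(smooth, prominence=prom)
    found = sorted(int(i) for i in idx)
    # boundary bins need explicit handling (find_peaks requires a rise on
    # both sides)
    interior_lo = found[0] if found else len(smooth) - 1
    if smooth[0] > smooth[1] and smooth[0] - smooth[: interior_lo + 1].min() >= prom:
        found.insert(0, 0)
    hi = len(smooth) - 1
    interior_hi = found[-1] if found else 0
    if hi not in found and smooth[hi] > smooth[hi - 1] and (
        smooth[hi] - smooth[interior_hi:].min() >= prom
    ):
        found.append(hi)
    return [float(i + offset) / N for i in found]


def run_qs(
    H: Hypergraph,
    params: DynamicsParameters,
    qs: QSConfig,
    init,
    seed: int,
) -> StateDistribution:
    """QS-sampled state distribution and per-node activity."""
    if H.node_count == 0:
        raise ValueError("empty hypergraph")
    rng = np.random.default_rng(int(seed))
    N = H.node_count
    Y0 = resolve_init(init, N, rng)
    if Y0.sum() == 0:
        raise ValueError("QS sampling needs an active initial state")
    eng = _Engine(H, params, rng)
    eng.reset(Y0, t=0.0)
    M = qs.memory_size
    states = [Y0.astype(np.int8).copy() for _ in range(M)]
    Y = Y0.astype(np.int8).copy()

    freq = np.zeros(N + 1, dtype=float)
    act = np.zeros(N, dtype=float)
    p_r = qs.replace_rate

    def run_phase(t_end: float, record: bool) -> None:
        nonlocal Y
        t_prev = eng.t
        while eng.t < t_end:
            out = eng.step()
            if out is None:
                # frozen (or absorbing with empty list update); hold state
                if record:
                    freq[eng.n_active] += t_end - t_prev
                    act[:] += Y * (t_end - t_prev)
                eng.t = t_end
                return
            t_ev, kind, payload = out
            dt = t_ev - t_prev
            n_pre = eng.n_active
            if kind == DEACT:
                n_pre += 1
            elif kind == GROUP:
                n_pre -= len(payload[1])
            else:
                n_pre -= 1
            if record:
                freq[n_pre] += dt
                act[:] += Y * dt
            # mirror the engine state
            if kind == DEACT:
                Y[payload] = 0
            elif kind == GROUP:
                for m in payload[1]:
                    Y[m] = 1
            else:
                Y[payload[1]] = 1
            t_prev = t_ev
            if eng.n_active == 0:
                pick = states[rng.integers(M)]
                eng.reset(pick, t=eng.t)
                Y = pick.copy()
            elif p_r > 0 and rng.random() < min(1.0, p_r * dt):
                states[rng.integers(M)] = Y.copy()

    run_phase(qs.t_relax, record=False)

    window_rho: list[float] = []
    window_chi: list[float] = []
    converged = False
    chi_prev = None
    t0 = eng.t
    for c in range(qs.c_max):
        freq_before = freq.copy()
        run_phase(t0 + (c + 1) * qs.t_window, record=True)
        dwin = freq - freq_before
        if dwin.sum() > 0:
            m1, m2 = _moments(dwin)
            window_rho.append(m1 / N)
            window_chi.append((m2 - m1 * m1) / m1 if m1 > 0 else np.nan)
        _, chi = summary_from_freq(freq)
        if chi_prev is not None and abs(chi - chi_prev) < qs.eps:
            converged = True
            break
        chi_prev = chi

    total = freq.sum()
    node_activity = act / total if total > 0 else act
    return StateDistribution(
        freq=freq,
        node_activity=node_activity,
        total_time=float(total),
        window_rho=window_rho,
        window_chi=window_chi,
        converged=converged,
        final_state=Y.copy(),
    )


def summary_from_freq(freq: np.ndarray) -> tuple[float, float]:
    if freq.sum() <= 0:
        return 0.0, 0.0
    m1, m2 = _moments(freq)
    N = len(freq) - 1
    return m1 / N, (m2 - m1 * m1) / m1 if m1 > 0 else 0.0


@dataclass
class BranchDiagram:
    """Per-lambda branch-labelled summaries from a sweep.

    ``records`` is a list of dicts with keys ``lam``, ``branch``,
    ``rho``, ``chi``, ``rho_se``, ``peaks``, ``init`` (seeding
    descriptor), and ``replica``.  Branch labels are ordinal in mean
    ``rho`` (0 = lowest) within each lambda.
    """

    records: list[dict]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.records)

    def branches_at(self, lam: float) -> dict[int, list[dict]]:
        out: dict[int, list[dict]] = {}
        for r in self.records:
            if r["lam"] == lam:
                out.setdefault(r["branch"], []).append(r)
        return out


def _cluster_branches(rhos: np.ndarray, ses: np.ndarray, N: int) -> np.ndarray:
    """Single-linkage 1-D clustering: split at sorted-rho gaps larger than
    ``5/N`` and 3 pooled standard errors."""
    order = np.argsort(rhos)
    labels = np.zeros(len(rhos), dtype=int)
    current = 0
    for prev, here in zip(order[:-1], order[1:]):
        gap = rhos[here] - rhos[prev]
        pooled = np.sqrt(
            (ses[here] ** 2 + ses[prev] ** 2) / 2.0
            if np.isfinite(ses[here]) and np.isfinite(ses[prev])
            else 0.0
        )
        if gap > 5.0 / N and gap > 3.0 * pooled:
            current += 1
        labels[here] = current
    labels[order[0]] = 0
    # relabel ordinal by cluster mean rho (ascending)
    means = {}
    for lab in np.unique(labels):
        means[lab] = rhos[labels == lab].mean()
    ranks = {lab: r for r, lab in enumerate(sorted(means, key=means.get))}
    return np.array([ranks[lab] for lab in labels])


def _describe_init(ic) -> str:
    if isinstance(ic, (float, np.floating)):
        return f"rho0={float(ic):g}"
    arr = np.asarray(ic)
    if arr.ndim == 1:
        return f"vector(n_active={int(np.count_nonzero(arr))})"
    return repr(ic)


def lambda_sweep(
    H: Hypergraph,
    params: DynamicsParameters,
    lambdas,
    seeding,
    qs: QSConfig,
    replicas: int = 1,
    seed: int = 0,
) -> BranchDiagram:
    """Run QS at each lambda for each initial condition and replica, then
    assign branch labels by clustering the order parameter.

    ``seeding`` is either the string ``"carryover"`` (the final
    micro-state at one lambda seeds the next; first lambda starts all
    active) or a list of initial-condition specs accepted by the
    simulator (fractions, binary vectors, or node sets).
    """
    lambdas = sorted(float(x) for x in lambdas)
    if not lambdas:
        raise ValueError("lambda grid is empty")
    rng = np.random.default_rng(int(seed))
    records: list[dict] = []
    carry = seeding == "carryover"
    inits = [1.0] if carry else list(seeding)
    carry_state: np.ndarray | None = None
    for lam in lambdas:
        p = params.replace(lam=lam)
        results = []
        for ic_idx, ic in enumerate(inits):
            for rep in range(replicas):
                sub = int(rng.integers(2**31 - 1))
                use_init = carry_state if (carry and carry_state is not None) else ic
                dist = run_qs(H, p, qs, use_init, seed=sub)
                rho, chi = summary(dist)
                results.append(
                    dict(
                        lam=lam,
                        rho=rho,
                        chi=chi,
                        rho_se=dist.rho_se(),
                        peaks=peaks(dist),
                        init=("carryover" if carry else _describe_init(ic)),
                        replica=rep,
                    )
                )
                if carry:
                    carry_state = dist.final_state
        rhos = np.array([r["rho"] for r in results])
        ses = np.array([r["rho_se"] for r in results])
        try:
            labels = _cluster_branches(rhos, ses, H.node_count)
        except Exception:  # pragma: no cover - defensive
            warnings.warn("branch clustering unresolved; using a single branch")
            labels = np.zeros(len(results), dtype=int)
        for r, lab in zip(results, labels):
            r["branch"] = int(lab)
        records.extend(results)
    return BranchDiagram(records=records)
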