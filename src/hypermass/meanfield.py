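"""Individual-based (first-order) mean-field approximation.

Writing ``y_i`` for the activation probability of node ``i``, the closed
ODE system is

    dy_i/dt = -delta * y_i
              + lam * (1 - y_i) * sum_{e_j : i in e_j} modulation(|e_j|)
                * sum_{k = Theta_j}^{|e_j| - 1} P^{(i)}_{e_j}(K = k),

where ``P^{(i)}_{e_j}`` is the Poisson-binomial distribution of the
number of active members of ``e_j`` *excluding* node ``i``.  Direct
subset enumeration of that distribution underflows for large groups; the
discrete-Fourier-transform identity over the characteristic function is
stable for cardinalities well beyond 80 and is used in the solver (the
enumeration is retained as a small-size oracle).

Steady states are found by adaptive Runge-Kutta integration (RK45 with
absolute error 1e-4 and relative error 1e-3 per step) until the residual
``max|dy/dt|`` falls below tolerance; branches are traced by marching a
lambda grid and reusing each steady state as the next initial condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.integrate import solve_ivp

from hypermass.hypergraph import DynamicsParameters, Hypergraph

__all__ = [
    "poisson_binomial_enum",
    "poisson_binomial_dft",
    "ode_rhs",
    "integrate_steady",
    "BranchTrace",
    "branch_continuation",
]

_ENUM_LIMIT = 20


def poisson_binomial_enum(probs) -> np.ndarray:
    """Exact Poisson-binomial pmf by subset enumeration (oracle only).

    Refuses vectors longer than 20 (combinatorial blow-up).
    """
    p = np.asarray(probs, dtype=float)
    if p.size > _ENUM_LIMIT:
        raise ValueError(f"enumeration limited to length {_ENUM_LIMIT}")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    m = p.size
    pmf = np.zeros(m + 1)
    idx = range(m)
    for k in range(m + 1):
        total = 0.0
        for active in combinations(idx, k):
            a = set(active)
            prod = 1.0
            for i in idx:
                prod *= p[i] if i in a else (1.0 - p[i])
            total += prod
        pmf[k] = total
    return pmf


def poisson_binomial_dft(probs) -> np.ndarray:
    """Poisson-binomial pmf via the characteristic-function / DFT identity.

    For ``m`` probabilities the support is ``{0, ..., m}``; with
    ``C = exp(2*pi*i/(m+1))``,

        P(K = k) = (m+1)^{-1} sum_{l=0}^{m} C^{-l k}
                   prod_m (1 + (C^l - 1) y_m).

    Stable for large ``m``; tiny negative entries from floating point are
    clipped at zero and the pmf renormalized (drift beyond 1e-6 warns).
    """
    p = np.asarray(probs, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    m = p.size
    if m == 0:
        return np.ones(1)
    L = m + 1
    l = np.arange(L)
    C_l = np.exp(2j * np.pi * l / L)  # shape (L,)
    terms = 1.0 + (C_l[:, None] - 1.0) * p[None, :]  # (L, m)
    x = terms.prod(axis=1)  # characteristic function samples
    pmf = np.fft.fft(x).real / L
    neg = pmf < 0
    if np.any(neg):
        pmf = np.where(neg, 0.0, pmf)
    s = pmf.sum()
    if abs(s - 1.0) > 1e-6:
        warnings.warn(f"Poisson-binomial renormalization drift {abs(s - 1.0):.3e}")
    return pmf / s


def _edge_groups(H: Hypergraph, params: DynamicsParameters):
    """Group hyperedges by cardinality for vectorized tail computation.

    Returns per-cardinality tuples ``(members, theta, weight)`` with
    ``members`` an ``(n_edges, c)`` index matrix and ``weight`` the
    modulation value ``lambda*(c)``.
    """
    by_card: dict[int, list[np.ndarray]] = {}
    for e in H.hyperedges:
        by_card.setdefault(e.size, []).append(e)
    out = []
    for c, edges in sorted(by_card.items()):
        E = np.vstack(edges)
        from hypermass.hypergraph import hyperedge_threshold

        theta = hyperedge_threshold(c, params.theta_star)
        out.append((E, theta, params.modulation(c)))
    return out


def _tail_contributions(E: np.ndarray, theta: int, y: np.ndarray) -> np.ndarray:
    """For each edge row and each member position, the probability that at
    least ``theta`` of the *other* members are active, capped at
    ``c - 1`` actives (the member itself is excluded).

    Exclusion products are exact prefix*suffix products of the DFT terms
    (no deconvolution); output shape matches ``E``.
    """
    nE, c = E.shape
    if theta > c - 1:
        return np.zeros((nE, c))
    if theta <= 0:
        return np.ones((nE, c))
    ymat = y[E]  # (nE, c)
    l = np.arange(c)
    C_l = np.exp(2j * np.pi * l / c)
    terms = 1.0 + (C_l[:, None, None] - 1.0) * ymat[None, :, :]  # (c, nE, c)
    # exclusion product over the member axis via prefix/suffix products
    pre = np.ones_like(terms)
    suf = np.ones_like(terms)
    np.cumprod(terms[:, :, :-1], axis=2, out=pre[:, :, 1:])
    np.cumprod(terms[:, :, :0:-1], axis=2, out=suf[:, :, -2::-1])
    X = pre * suf  # (c, nE, c): product over members != i
    pmf = np.fft.fft(X, axis=0).real / c  # k = 0..c-1 along axis 0
    tail = pmf[theta:, :, :].sum(axis=0)
    return np.clip(tail, 0.0, 1.0)


def ode_rhs(y: np.ndarray, H: Hypergraph, params: DynamicsParameters) -> np.ndarray:
    """Right-hand side of the mean-field system at state ``y``."""
    y = np.asarray(y, dtype=float)
    if y.shape != (H.node_count,):
        raise ValueError(
            f"state has shape {y.shape}, expected ({H.node_count},)"
        )
    drive = np.zeros(H.node_count)
    for E, theta, weight in _edge_groups(H, params):
        tail = _tail_contributions(E, theta, y)
        np.add.at(drive, E.ravel(), weight * tail.ravel())
    return -params.delta * y + params.lam * (1.0 - y) * drive


@dataclass
class SteadyState:
    """Converged (or truncated) steady state of the mean-field system."""

    y: np.ndarray
    residual: float
    converged: bool
    t_final: float

    @property
    def rho(self) -> float:
        return float(self.y.mean())


def integrate_steady(
    y0,
    H: Hypergraph,
    params: DynamicsParameters,
    residual_tol: float = 1e-8,
    t_limit: float = 1e4,
    t_ode: float = 50.0,
) -> SteadyState:
    """Find the steady state reached from ``y0``.

    An adaptive RK45 phase (per-step absolute error 1e-4, relative 1e-3,
    state clipped to ``[0, 1]`` after each accepted chunk) follows the
    flow for ``t_ode`` time units to settle into the right basin; the
    remaining slow relaxation is accelerated by damped fixed-point
    iteration of the steady-state map ``y <- lam*D/(delta + lam*D)``
    (``D`` the hyperedge drive), whose fixed points are exactly the ODE
    equilibria.  Additional ODE time is spent only if the iteration
    stalls; convergence means ``max|dy/dt| < residual_tol``.
    """
    y = np.clip(np.asarray(y0, dtype=float), 0.0, 1.0)
    if y.shape != (H.node_count,):
        raise ValueError("y0 dimension mismatch")

    groups = _edge_groups(H, params)

    def drive(yc):
        d = np.zeros(H.node_count)
        for E, theta, weight in groups:
            tail = _tail_contributions(E, theta, yc)
            np.add.at(d, E.ravel(), weight * tail.ravel())
        return d

    def rhs(t, yv):
        yc = np.clip(yv, 0.0, 1.0)
        return -params.delta * yc + params.lam * (1.0 - yc) * drive(yc)

    def residual(yc):
        return float(np.abs(rhs(0.0, yc)).max())

    def ode_phase(y, t, horizon):
        chunk = 1.0
        res = residual(y)
        while res > residual_tol and t < horizon:
            span = min(chunk, horizon - t)
            sol = solve_ivp(rhs, (t, t + span), y, method="RK45", atol=1e-4, rtol=1e-3)
            if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
                raise RuntimeError(
                    f"mean-field integration failed at t={t}: {sol.message}"
                )
            y = np.clip(sol.y[:, -1], 0.0, 1.0)
            t += span
            chunk = min(chunk * 2.0, 500.0)
            res = residual(y)
        return y, t, res

    def polish(y, max_iter=5000, omega=0.5):
        if params.delta <= 0:
            return y, residual(y)
        best, best_res = y, residual(y)
        for _ in range(max_iter):
            D = drive(y)
            target = params.lam * D / (params.delta + params.lam * D)
            y = (1.0 - omega) * y + omega * target
            res = residual(y)
            if res < best_res:
                best, best_res = y, res
            if res <= residual_tol:
                return y, res
            if res > 10.0 * best_res + 1e-12:
                break  # iteration diverging; hand back to the ODE
        return best, best_res

    t = 0.0
    y, t, res = ode_phase(y, t, min(t_ode, t_limit))
    if res > residual_tol:
        y, res = polish(y)
    while res > residual_tol and t < t_limit:
        y, t, res = ode_phase(y, t, min(t + 10 * t_ode, t_limit))
        if res > residual_tol:
            y, res = polish(y)
    return SteadyState(y=y, residual=res, converged=res <= residual_tol, t_final=t)


@dataclass
class BranchTrace:
    """One continuation trace: steady states along a lambda grid."""

    lambdas: list[float] = field(default_factory=list)
    states: list[np.ndarray] = field(default_factory=list)
    rhos: list[float] = field(default_factory=list)
    converged: list[bool] = field(default_factory=list)
    direction: str = "up"
    seed_descriptor: str = ""

    def add(self, lam: float, st: SteadyState) -> None:
        self.lambdas.append(lam)
        self.states.append(st.y)
        self.rhos.append(st.rho)
        self.converged.append(st.converged)

    def rho_at(self, lam: float) -> float | None:
        for l, r in zip(self.lambdas, self.rhos):
            if np.isclose(l, lam):
                return r
        return None


def branch_continuation(
    H: Hypergraph,
    params: DynamicsParameters,
    lambdas,
    seed_state,
    directions: tuple[str, ...] = ("up", "down"),
    seed_lambda: float | None = None,
    residual_tol: float = 1e-8,
    t_limit: float = 1e4,
    existing: list[BranchTrace] | None = None,
) -> list[BranchTrace]:
    """Trace steady-state branches by lambda continuation.

    Starting from ``seed_state`` at ``seed_lambda`` (default: grid
    midpoint), integrates to the steady state, then marches the sorted
    lambda grid in each requested direction, reusing the previous steady
    state as the initial condition.  A direction terminates early when
    the new steady state lands within ``1/N`` (in ``rho``) of an already
    recorded trace at the same lambda, or when integration fails to
    converge (trace truncated, flagged).
    """
    grid = sorted(float(x) for x in lambdas)
    if not grid:
        raise ValueError("empty lambda grid")
    N = H.node_count
    y_seed = np.clip(np.asarray(seed_state, dtype=float), 0.0, 1.0)
    if seed_lambda is None:
        seed_lambda = grid[len(grid) // 2]
    i0 = int(np.argmin(np.abs(np.array(grid) - seed_lambda)))
    known: list[BranchTrace] = list(existing) if existing else []
    traces: list[BranchTrace] = []
    merge_tol = 1.0 / N

    for direction in directions:
        idxs = range(i0, len(grid)) if direction == "up" else range(i0, -1, -1)
        trace = BranchTrace(direction=direction, seed_descriptor=f"seed@{grid[i0]:g}")
        y = y_seed.copy()
        for ii in idxs:
            lam = grid[ii]
            st = integrate_steady(
                y, H, params.replace(lam=lam), residual_tol=residual_tol, t_limit=t_limit
            )
            trace.add(lam, st)
            if not st.converged:
                break
            merged = False
            for other in known:
                r = other.rho_at(lam)
                if r is not None and abs(r - st.rho) < merge_tol:
                    merged = True
                    break
            if merged and ii != i0:
                break
            y = st.y.copy()
        traces.append(trace)
        known.append(trace)
    return traces
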