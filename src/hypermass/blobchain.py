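"""Exact occupancy chain of the hyperblob.

The hyperblob (random regular graph of degree ``k`` plus one hyperedge
containing every node) is homogeneous, so the contagion dynamics lump to
a birth-death chain on the number of active nodes ``n`` with an extra
jump to ``n = N``:

    Q[n, n-1] = delta * n                      (deactivation)
    Q[n, n+1] = lam_k * n * (N - n) / N        (pairwise spreading)
    Q[n, N]   = lam_star * 1{n >= theta}       (global hyperedge firing)

``lam_k`` is the lumped pairwise drive ``lambda * <k>`` and ``lam_star``
the bare rate of the size-N hyperedge whose critical mass is ``theta``.
The quasi-stationary (QS) chain zeroes the transition from ``n = 1`` to
the absorbing state ``n = 0``.

The QS stationary distribution follows from an O(N) forward recursion.
We evaluate it through the cut-balance (probability-flux) form

    delta * (n+1) * pi[n+1] = beta_n * pi[n]
                              + lam_star * sum_{i=theta}^{n} pi[i],

which telescopes the stationarity equations and is cancellation-free
(every term nonnegative); the terminal global-balance closure is kept as
a post-hoc residual check, and a dense null-space solve is available as
an independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.linalg import null_space
from scipy.sparse.linalg import expm_multiply

__all__ = [
    "BlobChainParams",
    "StationaryDistribution",
    "ScalingResult",
    "build_generator",
    "evolve",
    "stationary_pi",
    "stationary_nullspace",
    "chain_summary",
    "scaling_analysis",
    "fit_power_law",
]


@dataclass(frozen=True)
class BlobChainParams:
    """Parameters of the hyperblob occupancy chain.

    Exactly one of ``theta`` (integer critical mass of the global
    hyperedge) or ``theta_star`` (fraction; ``theta = ceil(theta_star*N)``)
    must determine the threshold.  ``qs=True`` applies the
    quasi-stationary constraint ``Q[1, 0] = 0``.
    """

    N: int
    lam_k: float
    lam_star: float
    delta: float = 1.0
    theta: int | None = None
    theta_star: float | None = None
    qs: bool = True

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if min(self.lam_k, self.lam_star, self.delta) < 0:
            raise ValueError("rates must be nonnegative")
        if self.theta is None:
            if self.theta_star is None:
                raise ValueError("provide theta or theta_star")
            object.__setattr__(self, "theta", int(math.ceil(self.theta_star * self.N)))
        th = self.theta
        if not 1 <= th <= self.N:
            raise ValueError(f"theta must lie in [1, N], got {th}")

    def replace(self, **kw) -> "BlobChainParams":
        d = dict(
            N=self.N,
            lam_k=self.lam_k,
            lam_star=self.lam_star,
            delta=self.delta,
            theta=self.theta,
            qs=self.qs,
        )
        d.update(kw)
        d.setdefault("theta_star", None)
        if "theta_star" in kw and kw["theta_star"] is not None:
            d["theta"] = None
        return BlobChainParams(**d)

    def birth_rates(self) -> np.ndarray:
        n = np.arange(self.N + 1, dtype=float)
        return self.lam_k * n * (self.N - n) / self.N

    def death_rates(self) -> np.ndarray:
        n = np.arange(self.N + 1, dtype=float)
        d = self.delta * n
        if self.qs:
            d[1] = 0.0
        return d


def build_generator(p: BlobChainParams) -> sp.csr_matrix:
    """Sparse generator over states ``0..N`` (rows sum to zero).

    The jump ``Q[n, N]`` adds on top of the birth rate at ``n = N - 1``;
    the self-jump at ``n = N`` is a no-op and omitted.
    """
    N = p.N
    beta = p.birth_rates()
    death = p.death_rates()
    rows, cols, vals = [], [], []
    for n in range(N + 1):
        if n >= 1 and death[n] > 0:
            rows.append(n)
            cols.append(n - 1)
            vals.append(death[n])
        out = death[n]
        if n <= N - 1 and beta[n] > 0:
            rows.append(n)
            cols.append(n + 1)
            vals.append(beta[n])
            out += beta[n]
        if p.theta <= n <= N - 1 and p.lam_star > 0:
            rows.append(n)
            cols.append(N)
            vals.append(p.lam_star)
            out += p.lam_star
        if out > 0:
            rows.append(n)
            cols.append(n)
            vals.append(-out)
    Q = sp.coo_matrix((vals, (rows, cols)), shape=(N + 1, N + 1)).tocsr()
    Q.sum_duplicates()
    return Q


def evolve(Q: sp.spmatrix, P0, times) -> np.ndarray:
    """Transient distributions ``P(t) = exp(Q^T t) P(0)`` at each time.

    Returns an array of shape ``(len(times), N+1)``; each row is
    renormalized (conservation drift must stay within 1e-10).
    """
    P0 = np.asarray(P0, dtype=float)
    if abs(P0.sum() - 1.0) > 1e-8 or np.any(P0 < -1e-12):
        raise ValueError("P0 must be a normalized distribution")
    A = sp.csr_matrix(Q).T.tocsc()
    out = np.empty((len(times), P0.size))
    for i, t in enumerate(np.asarray(times, dtype=float)):
        if t == 0:
            P = P0.copy()
        else:
            P = expm_multiply(A * t, P0)
        s = P.sum()
        if abs(s - 1.0) > 1e-10:
            P = P / s
        out[i] = np.clip(P, 0.0, None)
        out[i] /= out[i].sum()
    return out


@dataclass
class StationaryDistribution:
    """Stationary distribution ``pi`` over ``n`` active nodes plus the
    derived split at the global-hyperedge threshold."""

    pi: np.ndarray
    theta: int

    @property
    def N(self) -> int:
        return len(self.pi) - 1

    @property
    def p_lower(self) -> float:
        return float(self.pi[: self.theta].sum())

    @property
    def p_upper(self) -> float:
        return float(self.pi[self.theta:].sum())


def stationary_pi(p: BlobChainParams, residual_tol: float = 1e-6) -> StationaryDistribution:
    """QS stationary distribution by the O(N) forward recursion.

    Seeds ``pi[1] = 1`` and marches the cut-balance form upward with
    periodic renormalization against overflow; verifies the terminal
    global-balance closure to ``residual_tol`` (relative).
    """
    if not p.qs:
        raise ValueError("stationary_pi requires the QS-constrained chain")
    if p.delta <= 0:
        raise ValueError("delta must be positive for the recursion")
    N, th = p.N, p.theta
    beta = p.birth_rates()
    pi = np.zeros(N + 1, dtype=float)
    pi[1] = 1.0
    jump_sum = pi[1] if th <= 1 else 0.0
    for n in range(1, N):
        flux = beta[n] * pi[n] + p.lam_star * jump_sum
        pi[n + 1] = flux / (p.delta * (n + 1))
        if th <= n + 1:
            jump_sum += pi[n + 1]
        if pi[n + 1] > 1e250:
            pi[: n + 2] /= 1e250
            jump_sum /= 1e250
    total = pi.sum()
    pi /= total
    # closure: global balance at n = N (self-jump excluded on both sides)
    inflow = beta[N - 1] * pi[N - 1] + p.lam_star * pi[th : N].sum()
    outflow = p.delta * N * pi[N]
    scale = max(abs(inflow), abs(outflow), 1e-300)
    resid = abs(inflow - outflow) / scale
    if resid > residual_tol and outflow > 1e-280:
        raise ArithmeticError(
            f"stationary recursion closure residual {resid:.3e} exceeds "
            f"{residual_tol:.1e}; consider the null-space fallback"
        )
    return StationaryDistribution(pi=pi, theta=th)


def stationary_nullspace(Q: sp.spmatrix, theta: int | None = None) -> StationaryDistribution:
    """Stationary distribution as the normalized null vector of ``Q^T``
    (dense; oracle for moderate N).

    If state 0 is isolated (QS chain), it is excluded before the solve
    and reported with ``pi[0] = 0``.  A null space of dimension != 1
    raises a degeneracy error.
    """
    A = np.asarray(sp.csr_matrix(Q).todense(), dtype=float)
    if not np.any(A):
        raise np.linalg.LinAlgError("all-zero generator: degenerate null space")
    n_states = A.shape[0]
    drop0 = n_states > 1 and not A[0].any() and not A[:, 0].any()
    sub = A[1:, 1:] if drop0 else A
    ns = null_space(sub.T)
    if ns.shape[1] != 1:
        raise np.linalg.LinAlgError(
            f"null space dimension {ns.shape[1]} != 1 (degenerate chain)"
        )
    v = ns[:, 0]
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    v /= v.sum()
    pi = np.concatenate([[0.0], v]) if drop0 else v
    return StationaryDistribution(pi=pi, theta=theta if theta is not None else 0)


def chain_summary(dist: StationaryDistribution, p: BlobChainParams | None = None) -> dict:
    """Global and per-region summaries of a stationary distribution.

    Returns a dict with ``rho``, ``chi``, ``p_lower``, ``p_upper``, and
    regional conditional statistics (``rho_lower``, ``chi_lower``,
    ``rho_upper``, ``chi_upper``; NaN where the region carries no mass).
    The split is at the global-hyperedge threshold ``theta``.
    """
    pi = dist.pi
    th = p.theta if p is not None else dist.theta
    N = len(pi) - 1
    total = pi.sum()
    if not np.isclose(total, 1.0, atol=1e-8):
        raise ValueError("distribution must be normalized")
    n = np.arange(N + 1, dtype=float)

    def _stats(w: np.ndarray) -> tuple[float, float]:
        mass = w.sum()
        if mass <= 0:
            return float("nan"), float("nan")
        m1 = float((w * n).sum() / mass)
        m2 = float((w * n * n).sum() / mass)
        chi = (m2 - m1 * m1) / m1 if m1 > 0 else 0.0
        return m1 / N, chi

    rho, chi = _stats(pi)
    lower = pi.copy()
    lower[th:] = 0.0
    upper = pi.copy()
    upper[:th] = 0.0
    rho_lo, chi_lo = _stats(lower)
    rho_up, chi_up = _stats(upper)
    return dict(
        rho=rho,
        chi=chi,
        p_lower=float(pi[:th].sum()),
        p_upper=float(pi[th:].sum()),
        rho_lower=rho_lo,
        chi_lower=chi_lo,
        rho_upper=rho_up,
        chi_upper=chi_up,
    )


# ---------------------------------------------------------------------------
# Finite-size scaling of the transition window
# ---------------------------------------------------------------------------


def fit_power_law(sizes, widths) -> tuple[float, float]:
    """OLS fit of ``width ~ N^(-mu)`` on log-log scale.

    Returns ``(mu, standard error of mu)``.
    """
    x = np.log(np.asarray(sizes, dtype=float))
    y = np.log(np.asarray(widths, dtype=float))
    if x.size < 2:
        raise ValueError("need at least two sizes for the fit")
    A = np.vstack([x, np.ones_like(x)]).T
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    slope = coef[0]
    n = x.size
    if n > 2:
        yhat = A @ coef
        s2 = float(((y - yhat) ** 2).sum() / (n - 2))
        sxx = float(((x - x.mean()) ** 2).sum())
        se = math.sqrt(s2 / sxx)
    else:
        se = float("nan")
    return -slope, se


def _window_markers(lams: np.ndarray, summaries: list[dict], N: int):
    """Locate the transition window on a lambda grid.

    ``lam_rho_minus``: largest lambda whose global rho is within 1/N of
    the lower-region conditional rho; ``lam_rho_plus``: smallest lambda
    whose global rho is within 1/N of the upper-region conditional rho.
    ``lam_chi_minus/plus``: extremal finite-difference derivatives of
    chi(lambda) flanking the jump.
    """
    tol = 1.0 / N
    rho = np.array([s["rho"] for s in summaries])
    rho_lo = np.array([s["rho_lower"] for s in summaries])
    rho_up = np.array([s["rho_upper"] for s in summaries])
    chi = np.array([s["chi"] for s in summaries])
    near_lower = np.abs(rho - rho_lo) <= tol
    near_upper = np.abs(rho - rho_up) <= tol
    lam_minus = lams[near_lower][-1] if near_lower.any() else None
    lam_plus = lams[near_upper][0] if near_upper.any() else None
    dchi = np.diff(chi) / np.diff(lams)
    mid = 0.5 * (lams[:-1] + lams[1:])
    lam_chi_minus = float(mid[int(np.argmax(dchi))]) if dchi.size else None
    lam_chi_plus = float(mid[int(np.argmin(dchi))]) if dchi.size else None
    if lam_chi_minus is not None and lam_chi_plus is not None:
        lo, hi = sorted([lam_chi_minus, lam_chi_plus])
        lam_chi_minus, lam_chi_plus = lo, hi
    return lam_minus, lam_plus, lam_chi_minus, lam_chi_plus


@dataclass
class ScalingResult:
    """Per-size transition-window widths and the fitted scaling exponent."""

    sizes: list[int]
    width_rho: list[float]
    width_chi: list[float]
    resolved: list[bool]
    mu_rho: float
    mu_rho_se: float
    mu_chi: float
    mu_chi_se: float


def scaling_analysis(
    template: BlobChainParams,
    sizes,
    lam_grid,
    n_refine: int = 4,
    refine_factor: int = 10,
    min_window_points: int = 5,
) -> ScalingResult:
    """Widths of the hybrid-transition window versus system size.

    For each ``N`` the stationary summaries are evaluated over the
    (lumped pairwise drive) grid ``lam_grid``; the grid is refined around
    the jump until the window holds at least ``min_window_points``
    points or ``n_refine`` refinements are spent.  Sizes whose window
    stays unresolved are flagged and excluded from the log-log fit of
    ``width ~ N^(-mu)``.
    """
    sizes = [int(N) for N in sizes]
    if len(sizes) < 4:
        raise ValueError("scaling fit needs at least 4 sizes")
    base = np.sort(np.asarray(lam_grid, dtype=float))
    w_rho, w_chi, ok = [], [], []
    for N in sizes:
        p0 = template.replace(
            N=N,
            theta=None,
            theta_star=(
                template.theta_star
                if template.theta_star is not None
                else template.theta / template.N
            ),
        )

        def sweep(lams: np.ndarray):
            summ = []
            for lam in lams:
                d = stationary_pi(p0.replace(lam_k=float(lam)))
                summ.append(chain_summary(d, p0))
            return summ

        lams = base.copy()
        markers = _window_markers(lams, sweep(lams), N)
        for _ in range(n_refine):
            lm, lp = markers[0], markers[1]
            if lm is None or lp is None:
                break
            step = np.min(np.diff(lams))
            lo, hi = sorted([lm, lp])
            inside = np.sum((lams > lo) & (lams < hi))
            if inside >= min_window_points and (hi - lo) > 2 * step:
                break
            fine = np.arange(lo - 2 * step, hi + 2 * step + 1e-15, step / refine_factor)
            fine = fine[(fine > 0)]
            lams = np.unique(np.concatenate([lams, fine]))
            markers = _window_markers(lams, sweep(lams), N)
        lm, lp, cm, cp = markers
        if lm is None or lp is None:
            w_rho.append(float("nan"))
            w_chi.append(float("nan"))
            ok.append(False)
            continue
        w_rho.append(abs(lp - lm))
        w_chi.append(abs(cp - cm) if cm is not None and cp is not None else float("nan"))
        ok.append(True)
    ok_arr = np.array(ok)
    wr = np.array(w_rho)
    wc = np.array(w_chi)
    good_r = ok_arr & np.isfinite(wr) & (wr > 0)
    good_c = ok_arr & np.isfinite(wc) & (wc > 0)
    mu_r, se_r = (
        fit_power_law(np.array(sizes)[good_r], wr[good_r])
        if good_r.sum() >= 2
        else (float("nan"), float("nan"))
    )
    mu_c, se_c = (
        fit_power_law(np.array(sizes)[good_c], wc[good_c])
        if good_c.sum() >= 2
        else (float("nan"), float("nan"))
    )
    return ScalingResult(
        sizes=sizes,
        width_rho=w_rho,
        width_chi=w_chi,
        resolved=ok,
        mu_rho=mu_r,
        mu_rho_se=se_r,
        mu_chi=mu_c,
        mu_chi_se=se_c,
    )
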