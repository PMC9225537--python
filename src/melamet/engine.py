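"""Orthogonal-basis construction and metamer design.

The central idea: Gram-Schmidt-orthogonalize the five photoreceptor
sensitivities in the fixed order L, M, S, rod, ipRGC.  Because the first
four basis vectors span the cone+rod sensitivities, a spectrum written as
p = w1*e1 + ... + w5*e5 has cone and rod excitations that depend only on
w1..w4, while the ipRGC excitation alone responds to w5.  Sweeping w5 at
fixed w1..w4, subject to the device bounds 0 <= p(lambda) <= cap, yields the
feasible ipRGC modulation interval at a fixed colour; linear programs over
the same parameterization give the global maximum modulation and
five-receptor ("pentamer") pairs.

Two Gram-Schmidt conventions are supported.  The default, ``unit_diagonal``,
keeps the raw projection residuals as basis vectors so the coefficient
matrix alpha is upper triangular with unit diagonal (each sensitivity equals
its own basis vector plus projections on the earlier ones).  The
``unit_norm`` convention normalizes each residual; every physical result
(feasible intervals, metamer pairs) is independent of this choice because
it depends only on the span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space, solve_triangular
from scipy.optimize import linprog

from .core import Spectrum, WavelengthGrid
from .errors import (
    CapacityError,
    ConstraintViolationError,
    DegeneracyError,
    MelametError,
)
from .observers import ExcitationVector, PhotoreceptorSet, excitations_percent

__all__ = [
    "OrthogonalBasis",
    "FeasibleInterval",
    "MetamerPair",
    "PentamerPair",
    "build_basis",
    "synthesize",
    "realize",
    "coefficients_to_excitations",
    "excitations_to_coefficients",
    "feasible_iprgc_interval",
    "design_metamer_pair",
    "max_metamer_range",
    "pentamer_pair",
]

#: relative residual-norm threshold below which Gram-Schmidt is degenerate
_DEGENERACY_TOL = 1e-7

#: numerical slack allowed when validating realized spectra against bounds
_BOUND_TOL = 1e-7


@dataclass(frozen=True)
class OrthogonalBasis:
    """Signed orthogonal basis vectors plus the triangular coefficient matrix.

    ``vectors`` holds e1..en as rows; ``alpha`` satisfies
    sensitivity_j = sum_i alpha[i, j] * e_i.  ``excitation_matrix`` T maps
    coefficients to flat-white-percent excitations: E(w) = w @ T, where
    T[i, k] is the excitation of receptor k produced by one unit of e_i.
    """

    observer: PhotoreceptorSet
    vectors: np.ndarray
    alpha: np.ndarray
    excitation_matrix: np.ndarray
    convention: str = "unit_diagonal"

    @property
    def grid(self) -> WavelengthGrid:
        return self.observer.grid

    @property
    def n(self) -> int:
        return self.vectors.shape[0]


def build_basis(obs: PhotoreceptorSet, convention: str = "unit_diagonal") -> OrthogonalBasis:
    """Classical Gram-Schmidt over the observer's sensitivities, in order.

    Under ``unit_diagonal`` (default) the residuals are NOT renormalized and
    alpha[i, j] = <s_j, e_i> / <e_i, e_i> for i < j with alpha[j, j] = 1.
    Under ``unit_norm`` each residual is scaled to unit norm and
    alpha[i, j] = <s_j, e_i>, alpha[j, j] = ||residual_j||.
    """
    if convention not in ("unit_diagonal", "unit_norm"):
        raise ValueError(f"unknown convention {convention!r}")
    S = obs.as_matrix()
    step = obs.grid.step
    n = S.shape[0]
    E = np.zeros_like(S)
    alpha = np.zeros((n, n))
    for j in range(n):
        resid = S[j].astype(float).copy()
        for i in range(j):
            coeff = (E[i] @ S[j]) / (E[i] @ E[i])  # step cancels in the ratio
            resid -= coeff * E[i]
            if convention == "unit_diagonal":
                alpha[i, j] = coeff
            else:
                alpha[i, j] = (E[i] @ S[j]) * step  # <s_j, e_i> for unit-norm e_i
        rnorm = np.sqrt((resid @ resid) * step)
        snorm = np.sqrt((S[j] @ S[j]) * step)
        if rnorm < _DEGENERACY_TOL * snorm:
            raise DegeneracyError(
                f"receptor {obs.names[j]!r} is numerically in the span of its "
                f"predecessors (relative residual {rnorm / snorm:.2e})"
            )
        if convention == "unit_diagonal":
            alpha[j, j] = 1.0
            E[j] = resid
        else:
            alpha[j, j] = rnorm
            E[j] = resid / rnorm
    pw = np.full(S.shape[1], 100.0)
    T = 100.0 * (E @ S.T) / (S @ pw)[None, :]
    return OrthogonalBasis(obs, E, alpha, T, convention)


def synthesize(basis: OrthogonalBasis, w) -> np.ndarray:
    """Raw weighted sum of basis vectors; may be negative anywhere."""
    w = np.asarray(w, dtype=float)
    if w.shape != (basis.n,):
        raise ValueError(f"expected {basis.n} coefficients, got shape {w.shape}")
    return w @ basis.vectors


def realize(basis: OrthogonalBasis, w, cap: float = 100.0, label: str = "") -> Spectrum:
    """Validate 0 <= p(lambda) <= cap and wrap the synthesis as a Spectrum.

    Raises ConstraintViolationError with per-wavelength diagnostics when the
    combination is not physically realizable.
    """
    p = synthesize(basis, w)
    tol = _BOUND_TOL * max(cap, 1.0)
    lam = basis.grid.wavelengths
    bad = []
    for k in np.where((p < -tol) | (p > cap + tol))[0]:
        bound = 0.0 if p[k] < 0 else cap
        bad.append((float(lam[k]), float(p[k]), bound))
    if bad:
        raise ConstraintViolationError(
            f"spectrum violates [0, {cap}] bounds at {len(bad)} wavelengths "
            f"(first: {bad[0][0]} nm -> {bad[0][1]:.4g})",
            violations=bad,
        )
    return Spectrum(basis.grid, np.clip(p, 0.0, cap), label=label)


def coefficients_to_excitations(basis: OrthogonalBasis, w):
    """Excitations (percent of flat white) of synthesize(w)."""
    w = np.asarray(w, dtype=float)
    vals = w @ basis.excitation_matrix
    if basis.n == 5:
        return ExcitationVector.from_array(vals)
    return vals


def excitations_to_coefficients(basis: OrthogonalBasis, targets) -> np.ndarray:
    """Coefficients w1..wm reproducing the first m excitation targets.

    The excitation matrix restricted to the first m receptors is triangular,
    so the system has a unique solution; for the five-receptor observer with
    m = 4 this pins the cone and rod excitations while leaving the ipRGC
    coefficient w5 free.
    """
    t = np.asarray(targets, dtype=float)
    m = t.size
    if not 1 <= m < basis.n:
        raise ValueError(f"need between 1 and {basis.n - 1} targets, got {m}")
    if not np.all(np.isfinite(t)):
        raise ValueError("excitation targets must be finite")
    Tm = basis.excitation_matrix[:m, :m]
    if np.any(np.abs(np.diag(Tm)) < 1e-300):
        raise DegeneracyError("triangular excitation system is singular")
    return solve_triangular(Tm.T, t, lower=True)


@dataclass(frozen=True)
class FeasibleInterval:
    """Feasible ipRGC excitation interval at fixed cone+rod excitations."""

    feasible: bool
    i_min: float = 0.0
    i_max: float = 0.0
    binding_wavelengths: tuple = ()
    omega_fixed: tuple = ()
    omega5_bounds: tuple = (0.0, 0.0)

    @property
    def width(self) -> float:
        return self.i_max - self.i_min if self.feasible else 0.0


def feasible_iprgc_interval(obs, targets, cap: float = 100.0,
                            basis: OrthogonalBasis | None = None) -> FeasibleInterval:
    """Closed-form feasible ipRGC interval at the given (L, M, S, rod) percents.

    With w1..w4 fixed by triangular inversion and q = sum w_i e_i, the
    feasible set of w5 is the intersection over wavelengths of
    { w5 : 0 <= q(lk) + w5 * e5(lk) <= cap }, a closed interval; the ipRGC
    excitation is affine increasing in w5, so the interval maps directly to
    [i_min, i_max].  Infeasible targets return ``feasible=False`` rather
    than raising.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    if basis is None:
        basis = build_basis(obs) if isinstance(obs, PhotoreceptorSet) else obs
    m = basis.n - 1
    w_fixed = excitations_to_coefficients(basis, np.asarray(targets, float)[:m])
    q = w_fixed @ basis.vectors[:m]
    e_last = basis.vectors[m]
    lam = basis.grid.wavelengths
    tol = 1e-12 * max(np.max(np.abs(e_last)), 1.0)
    lo, hi = -np.inf, np.inf
    lo_idx = hi_idx = -1
    for k in range(lam.size):
        ek, qk = e_last[k], q[k]
        if ek > tol:
            l, h = -qk / ek, (cap - qk) / ek
        elif ek < -tol:
            l, h = (cap - qk) / ek, -qk / ek
        else:
            if qk < -1e-9 * cap or qk > cap * (1 + 1e-9):
                return FeasibleInterval(False, omega_fixed=tuple(w_fixed))
            continue
        if l > lo:
            lo, lo_idx = l, k
        if h < hi:
            hi, hi_idx = h, k
    if lo > hi:
        # zero-width targets (e.g. the flat white at the cap) can round to a
        # marginally inverted interval; collapse those to a point
        tol = 1e-7 * max(1.0, abs(lo), abs(hi))
        if lo - hi > tol:
            return FeasibleInterval(False, omega_fixed=tuple(w_fixed))
        lo = hi = 0.5 * (lo + hi)
    i_col = basis.excitation_matrix[:, m]
    i0 = float(w_fixed @ i_col[:m])
    slope = float(i_col[m])  # <e5, s5>-derived, strictly positive
    binding = tuple(
        float(lam[k]) for k in sorted({i for i in (lo_idx, hi_idx) if i >= 0})
    )
    return FeasibleInterval(
        True,
        i_min=i0 + lo * slope,
        i_max=i0 + hi * slope,
        binding_wavelengths=binding,
        omega_fixed=tuple(w_fixed),
        omega5_bounds=(float(lo), float(hi)),
    )


@dataclass(frozen=True)
class MetamerPair:
    """Two realizable spectra sharing cone+rod excitations, differing in ipRGC."""

    spectrum_max: Spectrum
    spectrum_min: Spectrum
    shared: tuple
    delta_i: float


def design_metamer_pair(obs, targets, cap: float = 100.0,
                        requested_delta="max") -> MetamerPair:
    """A metamer pair at the given cone+rod excitations.

    ``requested_delta="max"`` returns the pair at the interval endpoints;
    a numeric delta returns a symmetric pair around the interval midpoint.
    """
    basis = build_basis(obs) if isinstance(obs, PhotoreceptorSet) else obs
    interval = feasible_iprgc_interval(basis.observer, targets, cap, basis=basis)
    if not interval.feasible:
        raise CapacityError(
            f"targets {tuple(targets)} are infeasible under cap={cap}", achievable=0.0
        )
    lo, hi = interval.omega5_bounds
    slope = float(basis.excitation_matrix[basis.n - 1, basis.n - 1])
    if requested_delta == "max":
        w5_hi, w5_lo = hi, lo
    else:
        delta = float(requested_delta)
        if delta < 0:
            raise ValueError("requested_delta must be non-negative")
        if delta > interval.width * (1 + 1e-9):
            raise CapacityError(
                f"requested delta {delta:.4g}% exceeds the feasible width",
                achievable=interval.width,
            )
        mid = 0.5 * (lo + hi)
        half = 0.5 * delta / slope
        w5_hi, w5_lo = mid + half, mid - half
    w = np.append(np.asarray(interval.omega_fixed), 0.0)
    p_hi = realize(basis, np.append(w[:-1], w5_hi), cap, label="iprgc_max")
    p_lo = realize(basis, np.append(w[:-1], w5_lo), cap, label="iprgc_min")
    return MetamerPair(
        spectrum_max=p_hi,
        spectrum_min=p_lo,
        shared=tuple(float(t) for t in np.asarray(targets, float)[: basis.n - 1]),
        delta_i=(w5_hi - w5_lo) * slope,
    )


def _run_linprog(c, A_ub, b_ub, A_eq=None, b_eq=None):
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
        bounds=[(None, None)] * len(c), method="highs",
    )
    return res


def max_metamer_range(obs, match_rod: bool = True, cap: float = 100.0,
                      basis: OrthogonalBasis | None = None):
    """Global maximum of I(p1) - I(p2) over bounded metameric pairs.

    One linear program: the pair shares w1..w4 (w1..w3 when ``match_rod`` is
    False), each member has its own trailing coefficients, and both satisfy
    0 <= p <= cap per wavelength.  Returns ``(width_percent, MetamerPair)``.
    """
    if basis is None:
        basis = build_basis(obs) if isinstance(obs, PhotoreceptorSet) else obs
    n = basis.n
    ns = (n - 1) if match_rod else (n - 2)
    nf = n - ns
    E = basis.vectors
    nwl = E.shape[1]
    t_free = basis.excitation_matrix[ns:, n - 1]
    c = np.concatenate([np.zeros(ns), -t_free, t_free])
    A1 = np.hstack([E[:ns].T, E[ns:].T, np.zeros((nwl, nf))])
    A2 = np.hstack([E[:ns].T, np.zeros((nwl, nf)), E[ns:].T])
    A_ub = np.vstack([A1, -A1, A2, -A2])
    b_ub = np.concatenate([np.full(nwl, cap), np.zeros(nwl)] * 2)
    res = _run_linprog(c, A_ub, b_ub)
    if res.status != 0:
        raise MelametError(f"LP solver failed: {res.message} (status {res.status})")
    x = res.x
    w1 = np.concatenate([x[:ns], x[ns:ns + nf]])
    w2 = np.concatenate([x[:ns], x[ns + nf:]])
    p1 = realize(basis, w1, cap, label="iprgc_max")
    p2 = realize(basis, w2, cap, label="iprgc_min")
    shared = tuple((w1 @ basis.excitation_matrix)[:ns])
    return -res.fun, MetamerPair(p1, p2, shared=shared, delta_i=-res.fun)


@dataclass(frozen=True)
class PentamerPair:
    """Two spectra with identical excitations in ALL receptors."""

    spectrum_a: Spectrum
    spectrum_b: Spectrum
    l1_difference: float  # integral of |a - b| over wavelength
    excitations: object


def pentamer_pair(obs: PhotoreceptorSet, base: Spectrum, cap: float = 100.0,
                  max_iter: int = 30) -> PentamerPair:
    """Most-different spectrum pair with every receptor excitation equal.

    Finds a perturbation d in the null space of the receptor response map
    (so <d, s_k> = 0 for all k) maximizing the L1 spectral difference subject
    to 0 <= base +/- d/2 <= cap.  Maximizing an L1 norm over a polytope is a
    convex-maximization problem; it is solved by iterative sign
    linearization: fix a sign pattern, solve the resulting LP over the
    null-space coordinates, update the signs to match the solution, repeat
    until the pattern is stable.  Deterministic restarts over the leading
    null-space directions guard against poor local optima.
    """
    if base.grid != obs.grid:
        raise ValueError("base spectrum and observer must share a grid")
    S = obs.as_matrix()
    nwl = S.shape[1]
    if nwl <= S.shape[0]:
        raise ValueError("grid must have more samples than receptors")
    N = null_space(S)  # (nwl, nwl - n_receptors)
    u = 2.0 * np.minimum(base.values, cap - base.values)
    u = np.clip(u, 0.0, None)
    step = obs.grid.step
    if np.all(u <= 0):
        exc = excitations_percent(base, obs)
        return PentamerPair(base, base, 0.0, exc)
    A_ub = np.vstack([N, -N])
    b_ub = np.concatenate([u, u])
    best_d, best_l1 = np.zeros(nwl), -1.0
    n_restarts = min(3, N.shape[1])
    for j in range(n_restarts):
        sigma = np.sign(N[:, j])
        sigma[sigma == 0] = 1.0
        for _ in range(max_iter):
            res = _run_linprog(-(sigma @ N), A_ub, b_ub)
            if res.status != 0:
                raise MelametError(f"LP solver failed: {res.message}")
            d = N @ res.x
            new_sigma = np.sign(d)
            new_sigma[new_sigma == 0] = 1.0
            if np.array_equal(new_sigma, sigma):
                break
            sigma = new_sigma
        l1 = float(np.sum(np.abs(d))) * step
        if l1 > best_l1:
            best_l1, best_d = l1, d
    a_vals = np.clip(base.values + best_d / 2.0, 0.0, cap)
    b_vals = np.clip(base.values - best_d / 2.0, 0.0, cap)
    a = Spectrum(base.grid, a_vals, label="pentamer_a")
    b = Spectrum(base.grid, b_vals, label="pentamer_b")
    return PentamerPair(a, b, best_l1, excitations_percent(a, obs))
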