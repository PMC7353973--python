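"""Equilibria of the two-patch system and their linear stability.

Three routes to an equilibrium are implemented, matching the structure
of the model:

* **No movement** (``p = 1``, ``beta = 0``): the patches decouple and
  each behaves as a Lotka–Volterra pair with logistic prey. The resource
  settles at ``R* = mu / (c alpha)`` in both patches and the consumer at
  ``C_i* = (r_i / alpha) (1 - mu / (c alpha K_i))`` — closed form.
* **No demography** (``p = 0``): total consumers are conserved, and the
  unique positive equilibrium satisfies the flux balance
  ``C_L Q_HL = C_H Q_LH``, equivalently

      C_L*/C_H* = exp(-2 lam c alpha (R_H* - R_L*)),

  with each resource on its nullcline ``R_i* = K_i (1 - alpha C_i*/r_i)``.
  This reduces to a scalar root-finding problem in ``C_H`` on
  ``(0, 2 C_T)``, solved by bracketed Brent iteration (the log-ratio form
  of the balance is strictly monotone in ``C_H``, so the bracketed solve
  is unconditionally convergent). The equilibrium is independent of the
  mobility ``beta``, which only sets the speed of convergence.
* **General case** (``p = 1``, ``beta > 0``): no closed form; a
  multidimensional quasi-Newton root of the derivative field, seeded by
  default from the no-movement closed form (where the fitness gap is
  exactly zero, keeping the movement exponential tame even at extreme
  fitness sensitivity), with a long-integration fallback.

Stability is classified from eigenvalues of a finite-difference Jacobian
of the implemented right-hand side. For ``p = 0`` the conserved consumer
total induces a neutral direction in the full 4-D system, so stability is
assessed on the reduced 3-D system obtained by eliminating
``C_L = 2 C_T - C_H``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, root

from .model import (
    FitnessPair,
    ModelParams,
    SystemState,
    _rhs,
    fitness,
    movement_rate,
    simulate,
)

__all__ = [
    "ConservedTotal",
    "EquilibriumResult",
    "EquilibriumError",
    "equilibrium_no_movement",
    "equilibrium_no_demography",
    "equilibrium_numeric",
    "integrate_to_equilibrium",
    "find_equilibrium",
    "jacobian",
    "stability_eigenvalues",
    "flux_balance_check",
    "residual_norm",
]


class EquilibriumError(RuntimeError):
    """Raised when an equilibrium computation fails or its preconditions
    are violated."""


@dataclass(frozen=True)
class ConservedTotal:
    """Mean consumer density per patch, C_T, for the demography-free
    model; total consumers across both (equal-sized) patches is 2 C_T."""

    C_T: float

    def __post_init__(self) -> None:
        if not self.C_T > 0:
            raise ValueError(f"C_T must be > 0, got {self.C_T}")


@dataclass(frozen=True)
class EquilibriumResult:
    """An equilibrium state with diagnostics.

    Attributes
    ----------
    state : SystemState
        The equilibrium densities.
    fitness : FitnessPair
        Consumer fitness in each patch at the equilibrium.
    residual : float
        Max-norm of the derivative field at ``state``.
    stable : bool
        True iff every eigenvalue real part is negative.
    eigen_real_parts : tuple of float
        Real parts of the Jacobian eigenvalues used for classification:
        four for the full system, three when demography is off and the
        conserved-total reduction applies.
    method : str
        One of ``closed_form_no_movement``, ``implicit_no_demography``,
        ``numeric_root``, ``integration_endpoint``.
    """

    state: SystemState
    fitness: FitnessPair
    residual: float
    stable: bool
    eigen_real_parts: tuple
    method: str

    def to_record(self) -> dict:
        """Flatten to a plain record (CSV/JSON row)."""
        return {
            "R_H": self.state.R_H,
            "R_L": self.state.R_L,
            "C_H": self.state.C_H,
            "C_L": self.state.C_L,
            "w_H": self.fitness.w_H,
            "w_L": self.fitness.w_L,
            "residual": self.residual,
            "stable": self.stable,
            "method": self.method,
        }


def residual_norm(state: SystemState, params: ModelParams) -> float:
    """Max-norm of the derivative field at ``state``."""
    return float(np.max(np.abs(_rhs(state.as_array(), params))))


# ---------------------------------------------------------------------------
# Jacobians and stability


def _fd_jacobian(fun, x: np.ndarray) -> np.ndarray:
    """Central finite-difference Jacobian, step h = 1e-6 * max(1, |x_j|)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    J = np.empty((n, n))
    for j in range(n):
        h = 1e-6 * max(1.0, abs(x[j]))
        xp = x.copy()
        xm = x.copy()
        xp[j] += h
        xm[j] -= h
        J[:, j] = (fun(xp) - fun(xm)) / (2.0 * h)
    return J


def jacobian(state: SystemState, params: ModelParams) -> np.ndarray:
    """4x4 Jacobian of the derivative field at ``state`` by central
    finite differences on the implemented right-hand side (keeps the
    stability check honest against the code actually integrated)."""
    return _fd_jacobian(lambda y: _rhs(y, params), state.as_array())


def _reduced_rhs(y3: np.ndarray, params: ModelParams, two_CT: float) -> np.ndarray:
    """Demography-free dynamics on (R_H, R_L, C_H) with C_L eliminated
    through the conserved total."""
    y = np.array([y3[0], y3[1], y3[2], two_CT - y3[2]])
    d = _rhs(y, params)
    return d[:3]


def stability_eigenvalues(
    state: SystemState,
    params: ModelParams,
    total: ConservedTotal | None = None,
) -> tuple:
    """Real parts of the Jacobian eigenvalues governing local stability.

    For ``p = 0`` with a conserved total supplied, the 3-D reduced system
    (C_L eliminated) is linearized, removing the structural neutral mode
    along the conservation direction; otherwise the full 4-D system is
    used.
    """
    if params.p == 0 and total is not None:
        y3 = state.as_array()[:3]
        J = _fd_jacobian(lambda y: _reduced_rhs(y, params, 2.0 * total.C_T), y3)
    else:
        J = jacobian(state, params)
    re = np.sort(np.linalg.eigvals(J).real)[::-1]
    return tuple(float(v) for v in re)


def _build_result(
    state: SystemState,
    params: ModelParams,
    method: str,
    total: ConservedTotal | None = None,
) -> EquilibriumResult:
    eigs = stability_eigenvalues(state, params, total)
    return EquilibriumResult(
        state=state,
        fitness=fitness(state, params),
        residual=residual_norm(state, params),
        stable=max(eigs) < 0.0,
        eigen_real_parts=eigs,
        method=method,
    )


# ---------------------------------------------------------------------------
# Closed and implicit forms


def equilibrium_no_movement(params: ModelParams) -> EquilibriumResult:
    """Closed-form equilibrium for immobile consumers with demography
    (``p = 1``, ``beta = 0``): the classic Lotka–Volterra result in which
    the resource equilibrium is set by consumer mortality, identically in
    both patches, so fitness is exactly zero everywhere.

    Raises
    ------
    EquilibriumError
        If ``p != 1`` or ``beta != 0``, or if ``mu/(c alpha) >= K_i`` in
        either patch (the consumer cannot persist there, outside the
        positive-density regime considered).
    """
    if params.p != 1:
        raise EquilibriumError("closed form requires consumer demography (p = 1)")
    if params.beta != 0:
        raise EquilibriumError("closed form requires immobile consumers (beta = 0)")
    R_star = params.mu / (params.c * params.alpha)
    for label, patch in (("H", params.high), ("L", params.low)):
        if R_star >= patch.K:
            raise EquilibriumError(
                f"consumer cannot persist in patch {label}: "
                f"mu/(c*alpha) = {R_star:.6g} >= K = {patch.K:.6g}"
            )
    C_H = (params.high.r / params.alpha) * (1.0 - R_star / params.high.K)
    C_L = (params.low.r / params.alpha) * (1.0 - R_star / params.low.K)
    state = SystemState(R_H=R_star, R_L=R_star, C_H=C_H, C_L=C_L)
    return _build_result(state, params, "closed_form_no_movement")


def _resource_nullclines(params: ModelParams, C_H: float, C_L: float) -> tuple[float, float]:
    R_H = params.high.K * (1.0 - params.alpha * C_H / params.high.r)
    R_L = params.low.K * (1.0 - params.alpha * C_L / params.low.r)
    return R_H, R_L


def equilibrium_no_demography(
    params: ModelParams, total: ConservedTotal
) -> EquilibriumResult:
    """Unique positive equilibrium of the demography-free model.

    Solves the flux-balance condition in log-ratio form,

        g(C_H) = ln((2 C_T - C_H)/C_H)
                 + 2 lam c alpha [R_H(C_H) - R_L(2 C_T - C_H)] = 0,

    by Brent's method on the bracket ``(eps, 2 C_T - eps)``; ``g`` is
    strictly decreasing in ``C_H``, so the root is unique whenever the
    bracket straddles a sign change. The equilibrium does not depend on
    mobility ``beta``.

    Raises
    ------
    EquilibriumError
        If ``p != 0`` or ``beta <= 0`` (movement must couple the
        patches), or if the bracket shows no sign change or the solution
        leaves a resource density non-positive (parameters outside the
        positive-density regime).
    """
    if params.p != 0:
        raise EquilibriumError("implicit form requires demography off (p = 0)")
    if not params.beta > 0:
        raise EquilibriumError("implicit form requires beta > 0 (movement couples the patches)")
    two_CT = 2.0 * total.C_T
    k = 2.0 * params.lam * params.c * params.alpha

    def g(C_H: float) -> float:
        C_L = two_CT - C_H
        R_H, R_L = _resource_nullclines(params, C_H, C_L)
        return np.log(C_L / C_H) + k * (R_H - R_L)

    eps = 1e-12 * total.C_T
    a, b = eps, two_CT - eps
    ga, gb = g(a), g(b)
    if not (ga > 0 > gb or ga < 0 < gb):
        raise EquilibriumError(
            "flux-balance bracket shows no sign change; parameters appear to be "
            "outside the positive-density regime"
        )
    C_H = brentq(g, a, b, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    C_L = two_CT - C_H
    R_H, R_L = _resource_nullclines(params, C_H, C_L)
    if R_H <= 0 or R_L <= 0:
        raise EquilibriumError(
            f"equilibrium has non-positive resource density (R_H={R_H:.6g}, "
            f"R_L={R_L:.6g}); outside the positive-density regime"
        )
    state = SystemState(R_H=R_H, R_L=R_L, C_H=C_H, C_L=C_L)
    result = _build_result(state, params, "implicit_no_demography", total)
    if result.residual >= 1e-8:
        raise EquilibriumError(
            f"implicit solve left residual {result.residual:.3g} >= 1e-8"
        )
    return result


# ---------------------------------------------------------------------------
# General numerical routes


def _default_guess(params: ModelParams, total: ConservedTotal | None) -> SystemState:
    """Seed for the quasi-Newton solve.

    For p = 1 the no-movement closed form is used: its fitness gap is
    exactly zero, so the movement exponential starts at 1 regardless of
    lam. For p = 0, resources at half carrying capacity with consumers
    split equally.
    """
    if params.p == 1:
        R_star = params.mu / (params.c * params.alpha)
        if R_star < params.high.K and R_star < params.low.K:
            C_H = (params.high.r / params.alpha) * (1.0 - R_star / params.high.K)
            C_L = (params.low.r / params.alpha) * (1.0 - R_star / params.low.K)
            return SystemState(R_star, R_star, C_H, C_L)
        return SystemState(params.high.K / 2, params.low.K / 2, 1.0, 1.0)
    C_T = total.C_T if total is not None else 1.0
    return SystemState(params.high.K / 2, params.low.K / 2, C_T, C_T)


def equilibrium_numeric(
    params: ModelParams,
    guess: SystemState | None = None,
    total: ConservedTotal | None = None,
) -> EquilibriumResult:
    """Equilibrium by multidimensional root-finding on the derivative
    field (the general route when no closed or implicit form applies).

    For ``p = 0`` the conserved consumer total makes the full 4-D field
    singular at its fixed points, so the solve runs on the reduced 3-D
    system with the total taken from ``total`` or from the guess.

    Raises
    ------
    EquilibriumError
        On non-convergence, on a residual above 1e-10, or if the
        converged root has a negative component.
    """
    if guess is None:
        guess = _default_guess(params, total)
    if params.p == 0:
        if total is None:
            total = ConservedTotal(C_T=guess.total_consumers() / 2.0)
        two_CT = 2.0 * total.C_T
        sol = root(
            lambda y: _reduced_rhs(y, params, two_CT),
            guess.as_array()[:3],
            method="hybr",
            tol=1e-13,
        )
        y = np.append(sol.x, two_CT - sol.x[2])
    else:
        sol = root(lambda y: _rhs(y, params), guess.as_array(), method="hybr", tol=1e-13)
        y = sol.x
    if not sol.success:
        raise EquilibriumError(f"root-finding did not converge: {sol.message}")
    if y.min() < -1e-10:
        raise EquilibriumError(
            f"converged root has a negative component: {y} "
            "(outside the positive-density regime)"
        )
    state = SystemState.from_array(y, tol=1e-10)
    result = _build_result(state, params, "numeric_root", total)
    if result.residual >= 1e-10:
        raise EquilibriumError(
            f"numeric root left residual {result.residual:.3g} >= 1e-10"
        )
    return result


def integrate_to_equilibrium(
    params: ModelParams,
    init: SystemState,
    horizon: float = 5000.0,
    *,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> EquilibriumResult:
    """Equilibrium estimate from the endpoint of a long integration
    (the simulation route; slower but assumption-free, used to
    cross-validate the root-finding routes)."""
    sol = simulate(params, init, horizon, rtol=rtol, atol=atol)
    state = SystemState.from_array(sol.y[:, -1])
    total = ConservedTotal(state.total_consumers() / 2.0) if params.p == 0 else None
    return _build_result(state, params, "integration_endpoint", total)


def find_equilibrium(
    params: ModelParams,
    total: ConservedTotal | None = None,
    guess: SystemState | None = None,
    method: str = "auto",
) -> EquilibriumResult:
    """Dispatch to the cheapest valid equilibrium route.

    ``auto`` resolves to: closed form when ``p = 1`` and ``beta = 0``;
    the implicit scalar solve when ``p = 0``; otherwise the numeric root
    with a long-integration fallback on non-convergence.
    """
    if method == "auto":
        if params.p == 1 and params.beta == 0:
            method = "closed_form"
        elif params.p == 0:
            method = "implicit"
        else:
            method = "numeric"
    if method == "closed_form":
        return equilibrium_no_movement(params)
    if method == "implicit":
        if total is None:
            raise EquilibriumError(
                "the demography-free equilibrium needs the conserved total C_T"
            )
        return equilibrium_no_demography(params, total)
    if method == "numeric":
        try:
            return equilibrium_numeric(params, guess=guess, total=total)
        except EquilibriumError:
            init = guess if guess is not None else _default_guess(params, total)
            endpoint = integrate_to_equilibrium(params, init)
            # polish the endpoint so the result meets the root tolerance
            return equilibrium_numeric(params, guess=endpoint.state, total=total)
    if method == "integration":
        init = guess if guess is not None else _default_guess(params, total)
        return integrate_to_equilibrium(params, init)
    raise ValueError(f"unknown method {method!r}")


def flux_balance_check(result: EquilibriumResult, params: ModelParams) -> float:
    """Residual of the migration flux balance ``|C_L Q_HL - C_H Q_LH|``
    at a demography-free equilibrium (zero at the true fixed point; a
    perturbed state shows a positive residual)."""
    w = result.fitness
    Q_HL = movement_rate(w.w_H, w.w_L, params.beta, params.lam)
    Q_LH = movement_rate(w.w_L, w.w_H, params.beta, params.lam)
    return abs(result.state.C_L * Q_HL - result.state.C_H * Q_LH)
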