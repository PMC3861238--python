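"""Replicator(-mutator) dynamics over the strategy simplex.

The population state is a frequency vector ``x`` on the (m-1)-simplex,
``m = 26`` for the full strategy set.  Fitness is ``f = M x`` with ``M`` the
expected-payoff matrix, the mean payoff is ``phi = x . f``, and frequencies
evolve by the replicator-mutator equation with a uniform mutation kernel

    dx_i/dt = (mu/m) phi + (1 - mu) x_i f_i - x_i phi,

which preserves the simplex and reduces to the plain replicator equation
``dx_i/dt = x_i (f_i - phi)`` at ``mu = 0``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .automata import strategy_names

MatrixLike = Union[np.ndarray, pd.DataFrame]


def _as_array(M: MatrixLike) -> np.ndarray:
    return np.asarray(M, dtype=float)


class AttractorClass(enum.Enum):
    """Classes of terminal states observed in this game."""

    PURE_ALLD = "pure_alld"
    PURE_GRIM = "pure_grim"
    MIXED_FORGIVER = "mixed_forgiver"
    MIXED_SFORGIVER = "mixed_sforgiver"
    GRIM_ALLC = "grim_allc"
    OTHER = "other"


@dataclass(frozen=True)
class DynamicsParameters:
    """Integration controls.

    ``mu`` is the mutation rate; convergence is declared when the field's sup
    norm drops below ``tol``; ``t_max`` caps the integration time (payoff-time
    units).  Components are clipped at zero and renormalized only at
    reporting, not during stepping.
    """

    mu: float = 0.0
    tol: float = 1e-9
    t_max: float = 1e6
    rtol: float = 1e-10
    atol: float = 1e-12
    max_saddle_escapes: int = 8

    def __post_init__(self) -> None:
        if not 0 <= self.mu < 1:
            raise ValueError(f"mutation rate must lie in [0, 1), got {self.mu}")
        if self.tol <= 0 or self.t_max <= 0:
            raise ValueError("tol and t_max must be positive")


@dataclass(frozen=True)
class AttractorReport:
    """Terminal state of one trajectory.

    ``support`` maps strategy names with terminal frequency above 1% to their
    frequencies.  ``converged`` is False when the time cap was hit first; the
    class is then reported as OTHER.
    """

    x_star: np.ndarray
    attractor: AttractorClass
    residual: float
    support: Dict[str, float]
    t_end: float
    converged: bool
    saddle_escapes: int = 0


def sample_simplex(m: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform-random point on the (m-1)-simplex.

    Takes the negative logarithm of ``m`` uniform random numbers in (0, 1]
    and normalizes them to sum to one (equivalently a flat Dirichlet draw).
    """
    if m < 2:
        raise ValueError("need at least two strategies")
    u = 1.0 - rng.random(m)  # uniform on (0, 1]
    x = -np.log(u)
    return x / x.sum()


def replicator_derivative(
    x: np.ndarray, M: MatrixLike, mu: float = 0.0
) -> np.ndarray:
    """Time derivative of the frequency vector (uniform mutation kernel)."""
    M = _as_array(M)
    x = np.asarray(x, dtype=float)
    f = M @ x
    phi = x @ f
    if mu == 0.0:
        return x * (f - phi)
    m = x.size
    return (mu / m) * phi + (1.0 - mu) * x * f - x * phi


def _tangent_basis(m: int) -> np.ndarray:
    """Orthonormal basis of the tangent space {sum(delta) = 0}, shape (m, m-1)."""
    from scipy.linalg import null_space

    return null_space(np.ones((1, m)))


def tangent_jacobian(
    x: np.ndarray, M: MatrixLike, mu: float = 0.0, step: float = 1e-7
) -> np.ndarray:
    """Jacobian of the field by central differences, projected on the tangent space.

    Returns the (m-1) x (m-1) matrix ``Q^T J Q`` where the columns of ``Q``
    span the directions that keep the frequencies summing to one.
    """
    M = _as_array(M)
    x = np.asarray(x, dtype=float)
    m = x.size
    Q = _tangent_basis(m)
    cols = np.empty((m, m - 1))
    for k in range(m - 1):
        d = step * Q[:, k]
        cols[:, k] = (
            replicator_derivative(x + d, M, mu) - replicator_derivative(x - d, M, mu)
        ) / (2 * step)
    return Q.T @ cols


def classify_attractor(
    x: np.ndarray, names: Optional[Sequence[str]] = None
) -> AttractorClass:
    """Classify a converged terminal state.

    Pure states require a frequency above 0.99; mixed Forgiver/sForgiver
    states require the eponymous strategy to be the largest component with
    more than half the population; GRIM_ALLC requires the support (frequency
    above 1%) to be exactly {Grim, ALLC}.
    """
    if names is None:
        names = strategy_names()
    x = np.asarray(x, dtype=float)
    idx = {n: i for i, n in enumerate(names)}
    if x[idx["ALLD"]] > 0.99:
        return AttractorClass.PURE_ALLD
    if x[idx["Grim"]] > 0.99:
        return AttractorClass.PURE_GRIM
    top = int(np.argmax(x))
    if names[top] == "Forgiver" and x[top] > 0.5:
        return AttractorClass.MIXED_FORGIVER
    if names[top] == "sForgiver" and x[top] > 0.5:
        return AttractorClass.MIXED_SFORGIVER
    support = {names[i] for i in np.flatnonzero(x > 0.01)}
    if support == {"Grim", "ALLC"}:
        return AttractorClass.GRIM_ALLC
    return AttractorClass.OTHER


def integrate(
    x0: np.ndarray,
    M: MatrixLike,
    params: Optional[DynamicsParameters] = None,
    names: Optional[Sequence[str]] = None,
) -> AttractorReport:
    """Integrate the replicator(-mutator) flow to an attractor.

    Uses an adaptive stepper (LSODA) in chunks of 2000 time units; at each
    chunk boundary the residual ``||dx/dt||_inf`` is tested against ``tol``
    and the slow numerical drift off the simplex is projected away (states
    are never renormalized within a step).  A rest point with a significantly
    positive leading tangent-space eigenvalue is a saddle and is escaped by a
    small push along the unstable direction, so reports name genuine
    attractors; hitting the time cap yields ``converged=False`` / OTHER.
    """
    if params is None:
        params = DynamicsParameters()
    M = _as_array(M)
    if names is None:
        names = strategy_names() if M.shape[0] == 26 else [
            f"s{i}" for i in range(M.shape[0])
        ]
    mu = params.mu

    def rhs(t: float, x: np.ndarray) -> np.ndarray:
        with np.errstate(over="ignore", invalid="ignore"):
            return replicator_derivative(x, M, mu)

    def guard_event(t: float, x: np.ndarray) -> float:
        # stops runaway excursions off the simplex before they overflow
        with np.errstate(invalid="ignore"):
            m = np.max(np.abs(x))
        if not np.isfinite(m):
            m = 1e6
        return 1.5 - min(float(m), 1e6)

    guard_event.terminal = True  # type: ignore[attr-defined]

    # eigenvalues of true attractors are <= 0; saddles repel at O(payoff) rates
    saddle_tol = 1e-6 * max(1.0, float(np.max(np.abs(M))))
    x = np.asarray(x0, dtype=float).copy()
    t = 0.0
    escapes = 0
    failures = 0
    converged = False
    # Integrate in chunks: at chunk boundaries (never within a step) the
    # slow numerical drift off the invariant simplex is projected away,
    # which prevents capture by spurious off-simplex equilibria.
    chunk = 2000.0
    while True:
        if np.max(np.abs(replicator_derivative(x, M, mu))) < params.tol:
            # at rest: accept if it is a genuine attractor, else leave the
            # saddle along its unstable direction
            J = tangent_jacobian(x, M, mu)
            eigvals, eigvecs = np.linalg.eig(J)
            lead = int(np.argmax(eigvals.real))
            if eigvals.real[lead] <= saddle_tol:
                converged = True
                break
            if escapes >= params.max_saddle_escapes:
                break
            Q = _tangent_basis(x.size)
            direction = Q @ np.real(eigvecs[:, lead])
            direction /= np.max(np.abs(direction))
            # push far enough that the field clears the tolerance again
            delta = max(1e-7, 10.0 * params.tol / eigvals.real[lead])
            for sign in (1.0, -1.0):
                trial = x + sign * delta * direction
                if np.all(trial > -1e-15):
                    x = np.clip(trial, 0.0, None)
                    x /= x.sum()
                    break
            escapes += 1
        if t >= params.t_max:
            break
        try:
            sol = solve_ivp(
                rhs,
                (t, min(t + chunk, params.t_max)),
                x,
                method="LSODA",
                rtol=params.rtol,
                atol=params.atol,
                events=guard_event,
                dense_output=False,
            )
        except ValueError:
            # grazing event crossing confused the root finder: retry without
            sol = solve_ivp(
                rhs,
                (t, min(t + chunk, params.t_max)),
                x,
                method="LSODA",
                rtol=params.rtol,
                atol=params.atol,
            )
        x = sol.y[:, -1]
        t = sol.t[-1]
        if not np.all(np.isfinite(x)):
            finite = np.flatnonzero(np.all(np.isfinite(sol.y), axis=0))
            x = sol.y[:, finite[-1]] if finite.size else np.asarray(x0, float)
        x = np.clip(x, 0.0, None)
        x /= x.sum()
        if sol.status == -1:  # step failure: retry from the projected state
            failures += 1
            if failures > 5:
                break

    x = np.clip(x, 0.0, None)
    x /= x.sum()
    residual = float(np.max(np.abs(replicator_derivative(x, M, mu))))
    attractor = (
        classify_attractor(x, names) if converged else AttractorClass.OTHER
    )
    support = {
        str(names[i]): float(x[i]) for i in np.flatnonzero(x > 0.01)
    }
    return AttractorReport(
        x_star=x,
        attractor=attractor,
        residual=residual,
        support=support,
        t_end=float(t),
        converged=converged,
        saddle_escapes=escapes,
    )


@dataclass(frozen=True)
class BasinStatistics:
    """Basin-of-attraction estimate from uniform random starting points."""

    fractions: Dict[AttractorClass, float]
    n_starts: int
    n_unconverged: int
    counts: Dict[AttractorClass, int] = field(default_factory=dict)


def basin_statistics(
    M: MatrixLike,
    n_starts: int,
    params: Optional[DynamicsParameters] = None,
    *,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    names: Optional[Sequence[str]] = None,
) -> BasinStatistics:
    """Fractions of uniform-random starts converging to each attractor class."""
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    M = _as_array(M)
    counts: Dict[AttractorClass, int] = {c: 0 for c in AttractorClass}
    unconverged = 0
    for _ in range(n_starts):
        x0 = sample_simplex(M.shape[0], rng)
        report = integrate(x0, M, params, names=names)
        counts[report.attractor] += 1
        if not report.converged:
            unconverged += 1
    fractions = {c: counts[c] / n_starts for c in AttractorClass}
    return BasinStatistics(
        fractions=fractions,
        n_starts=n_starts,
        n_unconverged=unconverged,
        counts=counts,
    )
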