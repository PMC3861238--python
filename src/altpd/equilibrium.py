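"""Strict-Nash detection and local stability of replicator fixed points."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .dynamics import MatrixLike, _as_array, replicator_derivative, tangent_jacobian


@dataclass(frozen=True)
class NashReport:
    """Strict Nash equilibria among the pure strategies.

    ``margins[i] = min_{j != i} (M_ii - M_ji)`` is positive exactly for the
    reported strategies: no invader earns as much against the resident as the
    resident earns against itself.
    """

    indices: Tuple[int, ...]
    names: Tuple[str, ...]
    margins: Dict[int, float]


@dataclass(frozen=True)
class StabilityReport:
    """Local linear stability of a replicator(-mutator) fixed point.

    ``leading_real_part`` is the largest real part among the eigenvalues of
    the Jacobian restricted to the simplex tangent space.  ``boundary`` flags
    fixed points with extinct strategies, where eigenvalues along extinct
    directions describe invasion growth rates.
    """

    x_star: np.ndarray
    residual: float
    eigenvalues: np.ndarray
    leading_real_part: float
    boundary: bool
    well_conditioned: bool


def strict_nash(M: MatrixLike, names: Optional[Sequence[str]] = None) -> NashReport:
    """Strategies ``i`` with ``M_ii > M_ji`` for every ``j != i``."""
    A = _as_array(M)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("payoff matrix must be square")
    if names is None:
        if hasattr(M, "index"):
            names = list(M.index)  # type: ignore[union-attr]
        else:
            names = [f"s{i}" for i in range(A.shape[0])]
    m = A.shape[0]
    indices = []
    margins: Dict[int, float] = {}
    for i in range(m):
        others = np.delete(A[:, i], i)
        margin = float(A[i, i] - others.max())
        if margin > 0:
            indices.append(i)
            margins[i] = margin
    return NashReport(
        indices=tuple(indices),
        names=tuple(names[i] for i in indices),
        margins=margins,
    )


def verify_fixed_point(x: np.ndarray, M: MatrixLike, mu: float = 0.0) -> float:
    """Sup-norm of the replicator(-mutator) field at ``x``."""
    return float(np.max(np.abs(replicator_derivative(x, M, mu))))


def local_stability(
    x_star: np.ndarray,
    M: MatrixLike,
    mu: float = 0.0,
    *,
    boundary_threshold: float = 1e-6,
    residual_tolerance: float = 1e-8,
) -> StabilityReport:
    """Eigenvalues of the tangent-space Jacobian at a fixed point.

    The Jacobian is computed by central finite differences (step 1e-7) along
    an orthonormal tangent basis; the field is a smooth polynomial so this is
    accurate.  Raises ``ValueError`` if ``x_star`` is not a fixed point at
    ``residual_tolerance``.
    """
    x = np.asarray(x_star, dtype=float)
    residual = verify_fixed_point(x, M, mu)
    if residual > residual_tolerance:
        raise ValueError(
            f"not a fixed point: residual {residual:.3e} > {residual_tolerance:.1e}"
        )
    J = tangent_jacobian(x, M, mu)
    eigvals = np.linalg.eigvals(J)
    cond = np.linalg.cond(J) if np.all(np.isfinite(J)) else np.inf
    return StabilityReport(
        x_star=x,
        residual=residual,
        eigenvalues=eigvals,
        leading_real_part=float(np.max(eigvals.real)),
        boundary=bool(np.any(x < boundary_threshold)),
        well_conditioned=bool(np.isfinite(cond) and cond < 1e12),
    )
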