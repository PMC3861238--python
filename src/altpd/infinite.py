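"""Per-round payoffs in the infinitely long alternating game.

For ``epsilon > 0`` the joint mark chain of a strategy pair has a unique
stationary distribution ``v``; the long-run payoff per round is ``v . r``.
It is independent of which player opened the game, so the finite-game payoff
divided by the number of rounds converges to it as games grow long.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from scipy.linalg import null_space

from .automata import Strategy, by_name
from .game import build_transition_matrix, payoff_vectors


class ReducibleChainError(ValueError):
    """The joint chain has several recurrent classes (no unique stationary law).

    Raised for example at ``epsilon = 0``, where the noiseless chain can be
    absorbed in different classes depending on the initial state.
    """


def stationary_distribution(
    first: Strategy, second: Strategy, epsilon: float, *, tol: float = 1e-10
) -> np.ndarray:
    """Unique left fixed point ``v = v T`` of the pair's one-round kernel.

    Solves the linear system ``(T^t - I) v = 0`` with the normalization row
    appended (via the null space of ``T^t - I``).  Raises
    :class:`ReducibleChainError` when the fixed point is not unique.
    """
    T = build_transition_matrix(first, second, epsilon)
    ns = null_space(T.T - np.eye(16), rcond=1e-12)
    if ns.shape[1] != 1:
        raise ReducibleChainError(
            f"{ns.shape[1]} recurrent classes for {first.name} vs {second.name} "
            f"at epsilon={epsilon}; stationary distribution is not unique"
        )
    v = ns[:, 0]
    v = v / v.sum()
    if np.any(v < -1e-9):
        raise ReducibleChainError("stationary solve produced a signed vector")
    v = np.clip(v, 0.0, None)
    v /= v.sum()
    if np.max(np.abs(v @ T - v)) > tol:
        raise ReducibleChainError("stationary residual above tolerance")
    return v


def stationary_payoff_per_round(
    strategy_a: Strategy,
    strategy_b: Strategy,
    benefit: float,
    cost: float,
    epsilon: float,
) -> float:
    """Long-run payoff per round of A against B in the infinite game."""
    v = stationary_distribution(strategy_a, strategy_b, epsilon)
    r_first, _ = payoff_vectors(benefit, cost)
    return float(v @ r_first)


def forgiver_resists_alld(benefit: float, cost: float, epsilon: float) -> bool:
    """Whether ALLD cannot invade a Forgiver population in the infinite game.

    True exactly when Forgiver earns more per round against itself than ALLD
    earns against Forgiver.  When cooperation is not valuable enough (benefit
    close to cost) forgiveness is exploited and the test fails.
    """
    forgiver = by_name("Forgiver")
    alld = by_name("ALLD")
    self_pay = stationary_payoff_per_round(forgiver, forgiver, benefit, cost, epsilon)
    invader = stationary_payoff_per_round(alld, forgiver, benefit, cost, epsilon)
    return self_pay > invader


def invasion_threshold(
    cost: float,
    epsilon: float,
    *,
    b_low: Optional[float] = None,
    b_high: Optional[float] = None,
    tol: float = 1e-9,
) -> float:
    """Critical benefit above which Forgiver resists ALLD, by bisection."""
    lo = cost * (1 + 1e-9) if b_low is None else b_low
    hi = 100.0 * cost if b_high is None else b_high
    if forgiver_resists_alld(lo, cost, epsilon):
        return lo
    if not forgiver_resists_alld(hi, cost, epsilon):
        raise ValueError("no invasion threshold inside the bracket")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if forgiver_resists_alld(mid, cost, epsilon):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
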