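"""Exact expected payoffs in the finite noisy strictly alternating game.

The donation game: a cooperative move pays cost ``c`` and delivers benefit
``b > c`` to the opponent; a defective move pays and delivers nothing.  Play
strictly alternates and each player moves ``n`` times.  With probability
``epsilon`` a move is flipped (implementation error): the payoff follows the
move actually played and the opponent observes the actual move, but the
erring player's own automaton state is unchanged by its own error.

The match between two automata is a Markov chain on 16 joint states.  Each
player carries a *mark* -- its intention state plus an error star: ``c``
(intended C, played C), ``c*`` (intended C, played D), ``d`` (intended D,
played D), ``d*`` (intended D, played C).  A joint state is the pair of marks
after both players moved in a round.  The expected total payoff is

    pi = v . (sum_{k=0}^{n-1} T^k) . r

with ``v`` the joint-state distribution after round one, ``T`` the one-round
transition kernel and ``r`` the per-round payoff vector, averaged over which
player moves first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .automata import Strategy, enumerate_strategies, strategy_names

#: Mark labels in index order; a joint state (mark_first, mark_second) has
#: index ``4 * mark_first + mark_second``.
MARKS: Tuple[str, ...] = ("c", "c*", "d", "d*")

#: Intention state per mark: 0 = C, 1 = D.
MARK_STATE = np.array([0, 0, 1, 1])

#: Actual move per mark (the star flips the intention): 0 = C, 1 = D.
MARK_ACTUAL = np.array([0, 1, 1, 0])


@dataclass(frozen=True)
class GameParameters:
    """Parameters of one finite noisy alternating game.

    ``benefit`` and ``cost`` are in payoff units with ``benefit > cost > 0``;
    ``epsilon`` is the per-move implementation-error probability in
    ``[0, 1/2)``; ``rounds`` is the number of moves of *each* player.
    """

    benefit: float
    cost: float
    epsilon: float
    rounds: int

    def __post_init__(self) -> None:
        if not self.benefit > self.cost > 0:
            raise ValueError(
                f"need benefit > cost > 0, got b={self.benefit}, c={self.cost}"
            )
        _check_epsilon(self.epsilon)
        if self.rounds < 1:
            raise ValueError(f"rounds must be >= 1, got {self.rounds}")


def _check_epsilon(epsilon: float) -> None:
    if not 0 <= epsilon < 0.5:
        raise ValueError(f"error rate must lie in [0, 1/2), got {epsilon}")


def _quad(strategy: Strategy) -> np.ndarray:
    return np.asarray(strategy.quadruple, dtype=int).reshape(2, 2)


def build_transition_matrix(
    first: Strategy, second: Strategy, epsilon: float
) -> np.ndarray:
    """One-round 16x16 kernel for the pair, ``first`` moving first in a round.

    Within a round the first mover responds to the second mover's actual move
    of the previous round, then the second mover responds to the first
    mover's actual move of the current round.  Each new mark carries an error
    star independently with probability ``epsilon``.  Rows sum to one.
    """
    _check_epsilon(epsilon)
    qf, qs = _quad(first), _quad(second)
    e = np.array([1.0 - epsilon, epsilon])  # P(no star), P(star)
    T = np.zeros((16, 16))
    for mf in range(4):
        for ms in range(4):
            i = 4 * mf + ms
            lf = 1 - qf[MARK_STATE[mf], MARK_ACTUAL[ms]]
            for sf in (0, 1):
                mf_new = 2 * lf + sf
                ls = 1 - qs[MARK_STATE[ms], MARK_ACTUAL[mf_new]]
                for ss in (0, 1):
                    T[i, 4 * mf_new + 2 * ls + ss] += e[sf] * e[ss]
    return T


def initial_distribution(
    first: Strategy,
    second: Strategy,
    epsilon: float,
    *,
    second_mover_responds: bool = True,
) -> np.ndarray:
    """Joint-state distribution after round one, ``first`` opening the game.

    The first mover plays from its initial state.  By default the second
    mover's state first updates on the first mover's actual opening move
    (strict alternation); with ``second_mover_responds=False`` it plays its
    initial state blindly instead.
    """
    _check_epsilon(epsilon)
    qs = _quad(second)
    e = np.array([1.0 - epsilon, epsilon])
    init_f = 0 if first.initial_action == "C" else 1
    init_s = 0 if second.initial_action == "C" else 1
    v = np.zeros(16)
    for sf in (0, 1):
        mf = 2 * init_f + sf
        ls = 1 - qs[init_s, MARK_ACTUAL[mf]] if second_mover_responds else init_s
        for ss in (0, 1):
            v[4 * mf + 2 * ls + ss] += e[sf] * e[ss]
    return v


def payoff_vectors(benefit: float, cost: float) -> Tuple[np.ndarray, np.ndarray]:
    """Per-round payoff vectors ``(r_first, r_second)`` over joint states.

    Entry for joint state ``(m_first, m_second)``: a player receives
    ``benefit`` if the opponent's actual move was C and pays ``cost`` if its
    own actual move was C.
    """
    coop_f = (MARK_ACTUAL[:, None] == 0).astype(float)  # first's actual move C
    coop_s = (MARK_ACTUAL[None, :] == 0).astype(float)
    r_first = (benefit * coop_s - cost * coop_f).ravel()
    r_second = (benefit * coop_f - cost * coop_s).ravel()
    return r_first, r_second


def pair_payoffs(
    first: Strategy,
    second: Strategy,
    params: GameParameters,
    *,
    second_mover_responds: bool = True,
) -> Tuple[float, float]:
    """Expected total payoffs ``(first, second)`` for one fixed move order.

    Evaluates ``v . (sum_k T^k) . r`` by iterative accumulation (``v <- v T``
    once per round), which also covers absorbing chains where ``I - T`` is
    singular.
    """
    T = build_transition_matrix(first, second, params.epsilon)
    v = initial_distribution(
        first, second, params.epsilon, second_mover_responds=second_mover_responds
    )
    r_first, r_second = payoff_vectors(params.benefit, params.cost)
    acc = np.zeros(16)
    for _ in range(params.rounds):
        acc += v
        v = v @ T
    return float(acc @ r_first), float(acc @ r_second)


def game_payoff(
    strategy_a: Strategy,
    strategy_b: Strategy,
    params: GameParameters,
    *,
    second_mover_responds: bool = True,
) -> float:
    """Expected total payoff of A against B, averaged over who moves first."""
    pa_first, _ = pair_payoffs(
        strategy_a, strategy_b, params, second_mover_responds=second_mover_responds
    )
    _, pa_second = pair_payoffs(
        strategy_b, strategy_a, params, second_mover_responds=second_mover_responds
    )
    return 0.5 * (pa_first + pa_second)


def payoff_matrix(
    params: GameParameters,
    strategies: Optional[Sequence[Strategy]] = None,
    *,
    second_mover_responds: bool = True,
) -> pd.DataFrame:
    """Expected-payoff matrix over all strategy pairs, first-mover-averaged.

    Entry ``M.loc[i, j]`` is the expected total payoff of strategy ``i``
    against strategy ``j`` (self-play on the diagonal).  The matrix is
    generally asymmetric.
    """
    if strategies is None:
        strategies = enumerate_strategies()
    m = len(strategies)
    M = np.zeros((m, m))
    for i in range(m):
        for j in range(i, m):
            pf, ps = pair_payoffs(
                strategies[i],
                strategies[j],
                params,
                second_mover_responds=second_mover_responds,
            )
            if i == j:
                M[i, i] = 0.5 * (pf + ps)
                continue
            qf, qs = pair_payoffs(
                strategies[j],
                strategies[i],
                params,
                second_mover_responds=second_mover_responds,
            )
            M[i, j] = 0.5 * (pf + qs)
            M[j, i] = 0.5 * (ps + qf)
    names = strategy_names(strategies)
    return pd.DataFrame(M, index=names, columns=names)


# ---------------------------------------------------------------------------
# Monte-Carlo match simulator (independent oracle for the Markov engine)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MatchResult:
    """Realized moves and payoffs of one simulated match.

    ``moves_first``/``moves_second`` are the *actual* moves (strings of
    ``C``/``D``, one per round); ``errors_first``/``errors_second`` hold the
    1-based round indices where the player's move was flipped.
    """

    moves_first: str
    moves_second: str
    errors_first: Tuple[int, ...]
    errors_second: Tuple[int, ...]
    payoff_first: float
    payoff_second: float


def simulate_match(
    first: Strategy,
    second: Strategy,
    params: GameParameters,
    *,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    forced_errors: Optional[Iterable[Tuple[int, int]]] = None,
) -> MatchResult:
    """Play one strictly alternating match move by move.

    ``forced_errors`` is a list of ``(round, player)`` pairs (round 1-based,
    player 0 for the first mover, 1 for the second) whose moves are flipped
    deterministically; it requires ``epsilon == 0`` so that exactly the
    listed moves are erroneous.  The state-update conventions are identical
    to the Markov engine's.
    """
    forced = set()
    if forced_errors is not None:
        forced = {(int(r), int(p)) for r, p in forced_errors}
        if params.epsilon > 0:
            raise ValueError("forced_errors require epsilon = 0")
        for r, p in forced:
            if not (1 <= r <= params.rounds and p in (0, 1)):
                raise ValueError(f"forced error out of range: round {r}, player {p}")
    if rng is None:
        rng = np.random.default_rng(seed)

    qf, qs = _quad(first), _quad(second)
    state = [0 if first.initial_action == "C" else 1,
             0 if second.initial_action == "C" else 1]
    quads = [qf, qs]
    moves: List[List[str]] = [[], []]
    errors: List[List[int]] = [[], []]
    payoff = [0.0, 0.0]
    for rnd in range(1, params.rounds + 1):
        for player in (0, 1):
            other = 1 - player
            err = (rnd, player) in forced or (
                params.epsilon > 0 and rng.random() < params.epsilon
            )
            act = 1 - state[player] if err else state[player]
            if err:
                errors[player].append(rnd)
            moves[player].append("CD"[act])
            if act == 0:
                payoff[player] -= params.cost
                payoff[other] += params.benefit
            # the opponent's automaton responds to the actual move
            state[other] = 1 - quads[other][state[other], act]
    return MatchResult(
        moves_first="".join(moves[0]),
        moves_second="".join(moves[1]),
        errors_first=tuple(errors[0]),
        errors_second=tuple(errors[1]),
        payoff_first=payoff[0],
        payoff_second=payoff[1],
    )


def simulate_payoffs(
    first: Strategy,
    second: Strategy,
    params: GameParameters,
    n_matches: int,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized simulation of many matches; returns per-match payoff arrays.

    Implements the move-level game rules directly (no transition matrix), so
    it serves as an independent check of the Markov-chain engine.
    """
    qf = _quad(first)
    qs = _quad(second)
    sf = np.full(n_matches, 0 if first.initial_action == "C" else 1)
    ss = np.full(n_matches, 0 if second.initial_action == "C" else 1)
    pf = np.zeros(n_matches)
    ps = np.zeros(n_matches)
    b, c = params.benefit, params.cost
    for _ in range(params.rounds):
        err = rng.random(n_matches) < params.epsilon
        act_f = np.where(err, 1 - sf, sf)
        coop = act_f == 0
        pf -= c * coop
        ps += b * coop
        ss = 1 - qs[ss, act_f]
        err = rng.random(n_matches) < params.epsilon
        act_s = np.where(err, 1 - ss, ss)
        coop = act_s == 0
        ps -= c * coop
        pf += b * coop
        sf = 1 - qf[sf, act_s]
    return pf, ps


def simulate_mark_chain(
    first: Strategy,
    second: Strategy,
    epsilon: float,
    n_rounds: int,
    n_chains: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample joint mark states round by round; shape ``(n_chains, n_rounds)``.

    Entry values are joint-state indices ``4 * mark_first + mark_second``.
    Used to check the transition kernel against empirical frequencies.
    """
    _check_epsilon(epsilon)
    qf, qs = _quad(first), _quad(second)
    lf = np.full(n_chains, 0 if first.initial_action == "C" else 1)
    ls = np.full(n_chains, 0 if second.initial_action == "C" else 1)
    out = np.empty((n_chains, n_rounds), dtype=np.uint8)
    for k in range(n_rounds):
        star_f = rng.random(n_chains) < epsilon
        act_f = np.where(star_f, 1 - lf, lf)
        ls = 1 - qs[ls, act_f]
        star_s = rng.random(n_chains) < epsilon
        act_s = np.where(star_s, 1 - ls, ls)
        mf = 2 * lf + star_f
        ms = 2 * ls + star_s
        out[:, k] = 4 * mf + ms
        lf = 1 - qf[lf, act_s]
    return out
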