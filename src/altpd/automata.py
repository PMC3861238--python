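"""One- and two-state automaton strategies for the alternating Prisoner's Dilemma.

A strategy is a deterministic finite automaton over the two intention states
``C`` (cooperate on my next move) and ``D`` (defect on my next move).  It is
encoded as a quadruple ``(p_cc, p_cd, p_dc, p_dd)`` together with an initial
state: ``p_xy = 1`` means "when in state ``x`` and observing the opponent's
move ``y``, go to state ``C``"; ``p_xy = 0`` means "go to state ``D``".

There are 32 two-state automata (2 initial states x 16 transition tables).
For 8 of them the second state is unreachable, so they collapse onto the two
one-state automata ALLC and ALLD.  Adding those one-state automata back gives
the 26 distinct strategies handled by this package.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Dict, Literal, Sequence, Tuple

Action = Literal["C", "D"]
Quadruple = Tuple[int, int, int, int]


class Category(enum.Enum):
    """Behavioural classes of the 26 strategies.

    Sink-state strategies eventually lock into unconditional cooperation
    (``SINK_C``) or defection (``SINK_D``).  The remaining strategies keep
    moving between their two states; they are *suspicious* if they open with
    defection and *hopeful* if they open with cooperation.
    """

    SINK_C = "sink_c"
    SINK_D = "sink_d"
    SUSPICIOUS_DYNAMIC = "suspicious_dynamic"
    HOPEFUL_DYNAMIC = "hopeful_dynamic"


@dataclass(frozen=True)
class Strategy:
    """A deterministic automaton strategy.

    Parameters
    ----------
    index:
        1-based position in the canonical enumeration order.
    name:
        Field name where one exists (TFT, WSLS, Forgiver, ...), otherwise a
        systematic name ``<initial_action><p_cc><p_cd><p_dc><p_dd>``.
    quadruple:
        Transition table ``(p_cc, p_cd, p_dc, p_dd)`` with entries in {0, 1}.
    initial_action:
        The state (and hence the move) the automaton starts with.
    category:
        Behavioural class, see :class:`Category`.
    """

    index: int
    name: str
    quadruple: Quadruple
    initial_action: Action
    category: Category

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        q = "".join(map(str, self.quadruple))
        return f"{self.name}({q}/{self.initial_action})"


#: Field names for the strategies discussed in the literature.  The suspicious
#: variants (prefix "s") share the hopeful quadruple but open with defection.
NAMED_STRATEGIES: Dict[Tuple[Quadruple, Action], str] = {
    ((0, 0, 0, 0), "D"): "ALLD",
    ((1, 1, 1, 1), "C"): "ALLC",
    ((1, 0, 0, 0), "C"): "Grim",
    ((1, 0, 1, 0), "C"): "TFT",
    ((1, 0, 0, 1), "C"): "WSLS",
    ((1, 0, 1, 1), "C"): "Forgiver",
    ((0, 0, 1, 1), "C"): "Alternator",
    ((1, 1, 1, 0), "D"): "Grateful",
    ((1, 1, 0, 1), "D"): "ParadoxicGrateful",
    ((1, 1, 1, 1), "D"): "sALLC",
    ((1, 0, 1, 0), "D"): "sTFT",
    ((1, 0, 0, 1), "D"): "sWSLS",
    ((1, 0, 1, 1), "D"): "sForgiver",
}


def _transition_entry(quadruple: Quadruple, state: Action, observed: str) -> int:
    row = 0 if state == "C" else 1
    col = 0 if observed in ("c", "C") else 1
    return quadruple[2 * row + col]


def respond(state: Action, strategy: Strategy, observed_move: str) -> Action:
    """Next intention state after observing the opponent's actual move.

    ``observed_move`` is the opponent's *actual* move (``"c"`` or ``"d"``,
    case-insensitive).  The new state is ``C`` exactly when the corresponding
    quadruple entry is 1.
    """
    return "C" if _transition_entry(strategy.quadruple, state, observed_move) else "D"


def classify(strategy: Strategy) -> Category:
    """Behavioural class of a strategy.

    A strategy is ``SINK_C`` when its cooperative state is absorbing
    (``p_cc = p_cd = 1``) and reachable from the initial state, ``SINK_D``
    when the defective state is absorbing (``p_dc = p_dd = 0``) and
    reachable; otherwise it is a dynamic strategy, suspicious or hopeful
    according to its first move.
    """
    p_cc, p_cd, p_dc, p_dd = strategy.quadruple
    c_sink = p_cc == 1 and p_cd == 1
    d_sink = p_dc == 0 and p_dd == 0
    c_reachable = strategy.initial_action == "C" or p_dc == 1 or p_dd == 1
    d_reachable = strategy.initial_action == "D" or p_cc == 0 or p_cd == 0
    if c_sink and c_reachable:
        return Category.SINK_C
    if d_sink and d_reachable:
        return Category.SINK_D
    if strategy.initial_action == "D":
        return Category.SUSPICIOUS_DYNAMIC
    return Category.HOPEFUL_DYNAMIC


def has_conditional_cooperation(strategy: Strategy) -> bool:
    """Whether the automaton carries the conditional-cooperation motif.

    The motif: stay in ``C`` while the opponent cooperates (``p_cc = 1``) but
    leave ``C`` on a single observed defection (``p_cd = 0``).  It ensures the
    benefit of mutual cooperation while avoiding exploitation by
    defection-heavy opponents.
    """
    p_cc, p_cd = strategy.quadruple[0], strategy.quadruple[1]
    return p_cc == 1 and p_cd == 0


def _make(index: int, quadruple: Quadruple, initial: Action) -> Strategy:
    name = NAMED_STRATEGIES.get((quadruple, initial))
    if name is None:
        name = initial + "".join(map(str, quadruple))
    probe = Strategy(index, name, quadruple, initial, Category.HOPEFUL_DYNAMIC)
    return Strategy(index, name, quadruple, initial, classify(probe))


def enumerate_strategies() -> Tuple[Strategy, ...]:
    """The 26 distinct strategies in canonical order.

    Order: the one-state automata ALLD and ALLC first, then the 24 two-state
    automata sorted by (initial action ``C`` before ``D``, quadruple read as a
    4-bit number).  Two-state automata whose second state is unreachable
    (``p_cc = p_cd = 1`` with initial ``C``, or ``p_dc = p_dd = 0`` with
    initial ``D``) duplicate the one-state automata and are skipped.
    """
    out = [_make(1, (0, 0, 0, 0), "D"), _make(2, (1, 1, 1, 1), "C")]
    index = 3
    for initial in ("C", "D"):
        for bits in range(16):
            q: Quadruple = (
                (bits >> 3) & 1,
                (bits >> 2) & 1,
                (bits >> 1) & 1,
                bits & 1,
            )
            if initial == "C" and q[0] == 1 and q[1] == 1:
                continue
            if initial == "D" and q[2] == 0 and q[3] == 0:
                continue
            out.append(_make(index, q, initial))
            index += 1
    assert len(out) == 26
    return tuple(out)


def strategy_names(strategies: Sequence[Strategy] | None = None) -> Tuple[str, ...]:
    """Names in canonical order."""
    if strategies is None:
        strategies = enumerate_strategies()
    return tuple(s.name for s in strategies)


def by_name(name: str, strategies: Sequence[Strategy] | None = None) -> Strategy:
    """Look up a strategy by its canonical name."""
    if strategies is None:
        strategies = enumerate_strategies()
    for s in strategies:
        if s.name == name:
            return s
    raise KeyError(f"unknown strategy name: {name!r}")
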