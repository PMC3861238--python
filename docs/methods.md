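# Methods

## Game and error model

The strictly alternating donation game: players move in turns, `n` moves
each.  A cooperative move costs the mover `c` and pays the opponent `b`,
with `b > c > 0`; a defective move transfers nothing.  Noise is an
*imperceptive implementation error*: with probability `ε ∈ [0, 1/2)` per
move, the move actually played is the opposite of the mover's intention.
Payoffs and the opponent's observation follow the actual move; the erring
player's own automaton state is not updated by its own error (the player
does not notice it).

Strategies are deterministic automata over two intention states `C`/`D`,
encoded as a quadruple `(p_cc, p_cd, p_dc, p_dd)` (``p_xy = 1``: from state
`x`, on observing opponent move `y`, go to `C`) plus an initial state.  Of
the 32 two-state automata, 8 never reach their second state and collapse
onto the one-state automata ALLC/ALLD; adding those gives 26 distinct
strategies.  Canonical order: ALLD, ALLC, then two-state automata sorted by
(initial action `C` before `D`, quadruple as a 4-bit number).  Names follow
the field where they exist (Grim, TFT, WSLS, Forgiver, Alternator, Grateful,
ParadoxicGrateful, and the suspicious variants sALLC/sTFT/sWSLS/sForgiver);
the rest are named systematically, e.g. `C0110`.

## Alternation semantics

Every move after a player's first responds to the opponent's most recent
actual move.  Concretely, with first mover A: A's opening move comes from
A's initial state; B's automaton updates on A's actual opening move before
B's first move; thereafter each player's state updates immediately upon
observing each opponent move.  The alternative convention in which the
second mover plays its first move blindly from its initial state is kept
behind the `second_mover_responds=False` switch; the two conventions differ
only through suspicious/hopeful openings and are identical for the headline
results.

## Exact payoffs: the 16-state chain

A player's *mark* is its intention state plus an error star (`c`, `c*`, `d`,
`d*`; the star flips the actual move).  The joint state after a round is the
pair of marks, indexed `4·mark_first + mark_second` with mark order
(`c`, `c*`, `d`, `d*`).  One round of play defines a 16×16 row-stochastic
kernel `T`: the first mover's new intention follows its quadruple applied to
(own intention, opponent's last actual move) and acquires a star with
probability `ε`; the second mover then updates on the first mover's *new*
actual move.  Within-round coupling matters: the second mover's transition
depends on the realized star of the first mover's move.

With `v` the joint distribution after round one and `r` the per-round payoff
vector (`b` if the opponent's actual move is C, `−c` if the own actual move
is C), the expected total payoff is `v · (Σ_{k=0}^{n−1} T^k) · r`, evaluated
by iterative accumulation (`v ← vT` once per round) so that absorbing chains
with singular `I − T` need no special casing.  The two move orders induce
two different kernels (each order has its own within-round coupling); the
matrix entry is the arithmetic mean of the two single-order payoffs, which
is what "averaging over who moves first" means operationally.  A vectorized
move-level Monte-Carlo simulator implements the same rules without any
transition matrix and is used as an independent oracle (payoff agreement
within four standard errors at 10⁵ matches; kernel rows against empirical
transition frequencies of 10⁶ simulated rounds).

Parameter recovery: the four unconditional pairings have closed forms per
move (an unconditional strategy cooperates with probability `ε` or `1−ε`).
The published corner entries 10.0 / 190.0 / 280.0 / −80.0 pin
`b = 3, c = 1, ε = 0.05, n = 100` uniquely; all reference computations use
those values.

### Agreement with the published payoff excerpt

Under these semantics the engine reproduces the published 6×6 excerpt at one
decimal place in 30 of 36 cells, including all corners, TFT–TFT 104.5 and
Forgiver–Forgiver 174.8.  A handful of printed cells differ slightly but
genuinely (largest: ALLC vs Grim, exact −27.66 vs printed −28.8; also
Grim–Grim 28.047 vs 28.1 and WSLS–WSLS 106.42 vs 106.5).  The exact values
here are confirmed by the independent move-level simulator, and an
exhaustive search over first-round conventions, intra-round update orders,
initial-vector versus payoff averaging, and random game-length distributions
shows that no such variant reproduces those cells: the Grim-vs-ALLC value
they imply corresponds to a per-observation survival probability that cannot
be expressed through any lag structure at `ε = 0.05`.  We therefore keep the
exact chain; the residual discrepancies propagate into sub-percent shifts of
the mixed-equilibrium composition (e.g. Grateful 5.24 % here vs 5.6 %
reported, sALLC 4.85 % vs 3.8 %) while leaving every qualitative result and
the Forgiver share (82.35 % vs 82.6 %) intact.

## Replicator(–mutator) dynamics

Fitness is `f = M x`, mean payoff `φ = x·f`, and with a uniform mutation
kernel at rate `μ`

    ẋ_i = (μ/m) φ + (1 − μ) x_i f_i − x_i φ,   m = 26,

which preserves the simplex and reduces to `ẋ_i = x_i (f_i − φ)` at
`μ = 0` (all headline results use `μ = 0`).  Uniform-random starting points
are drawn by normalizing negative logarithms of uniform variates (a flat
Dirichlet draw; marginals Beta(1, m−1) are verified by a goodness-of-fit
test).

Numerical choices:

* **Integrator** LSODA, `rtol 1e−10`, `atol 1e−12`, in chunks of 2000
  payoff-time units up to `t_max = 1e6`.
* **Convergence** is declared when `‖ẋ‖_∞ < 1e−9` at a chunk boundary *and*
  the leading eigenvalue of the tangent-space Jacobian is non-positive (up
  to `1e−6`·max|M|).  A rest point failing the eigenvalue test is a saddle;
  the trajectory is pushed `max(1e−7, 10·tol/λ)` along the unstable
  direction and integration resumes, so reported attractors are genuine.
* **Simplex projection.** The field conserves `Σx` exactly, but numerical
  drift can carry a trajectory off the simplex, where the replicator field
  has spurious equilibria (observed at `b = 5`: a stalled state with
  component sum 1.18).  States are therefore clipped at zero and
  renormalized at chunk boundaries and on a blow-up guard (`max|x| > 1.5`),
  never within a step.
* **Classification thresholds**: pure equilibria at frequency > 0.99; the
  mixed Forgiver (or sForgiver) class requires that strategy to be the
  largest component with more than half the population; `GRIM_ALLC` requires
  support exactly {Grim, ALLC} above 1 %.  These separate the observed
  attractors by wide margins.

Basin statistics integrate ≥ 500 uniform-random starts per condition
(binomial ±5 percentage points covers the sampling error at that size).

## Mutation probes

Local stability is assessed both by eigenvalues and by short mutation runs.
Two regimes matter: at `μ = 1e−4` the cooperative alliance absorbs
perturbations (the mutation-dressed equilibrium shifts by O(μ/λ), so return
is measured against the dressed equilibrium), while the pure-ALLD state is
still locally attracting.  Escape from ALLD toward Grim requires enough
mutation pressure to supply cooperative interaction partners and sets in
around `μ ≈ 1e−2`; the departure test uses that rate.  Under this package's
matrix the suspicious-Forgiver alliance is not an attractor at
`b ∈ {2, 4, 5}` (`ε = 0.05`, `n = 100`): populations starting at 90 %
sForgiver flow to the Forgiver alliance, which realizes the qualitative
"sForgiver gives way to Forgiver" claim directly.

## Infinite game

For `ε > 0` the joint chain of the relevant pairs has a unique stationary
distribution `v∞` (computed from the null space of `Tᵗ − I`; reducible
chains, e.g. at `ε = 0`, raise an error rather than returning an arbitrary
branch).  The per-round payoff `v∞ · r` is independent of the move order and
equals the finite-game payoff per round in the long-game limit (verified at
`n = 10⁴` within `1e−3`).  Forgiver resists invasion by ALLD when its
self-payoff per round exceeds ALLD's payoff against it; at `c = 1`,
`ε = 0.05` the threshold benefit from bisection is `b* ≈ 2.27`, and the
resisting region is monotone in `b`.

## Problem sizes and limitations

Default problem sizes — 26 strategies, 100 rounds, 500 basin starts, 10⁵
Monte-Carlo matches, 10⁴-round long-game checks — were chosen so the full
suite completes in a few minutes on one core while keeping every sampling
error far below the assertion tolerances.  The model inherits the usual
limitations of this strategy space: deterministic automata with at most two
states, a single uniform error rate on implementation only (no perception
errors), no discounting, and a uniform mutation kernel.  Conclusions about
stability are relative to the restricted 26-strategy space; in unrestricted
spaces no strategy is robust against indirect invasion.
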