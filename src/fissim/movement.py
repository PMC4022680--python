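"""Daily movement: mimetic departure probabilities and the assignment pass.

Every morning all individuals sit in the resting area.  Individual *i*'s
probability of moving to resource area *s* on its daily draw is

    p_s = lambda_i,s + C * (sum of i's links to individuals already in s)

where ``lambda_i,s`` is *i*'s intrinsic (nutritional) per-day probability
of heading to *s* and ``C`` is the mimetic coefficient converting link
weight into follow-probability.  The remainder ``p0 = 1 - p1 - p2`` is the
probability of staying in the resting area.

Each individual gets one movement opportunity per day: the group is
visited in a random order, and probabilities are recomputed after every
single departure, so early movers exert mimetic pull on everyone
evaluated after them.  Individuals whose draw exceeds both thresholds
stay at rest for the day — a group whose members are mostly
cohesion-driven (low Nutrition/Sociality ratio) therefore rarely empties
the resting area, and only full two-area foraging days count as temporary
fissions.  The spec-style alternative in which rounds repeat (with fresh
draws) until the resting area empties is available as
``assign_day(..., mode="until_empty")``.

Intrinsic probabilities are heterogeneous and persistent: each
individual's total drive ``lambda1 + lambda2`` is split between the two
patches by a uniform draw held fixed for the whole simulation, so
individuals have patch preferences and subgroup composition can follow
nutritional needs.  The feasibility constraint
``lambda1 + lambda2 <= 1 - C * 100`` guarantees ``p1 + p2 <= 1`` whatever
the occupancy, because the links an individual could follow sum to at
most 100; the study design saturates it with equality, which is what lets
a mimetic chain capture the entire group on fully social days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, SimulationError
from .network import DayAssignment, SocialNetwork

#: numerical slack on the feasibility bound so that exact boundary
#: parameter sets (e.g. C=0.004, lambda=0.3 each) are accepted
_FEASIBILITY_TOL = 1e-9

#: give up on an "until_empty" day after this many rounds; reachable only
#: if the total departure probability can be zero
DEFAULT_ROUND_LIMIT = 10_000

#: how each individual's intrinsic probabilities relate to the condition's
#: (lambda1, lambda2) pair
PREFERENCE_SCHEMES = ("uniform", "homogeneous")

#: day-process variants
DAY_MODES = ("single_pass", "until_empty")


@dataclass(frozen=True)
class Condition:
    """One parameter cell of the model.

    Parameters
    ----------
    n
        Group size.
    C
        Mimetic coefficient: probability increment per unit of link weight
        toward individuals already present in an area.
    lambda1, lambda2
        Mean intrinsic per-day probabilities of moving to resource areas 1
        and 2 (per-individual values are drawn from these; see
        ``preference``).
    transfer
        Social-relations transfer percentage T in [0, 100] applied after
        each temporary fission.
    preference
        "uniform" (default): each individual's patch preference is a
        persistent uniform split, ``lambda_i1 = 2*lambda1*u`` and
        ``lambda_i2 = 2*lambda2*(1-u)`` with ``u ~ U(0,1)`` drawn once per
        simulation; "homogeneous": every individual uses exactly
        (lambda1, lambda2).
    redraw_daily
        Redraw the preference split every day instead of holding it fixed
        (off by default; destroys need-based sorting).
    """

    n: int
    C: float
    lambda1: float
    lambda2: float
    transfer: float
    preference: str = field(default="uniform")
    redraw_daily: bool = field(default=False)

    def __post_init__(self) -> None:
        if not isinstance(self.n, (int, np.integer)) or self.n < 2:
            raise ConfigurationError(f"group size must be an integer >= 2, got {self.n!r}")
        if self.C < 0.0:
            raise ConfigurationError(f"mimetic coefficient must be >= 0, got {self.C!r}")
        if self.lambda1 < 0.0 or self.lambda2 < 0.0:
            raise ConfigurationError("intrinsic probabilities must be >= 0")
        if not 0.0 <= self.transfer <= 100.0:
            raise ConfigurationError(
                f"transfer percentage must lie in [0, 100], got {self.transfer!r}"
            )
        if self.preference not in PREFERENCE_SCHEMES:
            raise ConfigurationError(
                f"preference must be one of {PREFERENCE_SCHEMES}, got {self.preference!r}"
            )
        if self.lambda1 + self.lambda2 > 1.0 - self.C * 100.0 + _FEASIBILITY_TOL:
            raise ConfigurationError(
                f"infeasible condition {self!r}: requires "
                f"(lambda1 + lambda2) <= 1 - C*100 = {1.0 - self.C * 100.0:g}"
            )

    @property
    def lambda_total(self) -> float:
        return self.lambda1 + self.lambda2


@dataclass(frozen=True)
class MoveProbabilities:
    """Per-draw probabilities of moving to area 1, area 2, or staying."""

    p1: float
    p2: float
    p0: float

    def __post_init__(self) -> None:
        tol = 1e-9
        for p in (self.p1, self.p2, self.p0):
            if not -tol <= p <= 1.0 + tol:
                raise ConfigurationError(f"probability {p!r} outside [0, 1]")
        if abs(self.p1 + self.p2 + self.p0 - 1.0) > tol:
            raise ConfigurationError("p1 + p2 + p0 must equal 1")


def draw_preferences(cond: Condition, rng: np.random.Generator) -> np.ndarray:
    """Per-individual intrinsic probabilities, shape ``(n, 2)``.

    Under the "uniform" scheme each individual's total drive is split
    between the patches by an independent ``u ~ U(0,1)``; the expectation
    over individuals equals the condition's (lambda1, lambda2) pair.  Any
    draw that would break the feasibility bound (possible only for
    asymmetric mean pairs) is rescaled onto it.
    """
    lam = np.tile([cond.lambda1, cond.lambda2], (cond.n, 1))
    if cond.preference == "uniform":
        u = rng.random(cond.n)
        lam = np.column_stack([2.0 * cond.lambda1 * u, 2.0 * cond.lambda2 * (1.0 - u)])
        bound = 1.0 - cond.C * 100.0
        tot = lam.sum(axis=1)
        over = tot > bound
        if np.any(over):
            if bound <= 0.0:
                lam[over] = 0.0
            else:
                lam[over] *= (bound / tot[over])[:, None]
    return lam


def move_probabilities(
    i: int,
    net: SocialNetwork,
    occupancy: np.ndarray,
    cond: Condition,
    *,
    lambdas: tuple[float, float] | None = None,
    direction: str = "outgoing",
) -> MoveProbabilities:
    """Departure probabilities of a still-resting individual *i*.

    ``occupancy`` codes the in-progress day: 0 = resting, 1/2 = already in
    that resource area.  The mimetic term sums the links between *i* and
    the individuals already present in each area; by default the moving
    individual's own (outgoing) weights are used, ``direction="incoming"``
    sums the links the occupants direct at *i* instead.  ``lambdas``
    overrides the condition's mean pair with *i*'s own preferences.
    """
    occ = np.asarray(occupancy)
    if occ[i] != 0:
        raise ConfigurationError(f"individual {i} has already left the resting area")
    lam1, lam2 = lambdas if lambdas is not None else (cond.lambda1, cond.lambda2)
    if direction == "outgoing":
        links = net.weights[i, :]
    elif direction == "incoming":
        links = net.weights[:, i]
    else:
        raise ConfigurationError(
            f"direction must be 'outgoing' or 'incoming', got {direction!r}"
        )
    p1 = lam1 + cond.C * float(links[occ == 1].sum())
    p2 = lam2 + cond.C * float(links[occ == 2].sum())
    return MoveProbabilities(p1=p1, p2=p2, p0=1.0 - p1 - p2)


def draw_move(p: MoveProbabilities, x: float) -> str:
    """Resolve one uniform draw ``x`` against the move probabilities.

    The thresholds are inclusive on the area side: ``x <= p1`` moves to
    s1, ``p1 < x <= p1 + p2`` moves to s2, anything larger stays.
    """
    if not 0.0 <= x <= 1.0:
        raise ConfigurationError(f"x must lie in [0, 1], got {x!r}")
    if p.p1 >= x:
        return "s1"
    if p.p1 + p.p2 >= x:
        return "s2"
    return "stay"


def assign_day(
    net: SocialNetwork,
    cond: Condition,
    rng: np.random.Generator,
    *,
    lambdas: np.ndarray | None = None,
    mode: str = "single_pass",
    round_limit: int = DEFAULT_ROUND_LIMIT,
    direction: str = "outgoing",
) -> DayAssignment:
    """Run one day's movement and return the end-of-day assignment.

    ``mode="single_pass"`` (default): every individual is visited once in
    a random order and gets one draw with probabilities recomputed from
    the current occupancy; whoever stays put rests for the day.
    ``mode="until_empty"``: the pass repeats (fresh order and fresh draws
    each round) until the resting area is empty, so the returned
    assignment is always complete.

    ``lambdas`` carries the per-individual preferences (shape ``(n, 2)``);
    if omitted a fresh draw is taken from ``rng`` — persistent preferences
    across days are the engine's responsibility.
    """
    n = net.n
    if cond.n != n:
        raise ConfigurationError(f"condition is for n={cond.n} but network has n={n}")
    if mode not in DAY_MODES:
        raise ConfigurationError(f"mode must be one of {DAY_MODES}, got {mode!r}")
    if lambdas is None:
        lambdas = draw_preferences(cond, rng)
    occ = np.zeros(n, dtype=np.int8)
    remaining = n
    rounds = 0
    while remaining > 0:
        rounds += 1
        if rounds > round_limit:
            raise SimulationError(
                f"day did not complete within {round_limit} rounds "
                f"({remaining} individuals still resting); the total departure "
                "probability is too small to empty the resting area"
            )
        visit = rng.permutation(n)
        for i in visit:
            if occ[i] != 0:
                continue
            p = move_probabilities(
                i, net, occ, cond, lambdas=(lambdas[i, 0], lambdas[i, 1]),
                direction=direction,
            )
            target = draw_move(p, rng.random())
            if target == "s1":
                occ[i] = 1
                remaining -= 1
            elif target == "s2":
                occ[i] = 2
                remaining -= 1
        if mode == "single_pass":
            break
    return DayAssignment(occ)
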