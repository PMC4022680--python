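"""Grooming-time social network and its rewiring after temporary fissions.

Each individual in a group of ``n`` animals owns a fixed budget of 100
units of social (grooming) time, distributed as directed, weighted links
to the other ``n - 1`` group members.  The weight ``w(i, k)`` is the
percentage of individual *i*'s social time spent grooming *k*; links are
directional, so ``w(i, k)`` and ``w(k, i)`` are independent.  The row sum
``sum_k w(i, k) == 100`` is a conserved quantity of the model: it holds at
initialisation and after every rewiring step.

A day on which the group forages split across the two resource areas is a
*temporary fission*.  After each temporary fission every individual
transfers a fixed percentage ``T`` of each of its links toward the other
subgroup onto its own subgroup companions, shared equally among them.
Repeated temporary fissions therefore cluster the network until the group
splits for good: an *irreversible fission* is declared when both subgroups
have at least four members and every individual directs at least 95% of
its social time within its own subgroup.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import numpy as np

from .errors import ConfigurationError

#: additive tolerance on the conserved row sum of 100
ROW_SUM_TOL = 1e-9

#: area codes used throughout: 1 and 2 are the two resource areas,
#: 0 is the resting area
AREA_LABELS = {0: "s0", 1: "s1", 2: "s2"}
LABEL_AREAS = {"s0": 0, "s1": 1, "s2": 2}


class SocialNetwork:
    """Directed weighted grooming-time network over ``n`` individuals.

    Parameters
    ----------
    weights
        ``(n, n)`` array of link weights in percent of social time;
        the diagonal must be zero (an individual does not groom itself).
    validate
        Check non-negativity, zero diagonal and the row-sum invariant.

    Individuals are identified by 0-based integer ids.
    """

    __slots__ = ("weights",)

    def __init__(self, weights: np.ndarray, *, validate: bool = True, copy: bool = True):
        w = np.array(weights, dtype=float, copy=copy)
        if w.ndim != 2 or w.shape[0] != w.shape[1] or w.shape[0] < 2:
            raise ConfigurationError(
                f"weights must be a square matrix over >= 2 individuals, got shape {w.shape}"
            )
        if validate:
            if np.any(np.diag(w) != 0.0):
                raise ConfigurationError("self-links w(i, i) must be zero")
            if np.any(w < 0.0):
                raise ConfigurationError("link weights must be non-negative")
            bad = np.abs(w.sum(axis=1) - 100.0) > ROW_SUM_TOL
            if np.any(bad):
                i = int(np.flatnonzero(bad)[0])
                raise ConfigurationError(
                    f"outgoing weights of individual {i} sum to {w[i].sum()!r}, expected 100"
                )
        self.weights = w

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def __getitem__(self, ik: tuple[int, int]) -> float:
        i, k = ik
        if i == k:
            raise KeyError("w(i, i) is undefined")
        return float(self.weights[i, k])

    def row_sums(self) -> np.ndarray:
        """Per-individual sum of outgoing weights (invariantly 100)."""
        return self.weights.sum(axis=1)

    def within_subgroup_sums(self, assign: "DayAssignment") -> np.ndarray:
        """For each individual, the outgoing weight directed at same-area members."""
        same = assign.areas[:, None] == assign.areas[None, :]
        np.fill_diagonal(same, False)
        return (self.weights * same).sum(axis=1)

    def copy(self) -> "SocialNetwork":
        return SocialNetwork(self.weights, validate=False, copy=True)

    def allclose(self, other: "SocialNetwork", atol: float = 1e-12) -> bool:
        return self.n == other.n and np.allclose(
            self.weights, other.weights, rtol=0.0, atol=atol
        )

    def __repr__(self) -> str:
        return f"SocialNetwork(n={self.n})"


class DayAssignment:
    """The end-of-day location of every individual.

    Each individual is in resource area 1 (``s1``), resource area 2
    (``s2``), or — on days when its motivation never reached its draw —
    still in the resting area (coded 0).  The day is a *temporary fission*
    iff everyone foraged and both resource areas are occupied; only such
    days rewire the grooming network.
    """

    __slots__ = ("areas",)

    def __init__(self, areas: Iterable[int] | np.ndarray):
        a = np.asarray(list(areas) if not isinstance(areas, np.ndarray) else areas,
                       dtype=np.int8)
        if a.ndim != 1 or a.size < 2:
            raise ConfigurationError("areas must be a 1-d sequence over >= 2 individuals")
        if not np.all((a >= 0) & (a <= 2)):
            raise ConfigurationError(
                "areas must be 0 (resting), 1 (s1) or 2 (s2) for every individual"
            )
        self.areas = a

    @classmethod
    def from_labels(cls, labels: Mapping[int, str]) -> "DayAssignment":
        """Build from an ``{individual: "s1" | "s2"}`` mapping."""
        n = len(labels)
        areas = np.zeros(n, dtype=np.int8)
        for i in range(n):
            areas[i] = LABEL_AREAS[labels[i]]
        return cls(areas)

    @property
    def n(self) -> int:
        return self.areas.size

    def members(self, area: int) -> np.ndarray:
        return np.flatnonzero(self.areas == area)

    @property
    def sizes(self) -> tuple[int, int]:
        """Occupancies of the two resource areas (resting individuals excluded)."""
        n1 = int(np.count_nonzero(self.areas == 1))
        n2 = int(np.count_nonzero(self.areas == 2))
        return n1, n2

    @property
    def n_resting(self) -> int:
        return int(np.count_nonzero(self.areas == 0))

    @property
    def complete(self) -> bool:
        """True when every individual left the resting area."""
        return self.n_resting == 0

    @property
    def is_temporary_fission(self) -> bool:
        n1, n2 = self.sizes
        return self.complete and n1 > 0 and n2 > 0

    def labels(self) -> dict[int, str]:
        return {i: AREA_LABELS[int(a)] for i, a in enumerate(self.areas)}

    def __eq__(self, other: object) -> bool:
        return isinstance(other, DayAssignment) and np.array_equal(self.areas, other.areas)

    def __repr__(self) -> str:
        n1, n2 = self.sizes
        return f"DayAssignment(n={self.n}, split={n1}/{n2})"


def init_egalitarian(n: int) -> SocialNetwork:
    """Egalitarian seed network: every individual grooms every other equally.

    Each of the ``n - 1`` outgoing links carries ``100 / (n - 1)`` percent
    of the owner's social time, so each row sums to 100.
    """
    if not isinstance(n, (int, np.integer)) or n < 2:
        raise ConfigurationError(f"group size must be an integer >= 2, got {n!r}")
    w = np.full((n, n), 100.0 / (n - 1))
    np.fill_diagonal(w, 0.0)
    return SocialNetwork(w, validate=False, copy=False)


def transfer_update(net: SocialNetwork, assign: DayAssignment, T: float) -> SocialNetwork:
    """Rewire the network after one day, transferring ``T`` percent of each
    cross-subgroup link onto same-subgroup companions.

    For each individual *i* with at least one same-area companion, every
    link toward the other area is multiplied by ``1 - T/100`` and the total
    weight removed is added back in equal shares to *i*'s links toward its
    ``N`` same-area companions, so *i*'s row sum stays exactly 100.  An
    individual alone in its area keeps its outgoing links unchanged (other
    individuals' links toward it still move).  A day without a temporary
    fission — anyone still resting, or everyone in one area — leaves the
    network unchanged.

    Returns a new :class:`SocialNetwork`; the input is not modified.
    """
    if not 0.0 <= T <= 100.0:
        raise ConfigurationError(f"transfer percentage must lie in [0, 100], got {T!r}")
    if net.n != assign.n:
        raise ConfigurationError(
            f"network has {net.n} individuals but assignment has {assign.n}"
        )
    if not assign.is_temporary_fission:
        return net.copy()
    q = T / 100.0
    same = assign.areas[:, None] == assign.areas[None, :]
    np.fill_diagonal(same, False)
    n_same = same.sum(axis=1)  # N: same-area companions of each individual

    w = net.weights.copy()
    movers = n_same > 0  # rows with at least one companion get rewired
    cross = ~same
    np.fill_diagonal(cross, False)
    cross &= movers[:, None]
    removed = np.where(cross, w * q, 0.0)
    loss = removed.sum(axis=1)
    w -= removed
    gain = np.zeros(net.n)
    gain[movers] = loss[movers] / n_same[movers]
    w += np.where(same, gain[:, None], 0.0)
    return SocialNetwork(w, validate=False, copy=False)


def check_irreversible(
    net: SocialNetwork,
    assign: DayAssignment,
    threshold: float = 95.0,
    min_subgroup: int = 4,
) -> bool:
    """Test the irreversible-fission criterion against a day's partition.

    True iff everyone foraged, both areas hold at least ``min_subgroup``
    individuals, and every individual directs at least ``threshold`` percent
    of its social time at same-area members (inclusive comparison).  A split
    with a subgroup of three or fewer is a dispersion, never a fission; a
    day with anyone resting or everyone in one area trivially fails.
    """
    if net.n != assign.n:
        raise ConfigurationError(
            f"network has {net.n} individuals but assignment has {assign.n}"
        )
    if not assign.complete:
        return False
    n1, n2 = assign.sizes
    if n1 < min_subgroup or n2 < min_subgroup:
        return False
    return bool(np.all(net.within_subgroup_sums(assign) >= threshold))
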