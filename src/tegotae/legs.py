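"""Leg identifiers and the neighbor topology of a hexapod.

Legs are labelled L1..L3 (left fore, middle, hind) and R1..R3.  Each leg's
neighbor set contains the ipsilateral legs of adjacent rank and the
contralateral leg of the same rank: fore and hind legs therefore have two
neighbors, middle legs three.  Neighbor ground-reaction forces enter the
coordination law weighted by their relation to the target leg (anterior
``k_a``, posterior ``k_p``, contralateral ``k_c``).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum, IntEnum
from typing import FrozenSet, Iterable, Mapping, Tuple

import numpy as np

__all__ = [
    "Side",
    "Rank",
    "Leg",
    "Relation",
    "LEGS",
    "NeighborSpec",
    "neighbor_set",
    "relation_weights",
    "build_topology",
    "mirror",
    "MIRROR_PERMUTATION",
]


class Side(Enum):
    LEFT = "L"
    RIGHT = "R"

    @property
    def opposite(self) -> "Side":
        return Side.RIGHT if self is Side.LEFT else Side.LEFT


class Rank(IntEnum):
    FORE = 1
    MIDDLE = 2
    HIND = 3


class Leg(Enum):
    """One of the six legs, canonical labels L1, L2, L3, R1, R2, R3."""

    L1 = (Side.LEFT, Rank.FORE)
    L2 = (Side.LEFT, Rank.MIDDLE)
    L3 = (Side.LEFT, Rank.HIND)
    R1 = (Side.RIGHT, Rank.FORE)
    R2 = (Side.RIGHT, Rank.MIDDLE)
    R3 = (Side.RIGHT, Rank.HIND)

    @property
    def side(self) -> Side:
        return self.value[0]

    @property
    def rank(self) -> Rank:
        return self.value[1]

    @property
    def label(self) -> str:
        return self.name

    @property
    def index(self) -> int:
        """Position in the canonical array ordering (L1, L2, L3, R1, R2, R3)."""
        return _LEG_INDEX[self]

    @classmethod
    def from_side_rank(cls, side: Side, rank: Rank) -> "Leg":
        return cls((side, Rank(rank)))

    @classmethod
    def from_label(cls, label: str) -> "Leg":
        return cls[label.upper()]

    @property
    def mirrored(self) -> "Leg":
        return Leg.from_side_rank(self.side.opposite, self.rank)


LEGS: Tuple[Leg, ...] = (Leg.L1, Leg.L2, Leg.L3, Leg.R1, Leg.R2, Leg.R3)
_LEG_INDEX = {leg: i for i, leg in enumerate(LEGS)}

#: index permutation that swaps left and right sides
MIRROR_PERMUTATION = np.array([LEGS.index(leg.mirrored) for leg in LEGS])


def mirror(values: np.ndarray) -> np.ndarray:
    """Apply the left/right mirror permutation to a per-leg array (last axis)."""
    return np.asarray(values)[..., MIRROR_PERMUTATION]


class Relation(Enum):
    ANTERIOR = "anterior"
    POSTERIOR = "posterior"
    CONTRALATERAL = "contralateral"


def _full_neighbors(leg: Leg) -> Tuple[Tuple[Leg, Relation], ...]:
    out = []
    if leg.rank > Rank.FORE:
        out.append((Leg.from_side_rank(leg.side, Rank(leg.rank - 1)), Relation.ANTERIOR))
    if leg.rank < Rank.HIND:
        out.append((Leg.from_side_rank(leg.side, Rank(leg.rank + 1)), Relation.POSTERIOR))
    out.append((Leg.from_side_rank(leg.side.opposite, leg.rank), Relation.CONTRALATERAL))
    return tuple(out)


_NEIGHBORS: Mapping[Leg, Tuple[Tuple[Leg, Relation], ...]] = {
    leg: _full_neighbors(leg) for leg in LEGS
}


@dataclass(frozen=True)
class NeighborSpec:
    """Neighbor set of one leg.

    ``neighbors`` lists the full (pre-amputation) topology; amputated
    neighbors stay listed but are flagged in ``amputated_neighbors`` and
    contribute zero force.  ``n_L`` is the averaging denominator of the
    neighbor Tegotae term: by default the full-topology neighbor count
    (2 for fore/hind legs, 3 for middle legs), optionally renormalized to
    the intact count.
    """

    target: Leg
    neighbors: Tuple[Tuple[Leg, Relation], ...]
    amputated_neighbors: FrozenSet[Leg]
    n_L: int

    def intact_neighbors(self) -> Tuple[Tuple[Leg, Relation], ...]:
        return tuple((l, r) for l, r in self.neighbors if l not in self.amputated_neighbors)


def neighbor_set(
    leg: Leg,
    amputated: Iterable[Leg] = (),
    renormalize_nL: bool = False,
) -> NeighborSpec:
    """Return the neighbor specification for ``leg``.

    Parameters
    ----------
    leg
        Target leg; must not itself be amputated.
    amputated
        Legs removed from the body.  They remain listed as neighbors but are
        flagged and contribute zero force.
    renormalize_nL
        If True, ``n_L`` counts only intact neighbors; by default amputation
        weakens rather than re-weights the neighbor term.
    """
    amputated = frozenset(amputated)
    if leg in amputated:
        raise ValueError(f"leg {leg.label} is amputated and has no neighbor set")
    neighbors = _NEIGHBORS[leg]
    flagged = frozenset(l for l, _ in neighbors) & amputated
    n_L = len(neighbors) - (len(flagged) if renormalize_nL else 0)
    return NeighborSpec(target=leg, neighbors=neighbors, amputated_neighbors=flagged, n_L=n_L)


def relation_weights(params) -> Mapping[Relation, float]:
    """Map each neighbor relation to its force weight from the parameter set."""
    return {
        Relation.ANTERIOR: params.k_a,
        Relation.POSTERIOR: params.k_p,
        Relation.CONTRALATERAL: params.k_c,
    }


def build_topology(
    params,
    amputated: Iterable[Leg] = (),
    renormalize_nL: bool = False,
) -> Tuple[np.ndarray, np.ndarray]:
    """Assemble the weighted neighbor matrix and averaging denominators.

    Returns ``(W, n_L)`` where ``W`` is a 6x6 matrix with ``W[i, j]`` the
    weight applied to leg ``j``'s vertical force in leg ``i``'s neighbor
    Tegotae term (zero for non-neighbors and amputated legs), and ``n_L`` the
    per-leg averaging denominator.
    """
    amputated = frozenset(amputated)
    W = np.zeros((6, 6))
    n_L = np.zeros(6)
    weights = relation_weights(params)
    for leg in LEGS:
        i = leg.index
        if leg in amputated:
            n_L[i] = 1.0  # unused; avoids division by zero
            continue
        spec = neighbor_set(leg, amputated, renormalize_nL)
        n_L[i] = max(spec.n_L, 1)
        for other, rel in spec.neighbors:
            if other in amputated:
                continue
            W[i, other.index] = weights[rel]
    return W, n_L
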