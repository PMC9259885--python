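"""Spot geometry of the four-hole touch-screen panel.

The task presents four nose-poke spots arranged on a 2x2 grid.  The two
*diagonal pairs* partition the spots; one pair is "rewarded" and the other
"never-rewarded" at any point of the protocol.  Two spots that are neither
identical nor diagonal partners are *adjacent* (same row or same column).

The default layout numbers the spots

    1  2
    3  4

so the diagonal pairs are ``{1, 4}`` and ``{2, 3}``, and e.g. spot 1 is
adjacent to spots 2 and 3.  Alternative labellings can be expressed by
constructing a :class:`SpotLayout` directly.
"""

from __future__ import annotations

from dataclasses import dataclass

Spot = int


@dataclass(frozen=True)
class SpotLayout:
    """Four spots partitioned into two diagonal pairs.

    Parameters
    ----------
    spot_ids:
        The four distinct spot labels.
    diagonal_pairs:
        Two disjoint unordered pairs covering all four spots.  The first
        pair is "diagonal A" (sign +1), the second "diagonal B" (sign -1);
        the sign convention is used by the synthetic agents.
    """

    spot_ids: tuple[Spot, Spot, Spot, Spot] = (1, 2, 3, 4)
    diagonal_pairs: tuple[frozenset[Spot], frozenset[Spot]] = (
        frozenset({1, 4}),
        frozenset({2, 3}),
    )

    def __post_init__(self) -> None:
        spots = set(self.spot_ids)
        if len(self.spot_ids) != 4 or len(spots) != 4:
            raise ValueError("layout requires exactly 4 distinct spots")
        pair_a, pair_b = self.diagonal_pairs
        if len(pair_a) != 2 or len(pair_b) != 2:
            raise ValueError("each diagonal pair must contain exactly 2 spots")
        if pair_a & pair_b:
            raise ValueError("diagonal pairs must be disjoint")
        if pair_a | pair_b != spots:
            raise ValueError("diagonal pairs must cover all 4 spots")

    def diagonal_partner(self, spot: Spot) -> Spot:
        """The spot diagonally opposite ``spot``."""
        for pair in self.diagonal_pairs:
            if spot in pair:
                (other,) = pair - {spot}
                return other
        raise KeyError(f"unknown spot {spot!r}")

    def adjacency(self, spot: Spot) -> frozenset[Spot]:
        """The two spots that are neither ``spot`` nor its diagonal partner."""
        partner = self.diagonal_partner(spot)
        return frozenset(s for s in self.spot_ids if s not in (spot, partner))

    def side(self, spot: Spot) -> int:
        """Sign of the spot's diagonal: +1 for diagonal A, -1 for diagonal B."""
        if spot in self.diagonal_pairs[0]:
            return 1
        if spot in self.diagonal_pairs[1]:
            return -1
        raise KeyError(f"unknown spot {spot!r}")

    def __contains__(self, spot: object) -> bool:
        return spot in self.spot_ids


DEFAULT_LAYOUT = SpotLayout()


@dataclass(frozen=True)
class DiagonalAssignment:
    """Which diagonal pair is currently rewarded.

    The rewarded pair yields a pellet when its *active* member is poked; the
    never-rewarded pair never yields a pellet.  Together the two pairs cover
    all four spots.
    """

    rewarded_pair: frozenset[Spot]
    never_rewarded_pair: frozenset[Spot]

    def __post_init__(self) -> None:
        if len(self.rewarded_pair) != 2 or len(self.never_rewarded_pair) != 2:
            raise ValueError("each pair must contain exactly 2 spots")
        if self.rewarded_pair & self.never_rewarded_pair:
            raise ValueError("rewarded and never-rewarded pairs must be disjoint")

    @property
    def spots(self) -> frozenset[Spot]:
        return self.rewarded_pair | self.never_rewarded_pair

    def rewarded_partner(self, spot: Spot) -> Spot:
        """The other rewarded spot."""
        if spot not in self.rewarded_pair:
            raise KeyError(f"spot {spot!r} is not rewarded")
        (other,) = self.rewarded_pair - {spot}
        return other

    @classmethod
    def from_layout(cls, layout: SpotLayout, rewarded_diagonal: int = 0) -> "DiagonalAssignment":
        """Assignment rewarding diagonal ``rewarded_diagonal`` (0 = A, 1 = B)."""
        return cls(
            rewarded_pair=layout.diagonal_pairs[rewarded_diagonal],
            never_rewarded_pair=layout.diagonal_pairs[1 - rewarded_diagonal],
        )
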