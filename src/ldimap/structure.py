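"""Helix models and bounded long-distance duplex scanning.

Helices are contiguous antiparallel stacks of canonical base pairs; bulges
and internal loops are represented as separate helices. There is no free
energy model here — candidate long-distance duplexes are ranked by pair
count and then by summed pair-class strength (G:C > A:U > G:U), which is
how the underlying splicing work reasons about stem stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import FrozenSet, Iterable, Optional, Sequence

from .coords import (
    BoundsError,
    Interval,
    Reference,
    Variant,
    check_position,
    pos_count,
    pos_step,
)

__all__ = [
    "BasePairRule",
    "WATSON_CRICK",
    "WOBBLE_OK",
    "Helix",
    "StructureModel",
    "ModelError",
    "build_wt_istl1",
    "extend_helix",
    "helix_length",
    "loop_length",
    "find_ldi_duplexes",
]

ISTL1_ANCHOR_5P = Interval(3, 10)   # 5' strand of the wild-type internal stem
ISTL1_ANCHOR_3P = Interval(290, 297)  # 3' strand (innermost pair 10:290)


class ModelError(ValueError):
    """A helix is inconsistent with the (mutated) reference sequence."""


_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class BasePairRule:
    """Which pairs count as canonical, and their strength ranking."""

    allow_wobble: bool = True
    strength_rank: tuple[tuple[str, int], ...] = (("GC", 3), ("AU", 2), ("GU", 1))

    def canonical(self, b1: str, b2: str) -> bool:
        pair = (b1, b2)
        return pair in _WC or (self.allow_wobble and pair in _WOBBLE)

    def strength(self, b1: str, b2: str) -> int:
        key = "".join(sorted((b1, b2)))
        # sorted() maps CG->CG, AU->AU, GU->GU
        table = {"CG": dict(self.strength_rank)["GC"],
                 "AU": dict(self.strength_rank)["AU"],
                 "GU": dict(self.strength_rank)["GU"]}
        return table.get(key, 0)


WATSON_CRICK = BasePairRule(allow_wobble=False)
WOBBLE_OK = BasePairRule(allow_wobble=True)


@dataclass(frozen=True)
class Helix:
    """Ordered antiparallel pair list, outermost pair first.

    Consecutive pairs step inward: i increases by one residue, j decreases
    by one residue (along the molecule, i.e. skipping deleted positions and
    the nonexistent coordinate 0). Every pair satisfies i < j.
    """

    pairs: tuple[tuple[int, int], ...]
    name: str = ""
    schematic: bool = False  # drawn from a published schematic, not sequence-validated

    def __post_init__(self) -> None:
        for i, j in self.pairs:
            check_position(i)
            check_position(j)
            if i >= j:
                raise ValueError(f"pair ({i},{j}) must satisfy i < j")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def outermost(self) -> tuple[int, int]:
        return self.pairs[0]

    @property
    def innermost(self) -> tuple[int, int]:
        return self.pairs[-1]

    @property
    def five_prime_strand(self) -> Interval:
        return Interval(self.pairs[0][0], self.pairs[-1][0])

    @property
    def three_prime_strand(self) -> Interval:
        return Interval(self.pairs[-1][1], self.pairs[0][1])

    def positions(self) -> FrozenSet[int]:
        return frozenset(p for pair in self.pairs for p in pair)

    def terminal_positions(self) -> FrozenSet[int]:
        """Residues of the outermost (distal) pair — the flexible helix end.

        The innermost pair is not included: it closes the enclosed loop and
        behaves like an interior stack in probing data.
        """
        if not self.pairs:
            return frozenset()
        return frozenset(self.pairs[0])

    def validate(self, ref: Reference, rule: BasePairRule = WOBBLE_OK) -> None:
        """Check nesting/adjacency and canonical pairing against a reference."""
        failing = []
        for (i1, j1), (i2, j2) in zip(self.pairs, self.pairs[1:]):
            if ref.successor(i1) != i2 or ref.predecessor(j1) != j2:
                raise ModelError(
                    f"helix {self.name!r} pairs ({i1},{j1})→({i2},{j2}) are not contiguous"
                )
        for i, j in self.pairs:
            if not (ref.covers(i) and ref.covers(j)):
                raise BoundsError(f"helix {self.name!r} pair ({i},{j}) outside reference")
            if not rule.canonical(ref.base_at(i), ref.base_at(j)):
                failing.append((i, j, ref.base_at(i), ref.base_at(j)))
        if failing:
            raise ModelError(f"non-canonical pairs in helix {self.name!r}: {failing}")


@dataclass(frozen=True)
class StructureModel:
    """A set of helices plus explicitly unpaired positions.

    Pseudoknot-freedom is not required: internal stems formed by
    long-distance interactions coexist with local terminal stem-loops.
    """

    helices: tuple[Helix, ...]
    unpaired: FrozenSet[int] = frozenset()
    name: str = ""

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for h in self.helices:
            dup = seen & h.positions()
            if dup:
                raise ValueError(f"position(s) {sorted(dup)} appear in two helices")
            seen.update(h.positions())

    def helix(self, name: str) -> Helix:
        for h in self.helices:
            if h.name == name:
                return h
        raise KeyError(f"no helix named {name!r}")

    def paired_positions(self) -> FrozenSet[int]:
        out: set[int] = set()
        for h in self.helices:
            out.update(h.positions())
        return frozenset(out)

    def terminal_positions(self) -> FrozenSet[int]:
        out: set[int] = set()
        for h in self.helices:
            out.update(h.terminal_positions())
        return frozenset(out)

    def positions(self) -> FrozenSet[int]:
        return self.paired_positions() | self.unpaired

    def without(self, name: str) -> "StructureModel":
        return replace(
            self,
            helices=tuple(h for h in self.helices if h.name != name),
            unpaired=self.unpaired | self.helix(name).positions(),
        )


def helix_length(h: Optional[Helix]) -> int:
    """Number of base pairs (0 for an empty/absent helix)."""
    return 0 if h is None else len(h.pairs)


def loop_length(h: Helix) -> int:
    """Residues enclosed between the strands at the innermost pair.

    Counted as valid coordinate positions strictly between i* and j*
    (the nonexistent position 0 is never counted).
    """
    if not h.pairs:
        raise ValueError("empty helix has no enclosed loop")
    i, j = h.innermost
    return pos_count(pos_step(i), pos_step(j, -1))


def build_wt_istl1(ref: Reference, rule: BasePairRule = WATSON_CRICK) -> Helix:
    """Build the wild-type 8-bp internal stem anchoring intron position 10 on 290.

    Pairs intron positions 3–10 with 297–290 (outermost 3:297, innermost
    10:290; 16 residues in total). Raises :class:`ModelError` listing the
    failing pairs if the reference cannot support canonical pairing.
    """
    need = list(ISTL1_ANCHOR_5P.positions()) + list(ISTL1_ANCHOR_3P.positions())
    for p in need:
        if not ref.covers(p):
            raise BoundsError(f"reference does not cover ISTL1 anchor position {p}")
    pairs = tuple(zip(ISTL1_ANCHOR_5P.positions(), reversed(ISTL1_ANCHOR_3P.positions())))
    h = Helix(pairs, name="ISTL1")
    h.validate(ref, rule)
    return h


def extend_helix(
    ref: Reference,
    h: Helix,
    v: Variant,
    rule: BasePairRule = WATSON_CRICK,
) -> Helix:
    """Maximal contiguous helix containing ``h``'s pairs on the mutated sequence.

    The variant is applied to the reference; the anchor pairs must remain
    canonical (a substitution breaking an anchor pair raises
    :class:`ModelError`, a deletion removing an anchored residue is a
    structural error). The helix is then grown greedily one pair at a time
    at both ends — loop-proximal beyond the innermost pair and distal
    beyond the outermost — while residues remain canonical under ``rule``.
    Idempotent: extending an already-maximal helix returns it unchanged.
    """
    mut = ref.apply(v) if not v.is_wildtype else ref
    for p in h.positions():
        if not mut.covers(p):
            raise ModelError(
                f"variant {v.label!r} deletes anchored helix position {p}"
            )
    h.validate(mut, rule)

    pairs = list(h.pairs)
    taken = set(h.positions())

    def grow(i: Optional[int], j: Optional[int]) -> Optional[tuple[int, int]]:
        if i is None or j is None or i >= j or i in taken or j in taken:
            return None
        if not (mut.covers(i) and mut.covers(j)):
            return None
        if not rule.canonical(mut.base_at(i), mut.base_at(j)):
            return None
        return (i, j)

    # loop-proximal growth
    while True:
        i, j = pairs[-1]
        nxt = grow(mut.successor(i), mut.predecessor(j))
        if nxt is None:
            break
        pairs.append(nxt)
        taken.update(nxt)
    # distal growth
    while True:
        i, j = pairs[0]
        nxt = grow(mut.predecessor(i), mut.successor(j))
        if nxt is None:
            break
        pairs.insert(0, nxt)
        taken.update(nxt)

    return Helix(tuple(pairs), name=h.name)


def find_ldi_duplexes(
    ref: Reference,
    query: Interval,
    search: Interval,
    min_bp: int = 3,
    rule: BasePairRule = WOBBLE_OK,
    occupied: Iterable[int] = (),
) -> list[Helix]:
    """Exhaustively enumerate maximal antiparallel duplexes between two regions.

    Every contiguous stack of >= ``min_bp`` canonical pairs with one strand
    in ``query`` and the other in ``search`` is reported once (as its
    maximal extension within the regions). Positions in ``occupied`` —
    typically residues locked inside other helices of a structure model —
    are not pairable. Results are sorted by (pair count, summed pair
    strength) descending, ties broken by the outermost pair's coordinates.
    Symmetric in its two regions.
    """
    if query.overlaps(search):
        raise ValueError(f"query {query} and search {search} regions overlap")
    if min_bp < 3:
        raise ValueError("min_bp must be >= 3")
    lo, hi = sorted((query, search))
    blocked = frozenset(occupied)

    lo_pos = [p for p in lo.positions() if ref.covers(p)]
    hi_pos = [p for p in hi.positions() if ref.covers(p)]
    lo_set, hi_set = set(lo_pos), set(hi_pos)

    def pairable(i: Optional[int], j: Optional[int]) -> bool:
        return (
            i is not None
            and j is not None
            and i in lo_set
            and j in hi_set
            and i not in blocked
            and j not in blocked
            and i < j
            and rule.canonical(ref.base_at(i), ref.base_at(j))
        )

    duplexes: list[Helix] = []
    for a in lo_pos:
        for b in hi_pos:
            if not pairable(a, b):
                continue
            # only start runs at their outermost pair, so each run is emitted once
            if pairable(ref.predecessor(a), ref.successor(b)):
                continue
            pairs = [(a, b)]
            i, j = ref.successor(a), ref.predecessor(b)
            while pairable(i, j):
                pairs.append((i, j))
                i, j = ref.successor(i), ref.predecessor(j)  # type: ignore[arg-type]
            if len(pairs) >= min_bp:
                duplexes.append(Helix(tuple(pairs), name=f"duplex{a}:{b}"))

    def strength(h: Helix) -> int:
        return sum(rule.strength(ref.base_at(i), ref.base_at(j)) for i, j in h.pairs)

    duplexes.sort(key=lambda h: (-len(h.pairs), -strength(h), h.pairs[0][0], h.pairs[0][1]))
    return duplexes
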