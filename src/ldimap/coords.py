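"""Coordinate system, reference sequences and mutation nomenclature.

Intron coordinates are signed integers: position 1 is the first intronic
nucleotide, positive values count downstream into the intron, negative
values count back into the upstream exon (-1 is the last exonic residue).
Position 0 does not exist. Intervals are inclusive at both ends, so a
deletion named ``Δ281–300`` removes exactly 20 nt.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Literal, Optional, Sequence

RNA_BASES = frozenset("ACGU")

__all__ = [
    "Interval",
    "Edit",
    "Variant",
    "ReferenceSequence",
    "Reference",
    "VariantParseError",
    "BoundsError",
    "check_position",
    "pos_step",
    "pos_range",
    "pos_count",
    "normalize_rna",
    "parse_variant_label",
    "apply_variant",
]


class VariantParseError(ValueError):
    """A variant label does not follow the deletion/substitution grammar."""


class BoundsError(ValueError):
    """A coordinate falls outside the reference span."""


def check_position(p: int) -> int:
    if not isinstance(p, int) or isinstance(p, bool) or p == 0:
        raise ValueError(f"invalid intron position {p!r}: must be a nonzero integer")
    return p


def pos_step(p: int, k: int = 1) -> int:
    """Move ``k`` steps along the coordinate axis, skipping the nonexistent 0."""
    check_position(p)
    q = p + k
    # crossing the exon-intron junction skips 0
    if p < 0 <= q:
        q += 1
    elif p > 0 >= q:
        q -= 1
    return q


def pos_range(start: int, end: int) -> Iterator[int]:
    """Inclusive run of valid positions from start to end (start <= end)."""
    check_position(start)
    check_position(end)
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    p = start
    while p <= end:
        yield p
        p = pos_step(p)


def pos_count(start: int, end: int) -> int:
    """Number of residues in the inclusive interval [start, end]."""
    n = end - start + 1
    if start < 0 < end:
        n -= 1  # no position 0
    return n


def normalize_rna(seq: str) -> str:
    """Uppercase and transcribe T→U; reject anything outside the RNA alphabet."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - RNA_BASES
    if bad:
        raise ValueError(f"non-RNA characters in sequence: {sorted(bad)}")
    return s


@dataclass(frozen=True, order=True)
class Interval:
    """Closed interval of intron positions (both ends included)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        check_position(self.start)
        check_position(self.end)
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return pos_count(self.start, self.end)

    def __contains__(self, p: int) -> bool:
        return self.start <= p <= self.end and p != 0

    def positions(self) -> list[int]:
        return list(pos_range(self.start, self.end))

    def overlaps(self, other: "Interval") -> bool:
        return self.start <= other.end and other.start <= self.end

    def __str__(self) -> str:
        return f"{self.start}–{self.end}"


@dataclass(frozen=True)
class Edit:
    kind: Literal["deletion", "substitution"]
    interval: Interval
    replacement: Optional[str] = None  # single base, substitutions only

    def __post_init__(self) -> None:
        if self.kind == "substitution":
            if len(self.interval) != 1:
                raise ValueError("substitution edits cover exactly one position")
            if self.replacement not in RNA_BASES:
                raise ValueError(f"substitution base {self.replacement!r} not in ACGU")
        elif self.kind == "deletion":
            if self.replacement is not None:
                raise ValueError("deletion edits carry no replacement base")
        else:
            raise ValueError(f"unknown edit kind {self.kind!r}")


@dataclass(frozen=True)
class Variant:
    """A named set of non-overlapping deletions/substitutions."""

    label: str
    edits: tuple[Edit, ...] = ()

    def __post_init__(self) -> None:
        ivs = sorted(e.interval for e in self.edits)
        for a, b in zip(ivs, ivs[1:]):
            if a.end >= b.start:
                raise ValueError(f"overlapping edits in {self.label!r}: {a} vs {b}")

    @property
    def is_wildtype(self) -> bool:
        return not self.edits

    def deletions(self) -> list[Edit]:
        return [e for e in self.edits if e.kind == "deletion"]

    def substitutions(self) -> list[Edit]:
        return [e for e in self.edits if e.kind == "substitution"]


WT = Variant("WT")

_DEL_RE = re.compile(r"^(?:Δ|∆|del)\s*(-?\d+)\s*[–—-]\s*(-?\d+)$", re.IGNORECASE)
_SUB_RE = re.compile(r"^(-?\d+)([ACGUTacgut])$")


def parse_variant_label(label: str) -> Variant:
    """Parse the field's mutant-name grammar into a structured :class:`Variant`.

    ``Δ281–300`` (or ``del281-300``) is a deletion of the inclusive interval;
    slash-separated tokens like ``286G/288U/289G/298A`` are substitutions,
    ``289G`` meaning "replace the residue at intron position 289 with G".
    ``WT`` (or ``wt``) names the unedited reference.
    """
    text = label.strip()
    if not text:
        raise VariantParseError("empty variant label")
    if text.upper() == "WT":
        return Variant("WT")

    m = _DEL_RE.match(text)
    if m:
        start, end = int(m.group(1)), int(m.group(2))
        try:
            iv = Interval(start, end)
        except ValueError as exc:
            raise VariantParseError(f"bad deletion token {text!r}: {exc}") from exc
        return Variant(text, (Edit("deletion", iv),))

    edits = []
    for token in text.split("/"):
        token = token.strip()
        m = _SUB_RE.match(token)
        if not m:
            raise VariantParseError(f"malformed variant token {token!r} in {label!r}")
        pos, base = int(m.group(1)), normalize_rna(m.group(2))
        if pos == 0:
            raise VariantParseError(f"position 0 is invalid in token {token!r}")
        edits.append(Edit("substitution", Interval(pos, pos), base))
    try:
        return Variant(text, tuple(edits))
    except ValueError as exc:
        raise VariantParseError(str(exc)) from exc


@dataclass(frozen=True)
class ReferenceSequence:
    """A contiguous reference segment with known residues.

    ``origin_offset`` is the intron coordinate of the first residue; the
    segment runs through consecutive coordinates (skipping 0 if it crosses
    the exon-intron junction). DNA input is transcribed to RNA on ingest.
    """

    residues: str
    origin_offset: int
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", normalize_rna(self.residues))
        check_position(self.origin_offset)
        if not self.residues:
            raise ValueError("empty reference segment")

    @property
    def span(self) -> Interval:
        end = self.origin_offset
        for _ in range(len(self.residues) - 1):
            end = pos_step(end)
        return Interval(self.origin_offset, end)

    def positions(self) -> list[int]:
        return self.span.positions()

    def base_at(self, p: int) -> str:
        sp = self.span
        if p not in sp:
            raise BoundsError(f"position {p} outside segment {self.name!r} span {sp}")
        idx = pos_count(self.origin_offset, p) - 1
        return self.residues[idx]


@dataclass(frozen=True)
class Reference:
    """One or more non-overlapping reference segments plus applied edits.

    Positions keep their wild-type labels after mutation: a substitution
    changes the base under a label, a deletion removes labels. Adjacency
    (used by helix extension and duplex scanning) holds within a segment;
    a deletion joins its flanks. Two separate segments are *not* adjacent —
    a gap between printed segments is missing data, not a junction.
    """

    segments: tuple[tuple[tuple[int, ...], str], ...]  # (labels, bases) per segment
    name: str = "ref"

    @classmethod
    def from_segments(cls, segs: Sequence[ReferenceSequence], name: str = "ref") -> "Reference":
        built = []
        seen: set[int] = set()
        for s in segs:
            labels = tuple(s.positions())
            if seen & set(labels):
                raise ValueError("overlapping reference segments")
            seen.update(labels)
            built.append((labels, s.residues))
        built.sort(key=lambda t: t[0][0])
        return cls(tuple(built), name=name)

    # -- lookup ---------------------------------------------------------
    def _find(self, p: int) -> Optional[tuple[int, int]]:
        for si, (labels, _) in enumerate(self.segments):
            # labels are sorted within a segment
            if labels and labels[0] <= p <= labels[-1]:
                try:
                    return si, labels.index(p)
                except ValueError:
                    return None
        return None

    def covers(self, p: int) -> bool:
        return self._find(p) is not None

    def covers_interval(self, iv: Interval) -> bool:
        return all(self.covers(p) for p in iv.positions())

    def base_at(self, p: int) -> str:
        hit = self._find(p)
        if hit is None:
            raise BoundsError(f"position {p} not covered by reference {self.name!r}")
        si, i = hit
        return self.segments[si][1][i]

    def slice(self, iv: Interval) -> str:
        return "".join(self.base_at(p) for p in iv.positions())

    def successor(self, p: int) -> Optional[int]:
        """Next residue 3' of p on the (possibly mutated) molecule, or None."""
        hit = self._find(p)
        if hit is None:
            return None
        si, i = hit
        labels = self.segments[si][0]
        return labels[i + 1] if i + 1 < len(labels) else None

    def predecessor(self, p: int) -> Optional[int]:
        hit = self._find(p)
        if hit is None:
            return None
        si, i = hit
        return self.segments[si][0][i - 1] if i > 0 else None

    def positions(self) -> list[int]:
        out: list[int] = []
        for labels, _ in self.segments:
            out.extend(labels)
        return out

    # -- mutation -------------------------------------------------------
    def apply(self, variant: Variant, strict: bool = True) -> "Reference":
        ref, _ = apply_variant(self, variant, strict=strict)
        return ref


def apply_variant(
    ref: Reference, v: Variant, strict: bool = True
) -> tuple[Reference, dict[int, Optional[int]]]:
    """Apply a variant; return the mutant reference and a coordinate lift table.

    The lift table maps every wild-type position of the reference to its
    0-based index along the mutant molecule (concatenating segments in
    order), or ``None`` if the position was deleted. With ``strict`` every
    edited position must be covered by the reference; without it, edits at
    uncovered positions are dropped (they cannot change the covered view —
    useful when a variant is defined on the full intron but only the
    printed segments are in hand).
    """
    if strict:
        for e in v.edits:
            for p in e.interval.positions():
                if not ref.covers(p):
                    raise BoundsError(
                        f"edit {e.kind} at {e.interval} of {v.label!r} outside reference span"
                    )

    deleted: set[int] = set()
    subs: dict[int, str] = {}
    for e in v.edits:
        if e.kind == "deletion":
            deleted.update(p for p in e.interval.positions() if ref.covers(p))
        elif ref.covers(e.interval.start):
            subs[e.interval.start] = e.replacement  # type: ignore[assignment]

    new_segments = []
    lift: dict[int, Optional[int]] = {}
    idx = 0
    for labels, bases in ref.segments:
        keep_labels: list[int] = []
        keep_bases: list[str] = []
        for p, b in zip(labels, bases):
            if p in deleted:
                lift[p] = None
                continue
            lift[p] = idx
            idx += 1
            keep_labels.append(p)
            keep_bases.append(subs.get(p, b))
        if keep_labels:
            new_segments.append((tuple(keep_labels), "".join(keep_bases)))
    name = ref.name if v.is_wildtype else f"{ref.name}|{v.label}"
    return Reference(tuple(new_segments), name=name), lift
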