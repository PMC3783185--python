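"""Core-region inference from overlapping deletion and point-substitution scans.

A minigene perturbation scan assigns each tested variant a three-valued
response phenotype: whether the splice-switching readout (here, the
inhibitory effect of the L14 oligonucleotide) is *retained*, *partial*, or
*abrogated*. A position belongs to the functional core iff it was covered
by at least one tested deletion and every deletion covering it abrogated
the response. Positions never tested cannot be claimed required and are
excluded.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .coords import Interval, Reference, Variant, pos_step

__all__ = [
    "Call",
    "ScanPolicy",
    "PerturbationRecord",
    "CoreRegion",
    "infer_core_region",
    "point_scan_core",
    "core_motif",
]


class Call(str, enum.Enum):
    RETAINED = "retained"
    PARTIAL = "partial"
    ABROGATED = "abrogated"


@dataclass(frozen=True)
class ScanPolicy:
    """How to resolve 'to a lesser extent' (partial) phenotype calls."""

    partial_as: Call = Call.RETAINED

    def __post_init__(self) -> None:
        if self.partial_as not in (Call.RETAINED, Call.ABROGATED):
            raise ValueError("partial_as must be retained or abrogated")

    def resolve(self, call: Call) -> Call:
        return self.partial_as if call is Call.PARTIAL else call


@dataclass(frozen=True)
class PerturbationRecord:
    variant: Variant
    call: Call
    figure: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "call", Call(self.call))


@dataclass(frozen=True)
class CoreRegion:
    interval: Interval
    motif: Optional[str] = None

    @property
    def length_nt(self) -> int:
        return len(self.interval)


def _deletion_interval(rec: PerturbationRecord) -> Interval:
    dels = rec.variant.deletions()
    if rec.variant.substitutions() or len(dels) != 1:
        raise TypeError(
            f"deletion-scan records must carry exactly one deletion: {rec.variant.label!r}"
        )
    return dels[0].interval


def _runs(positions: Iterable[int]) -> list[Interval]:
    """Maximal runs of consecutive positions as inclusive intervals."""
    out: list[Interval] = []
    sorted_pos = sorted(set(positions))
    if not sorted_pos:
        return out
    start = prev = sorted_pos[0]
    for p in sorted_pos[1:]:
        if p != pos_step(prev):
            out.append(Interval(start, prev))
            start = p
        prev = p
    out.append(Interval(start, prev))
    return out


def infer_core_region(
    records: Sequence[PerturbationRecord],
    policy: ScanPolicy = ScanPolicy(),
    ref: Optional[Reference] = None,
) -> list[CoreRegion]:
    """Infer the functional core(s) from an overlapping-deletion scan.

    A position is in the core iff it is covered by >=1 tested deletion and
    every tested deletion covering it is abrogated after resolving partial
    calls through ``policy``. Maximal runs of core positions are returned;
    when a reference is supplied each core carries its wild-type motif.
    """
    if not records:
        raise ValueError("no perturbation records supplied")
    windows = [(_deletion_interval(r), policy.resolve(r.call)) for r in records]
    if not any(call is Call.ABROGATED for _, call in windows):
        warnings.warn("no abrogated deletion after policy resolution; empty core")
        return []

    core: set[int] = set()
    covered: set[int] = set()
    for iv, _ in windows:
        covered.update(iv.positions())
    for p in covered:
        calls = [call for iv, call in windows if p in iv]
        if all(c is Call.ABROGATED for c in calls):
            core.add(p)

    out = []
    for iv in _runs(core):
        motif = core_motif(ref, iv) if ref is not None and ref.covers_interval(iv) else None
        out.append(CoreRegion(iv, motif))
    return out


def point_scan_core(
    records: Sequence[PerturbationRecord],
    ref: Optional[Reference] = None,
) -> Optional[CoreRegion]:
    """Infer the core from a single-nucleotide substitution scan.

    Each record is one substitution; a position is core-eligible iff every
    tested substitution at it abrogates the response. The longest maximal
    run of core positions is returned (leftmost on ties); ``None`` if no
    substitution abrogates.
    """
    if not records:
        raise ValueError("no perturbation records supplied")
    by_pos: dict[int, list[Call]] = {}
    for r in records:
        subs = r.variant.substitutions()
        if r.variant.deletions() or len(subs) != 1:
            raise TypeError(
                f"point-scan records must carry exactly one substitution: {r.variant.label!r}"
            )
        by_pos.setdefault(subs[0].interval.start, []).append(r.call)

    core = {p for p, calls in by_pos.items() if all(c is Call.ABROGATED for c in calls)}
    runs = _runs(core)
    if not runs:
        return None
    best = max(runs, key=lambda iv: (len(iv), -iv.start))
    motif = core_motif(ref, best) if ref is not None and ref.covers_interval(best) else None
    return CoreRegion(best, motif)


def core_motif(ref: Reference, interval: Interval) -> str:
    """Wild-type residues over an inclusive interval."""
    return ref.slice(interval)
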