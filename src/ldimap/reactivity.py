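"""Quantification, classification and comparison of SHAPE (1M7) reactivities.

Per-position band intensities from primer-extension lanes are reduced to
reactivities by subtracting the no-reagent (DMSO) lane from the 1M7 lane,
clamping at zero, and normalizing to the most reactive position *within
each extension primer's window*. Classes follow the probing convention
used throughout: normalized reactivity above 0.5 is "high", between 0.3
and 0.5 inclusive is "moderate", below 0.3 is "low". Positions where the
reverse transcriptase stops prematurely in the control lane (falloffs) are
flagged and excluded from structure-level summaries.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .structure import StructureModel

__all__ = [
    "ReactivityClass",
    "DiffCall",
    "LaneProfile",
    "ReactivityProfile",
    "DifferentialProfile",
    "compute_reactivity",
    "classify_value",
    "classify",
    "count_protected",
    "detect_falloff",
    "merge_primers",
    "differential_profile",
    "structure_concordance",
    "AlignmentError",
]

MODERATE_LOW = 0.3
MODERATE_HIGH = 0.5
DEFAULT_DELTA = 0.15
DEFAULT_FALLOFF_FACTOR = 3.0


class AlignmentError(ValueError):
    """Two profiles do not cover the same positions."""


class ReactivityClass(str, enum.Enum):
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"


class DiffCall(str, enum.Enum):
    PROTECTED = "protected"
    UNCHANGED = "unchanged"
    EXPOSED = "exposed"


@dataclass(frozen=True)
class LaneProfile:
    """Raw band intensities for one extension primer (1M7 + DMSO lanes)."""

    primer_id: str
    positions: tuple[int, ...]
    intensity_1m7: tuple[float, ...]
    intensity_dmso: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.positions)
        if len(self.intensity_1m7) != n or len(self.intensity_dmso) != n:
            raise ValueError("lane vectors must have equal length")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("lane positions must be strictly increasing")
        if any(x < 0 for x in self.intensity_1m7) or any(x < 0 for x in self.intensity_dmso):
            raise ValueError("band intensities must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "primer_id": self.primer_id,
                "intensity_1m7": self.intensity_1m7,
                "intensity_dmso": self.intensity_dmso,
            }
        )


@dataclass(frozen=True)
class ReactivityProfile:
    """Per-position reactivity for one primer window (or a merged profile)."""

    primer_id: str
    positions: tuple[int, ...]
    raw: tuple[float, ...]
    normalized: tuple[float, ...]
    classes: tuple[ReactivityClass, ...] = ()
    falloff: tuple[bool, ...] = ()
    provenance: tuple[str, ...] = ()  # per-position primer of origin (merged profiles)
    degenerate: bool = False  # all-zero raw signal

    def __post_init__(self) -> None:
        n = len(self.positions)
        if not self.falloff:
            object.__setattr__(self, "falloff", (False,) * n)
        if not self.provenance:
            object.__setattr__(self, "provenance", (self.primer_id,) * n)
        for name in ("raw", "normalized", "classes", "falloff", "provenance"):
            v = getattr(self, name)
            if v and len(v) != n:
                raise ValueError(f"{name} length {len(v)} != positions length {n}")

    @property
    def window_center(self) -> float:
        return (self.positions[0] + self.positions[-1]) / 2.0

    def index_of(self, p: int) -> int:
        try:
            return self.positions.index(p)
        except ValueError:
            raise KeyError(f"position {p} not in profile {self.primer_id!r}") from None

    def value_at(self, p: int) -> float:
        return self.normalized[self.index_of(p)]

    def class_at(self, p: int) -> ReactivityClass:
        return self.classes[self.index_of(p)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "primer_id": self.provenance,
                "raw": self.raw,
                "normalized": self.normalized,
                "class": [c.value for c in self.classes] if self.classes else None,
                "falloff": self.falloff,
            }
        )


@dataclass(frozen=True)
class DifferentialProfile:
    """Per-position change between two normalized profiles (alt minus ref)."""

    positions: tuple[int, ...]
    delta: tuple[float, ...]
    calls: tuple[DiffCall, ...]
    margin: float

    def call_at(self, p: int) -> DiffCall:
        return self.calls[self.positions.index(p)]

    def positions_called(self, call: DiffCall) -> list[int]:
        return [p for p, c in zip(self.positions, self.calls) if c is call]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": self.positions, "delta": self.delta,
             "call": [c.value for c in self.calls]}
        )


def compute_reactivity(lane: LaneProfile) -> ReactivityProfile:
    """Subtract the DMSO lane from the 1M7 lane, clamp at 0, max-normalize.

    Normalization is per primer window: the most reactive position gets 1.
    If every position is zero after subtraction the profile is degenerate
    (all normalized values 0) and a warning is attached.
    """
    raw = np.maximum(0.0, np.asarray(lane.intensity_1m7) - np.asarray(lane.intensity_dmso))
    top = raw.max() if raw.size else 0.0
    degenerate = top <= 0.0
    if degenerate:
        warnings.warn(f"degenerate reactivity profile for primer {lane.primer_id!r}")
        norm = np.zeros_like(raw)
    else:
        norm = raw / top
    profile = ReactivityProfile(
        primer_id=lane.primer_id,
        positions=lane.positions,
        raw=tuple(float(x) for x in raw),
        normalized=tuple(float(x) for x in norm),
        degenerate=degenerate,
    )
    return classify(profile)


def classify_value(x: float) -> ReactivityClass:
    if x > MODERATE_HIGH:
        return ReactivityClass.HIGH
    if x >= MODERATE_LOW:
        return ReactivityClass.MODERATE
    return ReactivityClass.LOW


def classify(profile: ReactivityProfile) -> ReactivityProfile:
    """Assign low/moderate/high classes from normalized reactivity (idempotent)."""
    classes = tuple(classify_value(x) for x in profile.normalized)
    return replace(profile, classes=classes)


def count_protected(profile: ReactivityProfile, residues: Iterable[int]) -> int:
    """Count residues with class 'low' (falloff-flagged residues are excluded)."""
    residues = list(residues)
    missing = [p for p in residues if p not in profile.positions]
    if missing:
        raise KeyError(f"positions missing from profile: {sorted(missing)}")
    n = 0
    for p in residues:
        i = profile.index_of(p)
        if profile.falloff[i]:
            continue
        if profile.classes[i] is ReactivityClass.LOW:
            n += 1
    return n


def detect_falloff(lane: LaneProfile, threshold: float = DEFAULT_FALLOFF_FACTOR) -> set[int]:
    """Flag positions where the control lane carries a premature-stop signal.

    A reverse-transcriptase falloff produces a strong band in the DMSO
    (no-reagent) lane; positions whose DMSO intensity exceeds ``threshold``
    times the primer-window median DMSO intensity are flagged.
    """
    dmso = np.asarray(lane.intensity_dmso, dtype=float)
    if dmso.size == 0 or not math.isfinite(threshold):
        return set()
    med = float(np.median(dmso))
    if med <= 0:
        return {p for p, x in zip(lane.positions, dmso) if x > 0 and threshold < math.inf}
    return {p for p, x in zip(lane.positions, dmso) if x > threshold * med}


def apply_falloff(profile: ReactivityProfile, flagged: Iterable[int]) -> ReactivityProfile:
    """Mark the given positions as falloff-confounded (class unreliable)."""
    flagged = set(flagged)
    return replace(profile, falloff=tuple(p in flagged for p in profile.positions))


def merge_primers(profiles: Sequence[ReactivityProfile]) -> ReactivityProfile:
    """Combine per-primer profiles into one; nearest window-center wins overlaps.

    Because normalization is per primer, merged values carry per-primer
    scale and should be compared class-wise across primer windows; the
    contributing primer is recorded per position.
    """
    if not profiles:
        raise ValueError("merge_primers needs at least one profile")
    best: dict[int, tuple[float, ReactivityProfile, int]] = {}
    conflicts: list[int] = []
    for prof in profiles:
        for i, p in enumerate(prof.positions):
            d = abs(p - prof.window_center)
            if p in best:
                prev_d, prev_prof, prev_i = best[p]
                if prof.classes[i] is not prev_prof.classes[prev_i]:
                    conflicts.append(p)
                if d < prev_d:
                    best[p] = (d, prof, i)
            else:
                best[p] = (d, prof, i)
    if conflicts:
        warnings.warn(
            f"class conflicts at overlapping positions {sorted(set(conflicts))}; "
            "nearest-window-center value kept"
        )
    order = sorted(best)
    picks = [best[p] for p in order]
    return ReactivityProfile(
        primer_id="merged",
        positions=tuple(order),
        raw=tuple(prof.raw[i] for _, prof, i in picks),
        normalized=tuple(prof.normalized[i] for _, prof, i in picks),
        classes=tuple(prof.classes[i] for _, prof, i in picks),
        falloff=tuple(prof.falloff[i] for _, prof, i in picks),
        provenance=tuple(prof.provenance[i] for _, prof, i in picks),
    )


def differential_profile(
    ref_profile: ReactivityProfile,
    alt_profile: ReactivityProfile,
    margin: float = DEFAULT_DELTA,
) -> DifferentialProfile:
    """Three-way protected/unchanged/exposed calls from two aligned profiles.

    delta = alt normalized minus ref normalized; a position is *protected*
    when delta <= -margin and *exposed* when delta >= +margin.
    """
    if ref_profile.positions != alt_profile.positions:
        raise AlignmentError("profiles cover different positions")
    delta = tuple(
        a - r for r, a in zip(ref_profile.normalized, alt_profile.normalized)
    )
    calls = tuple(
        DiffCall.PROTECTED if d <= -margin else DiffCall.EXPOSED if d >= margin
        else DiffCall.UNCHANGED
        for d in delta
    )
    return DifferentialProfile(ref_profile.positions, delta, calls, margin)


def structure_concordance(profile: ReactivityProfile, model: StructureModel) -> float:
    """Fraction of evaluable positions whose reactivity class fits the model.

    Interior stem positions should be low; helix-terminal (outermost-pair)
    residues fray and are expected moderate or high, as are explicitly
    unpaired positions. Falloff-flagged positions and positions absent
    from the model are not evaluable. Returns NaN if nothing is evaluable.
    """
    paired = model.paired_positions()
    terminal = model.terminal_positions()
    unpaired = model.unpaired
    ok = total = 0
    for i, p in enumerate(profile.positions):
        if profile.falloff[i]:
            continue
        if p in paired:
            total += 1
            if p in terminal:
                ok += profile.classes[i] is not ReactivityClass.LOW
            else:
                ok += profile.classes[i] is ReactivityClass.LOW
        elif p in unpaired:
            total += 1
            ok += profile.classes[i] is not ReactivityClass.LOW
    return ok / total if total else float("nan")
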