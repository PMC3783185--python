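"""Antisense-oligonucleotide mapping and splicing-effect rules.

An ASO is defined by its annealing interval on the pre-mRNA (intron
coordinates). The effect-direction rules encode the mechanistic model the
deletion/mutation/probing work supports: the inhibitory effect of a
free intron position 10 ("10C") requires an intact long-distance stem
(ISTL1) pairing it with LS-1; sequestering the 3' strands of the internal
stems releases the 5' splice site region and stimulates exon inclusion.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .coords import BoundsError, Interval, Reference, Variant, pos_count
from .structure import (
    BasePairRule,
    Helix,
    StructureModel,
    WATSON_CRICK,
    find_ldi_duplexes,
)

__all__ = [
    "ISS_N1",
    "ISS_N2",
    "TEN_C",
    "ASORecord",
    "StrandCoverage",
    "SequestrationReport",
    "Effect",
    "EffectCall",
    "sequestration",
    "istl1_forms",
    "predict_effect",
    "aso_walk",
]

ISS_N1 = Interval(10, 24)   # intronic silencer just downstream of the 5' ss
ISS_N2 = Interval(275, 297)  # 3' strands of ISTL1/2/3 (this work's silencer)
TEN_C = 10                   # the intron position whose pairing drives the LDI

DEFAULT_MIN_LDI_BP = 6       # smallest duplex pairing 10C that counts as "formed"
DEFAULT_MIN_COVERAGE = 0.8   # 3'-strand coverage fraction that counts as sequestered


class Effect(str, enum.Enum):
    STIMULATORY = "stimulatory"
    INHIBITORY = "inhibitory"
    NEUTRAL = "neutral"


@dataclass(frozen=True)
class ASORecord:
    """An antisense oligonucleotide named by its target interval."""

    name: str
    target: Interval

    @property
    def length_nt(self) -> int:
        return len(self.target)

    @classmethod
    def from_name(cls, name: str) -> "ASORecord":
        """Parse names of the form ``ASO <start>-<end>`` into their interval."""
        token = name.strip()
        body = token[3:].strip() if token.upper().startswith("ASO") else token
        for sep in ("–", "—", "-"):
            if sep in body:
                a, _, b = body.partition(sep)
                try:
                    return cls(token, Interval(int(a), int(b)))
                except ValueError:
                    break
        raise ValueError(f"cannot parse ASO target interval from name {name!r}")

    def covers(self, p: int) -> bool:
        return p in self.target

    def coverage_fraction(self, iv: Interval) -> float:
        if not self.target.overlaps(iv):
            return 0.0
        lo = max(self.target.start, iv.start)
        hi = min(self.target.end, iv.end)
        return pos_count(lo, hi) / len(iv)


@dataclass(frozen=True)
class StrandCoverage:
    helix: str
    strand: str  # "5p" or "3p"
    interval: Interval
    fraction: float
    released: bool  # True when the partner strand is fully sequestered


@dataclass(frozen=True)
class SequestrationReport:
    aso: ASORecord
    coverage: tuple[StrandCoverage, ...]
    tenC_free: bool

    def fraction(self, helix: str, strand: str) -> float:
        for c in self.coverage:
            if c.helix == helix and c.strand == strand:
                return c.fraction
        raise KeyError(f"no strand {strand!r} of helix {helix!r} in report")

    def released(self, helix: str, strand: str) -> bool:
        for c in self.coverage:
            if c.helix == helix and c.strand == strand:
                return c.released
        raise KeyError(f"no strand {strand!r} of helix {helix!r} in report")


@dataclass(frozen=True)
class EffectCall:
    call: Effect
    fired_rules: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.fired_rules and self.call is not Effect.NEUTRAL:
            raise ValueError("non-neutral calls must name the fired rule")


def sequestration(
    aso: ASORecord,
    model: StructureModel,
    ref: Optional[Reference] = None,
    substrate: Interval = Interval(-23, 444),
) -> SequestrationReport:
    """Per-helix strand coverage of an ASO target, and what it releases.

    A strand counts as *released* when its pairing partner strand is fully
    covered by the ASO. ``substrate`` bounds the sensible target space
    (exon 3' end through the intron); a target outside it is an error.
    """
    if not (aso.target.start in substrate and aso.target.end in substrate):
        raise BoundsError(
            f"ASO {aso.name!r} target {aso.target} outside substrate {substrate}"
        )
    cov: list[StrandCoverage] = []
    for h in model.helices:
        f5 = aso.coverage_fraction(h.five_prime_strand)
        f3 = aso.coverage_fraction(h.three_prime_strand)
        cov.append(StrandCoverage(h.name, "5p", h.five_prime_strand, f5, released=f3 == 1.0))
        cov.append(StrandCoverage(h.name, "3p", h.three_prime_strand, f3, released=f5 == 1.0))
    return SequestrationReport(aso, tuple(cov), tenC_free=not aso.covers(TEN_C))


def istl1_forms(
    variant: Variant,
    ref: Reference,
    model: StructureModel,
    min_bp: int = DEFAULT_MIN_LDI_BP,
    rule: BasePairRule = WATSON_CRICK,
    query: Interval = Interval(1, 14),
    search: Interval = Interval(275, 300),
) -> bool:
    """Can the 10C-anchored long-distance stem form on the mutated sequence?

    Operationalized as: the complementarity scan between the intron 5' end
    and the LS-1 region, with positions locked in the *other* helices of
    the model unavailable, yields a contiguous duplex of >= ``min_bp``
    pairs that includes position 10. Watson-Crick pairing by default: the
    functional scans behave as strict-WC (e.g. a U·G wobble at 8:292 does
    not rescue the interaction).
    """
    mut = ref.apply(variant, strict=False)
    if not mut.covers(TEN_C):
        return False
    occupied = set()
    for h in model.helices:
        if h.name != "ISTL1":
            occupied.update(h.positions())
    occupied -= {TEN_C}
    for d in find_ldi_duplexes(mut, query, search, min_bp=min_bp, rule=rule,
                               occupied=occupied):
        if TEN_C in d.positions():
            return True
    return False


def predict_effect(
    variant: Variant,
    aso: ASORecord,
    ref: Reference,
    model: StructureModel,
    min_ldi_bp: int = DEFAULT_MIN_LDI_BP,
    min_3p_coverage: float = DEFAULT_MIN_COVERAGE,
    rule: BasePairRule = WATSON_CRICK,
) -> EffectCall:
    """Predicted direction of an ASO's effect on exon 7 splicing.

    Ordered rules; the first match fires:

    R1  ASO covers intron position 10 and overlaps ISS-N1 → stimulatory
        (the inhibitory 10C is sequestered along with the silencer).
    R2  ASO overlaps ISS-N1, leaves 10 free, and the 10C-anchored stem can
        form on the variant → inhibitory (the silencer duplex with the ASO
        plus the intact long-distance stem lock down the 5' ss).
    R3  ASO overlaps ISS-N1, leaves 10 free, and the stem cannot form →
        stimulatory (silencer sequestered, no 10C-mediated lockdown).
    R4  ASO covers >= ``min_3p_coverage`` of the 3' strand of one of the
        internal stems (the ISS-N2 constituents) → stimulatory (releases
        the 5' splice-site region / positive-factor sites).
    R5  otherwise → neutral.

    Only the ASO-response *direction* is predicted; baseline splicing
    levels of a variant are outside what the rules determine.
    """
    if aso.covers(TEN_C) and aso.target.overlaps(ISS_N1):
        return EffectCall(Effect.STIMULATORY, ("R1",))
    if aso.target.overlaps(ISS_N1):
        if istl1_forms(variant, ref, model, min_bp=min_ldi_bp, rule=rule):
            return EffectCall(Effect.INHIBITORY, ("R2",))
        return EffectCall(Effect.STIMULATORY, ("R3",))
    for h in model.helices:
        if h.name.startswith("ISTL"):
            if aso.coverage_fraction(h.three_prime_strand) >= min_3p_coverage:
                return EffectCall(Effect.STIMULATORY, ("R4",))
    return EffectCall(Effect.NEUTRAL, ())


def aso_walk(
    asos: Sequence[ASORecord],
    ref: Reference,
    model: StructureModel,
    variant: Variant = Variant("WT"),
    **kwargs,
) -> pd.DataFrame:
    """Effect calls and sequestration fractions for a set of ASOs.

    The returned table annotates each ASO with its coverage of ISS-N2 (the
    region spanned by the 3' strands of the internal stems) and of each
    stem's 3' strand, the freedom of position 10, the fired rule and the
    predicted call.
    """
    rows = []
    for aso in asos:
        seq = sequestration(aso, model, ref)
        call = predict_effect(variant, aso, ref, model, **kwargs)
        row: dict[str, object] = {
            "aso": aso.name,
            "target_start": aso.target.start,
            "target_end": aso.target.end,
            "length_nt": aso.length_nt,
            "tenC_free": seq.tenC_free,
            "iss_n2_coverage": aso.coverage_fraction(ISS_N2),
            "call": call.call.value,
            "fired_rules": "+".join(call.fired_rules),
        }
        for h in model.helices:
            if h.name.startswith("ISTL"):
                row[f"{h.name}_3p_coverage"] = seq.fraction(h.name, "3p")
                row[f"{h.name}_5p_released"] = seq.released(h.name, "5p")
        rows.append(row)
    return pd.DataFrame(rows)
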