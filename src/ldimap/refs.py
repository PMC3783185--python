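"""Built-in reference data: printed sequence segments, the probed structure
model, the perturbation-scan tables and the ASO catalog.

Only two sequence stretches of the *SMN2* exon 7 / intron 7 region are
needed by the analyses and are encoded here: the exon 7 3' end plus the
first 25 intronic nucleotides, and intron positions 282–300 (the
long-distance pairing region). Positions are intron coordinates; negative
values are exonic.

The internal stems ISTL2/ISTL3 and the local hairpin TSL3 are published
only as schematics; their pair tables below are *schematic* stand-ins
whose strand intervals match the described layout (the 3' strands of
ISTL1/2/3 tile ISS-N2, intron 275–297) and are never validated against
sequence. Replace them with user-supplied helices for other systems.
"""

from __future__ import annotations

from .aso import ASORecord
from .coords import Interval, Reference, ReferenceSequence, Variant
from .scan import Call, PerturbationRecord
from .structure import WOBBLE_OK, Helix, StructureModel, build_wt_istl1, extend_helix
from .coords import parse_variant_label

__all__ = [
    "EXON7_3P",
    "INTRON_5P",
    "LDI_REGION",
    "wt_reference",
    "wt_structure_model",
    "ISS_N1",
    "ISS_N2",
    "SUBSTRATE_SPAN",
    "ASO_CATALOG",
    "fig2_20nt_scan",
    "fig3_10nt_scan",
    "fig3_5nt_scan",
    "fig4_point_scan",
    "l14_response_table",
]

# Exon 7 3' end, positions -17..-1 (the last residue, -1, is an A).
EXON7_3P = "AUUCCUUAAAUUAAGGA"
# Intron 7 positions 1..25. ISS-N1 (CCAGCAUUAUGAAAG) occupies 10-24.
INTRON_5P = "GUAAGUCUGCCAGCAUUAUGAAAGU"
# Intron 7 positions 282..300: the GCAGAC motif at 282-287, LS-1 (GCAGAC)
# at 290-295, and the U-rich tract from 296.
LDI_REGION = "GCAGACAAGCAGACUUUUU"

ISS_N1 = Interval(10, 24)
ISS_N2 = Interval(275, 297)
INTRON_LENGTH = 444
# The probing substrate: 23 exonic + 444 intronic residues (467 nt).
SUBSTRATE_SPAN = Interval(-23, INTRON_LENGTH)


def wt_reference() -> Reference:
    """Wild-type reference over the two printed segments."""
    return Reference.from_segments(
        [
            ReferenceSequence(EXON7_3P + INTRON_5P, -17, name="exon7_3p+intron_5p"),
            ReferenceSequence(LDI_REGION, 282, name="ldi_region"),
        ],
        name="SMN2-ex7/in7",
    )


def _schematic(name: str, i5: Interval, i3: Interval) -> Helix:
    pairs = tuple(zip(i5.positions(), reversed(i3.positions())))
    return Helix(pairs, name=name, schematic=True)


def wt_structure_model(ref: Reference | None = None) -> StructureModel:
    """The probed wild-type model: ISTL1 (sequence-validated) + schematic stems.

    Unpaired positions are everything else on the 467-nt substrate; the
    independently folding internal modules are treated as unpaired here,
    which is adequate for the long-distance-interaction analyses (their
    internal structure never enters a computation).
    """
    ref = ref if ref is not None else wt_reference()
    istl1 = build_wt_istl1(ref)
    istl2 = _schematic("ISTL2", Interval(52, 58), Interval(283, 289))
    istl3 = _schematic("ISTL3", Interval(62, 69), Interval(275, 282))
    tsl3 = _schematic("TSL3", Interval(16, 25), Interval(38, 47))
    helices = (istl1, istl2, istl3, tsl3)
    paired = frozenset(p for h in helices for p in h.positions())
    unpaired = frozenset(SUBSTRATE_SPAN.positions()) - paired
    return StructureModel(helices, unpaired=unpaired, name="WT")


ISTL1_M4 = parse_variant_label("286G/288U/289G/298A")


def istl1_m4_structure_model(ref: Reference | None = None) -> tuple[StructureModel, Reference]:
    """Probed model of the stem-strengthened quadruple mutant.

    The internal stem is extended maximally on the mutated sequence
    (wobble allowed: the extension reaches the last exonic residue). The
    probing showed the strengthened stem destabilizes the neighboring
    local structures, so ISTL2 and TSL3 are released to unpaired here;
    ISTL3 is kept. Returns the model together with the mutated reference.
    """
    ref = ref if ref is not None else wt_reference()
    mut = ref.apply(ISTL1_M4)
    extended = extend_helix(ref, build_wt_istl1(ref), ISTL1_M4, rule=WOBBLE_OK)
    istl3 = _schematic("ISTL3", Interval(62, 69), Interval(275, 282))
    helices = (extended, istl3)
    paired = frozenset(p for h in helices for p in h.positions())
    unpaired = frozenset(SUBSTRATE_SPAN.positions()) - paired
    return StructureModel(helices, unpaired=unpaired, name="ISTL1-M4"), mut


# --------------------------------------------------------------------------
# Antisense oligonucleotides (target coordinates on intron 7; ASO-D reaches
# into exon 7). F14/L14 cover the first/last 14 residues of ISS-N1's span
# with/without position 10.
ASO_CATALOG: dict[str, ASORecord] = {
    a.name: a
    for a in (
        ASORecord("F14", Interval(1, 14)),
        ASORecord("L14", Interval(11, 24)),
        ASORecord("Anti-N1", Interval(10, 29)),
        ASORecord("ASO 276-290", Interval(276, 290)),
        ASORecord("ASO 283-297", Interval(283, 297)),
        ASORecord("ASO-M", Interval(275, 297)),   # mutant 3' strand, probing aid
        ASORecord("ASO-D", Interval(-6, 14)),     # 5' strand invader, schematic target
        ASORecord("ASO-ISS-N2", Interval(275, 297)),  # full ISS-N2 coverage, 23 nt
    )
}


# --------------------------------------------------------------------------
# Perturbation scans. Calls are the L14-response phenotype: "retained" =
# L14 still promotes exon 7 skipping in the mutant, "abrogated" = that
# inhibitory effect is lost, "partial" = lost to a lesser extent.

def _records(rows: list[tuple[str, Call]], figure: str) -> list[PerturbationRecord]:
    return [PerturbationRecord(parse_variant_label(lbl), c, figure) for lbl, c in rows]


def fig2_20nt_scan() -> list[PerturbationRecord]:
    """20-nt overlapping deletion scan of Areas 1 and 2 of intron 7.

    Windows named in the running text carry their reported calls
    (abrogated: Δ271–290, Δ281–300, Δ291–310; partial: Δ262–281); the
    flanking windows tile the two scanned areas and all retained the L14
    response.
    """
    area1_starts = [195, 205, 215, 225, 235, 245, 255]
    area2_starts = [325, 335, 345, 355, 365, 375, 385]
    rows: list[tuple[str, Call]] = []
    for s in area1_starts + area2_starts:
        rows.append((f"Δ{s}–{s + 19}", Call.RETAINED))
    rows += [
        ("Δ262–281", Call.PARTIAL),
        ("Δ271–290", Call.ABROGATED),
        ("Δ281–300", Call.ABROGATED),
        ("Δ291–310", Call.ABROGATED),
        ("Δ301–320", Call.RETAINED),
    ]
    return _records(rows, "Fig2A")


def fig3_10nt_scan() -> list[PerturbationRecord]:
    """11 ten-nt deletions at 5-nt offsets tiling intron positions 261–320."""
    abrogated = {281, 286, 291}
    partial = {296}
    rows = []
    for s in range(261, 312, 5):
        call = (
            Call.ABROGATED if s in abrogated
            else Call.PARTIAL if s in partial
            else Call.RETAINED
        )
        rows.append((f"Δ{s}–{s + 9}", call))
    return _records(rows, "Fig3A")


def fig3_5nt_scan() -> list[PerturbationRecord]:
    """Five 5-nt deletions over 284–300; Δ287–291/Δ290–294/Δ293–297 abrogate."""
    abrogated = {287, 290, 293}
    rows = [
        (f"Δ{s}–{s + 4}", Call.ABROGATED if s in abrogated else Call.RETAINED)
        for s in (284, 287, 290, 293, 296)
    ]
    return _records(rows, "Fig3B")


# One representative substitution per scanned position 288-297; every
# tested substitution within 290-295 abrogated the L14 response, the
# flanking ones did not.
_POINT_SCAN_ROWS: list[tuple[str, Call]] = [
    ("288U", Call.RETAINED),
    ("289G", Call.RETAINED),
    ("290C", Call.ABROGATED),
    ("291A", Call.ABROGATED),
    ("292G", Call.ABROGATED),
    ("293C", Call.ABROGATED),
    ("294C", Call.ABROGATED),
    ("295A", Call.ABROGATED),
    ("296A", Call.RETAINED),
    ("297A", Call.RETAINED),
]


def fig4_point_scan() -> list[PerturbationRecord]:
    """Single-nucleotide substitution scan over intron positions 288–297."""
    return _records(_POINT_SCAN_ROWS, "Fig4C")


def l14_response_table() -> list[PerturbationRecord]:
    """Every (minigene variant, L14-response) annotation with a clear call,
    across the deletion scans, the point scan and the helix-engineering
    mutants; partial ('to a lesser extent') rows keep their partial call so
    a consumer can exclude them explicitly."""
    rows: list[PerturbationRecord] = []
    rows += fig2_20nt_scan()
    rows += fig3_10nt_scan()
    rows += fig3_5nt_scan()
    rows += fig4_point_scan()
    helix_rows: list[tuple[str, Call]] = [
        ("286G", Call.RETAINED),
        ("298A", Call.RETAINED),
        ("288U/289G", Call.RETAINED),
        ("286G/288U/289G/298A", Call.RETAINED),  # ISTL1-M4
        ("8C", Call.ABROGATED),
        ("10G", Call.ABROGATED),
        ("8C/292G", Call.RETAINED),     # compensatory: stem restored
        ("10G/290C", Call.RETAINED),    # compensatory: stem restored
        ("Δ290–295", Call.ABROGATED),   # LS-1 deleted
        ("Δ282–287", Call.RETAINED),    # identical upstream motif deleted
    ]
    rows += _records(helix_rows, "Fig4-5/S1")
    return rows
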