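"""File-format glue: FASTA references, TSV tables, CT / multi-bracket
dot-bracket structure files, JSON reports.

FASTA headers carry the coordinate anchor as ``>name offset=<origin>``,
where the origin is the intron coordinate of the first residue. Structure
files index residues 1..N along the supplied reference and keep the intron
coordinate in the CT "original numbering" column.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .aso import ASORecord
from .coords import Interval, Reference, ReferenceSequence, parse_variant_label
from .reactivity import LaneProfile, ReactivityProfile
from .scan import Call, PerturbationRecord
from .structure import Helix, StructureModel, loop_length

PathLike = Union[str, Path]

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_scan_tsv",
    "write_scan_tsv",
    "read_lanes_tsv",
    "write_lanes_tsv",
    "write_profile_tsv",
    "write_shape_column",
    "read_asos_tsv",
    "write_ct",
    "write_dot_bracket",
    "read_dot_bracket",
    "helix_report",
    "write_json_report",
]


# -- FASTA -----------------------------------------------------------------

def _parse_offset(description: str) -> int:
    for field in description.split():
        if field.startswith("offset="):
            return int(field.split("=", 1)[1])
    return 1


def read_fasta(path: PathLike) -> Reference:
    """Read reference segments; each record's ``offset=`` anchors residue 1."""
    segments = []
    for rec in SeqIO.parse(str(path), "fasta"):
        segments.append(
            ReferenceSequence(str(rec.seq), _parse_offset(rec.description), name=rec.id)
        )
    if not segments:
        raise ValueError(f"no FASTA records in {path}")
    return Reference.from_segments(segments, name=Path(path).stem)


def write_fasta(ref: Reference, path: PathLike) -> None:
    records = []
    for k, (labels, bases) in enumerate(ref.segments):
        records.append(
            SeqRecord(
                Seq(bases),
                id=f"{ref.name}.{k}",
                description=f"offset={labels[0]}",
            )
        )
    SeqIO.write(records, str(path), "fasta")


# -- scan tables -----------------------------------------------------------

def read_scan_tsv(path: PathLike) -> list[PerturbationRecord]:
    """Columns: variant_label, call (retained|partial|abrogated)[, figure]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"variant_label", "call"}
    if not required <= set(df.columns):
        raise ValueError(f"scan table needs columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            PerturbationRecord(
                parse_variant_label(row["variant_label"]),
                Call(row["call"]),
                figure=str(row.get("figure", "") or ""),
            )
        )
    return out


def write_scan_tsv(records: Sequence[PerturbationRecord], path: PathLike) -> None:
    pd.DataFrame(
        {
            "variant_label": [r.variant.label for r in records],
            "call": [r.call.value for r in records],
            "figure": [r.figure for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


# -- probing lanes and profiles -------------------------------------------

def read_lanes_tsv(path: PathLike) -> list[LaneProfile]:
    """Columns: position, primer_id, intensity_1m7, intensity_dmso."""
    df = pd.read_csv(path, sep="\t")
    lanes = []
    for primer_id, grp in df.groupby("primer_id", sort=False):
        grp = grp.sort_values("position")
        lanes.append(
            LaneProfile(
                str(primer_id),
                tuple(int(p) for p in grp["position"]),
                tuple(float(x) for x in grp["intensity_1m7"]),
                tuple(float(x) for x in grp["intensity_dmso"]),
            )
        )
    return lanes


def write_lanes_tsv(lanes: Sequence[LaneProfile], path: PathLike) -> None:
    pd.concat([lane.to_frame() for lane in lanes]).to_csv(path, sep="\t", index=False)


def write_profile_tsv(profile: ReactivityProfile, path: PathLike) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False)


def write_shape_column(profile: ReactivityProfile, path: PathLike) -> None:
    """Two-column (position, reactivity) export for structure-drawing tools;
    falloff-confounded positions carry the no-data sentinel -999."""
    with open(path, "w") as fh:
        for p, x, bad in zip(profile.positions, profile.normalized, profile.falloff):
            fh.write(f"{p}\t{-999 if bad else round(x, 4)}\n")


# -- ASOs ------------------------------------------------------------------

def read_asos_tsv(path: PathLike) -> list[ASORecord]:
    """Columns: name[, start, end]; interval parsed from the name if absent."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        if "start" in df.columns and not pd.isna(row.get("start")):
            out.append(ASORecord(str(row["name"]), Interval(int(row["start"]), int(row["end"]))))
        else:
            out.append(ASORecord.from_name(str(row["name"])))
    return out


# -- structure files -------------------------------------------------------

def _pair_map(model: StructureModel) -> dict[int, int]:
    pm: dict[int, int] = {}
    for h in model.helices:
        for i, j in h.pairs:
            pm[i] = j
            pm[j] = i
    return pm


def write_ct(model: StructureModel, ref: Reference, path: PathLike, title: str = "") -> None:
    """Classic 6-column CT; column 6 keeps the intron coordinate."""
    order = [p for p in ref.positions()]
    index = {p: k + 1 for k, p in enumerate(order)}
    pm = _pair_map(model)
    with open(path, "w") as fh:
        fh.write(f"{len(order)}\t{title or model.name}\n")
        for k, p in enumerate(order, start=1):
            partner = index.get(pm.get(p, 0), 0)
            fh.write(
                f"{k}\t{ref.base_at(p)}\t{k - 1}\t{k + 1 if k < len(order) else 0}"
                f"\t{partner}\t{p}\n"
            )


_BRACKETS = ["()", "[]", "{}", "<>", "Aa", "Bb", "Cc"]


def _assign_layers(helices: Sequence[Helix]) -> list[int]:
    """Greedy layer assignment so crossing helices use different brackets."""

    def crosses(a: Helix, b: Helix) -> bool:
        (ai, aj) = a.outermost
        (bi, bj) = b.outermost
        return ai < bi < aj < bj or bi < ai < bj < aj

    layers: list[list[Helix]] = []
    out = []
    for h in helices:
        for li, members in enumerate(layers):
            if not any(crosses(h, m) for m in members):
                members.append(h)
                out.append(li)
                break
        else:
            layers.append([h])
            out.append(len(layers) - 1)
    if len(layers) > len(_BRACKETS):
        raise ValueError("too many crossing helix layers for the bracket alphabets")
    return out


def write_dot_bracket(model: StructureModel, ref: Reference, path: PathLike) -> None:
    """Multi-bracket dot-bracket: crossing stems get successive alphabets."""
    order = ref.positions()
    index = {p: k for k, p in enumerate(order)}
    chars = ["."] * len(order)
    for h, layer in zip(model.helices, _assign_layers(model.helices)):
        op, cl = _BRACKETS[layer]
        for i, j in h.pairs:
            if i in index and j in index:
                chars[index[i]] = op
                chars[index[j]] = cl
    with open(path, "w") as fh:
        fh.write(f">{model.name or 'structure'} origin={order[0]}\n")
        fh.write("".join(ref.base_at(p) for p in order) + "\n")
        fh.write("".join(chars) + "\n")


def read_dot_bracket(path: PathLike) -> list[tuple[int, int]]:
    """Pairs (as 0-based string indices) from a multi-bracket dot-bracket file."""
    lines = [ln.rstrip("\n") for ln in open(path) if ln.strip()]
    struct = lines[-1]
    opens = {b[0]: b for b in _BRACKETS}
    closes = {b[1]: b for b in _BRACKETS}
    stacks: dict[str, list[int]] = {b: [] for b in _BRACKETS}
    pairs = []
    for k, c in enumerate(struct):
        if c in opens:
            stacks[opens[c]].append(k)
        elif c in closes:
            if not stacks[closes[c]]:
                raise ValueError(f"unbalanced bracket {c!r} at column {k}")
            pairs.append((stacks[closes[c]].pop(), k))
    for b, st in stacks.items():
        if st:
            raise ValueError(f"unclosed bracket {b[0]!r}")
    return sorted(pairs)


# -- JSON reports ----------------------------------------------------------

def helix_report(h: Helix) -> dict:
    return {
        "name": h.name,
        "pairs": [list(p) for p in h.pairs],
        "length_bp": len(h.pairs),
        "loop_length_nt": loop_length(h) if h.pairs else None,
        "five_prime_strand": [h.five_prime_strand.start, h.five_prime_strand.end],
        "three_prime_strand": [h.three_prime_strand.start, h.three_prime_strand.end],
    }


def write_json_report(payload: dict, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
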