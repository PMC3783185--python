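# Methods

## Coordinate system and sequences

Intron coordinates are signed integers with no position 0: +1 is the first
intronic nucleotide, −1 the last exonic one. Intervals are closed at both
ends, so the deletion name Δ281–300 removes exactly 20 nt; any half-open
convention would make the published mutant names ambiguous. DNA input is
transcribed to the RNA alphabet on ingest.

Only two sequence stretches enter any computation and both ship with the
package: the exon 7 3′ end plus intron positions 1–25
(`AUUCCUUAAAUUAAGGA` + `GUAAGUCUGCCAGCAUUAUGAAAGU`), and intron positions
282–300 (`GCAGACAAGCAGACUUUUU`). The full 444-nt intron is not required;
a `Reference` holds multiple non-adjacent segments, and positions in the
coverage gap are simply unavailable rather than guessed. After a deletion
the flanking residues become adjacent (they are joined on the molecule);
two distinct segments never do (the gap is missing data, not a junction).

Variants follow the field's mutant-name grammar: `Δ<start>–<end>` for
deletions, slash-separated `<pos><base>` tokens for substitutions
(`289G` = replace the residue at intron 289 with G). Applying a variant
yields a mutated reference that keeps wild-type position labels, plus a
lift table mapping each wild-type position to its index on the mutant
molecule (or "deleted").

## Core mapping from perturbation scans

Each scanned minigene carries one deletion (or one substitution) and a
three-valued response call: the reference ASO's inhibitory effect
*retained*, *partial* ("to a lesser extent") or *abrogated*. The membership
rule is conservative: a position is in the core iff it was covered by at
least one tested deletion **and** every tested deletion covering it is
abrogated. Positions never covered cannot be claimed required and are
excluded; disjoint runs are reported as separate cores.

Partial calls are resolved through an explicit `ScanPolicy` because the
source scans resolve them differently: in the 20-nt scan the partial
Δ262–281 is treated as non-abrogating (core 282–300, 19 nt) while in the
10-nt scan the partial Δ296–305 is treated as abrogating (core 286–300,
15 nt). The default is `partial_as=retained` (the conservative choice);
every reported result states the policy used.

The point-substitution scan uses the analogous per-position rule (every
tested substitution at the position abrogates) and returns the longest
maximal run, which for the 288–297 scan is the 6-nt LS-1 (290–295,
`GCAGAC`).

Of the published scan tables, only the informative windows are named in
the running text; the flanking windows are transcribed here as uniform
tilings of the scanned areas with retained calls. The inferred cores are
insensitive to that layout because the boundary-setting windows (Δ262–281,
Δ301–320, and the named abrogating windows) are all explicit.

## Helix model

A `Helix` is a contiguous antiparallel stack of canonical pairs; bulged or
interrupted stems are separate helices. This matches the combinatorial
reasoning being modeled, where a single mismatch (11:289 in the wild type)
blocks growth until a mutation repairs it. `BasePairRule` controls wobble
admission (default: G·U allowed) and ranks pair strength G:C > A:U > G:U.

The wild-type internal stem is built from its anchor: intron 3–10 paired
with 297–290, innermost pair 10:290, eight Watson–Crick pairs, 16 residues,
enclosing a 279-nt loop (`j* − i* − 1` across valid coordinates).
`extend_helix` applies a variant, revalidates the anchor pairs (a mutation
that breaks one is a model error; a deletion of an anchored residue is a
structural error) and then grows the stem greedily one pair at a time at
the loop-proximal and distal ends. The published extension arithmetic is
reproduced exactly: +1 bp for 289G, 0 for 288U or 286G alone, +3 for
288U/289G, and ≥13 bp total for the quadruple mutant. The quadruple-mutant
figure is reported Watson–Crick-only (13 bp); with wobble admitted the
same stem reaches 15 bp through a G·U at 1:299 and an A:U at −1:300,
consistent with the published "at least 13 bp" phrasing and with the
observed protection of the last exonic residue in that mutant.

`find_ldi_duplexes` is a bounded complementarity scanner, not a folding
engine: it enumerates every maximal contiguous duplex between two disjoint
regions, with deterministic ranking (pair count, then summed strength,
then outermost-pair coordinates) and strand-swap symmetry. Full
minimum-free-energy folding is deliberately out of scope. An `occupied`
position set makes residues locked in other helices unpairable; this is
how the scanner captures why the upstream `GCAGAC` twin at 282–287 —
sequence-identical and complementary to intron 5–10 — cannot substitute
for LS-1: it is held inside the neighboring internal stem (ISTL2).

ISTL2, ISTL3 and the local hairpin TSL3 are published only schematically;
they are encoded as schematic, user-replaceable pair tables whose strand
intervals tile the described layout (the 3′ strands of the three internal
stems compose ISS-N2, intron 275–297) and are never validated against
sequence. The independently folding internal modules of the intron are
treated as unpaired in the default model; their internal structure never
enters a computation here.

## Reactivity analysis

Raw reactivity is `max(0, 1M7 − DMSO)` per position — negative differences
are clamped because a negative modification signal is physically
meaningless. Normalization is per extension primer (most reactive position
= 1), so merged profiles carry per-primer scale and are compared
class-wise across primers. Classes: low < 0.3 ≤ moderate ≤ 0.5 < high;
ties at both thresholds fall to moderate.

Falloff detection flags positions whose control-lane (DMSO) intensity
exceeds a configurable multiple (default 3×) of the primer-window median —
the signature of a reverse-transcriptase stop present with and without
reagent. Flagged positions are excluded from protected counts and
concordance. Overlapping primer windows are reconciled by
nearest-window-center; this is a declared convention of this package, with
the contributing primer recorded per position and class conflicts logged.

Differential profiles call a position protected/exposed when the
normalized difference crosses ±δ; δ defaults to 0.15 normalized units,
calibrated so the noise-free wild-type vs strengthened-stem comparison
calls exactly the newly paired 5′-strand residues
(−1, 1, 2, 3, 11, 12, 13, 14) protected.

Structure concordance scores each evaluable position against the model:
interior stem residues are expected low; helix-terminal (outermost-pair)
residues fray and are expected moderate/high, like unpaired residues.
Under this convention a noise-free simulated profile scores 1.0 against
its generating model, and the probed stem annotation (moderate circles at
3A and 293G only) scores 14/16 against the stem — the two mismatches being
the interior 293G that reacts and the terminal 297U that does not.

## ASO effect rules

Effect direction (never magnitude, and never a variant's baseline splicing
level) is predicted by ordered rules. ISS-N1 is modeled as intron 10–24,
consistent with the F14/L14 14-mers covering 1–14 (including ¹⁰C) and
11–24 (excluding it). "The stem can form" is operationalized as: the
duplex scan on the mutated sequence, with other-helix positions occupied,
returns ≥ 6 contiguous pairs involving position 10. Formation checks use
Watson–Crick pairing only: the functional data behave strictly (a G·U
wobble at 8:292 in the 292G mutant does not preserve the interaction).

- R1: ASO covers position 10 and overlaps ISS-N1 → stimulatory.
- R2: ASO overlaps ISS-N1, leaves 10 free, stem forms → inhibitory.
- R3: ASO overlaps ISS-N1, leaves 10 free, stem cannot form → stimulatory.
- R4: ASO covers ≥ 80% of the 3′ strand of any internal stem (the ISS-N2
  constituents) → stimulatory. Covering any one of the three strands
  releases silencing structure; the weaker response of an ASO that misses
  the ISTL1 strand (e.g. ASO 276–290) is annotation, not a fourth class.
- R5: otherwise neutral.

The fired rule is always reported. Across every transcribed
(variant, L14-response) annotation with a clear call — 53 rows spanning
the three deletion scans, the point scan, the stem-strengthening and
compensatory mutants — the predicted directions match with zero
mismatches; the two "to a lesser extent" rows are excluded and listed.
Protein-factor interactions (the silencing is protein-independent in the
source data) carry no weight in the rules.

## Synthetic data

The lane simulator draws per-position stop intensities
`scale·p + background` (reagent lane) and `background` (control lane),
with multiplicative lognormal noise of a given CV and optional falloff
stops added to both lanes. Modification probabilities come from a
structure model: 0.6 unpaired, 0.35 at helix-terminal and wobble
positions, 0.05 inside stems — defaults chosen so the default simulation
reproduces the qualitative probing pattern (exactly 14 of the 16 stem
residues at the protected level). Stops are independent per position, not
a sequential drop-off cascade: the analysis consumes relative band
intensities only, so read-through attrition would cancel in the
normalization. The probing substrate is modeled as positions −23…444
(467 residues).

The scan simulator plants a core interval and calls a window abrogated iff
it overlaps the core, with optional independent call-flips. All simulators
are bit-reproducible under a seed.

What the simulators do *not* emulate: gel densitometry artifacts,
sequencing-ladder registration, nucleotide-specific reactivity biases
(e.g. weakly reactive C residues in flexible regions), replicate
variability structure, or read-through attrition along a lane. Passing
round-trip tests therefore demonstrates the correctness of the analysis
arithmetic and inference rules, not robustness to every artifact of real
gels.

## Numerical and degenerate-input conventions

All-zero reactivity profiles normalize to zero with a warning rather than
dividing by zero. A scan with no abrogated window returns an empty core
with a warning, not an exception. Duplex ranking ties break
deterministically by outermost-pair coordinates. Problem sizes throughout
are those of the source experiments (≤ 23 windows per scan, ≤ 467-residue
substrate, ≤ 25-nt regions per duplex scan side), so every analysis runs
in well under a second; property tests against brute-force oracles use
comparable sizes.

## Known limitations

- No thermodynamics: duplex ranking by pair count and class is a
  qualitative proxy; competing structures are not scored.
- The schematic stems (ISTL2/ISTL3/TSL3) fix strand intervals, not true
  pair composition; conclusions that depend on their exact geometry should
  re-derive them from user-supplied models.
- Sequence outside the two printed segments is unavailable by design;
  analyses requiring it must supply their own reference.
- Effect rules predict direction only and inherit the scope of the
  perturbation set they were validated on (intron 7 of *SMN2*).
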