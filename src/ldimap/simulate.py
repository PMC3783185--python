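"""Synthetic inputs: probing lanes from a ground-truth structure, and
perturbation-scan phenotype tables from a planted core.

The lane simulator emulates a primer-extension readout of a chemical
probing experiment: each position's stop intensity in the reagent lane is
proportional to its modification probability (high for unpaired residues,
low inside stems, intermediate at helix ends and wobble pairs) on top of a
no-reagent background; reverse-transcriptase falloff sites add a strong
stop to both lanes; multiplicative lognormal noise models band-by-band
quantification error. Stops are modeled per position independently rather
than as a sequential drop-off cascade — the downstream analysis consumes
relative band intensities only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .coords import Interval, Reference, Variant
from .scan import Call, PerturbationRecord
from .structure import BasePairRule, StructureModel, WOBBLE_OK
from .reactivity import LaneProfile

__all__ = [
    "ProbeSimParams",
    "ScanSimParams",
    "simulate_truth_reactivity",
    "simulate_lanes",
    "simulate_scan",
]

SIGNAL_SCALE = 1000.0  # arbitrary band-intensity units for a certain modification


@dataclass(frozen=True)
class ProbeSimParams:
    """Ground-truth modification and readout-noise parameters."""

    p_mod_unpaired: float = 0.6
    p_mod_terminal: float = 0.35  # helix-end and wobble positions
    p_mod_paired: float = 0.05
    dmso_background: float = 50.0
    noise_cv: float = 0.2
    falloff_sites: tuple[tuple[int, float], ...] = ()  # (position, stop_fraction)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_mod_paired < self.p_mod_terminal < self.p_mod_unpaired <= 1:
            raise ValueError("need 0 <= p_paired < p_terminal < p_unpaired <= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


@dataclass(frozen=True)
class ScanSimParams:
    """Planted-core deletion scan parameters."""

    true_core: Interval
    windows: tuple[Interval, ...]
    flip_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.flip_prob < 0.5:
            raise ValueError("flip_prob must be in [0, 0.5)")
        if not self.windows:
            raise ValueError("at least one scan window required")


def simulate_truth_reactivity(
    model: StructureModel,
    params: ProbeSimParams,
    ref: Optional[Reference] = None,
    rule: BasePairRule = WOBBLE_OK,
) -> dict[int, float]:
    """Per-position true modification probability implied by a structure model.

    Interior stem positions get ``p_mod_paired``; helix-terminal positions
    — and wobble-paired positions, when a reference is supplied to
    identify them — get ``p_mod_terminal``; unpaired positions get
    ``p_mod_unpaired``. Deterministic given model and params.
    """
    paired = model.paired_positions()
    terminal = set(model.terminal_positions())
    if ref is not None:
        for h in model.helices:
            if h.schematic:
                continue
            for i, j in h.pairs:
                if ref.covers(i) and ref.covers(j):
                    if (ref.base_at(i), ref.base_at(j)) in (("G", "U"), ("U", "G")):
                        terminal.update((i, j))
    truth: dict[int, float] = {}
    for p in sorted(model.positions()):
        if p in paired:
            truth[p] = params.p_mod_terminal if p in terminal else params.p_mod_paired
        else:
            truth[p] = params.p_mod_unpaired
    return truth


def _lognormal_noise(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    if cv <= 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)


def simulate_lanes(
    truth: dict[int, float],
    params: ProbeSimParams,
    primer_id: str = "sim",
    window: Optional[Interval] = None,
) -> LaneProfile:
    """Simulate paired (1M7, DMSO) lane intensities for one primer window.

    Reagent-lane stops are ``SIGNAL_SCALE * p + background``; the control
    lane is background only. Falloff sites add ``stop_fraction`` of the
    full scale to *both* lanes. Bit-reproducible under ``params.seed``.
    """
    positions = sorted(truth)
    if window is not None:
        positions = [p for p in positions if p in window]
    if not positions:
        raise ValueError("no positions to simulate")
    rng = np.random.default_rng(params.seed)
    p = np.array([truth[q] for q in positions])
    falloff = dict(params.falloff_sites)
    stop = np.array([falloff.get(q, 0.0) * SIGNAL_SCALE for q in positions])

    n = len(positions)
    mod = (SIGNAL_SCALE * p + params.dmso_background + stop) * _lognormal_noise(
        rng, params.noise_cv, n
    )
    ctrl = (params.dmso_background + stop) * _lognormal_noise(rng, params.noise_cv, n)
    return LaneProfile(
        primer_id,
        tuple(positions),
        tuple(float(x) for x in mod),
        tuple(float(x) for x in ctrl),
    )


def simulate_scan(params: ScanSimParams) -> list[PerturbationRecord]:
    """Phenotype table for a deletion scan with a planted functional core.

    A window's true call is *abrogated* iff it removes at least one core
    position (window ∩ core ≠ ∅); calls are then flipped independently
    with ``flip_prob``. Seeded and reproducible.
    """
    from .coords import Edit, Variant as V

    rng = np.random.default_rng(params.seed)
    records = []
    for w in params.windows:
        truth = Call.ABROGATED if w.overlaps(params.true_core) else Call.RETAINED
        call = truth
        if params.flip_prob > 0 and rng.random() < params.flip_prob:
            call = Call.RETAINED if truth is Call.ABROGATED else Call.ABROGATED
        variant = V(f"Δ{w.start}–{w.end}", (Edit("deletion", w),))
        records.append(PerturbationRecord(variant, call, figure="sim"))
    return records
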