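"""Reactivity arithmetic, classification, merging, differentials, concordance."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ldimap import refs
from ldimap.coords import Interval
from ldimap.reactivity import (
    AlignmentError,
    DiffCall,
    LaneProfile,
    ReactivityClass,
    ReactivityProfile,
    apply_falloff,
    classify,
    classify_value,
    compute_reactivity,
    count_protected,
    detect_falloff,
    differential_profile,
    merge_primers,
    structure_concordance,
)
from ldimap.simulate import ProbeSimParams, simulate_lanes, simulate_truth_reactivity


def lane(positions, mod, dmso, primer="p1"):
    return LaneProfile(primer, tuple(positions), tuple(mod), tuple(dmso))


def profile_from_classes(positions, classes, primer="fig"):
    """Profile with normalized values representative of the given classes."""
    value = {"low": 0.1, "moderate": 0.4, "high": 0.9}
    norm = tuple(value[c] for c in classes)
    return classify(
        ReactivityProfile(primer, tuple(positions), raw=norm, normalized=norm)
    )


class TestComputeReactivity:
    def test_null_signal_is_degenerate_with_warning(self):
        with pytest.warns(UserWarning):
            prof = compute_reactivity(lane([1, 2, 3], [5, 5, 5], [5, 5, 5]))
        assert set(prof.normalized) == {0.0}
        assert prof.degenerate

    def test_single_reactive_position_normalizes_to_one(self):
        prof = compute_reactivity(lane([1, 2, 3], [10, 0, 0], [2, 0, 0]))
        assert prof.normalized[0] == 1.0
        assert prof.raw[0] == 8.0

    def test_subtraction_clamped_at_zero(self):
        prof = compute_reactivity(lane([1, 2], [3, 10], [8, 2]))
        assert prof.raw[0] == 0.0

    def test_negative_intensities_rejected(self):
        with pytest.raises(ValueError):
            lane([1], [-1.0], [0.0])

    def test_rank_agreement_with_simulated_truth(self, ref, wt_model):
        from scipy.stats import spearmanr

        params = ProbeSimParams(seed=5)
        truth = simulate_truth_reactivity(wt_model, params, ref=ref)
        prof = compute_reactivity(simulate_lanes(truth, params))
        t = [truth[p] for p in prof.positions]
        rho, _ = spearmanr(t, prof.normalized)
        assert rho > 0

    @given(
        mod=st.lists(st.floats(min_value=0, max_value=1e4), min_size=2, max_size=20),
        dmso=st.floats(min_value=0, max_value=100),
        scale=st.floats(min_value=0.01, max_value=100),
    )
    def test_normalization_is_scale_invariant(self, mod, dmso, scale):
        positions = list(range(1, len(mod) + 1))
        base = [m + dmso for m in mod]
        if max(mod) <= 0:
            return
        a = compute_reactivity(lane(positions, base, [dmso] * len(mod)))
        b = compute_reactivity(
            lane(positions, [scale * x for x in base], [scale * dmso] * len(mod))
        )
        assert np.allclose(a.normalized, b.normalized, atol=1e-9)


class TestClassification:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.51, ReactivityClass.HIGH),
            (0.5, ReactivityClass.MODERATE),
            (0.3, ReactivityClass.MODERATE),
            (0.2999, ReactivityClass.LOW),
            (0.0, ReactivityClass.LOW),
        ],
    )
    def test_threshold_boundaries(self, value, expected):
        assert classify_value(value) is expected

    def test_classify_is_idempotent(self):
        prof = profile_from_classes([1, 2, 3], ["low", "moderate", "high"])
        assert classify(prof) == prof


class TestProtectedCounts:
    def istl1_profile(self, wt_model):
        """Profile over the 16 stem residues with the probed annotation:
        some modification only at positions 3 and 293."""
        residues = sorted(wt_model.helix("ISTL1").positions())
        classes = ["moderate" if p in (3, 293) else "low" for p in residues]
        return profile_from_classes(residues, classes), residues

    def test_14_of_16_stem_residues_protected(self, wt_model):
        prof, residues = self.istl1_profile(wt_model)
        assert count_protected(prof, residues) == 14

    def test_all_low_and_all_high_extremes(self):
        prof = profile_from_classes([1, 2, 3], ["low"] * 3)
        assert count_protected(prof, [1, 2, 3]) == 3
        prof = profile_from_classes([1, 2, 3], ["high"] * 3)
        assert count_protected(prof, [1, 2, 3]) == 0

    def test_missing_positions_raise_key_error(self):
        prof = profile_from_classes([1, 2], ["low", "low"])
        with pytest.raises(KeyError, match="99"):
            count_protected(prof, [1, 99])

    def test_partition_invariant(self, wt_model):
        prof, residues = self.istl1_profile(wt_model)
        non_low = sum(
            1 for p in residues if prof.class_at(p) is not ReactivityClass.LOW
        )
        assert count_protected(prof, residues) + non_low == len(residues)


class TestFalloff:
    def test_simulated_falloff_sites_flagged(self, ref):
        m4_model, m4_ref = refs.istl1_m4_structure_model(ref)
        params = ProbeSimParams(
            noise_cv=0.0, falloff_sites=((292, 0.8), (293, 0.8))
        )
        truth = simulate_truth_reactivity(m4_model, params, ref=m4_ref)
        sim = simulate_lanes(truth, params)
        assert detect_falloff(sim, 3.0) == {292, 293}

    def test_flat_control_lane_has_no_falloff(self):
        assert detect_falloff(lane([1, 2, 3], [9, 9, 9], [4, 4, 4])) == set()

    def test_infinite_threshold_flags_nothing(self):
        assert detect_falloff(lane([1, 2], [9, 9], [4, 400]), math.inf) == set()

    def test_falloff_positions_excluded_from_protected_count(self):
        prof = profile_from_classes([1, 2, 3], ["low", "low", "low"])
        prof = apply_falloff(prof, {2})
        assert count_protected(prof, [1, 2, 3]) == 2


class TestMergePrimers:
    def test_disjoint_windows_concatenate(self):
        a = profile_from_classes([1, 2], ["low", "high"], primer="a")
        b = profile_from_classes([5, 6], ["moderate", "low"], primer="b")
        merged = merge_primers([a, b])
        assert merged.positions == (1, 2, 5, 6)
        assert merged.provenance == ("a", "a", "b", "b")

    def test_overlap_conflict_resolved_by_nearest_center(self):
        a = profile_from_classes([1, 2, 3, 4, 5], ["high"] * 5, primer="a")
        b = profile_from_classes([5, 6, 7, 8, 9], ["low"] * 5, primer="b")
        with pytest.warns(UserWarning, match="conflict"):
            merged = merge_primers([a, b])
        # position 5 is 2 units from a's center (3) and 2 from b's (7): first wins;
        # but class conflict is reported either way
        assert merged.class_at(5) in (ReactivityClass.HIGH, ReactivityClass.LOW)
        assert merged.provenance[merged.index_of(6)] == "b"

    def test_ten_primer_tiling_covers_467nt_substrate_without_gaps(self, ref, wt_model):
        params = ProbeSimParams(noise_cv=0.0)
        truth = simulate_truth_reactivity(wt_model, params, ref=ref)
        span = sorted(truth)
        assert len(span) == 467
        profiles = []
        for k in range(10):
            window = Interval(span[47 * k], span[min(467, 47 * (k + 1) + 5) - 1])
            sim = simulate_lanes(truth, params, primer_id=f"p{k}", window=window)
            profiles.append(compute_reactivity(sim))
        merged = merge_primers(profiles)
        assert merged.positions == tuple(span)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            merge_primers([])


class TestDifferentialProfiles:
    def test_identical_profiles_are_unchanged(self):
        prof = profile_from_classes([1, 2, 3], ["low", "moderate", "high"])
        diff = differential_profile(prof, prof)
        assert set(diff.calls) == {DiffCall.UNCHANGED}

    def test_position_mismatch_is_alignment_error(self):
        a = profile_from_classes([1, 2], ["low", "low"])
        b = profile_from_classes([1, 3], ["low", "low"])
        with pytest.raises(AlignmentError):
            differential_profile(a, b)

    def test_stem_strengthening_protects_the_extended_5p_strand(self, ref, wt_model):
        """Noise-free wild-type vs strengthened-stem profiles over the 5'
        window call exactly the newly paired residues protected."""
        m4_model, m4_ref = refs.istl1_m4_structure_model(ref)
        window = Interval(-17, 25)
        p0 = ProbeSimParams(noise_cv=0.0)
        t_wt = simulate_truth_reactivity(wt_model, p0, ref=ref)
        t_m4 = simulate_truth_reactivity(m4_model, p0, ref=m4_ref)
        prof_wt = compute_reactivity(simulate_lanes(t_wt, p0, "p10", window=window))
        prof_m4 = compute_reactivity(simulate_lanes(t_m4, p0, "p10", window=window))
        diff = differential_profile(prof_wt, prof_m4)
        assert diff.positions_called(DiffCall.PROTECTED) == [-1, 1, 2, 3, 11, 12, 13, 14]

    def test_protected_set_reproduced_at_default_noise(self, ref, wt_model):
        m4_model, m4_ref = refs.istl1_m4_structure_model(ref)
        window = Interval(-17, 25)
        t_wt = simulate_truth_reactivity(wt_model, ProbeSimParams(), ref=ref)
        t_m4 = simulate_truth_reactivity(m4_model, ProbeSimParams(), ref=m4_ref)
        prof_wt = compute_reactivity(
            simulate_lanes(t_wt, ProbeSimParams(seed=21), "p10", window=window)
        )
        prof_m4 = compute_reactivity(
            simulate_lanes(t_m4, ProbeSimParams(seed=22), "p10", window=window)
        )
        diff = differential_profile(prof_wt, prof_m4)
        assert {-1, 1, 2, 3, 11, 12, 13, 14} <= set(
            diff.positions_called(DiffCall.PROTECTED)
        )

    def test_strand_release_exposes_3p_strand_except_291(self):
        """Invading the strengthened stem's 5' strand releases its 3' strand;
        the C at 291 stays weakly reactive (constructed per the probing data)."""
        positions = list(range(283, 301))
        locked = ["low"] * len(positions)
        released = [
            "high" if 286 <= p <= 299 and p != 291 else "low" for p in positions
        ]
        prof_locked = profile_from_classes(positions, locked)
        prof_released = profile_from_classes(positions, released)
        diff = differential_profile(prof_locked, prof_released)
        assert diff.positions_called(DiffCall.EXPOSED) == [
            p for p in range(286, 300) if p != 291
        ]


class TestConcordance:
    def test_noise_free_profile_matches_its_model_perfectly(self, ref, wt_model):
        p0 = ProbeSimParams(noise_cv=0.0)
        truth = simulate_truth_reactivity(wt_model, p0, ref=ref)
        prof = compute_reactivity(simulate_lanes(truth, p0))
        assert structure_concordance(prof, wt_model) == 1.0

    def test_14_of_16_for_probed_stem_annotation(self, wt_model):
        residues = sorted(wt_model.helix("ISTL1").positions())
        classes = ["moderate" if p in (3, 293) else "low" for p in residues]
        prof = profile_from_classes(residues, classes)
        model = refs.wt_structure_model()
        only_istl1 = type(model)((model.helix("ISTL1"),), unpaired=frozenset())
        assert structure_concordance(prof, only_istl1) == pytest.approx(14 / 16)

    def test_true_model_beats_model_without_the_stem(self, ref, wt_model):
        params = ProbeSimParams(seed=1)
        truth = simulate_truth_reactivity(wt_model, params, ref=ref)
        prof = compute_reactivity(simulate_lanes(truth, params))
        assert structure_concordance(prof, wt_model) > structure_concordance(
            prof, wt_model.without("ISTL1")
        )

    def test_shuffled_classes_score_near_chance(self, ref, wt_model):
        """Permutation oracle: concordance of class-shuffled profiles matches
        the expectation under the marginal class frequencies."""
        p0 = ProbeSimParams(noise_cv=0.0)
        truth = simulate_truth_reactivity(wt_model, p0, ref=ref)
        prof = compute_reactivity(simulate_lanes(truth, p0))
        rng = np.random.default_rng(0)
        classes = np.array([c.value for c in prof.classes])
        scores = []
        for _ in range(1000):
            rng.shuffle(classes)
            shuffled = classify(
                ReactivityProfile(
                    "shuf",
                    prof.positions,
                    raw=prof.raw,
                    normalized=tuple(
                        {"low": 0.1, "moderate": 0.4, "high": 0.9}[c] for c in classes
                    ),
                )
            )
            scores.append(structure_concordance(shuffled, wt_model))
        n = len(prof.positions)
        frac_low = sum(c is ReactivityClass.LOW for c in prof.classes) / n
        interior = wt_model.paired_positions() - wt_model.terminal_positions()
        n_interior = sum(1 for p in prof.positions if p in interior)
        expected = (
            n_interior * frac_low + (n - n_interior) * (1 - frac_low)
        ) / n
        assert np.mean(scores) == pytest.approx(expected, abs=0.01)
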