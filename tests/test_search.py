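"""Segment search: window feasibility, bisection vs exhaustive oracle."""

import math

import numpy as np
import pytest

from rnalcs.mcq import mcq
from rnalcs.search import (
    Mode,
    SearchError,
    brute_force_lcs,
    coverage,
    feasibility_profile,
    feasible_at_length,
    lcs_search,
    segment_mcq,
)
from rnalcs.search import _brute_feasible
from rnalcs.synth import make_planted_instance, perturb_torsions, random_torsion_matrix

DEG = math.radians

MODES = (Mode.SEQUENCE_DEPENDENT, Mode.SEQUENCE_INDEPENDENT)


def rotate_rows(matrix, rows, offset_rad):
    """Copy with every defined angle of the given 0-based rows shifted."""
    vals = matrix.values.copy()
    block = vals[rows]
    defined = ~np.isnan(block)
    block[defined] = np.mod(block[defined] + offset_rad + math.pi, 2 * math.pi) - math.pi
    vals[rows] = block
    from dataclasses import replace

    return replace(matrix, values=vals, break_flags=matrix.break_flags.copy())


class TestSegmentMcq:
    def test_full_range_identical_is_zero(self):
        t = random_torsion_matrix(8, 0)
        assert float(segment_mcq(t, t, (1, 8), (1, 8))) == 0.0

    def test_matches_direct_mcq_on_random_ranges(self):
        rng = np.random.default_rng(10)
        a = random_torsion_matrix(20, rng)
        b = random_torsion_matrix(20, rng)
        for _ in range(25):
            ms = int(rng.integers(1, 16))
            ts = int(rng.integers(1, 16))
            L = int(rng.integers(1, 6))
            got = segment_mcq(a, b, (ms, ms + L - 1), (ts, ts + L - 1))
            ref = mcq(a.values[ms - 1 : ms + L - 1], b.values[ts - 1 : ts + L - 1])
            assert float(got) == pytest.approx(float(ref), abs=1e-12)

    def test_unequal_ranges_rejected(self):
        t = random_torsion_matrix(8, 0)
        with pytest.raises(SearchError, match="equal length"):
            segment_mcq(t, t, (1, 4), (1, 5))

    def test_out_of_bounds_rejected(self):
        t = random_torsion_matrix(8, 0)
        with pytest.raises(SearchError, match="bounds"):
            segment_mcq(t, t, (5, 9), (1, 5))


class TestFeasibleAtLength:
    @pytest.mark.parametrize("mode", MODES)
    def test_identical_structures_all_windows_feasible(self, mode):
        t = random_torsion_matrix(15, 3)
        for L in (1, 7, 15):
            segs = feasible_at_length(t, t, L, DEG(5.0), mode)
            assert len(segs) == 15 - L + 1
            assert all(float(s.actual_mcq) < 1e-12 for s in segs)

    def test_quarter_turn_contamination_leaves_one_window(self):
        # rows outside 1..10 shifted by pi/2: any window containing b such
        # rows has MCQ atan2(8b, 8(10-b)) >= atan2(1, 9) ~ 6.3 deg > 5 deg
        target = random_torsion_matrix(20, 5)
        model = rotate_rows(target, np.arange(10, 20), math.pi / 2)
        segs = feasible_at_length(model, target, 10, DEG(5.0), Mode.SEQUENCE_DEPENDENT)
        assert [(s.model_start, s.model_end) for s in segs] == [(1, 10)]
        assert feasible_at_length(model, target, 11, DEG(5.0), Mode.SEQUENCE_DEPENDENT) == []
        # agrees with the direct-evaluation oracle
        oracle = _brute_feasible(model, target, 10, DEG(5.0), Mode.SEQUENCE_DEPENDENT)
        assert [(s.model_start, s.model_end) for s in oracle] == [(1, 10)]

    def test_sequence_independent_finds_shifted_placement(self):
        target = random_torsion_matrix(30, 8)
        # model is target rows 10..19 placed at model positions 1..10 plus noise rows
        vals = random_torsion_matrix(12, 9).values.copy()
        vals[1:11] = target.values[10:20]
        from dataclasses import replace

        model = replace(
            random_torsion_matrix(12, 9),
            values=vals,
        )
        segs = feasible_at_length(model, target, 10, DEG(1.0), Mode.SEQUENCE_INDEPENDENT)
        placements = {(s.model_start, s.target_start) for s in segs}
        assert (2, 11) in placements

    def test_break_excludes_spanning_windows(self):
        t = random_torsion_matrix(12, 4)
        from dataclasses import replace

        flags = t.break_flags.copy()
        flags[5] = True
        broken = replace(t, values=t.values.copy(), break_flags=flags)
        segs = feasible_at_length(broken, broken, 7, DEG(5.0), Mode.SEQUENCE_DEPENDENT)
        assert segs == []  # every window of 7 spans the break
        segs6 = feasible_at_length(broken, broken, 6, DEG(5.0), Mode.SEQUENCE_DEPENDENT)
        assert [(s.model_start, s.model_end) for s in segs6] == [(1, 6), (7, 12)]

    def test_length_out_of_range(self):
        t = random_torsion_matrix(5, 0)
        with pytest.raises(SearchError, match="out of range"):
            feasible_at_length(t, t, 6, DEG(5.0), Mode.SEQUENCE_DEPENDENT)


class TestLcsSearch:
    @pytest.mark.parametrize("mode", MODES)
    def test_identical_structures(self, mode):
        t = random_torsion_matrix(30, 1)
        r = lcs_search(t, t, DEG(10.0), mode)
        assert r.lcs == 30
        assert r.coverage_percent == 100.0
        assert float(r.segments[0].actual_mcq) == 0.0
        assert r.probes == [(30, 1)]  # whole structure feasible on first probe

    @pytest.mark.parametrize("mode", MODES)
    def test_small_global_noise_returns_whole_structure(self, mode):
        t = random_torsion_matrix(25, 2)
        m = perturb_torsions(t, 5.0, seed=3)
        r = lcs_search(m, t, DEG(10.0), mode)
        assert r.lcs == 25 and len(r.probes) == 1

    @pytest.mark.parametrize("mode", MODES)
    def test_planted_run_recovered(self, mode):
        inst = make_planted_instance(
            n=40, planted_start=10, planted_length=12, inside_noise=2.0, outside_noise=90.0,
            seed=7, threshold_degrees=10.0,
        )
        r = lcs_search(inst.model, inst.target, DEG(10.0), mode)
        assert r.lcs == 12
        assert [(s.model_start, s.model_end) for s in r.segments] == [(10, 21)]
        assert r.segments[0].target_start == 10

    def test_no_feasible_residue_gives_zero(self):
        target = random_torsion_matrix(15, 6)
        model = rotate_rows(target, np.arange(15), math.pi / 2)
        for mode in MODES:
            r = lcs_search(model, target, DEG(1.0), mode)
            assert r.lcs == 0 and r.segments == [] and r.coverage_percent == 0.0
            b = brute_force_lcs(model, target, DEG(1.0), mode)
            assert b.lcs == 0

    def test_unequal_lengths_sequence_independent(self):
        target = random_torsion_matrix(30, 11)
        from dataclasses import replace

        model = replace(target, values=target.values[:18].copy(),
                        residue_labels=target.residue_labels[:18],
                        break_flags=target.break_flags[:17].copy())
        r = lcs_search(model, target, DEG(5.0), Mode.SEQUENCE_INDEPENDENT)
        assert r.lcs == 18  # the prefix matches exactly
        assert r.probes[0][0] == 18  # initial window is min(n_model, n_target)

    def test_validation_errors(self):
        a = random_torsion_matrix(10, 0)
        b = random_torsion_matrix(12, 0)
        with pytest.raises(SearchError, match="equal residue counts"):
            lcs_search(a, b, DEG(5.0), Mode.SEQUENCE_DEPENDENT)
        with pytest.raises(SearchError, match="positive"):
            lcs_search(a, a, 0.0, Mode.SEQUENCE_DEPENDENT)
        c = random_torsion_matrix(10, 0, angle_set=("alpha", "beta"))
        with pytest.raises(SearchError, match="angle sets"):
            lcs_search(a, c, DEG(5.0), Mode.SEQUENCE_DEPENDENT)

    @pytest.mark.parametrize("mode", MODES)
    def test_reported_segments_recheck(self, mode):
        inst = make_planted_instance(
            n=30, planted_start=5, planted_length=10, inside_noise=4.0, outside_noise=80.0,
            seed=13, threshold_degrees=12.0,
        )
        r = lcs_search(inst.model, inst.target, DEG(12.0), mode)
        runs = np.cumsum(np.concatenate(([0], inst.model.break_flags)))
        for s in r.segments:
            v = segment_mcq(
                inst.model, inst.target, (s.model_start, s.model_end), (s.target_start, s.target_end)
            )
            assert float(v) <= DEG(12.0) + 1e-12
            assert float(v) == pytest.approx(float(s.actual_mcq), abs=1e-9)
            assert runs[s.model_start - 1] == runs[s.model_end - 1]  # break-free
        # optimality certificate: lcs feasible, lcs+1 infeasible
        if r.lcs < min(r.n_model, r.n_target):
            assert feasible_at_length(inst.model, inst.target, r.lcs + 1, DEG(12.0), mode) == []


class TestOracleEquivalence:
    @pytest.mark.parametrize("mode", MODES)
    def test_random_instances_match_exhaustive_search(self, mode):
        rng = np.random.default_rng(100 if mode is Mode.SEQUENCE_DEPENDENT else 101)
        checked = 0
        for _ in range(20):
            n = int(rng.integers(6, 26))
            noise = float(rng.uniform(10.0, 70.0))
            threshold = DEG(float(rng.uniform(5.0, 30.0)))
            target = random_torsion_matrix(n, rng)
            model = perturb_torsions(target, noise, seed=rng)
            profile = feasibility_profile(model, target, threshold, mode)
            lcs_true = int(np.max(np.nonzero(profile)[0]) + 1) if profile.any() else 0
            monotone = bool(profile[:lcs_true].all())
            r = lcs_search(model, target, threshold, mode)
            if monotone:
                assert r.lcs == lcs_true
                if lcs_true:
                    oracle = _brute_feasible(model, target, lcs_true, threshold, mode)
                    assert [s.model_start for s in r.segments] == [s.model_start for s in oracle]
                    for got, ref in zip(r.segments, oracle):
                        assert float(got.actual_mcq) == pytest.approx(float(ref.actual_mcq), abs=1e-9)
                checked += 1
            else:
                # non-monotone: bisection may under-shoot but must stay feasible
                assert r.lcs <= lcs_true
                if r.lcs:
                    assert profile[r.lcs - 1]
        assert checked >= 10  # monotone instances dominate


class TestMonotonicityInvariants:
    def test_threshold_monotonicity_exhaustive(self):
        rng = np.random.default_rng(55)
        thresholds = [DEG(t) for t in (5, 10, 15, 20, 25, 30)]
        for _ in range(5):
            n = int(rng.integers(8, 16))
            target = random_torsion_matrix(n, rng)
            model = perturb_torsions(target, float(rng.uniform(15, 60)), seed=rng)
            for mode in MODES:
                lcss = [brute_force_lcs(model, target, t, mode).lcs for t in thresholds]
                assert lcss == sorted(lcss)

    def test_mode_dominance_exhaustive(self):
        # the diagonal placement is always among those tried in the
        # sequence-independent mode, so its LCS can only be larger
        rng = np.random.default_rng(56)
        for _ in range(5):
            n = int(rng.integers(8, 16))
            target = random_torsion_matrix(n, rng)
            model = perturb_torsions(target, float(rng.uniform(15, 60)), seed=rng)
            threshold = DEG(float(rng.uniform(8, 25)))
            dep = brute_force_lcs(model, target, threshold, Mode.SEQUENCE_DEPENDENT).lcs
            indep = brute_force_lcs(model, target, threshold, Mode.SEQUENCE_INDEPENDENT).lcs
            assert indep >= dep


@pytest.mark.parametrize(
    "lcs,n,expected", [(71, 71, 100.0), (0, 62, 0.0), (31, 62, 50.0)]
)
def test_coverage(lcs, n, expected):
    assert coverage(lcs, n) == pytest.approx(expected)


def test_coverage_invalid():
    with pytest.raises(SearchError):
        coverage(5, 0)
    with pytest.raises(SearchError):
        coverage(10, 5)
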