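"""Longest-continuous-segment search in torsion-angle space.

Given torsion matrices of a model and a target structure and an MCQ
threshold, find the longest run of consecutive model residues whose MCQ
distance to a target segment does not exceed the threshold.

Two modes:

* sequence-dependent — the model window i..j is compared only with target
  residues i..j (requires equal-length structures, fixed correspondence);
* sequence-independent — each model window slides residue-by-residue along
  the target; the window is feasible if any placement fits, and the recorded
  placement is the minimum-MCQ one (ties: smallest target start).

The search over window lengths is a divide-and-conquer bisection of the
feasibility interval: the first probe is the whole structure; on failure the
window shrinks to half (rounded up), on success it grows halfway back toward
the smallest known-infeasible size.  Under monotone feasibility in the window
length this returns the exact maximum with O(log2 n) probes; total work is
O(n log2 n) sequence-dependent, O(n^2 log2 n) sequence-independent.
Feasibility is not mathematically guaranteed to be monotone (a sub-window's
MCQ can exceed its parent's); :func:`brute_force_lcs` provides an exhaustive
reference, and :func:`feasibility_profile` makes non-monotone instances
visible.

Windows never span a flagged backbone break: "continuous" means a connected
backbone, in either structure.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .mcq import McqValue, delta_matrix, mcq
from .torsions import TorsionMatrix

__all__ = [
    "Mode",
    "Segment",
    "LcsResult",
    "SearchError",
    "segment_mcq",
    "feasible_at_length",
    "lcs_search",
    "brute_force_lcs",
    "feasibility_profile",
    "coverage",
]


class Mode(enum.Enum):
    SEQUENCE_DEPENDENT = "seq-dep"
    SEQUENCE_INDEPENDENT = "seq-indep"


class SearchError(ValueError):
    """Invalid inputs to the segment search."""


@dataclass(frozen=True)
class Segment:
    """A contiguous model window and its placement in the target (1-based, inclusive)."""

    model_start: int
    model_end: int
    target_start: int
    target_end: int
    length: int
    actual_mcq: McqValue

    def __post_init__(self):
        if self.model_end - self.model_start + 1 != self.length:
            raise ValueError("model range length mismatch")
        if self.target_end - self.target_start + 1 != self.length:
            raise ValueError("target range length mismatch")


@dataclass
class LcsResult:
    """Outcome of one (model, target, threshold, mode) run.

    ``lcs`` is the optimal segment length in residues (0 = no feasible
    segment at all); ``segments`` lists every co-optimal model window in
    ascending model-start order; ``coverage_percent`` is 100*lcs/n_target.
    """

    lcs: int
    coverage_percent: float
    segments: list[Segment]
    threshold_degrees: float
    mode: Mode
    n_model: int = 0
    n_target: int = 0
    probes: list[tuple[int, int]] = field(default_factory=list)  # (length, n feasible)

    @property
    def best_mcq(self) -> McqValue | None:
        """Smallest actual MCQ among co-optimal segments; None when lcs = 0."""
        if not self.segments:
            return None
        return min((s.actual_mcq for s in self.segments), key=float)


def coverage(lcs: int, n_target: int) -> float:
    """Target coverage of a segment of length ``lcs``, in percent."""
    if n_target <= 0:
        raise SearchError("target length must be positive")
    if not 0 <= lcs <= n_target:
        raise SearchError("segment length out of range")
    return 100.0 * lcs / n_target


def segment_mcq(
    model_m: TorsionMatrix,
    target_m: TorsionMatrix,
    model_range: tuple[int, int],
    target_range: tuple[int, int],
) -> McqValue:
    """MCQ between a model and a target segment, 1-based inclusive ranges."""
    ms, me = model_range
    ts, te = target_range
    if me - ms != te - ts:
        raise SearchError("segment ranges must have equal length")
    if not (1 <= ms <= me <= model_m.n_residues and 1 <= ts <= te <= target_m.n_residues):
        raise SearchError("segment range out of bounds")
    return mcq(model_m.rows(ms - 1, me), target_m.rows(ts - 1, te))


def _check_pair(model_m: TorsionMatrix, target_m: TorsionMatrix, mode: Mode) -> None:
    if model_m.angle_set != target_m.angle_set:
        raise SearchError(
            f"angle sets differ: {model_m.angle_set} vs {target_m.angle_set}"
        )
    if model_m.n_residues == 0 or target_m.n_residues == 0:
        raise SearchError("empty torsion matrix")
    if mode is Mode.SEQUENCE_DEPENDENT and model_m.n_residues != target_m.n_residues:
        raise SearchError(
            "sequence-dependent mode requires equal residue counts "
            f"({model_m.n_residues} vs {target_m.n_residues})"
        )


def _run_ids(break_flags: np.ndarray, n: int) -> np.ndarray:
    """Label each residue with the id of its break-free run."""
    ids = np.zeros(n, dtype=int)
    if n > 1:
        ids[1:] = np.cumsum(np.asarray(break_flags, dtype=int))
    return ids


class _SearchEngine:
    """Windowed MCQ evaluation with prefix sums, shared across length probes.

    For a fixed residue pairing, the per-position Delta values do not depend
    on the window length, so each alignment (the single diagonal in
    sequence-dependent mode, every diagonal offset in sequence-independent
    mode) is reduced once to cumulative sums of sin Delta / cos Delta; any
    window MCQ then costs O(1).
    """

    def __init__(self, model_m: TorsionMatrix, target_m: TorsionMatrix, mode: Mode):
        self.mode = mode
        self.n_m = model_m.n_residues
        self.n_t = target_m.n_residues
        self.model_runs = _run_ids(model_m.break_flags, self.n_m)
        self.target_runs = _run_ids(target_m.break_flags, self.n_t)
        self._A = model_m.values
        self._B = target_m.values
        self._diag_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def _diagonal_sums(self, d: int) -> tuple[np.ndarray, np.ndarray]:
        """Cumulative (sin, cos) sums for pairing model row r with target row r+d."""
        try:
            return self._diag_cache[d]
        except KeyError:
            pass
        m_lo = max(0, -d)
        m_hi = min(self.n_m, self.n_t - d)
        deltas = delta_matrix(self._A[m_lo:m_hi], self._B[m_lo + d : m_hi + d])
        s = np.concatenate(([0.0], np.cumsum(np.sin(deltas).sum(axis=1))))
        c = np.concatenate(([0.0], np.cumsum(np.cos(deltas).sum(axis=1))))
        self._diag_cache[d] = (s, c)
        return s, c

    def _valid_windows(self, runs: np.ndarray, L: int) -> np.ndarray:
        """Boolean mask over 0-based start positions of break-free windows."""
        n = len(runs)
        if L > n:
            return np.zeros(0, dtype=bool)
        return runs[: n - L + 1] == runs[L - 1 :]

    def window_mcqs(self, L: int, d: int) -> tuple[np.ndarray, np.ndarray]:
        """(model start positions, MCQ values) of all windows on diagonal d.

        Only windows break-free in both structures are returned; positions
        are 0-based model starts.
        """
        m_lo = max(0, -d)
        m_hi = min(self.n_m, self.n_t - d)
        span = m_hi - m_lo
        if span < L:
            return np.zeros(0, dtype=int), np.zeros(0)
        s, c = self._diagonal_sums(d)
        win_s = s[L:] - s[:-L]
        win_c = c[L:] - c[:-L]
        starts = np.arange(m_lo, m_hi - L + 1)
        ok_m = self._valid_windows(self.model_runs, L)[starts]
        ok_t = self._valid_windows(self.target_runs, L)[starts + d]
        keep = ok_m & ok_t
        return starts[keep], np.arctan2(win_s[keep], win_c[keep])

    def feasible(self, L: int, threshold: float) -> list[Segment]:
        """All feasible model windows of length L, ascending model start."""
        if self.mode is Mode.SEQUENCE_DEPENDENT:
            starts, vals = self.window_mcqs(L, 0)
            segs = []
            for s0, v in zip(starts, vals):
                if v <= threshold:
                    segs.append(
                        Segment(s0 + 1, s0 + L, s0 + 1, s0 + L, L, McqValue(float(v)))
                    )
            return segs

        n_starts = self.n_m - L + 1
        best = np.full(n_starts, np.inf)
        best_t = np.full(n_starts, -1, dtype=int)
        # ascending d means ascending target start for each model window, so a
        # strict '<' update keeps the smallest target start among ties
        for d in range(-(self.n_m - L), self.n_t - L + 1):
            starts, vals = self.window_mcqs(L, d)
            if len(starts) == 0:
                continue
            better = vals < best[starts]
            idx = starts[better]
            best[idx] = vals[better]
            best_t[idx] = idx + d
        segs = []
        for s0 in range(n_starts):
            if best[s0] <= threshold:
                t0 = int(best_t[s0])
                segs.append(
                    Segment(s0 + 1, s0 + L, t0 + 1, t0 + L, L, McqValue(float(best[s0])))
                )
        return segs


def feasible_at_length(
    model_m: TorsionMatrix,
    target_m: TorsionMatrix,
    L: int,
    threshold: float,
    mode: Mode,
) -> list[Segment]:
    """All feasible model windows of length L (threshold in radians)."""
    _check_pair(model_m, target_m, mode)
    if not 1 <= L <= min(model_m.n_residues, target_m.n_residues):
        raise SearchError(f"window length {L} out of range")
    return _SearchEngine(model_m, target_m, mode).feasible(L, threshold)


def lcs_search(
    model_m: TorsionMatrix,
    target_m: TorsionMatrix,
    threshold: float,
    mode: Mode = Mode.SEQUENCE_INDEPENDENT,
) -> LcsResult:
    """Find the longest feasible continuous segment (threshold in radians).

    The first probe is the whole structure (the common length in
    sequence-independent mode); afterwards the window length is bisected
    between the largest known-feasible and the smallest known-infeasible
    size, midpoint rounded up, until they are adjacent.  Each distinct
    length is evaluated at most once.
    """
    _check_pair(model_m, target_m, mode)
    if not threshold > 0:
        raise SearchError("threshold must be positive")

    engine = _SearchEngine(model_m, target_m, mode)
    n = min(model_m.n_residues, target_m.n_residues)
    probes: list[tuple[int, int]] = []

    segs = engine.feasible(n, threshold)
    probes.append((n, len(segs)))
    if segs:
        lo, best_segs = n, segs
    else:
        lo, best_segs = 0, []
        hi = n
        while hi - lo > 1:
            mid = (lo + hi + 1) // 2  # midpoint rounded up
            segs = engine.feasible(mid, threshold)
            probes.append((mid, len(segs)))
            if segs:
                lo, best_segs = mid, segs
            else:
                hi = mid

    return LcsResult(
        lcs=lo,
        coverage_percent=coverage(lo, target_m.n_residues),
        segments=best_segs,
        threshold_degrees=math.degrees(threshold),
        mode=mode,
        n_model=model_m.n_residues,
        n_target=target_m.n_residues,
        probes=probes,
    )


# ---------------------------------------------------------------------------
# Exhaustive reference implementation (testing oracle)
# ---------------------------------------------------------------------------


def _brute_windows(break_flags: np.ndarray, n: int, L: int) -> list[int]:
    runs = _run_ids(break_flags, n)
    return [s for s in range(n - L + 1) if runs[s] == runs[s + L - 1]]


def _brute_feasible(
    model_m: TorsionMatrix,
    target_m: TorsionMatrix,
    L: int,
    threshold: float,
    mode: Mode,
) -> list[Segment]:
    """Direct evaluation of every window pair; no shared prefix sums."""
    segs = []
    t_windows = _brute_windows(target_m.break_flags, target_m.n_residues, L)
    for s0 in _brute_windows(model_m.break_flags, model_m.n_residues, L):
        if mode is Mode.SEQUENCE_DEPENDENT:
            if s0 not in t_windows:
                continue
            v = mcq(model_m.rows(s0, s0 + L), target_m.rows(s0, s0 + L))
            if v.radians <= threshold:
                segs.append(Segment(s0 + 1, s0 + L, s0 + 1, s0 + L, L, v))
        else:
            best, best_t = math.inf, -1
            for t0 in t_windows:
                v = mcq(model_m.rows(s0, s0 + L), target_m.rows(t0, t0 + L)).radians
                if v < best:
                    best, best_t = v, t0
            if best <= threshold:
                segs.append(
                    Segment(s0 + 1, s0 + L, best_t + 1, best_t + L, L, McqValue(best))
                )
    return segs


def brute_force_lcs(
    model_m: TorsionMatrix,
    target_m: TorsionMatrix,
    threshold: float,
    mode: Mode = Mode.SEQUENCE_INDEPENDENT,
) -> LcsResult:
    """Exhaustive search over every length, longest first (exact reference).

    Intended for small inputs (n up to ~100); the result is the true maximal
    feasible length even when feasibility is not monotone in the length.
    """
    _check_pair(model_m, target_m, mode)
    if not threshold > 0:
        raise SearchError("threshold must be positive")
    n = min(model_m.n_residues, target_m.n_residues)
    for L in range(n, 0, -1):
        segs = _brute_feasible(model_m, target_m, L, threshold, mode)
        if segs:
            return LcsResult(
                lcs=L,
                coverage_percent=coverage(L, target_m.n_residues),
                segments=segs,
                threshold_degrees=math.degrees(threshold),
                mode=mode,
                n_model=model_m.n_residues,
                n_target=target_m.n_residues,
            )
    return LcsResult(
        lcs=0,
        coverage_percent=0.0,
        segments=[],
        threshold_degrees=math.degrees(threshold),
        mode=mode,
        n_model=model_m.n_residues,
        n_target=target_m.n_residues,
    )


def feasibility_profile(
    model_m: TorsionMatrix,
    target_m: TorsionMatrix,
    threshold: float,
    mode: Mode,
) -> np.ndarray:
    """Boolean feasibility per window length L = 1..min(n_model, n_target).

    Computed by direct evaluation (oracle-grade).  Entry L-1 answers "does a
    feasible window of length L exist".  A profile of the form
    True...True False...False is monotone; the bisection search is exact on
    such instances.
    """
    _check_pair(model_m, target_m, mode)
    n = min(model_m.n_residues, target_m.n_residues)
    return np.array(
        [bool(_brute_feasible(model_m, target_m, L, threshold, mode)) for L in range(1, n + 1)]
    )
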