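"""Mean of Circular Quantities (MCQ): dissimilarity of two torsion matrices.

Given two equal-shape torsion matrices, every position contributes an angular
distance Delta in [0, pi]:

* both angles undefined           -> Delta = 0   (counts as agreement),
* exactly one undefined           -> Delta = pi  (maximal penalty),
* both defined                    -> Delta = min(diff, 2*pi - diff),
                                     diff = |mod(t) - mod(t')|, mod into [0, 2*pi).

The MCQ is then the circular mean magnitude

    MCQ = atan2(sum sin Delta, sum cos Delta),

which lies in [0, pi] because every sin Delta >= 0.  Zero means identical
torsions; the larger the value, the more the structures differ.  atan2(0, 0)
(possible only for empty input or exact cancellation) is taken as 0.

Counting a both-undefined pair as perfect agreement dilutes the mean; the
alternative of excluding such pairs from the sums is available via
``both_undefined="skip"`` but is not the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["McqValue", "mod_2pi", "angle_delta", "delta_matrix", "mcq", "mcq_from_deltas"]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class McqValue:
    """An MCQ distance; radians in [0, pi], degrees derived on demand."""

    radians: float

    @property
    def degrees(self) -> float:
        return math.degrees(self.radians)

    def __float__(self) -> float:
        return self.radians

    def __repr__(self) -> str:
        return f"McqValue({self.degrees:.2f} deg)"


def mod_2pi(t):
    """Map angle(s) in radians onto [0, 2*pi)."""
    return np.mod(t, TWO_PI)


def angle_delta(t: float, t_prime: float) -> float:
    """Angular distance between two (possibly undefined) angles, in [0, pi]."""
    t_nan = math.isnan(t)
    p_nan = math.isnan(t_prime)
    if t_nan and p_nan:
        return 0.0
    if t_nan or p_nan:
        return math.pi
    diff = abs(float(mod_2pi(t)) - float(mod_2pi(t_prime)))
    return min(diff, TWO_PI - diff)


def delta_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized :func:`angle_delta` over two equal-shape angle arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    a_nan = np.isnan(a)
    b_nan = np.isnan(b)
    diff = np.abs(mod_2pi(np.where(a_nan, 0.0, a)) - mod_2pi(np.where(b_nan, 0.0, b)))
    delta = np.minimum(diff, TWO_PI - diff)
    delta = np.where(a_nan | b_nan, math.pi, delta)  # one-sided undefined
    delta = np.where(a_nan & b_nan, 0.0, delta)  # both undefined
    return delta


def mcq_from_deltas(deltas: np.ndarray) -> McqValue:
    """Circular mean magnitude of a set of Delta values in [0, pi]."""
    s = float(np.sin(deltas).sum())
    c = float(np.cos(deltas).sum())
    return McqValue(math.atan2(s, c))  # atan2(0, 0) == 0


def mcq(rows_a: np.ndarray, rows_b: np.ndarray, both_undefined: str = "agree") -> McqValue:
    """MCQ between two equal-shape torsion-angle slices (radians, NaN undefined).

    Parameters
    ----------
    rows_a, rows_b:
        Equal-shape arrays of angles; rows are residues, columns angle types.
    both_undefined:
        ``"agree"`` (default) counts a both-undefined pair as Delta = 0;
        ``"skip"`` removes such pairs from the sums instead of letting them
        dilute the mean.
    """
    a = np.asarray(rows_a, dtype=float)
    b = np.asarray(rows_b, dtype=float)
    deltas = delta_matrix(a, b)
    if both_undefined == "skip":
        deltas = deltas[~(np.isnan(a) & np.isnan(b))]
    elif both_undefined != "agree":
        raise ValueError("both_undefined must be 'agree' or 'skip'")
    return mcq_from_deltas(deltas)
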