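"""Trigonometric representation of an RNA chain: the n x |T| torsion matrix.

Each residue is described by up to eight angles,
T = {alpha, beta, gamma, delta, epsilon, zeta, P, chi}:

* alpha..zeta — the six backbone torsions around the phosphodiester linkage,
  defined by the standard atom quadruples (alpha and epsilon/zeta reach into
  the previous/next residue);
* chi — the glycosidic torsion orienting the base: O4'-C1'-N9-C4 for purines,
  O4'-C1'-N1-C2 for pyrimidines;
* P — the Altona–Sundaralingam pseudorotation phase of the ribose ring,
  computed from the five endocyclic torsions tau0..tau4.

Angles are stored in radians in [-pi, pi); an undefined angle (chain
terminus, chain break, missing atom, degenerate geometry) is NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import UNDEFINED, dihedral
from .structure import Residue, ResidueChain

__all__ = [
    "DEFAULT_ANGLE_SET",
    "BACKBONE_QUADRUPLES",
    "TAU_QUADRUPLES",
    "TorsionMatrix",
    "backbone_torsions",
    "chi_torsion",
    "pseudorotation_phase",
    "torsion_matrix",
]

#: The canonical measured angle set, in fixed column order.
DEFAULT_ANGLE_SET = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "P", "chi")

# Backbone torsion quadruples as (residue offset, atom name) pairs.
BACKBONE_QUADRUPLES: dict[str, tuple[tuple[int, str], ...]] = {
    "alpha": ((-1, "O3'"), (0, "P"), (0, "O5'"), (0, "C5'")),
    "beta": ((0, "P"), (0, "O5'"), (0, "C5'"), (0, "C4'")),
    "gamma": ((0, "O5'"), (0, "C5'"), (0, "C4'"), (0, "C3'")),
    "delta": ((0, "C5'"), (0, "C4'"), (0, "C3'"), (0, "O3'")),
    "epsilon": ((0, "C4'"), (0, "C3'"), (0, "O3'"), (1, "P")),
    "zeta": ((0, "C3'"), (0, "O3'"), (1, "P"), (1, "O5'")),
}

# Endocyclic ribose torsions tau0..tau4 (all within one residue).
TAU_QUADRUPLES: tuple[tuple[str, str, str, str], ...] = (
    ("C4'", "O4'", "C1'", "C2'"),  # tau0
    ("O4'", "C1'", "C2'", "C3'"),  # tau1
    ("C1'", "C2'", "C3'", "C4'"),  # tau2
    ("C2'", "C3'", "C4'", "O4'"),  # tau3
    ("C3'", "C4'", "O4'", "C1'"),  # tau4
)

_PHASE_DENOM = 2.0 * (math.sin(math.radians(36.0)) + math.sin(math.radians(72.0)))


@dataclass
class TorsionMatrix:
    """n x k matrix of torsion angles (radians, NaN = undefined).

    ``break_flags`` records backbone discontinuities between consecutive rows
    (length n-1); window-based segment searches never cross a flagged pair.
    """

    values: np.ndarray
    residue_labels: list[tuple[str, int, str, str]]
    angle_set: tuple[str, ...] = DEFAULT_ANGLE_SET
    break_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("torsion matrix must be 2-D")
        if self.values.shape[1] != len(self.angle_set):
            raise ValueError("column count must match angle_set")
        if len(self.residue_labels) != self.values.shape[0]:
            raise ValueError("one residue label per row required")
        if self.break_flags is None:
            self.break_flags = np.zeros(max(self.n_residues - 1, 0), dtype=bool)
        else:
            self.break_flags = np.asarray(self.break_flags, dtype=bool)
            if self.break_flags.shape != (max(self.n_residues - 1, 0),):
                raise ValueError("break_flags must have length n-1")

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]

    def rows(self, start: int, stop: int) -> np.ndarray:
        """Row slice [start, stop) of the value grid (0-based)."""
        return self.values[start:stop]

    def undefined_count(self) -> int:
        return int(np.isnan(self.values).sum())

    def to_frame(self):
        """Debug view: one row per residue, angles in degrees, NaN = undefined."""
        import pandas as pd

        idx = [f"{c}{n}{i.strip()}" for c, n, i, _ in self.residue_labels]
        return pd.DataFrame(np.degrees(self.values), index=idx, columns=list(self.angle_set))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, float_format="%.3f")


def _quadruple_value(
    chain: ResidueChain, i: int, quad: tuple[tuple[int, str], ...]
) -> float:
    """Evaluate one torsion quadruple at residue i, honouring breaks/termini."""
    n = len(chain.residues)
    pts = []
    offsets = [off for off, _ in quad]
    lo, hi = min(offsets), max(offsets)
    if i + lo < 0 or i + hi >= n:
        return UNDEFINED
    # crossing a flagged backbone break makes the angle undefined
    flags = chain.break_flags
    if flags:
        for j in range(i + lo, i + hi):
            if flags[j]:
                return UNDEFINED
    for off, name in quad:
        atom = chain.residues[i + off].atom(name)
        if atom is None:
            return UNDEFINED
        pts.append(atom)
    return dihedral(*pts)


def backbone_torsions(chain: ResidueChain, i: int) -> dict[str, float]:
    """The six backbone torsions of residue i (0-based); NaN where undefined."""
    if not 0 <= i < len(chain.residues):
        raise IndexError(f"residue index {i} out of range")
    return {
        name: _quadruple_value(chain, i, quad)
        for name, quad in BACKBONE_QUADRUPLES.items()
    }


def chi_torsion(r: Residue) -> float:
    """Glycosidic torsion chi; NaN if base type unknown or atoms missing."""
    if "N9" in r.atoms:
        quad = ("O4'", "C1'", "N9", "C4")
    elif "N1" in r.atoms:
        quad = ("O4'", "C1'", "N1", "C2")
    else:
        return UNDEFINED
    pts = [r.atom(name) for name in quad]
    if any(p is None for p in pts):
        return UNDEFINED
    return dihedral(*pts)


def ring_torsions(r: Residue) -> list[float]:
    """The five endocyclic ribose torsions tau0..tau4 (NaN where undefined)."""
    out = []
    for quad in TAU_QUADRUPLES:
        pts = [r.atom(name) for name in quad]
        out.append(UNDEFINED if any(p is None for p in pts) else dihedral(*pts))
    return out


def pseudorotation_phase_from_taus(taus) -> float:
    """Altona–Sundaralingam phase P from tau0..tau4 (radians, [-pi, pi)).

    P = atan2((tau4 + tau1) - (tau3 + tau0), 2*tau2*(sin 36 + sin 72)).
    The fully planar ring (all taus zero) maps to 0 by the atan2(0, 0) = 0
    convention.
    """
    t0, t1, t2, t3, t4 = taus
    if any(math.isnan(t) for t in (t0, t1, t2, t3, t4)):
        return UNDEFINED
    y = (t4 + t1) - (t3 + t0)
    x = t2 * _PHASE_DENOM
    p = math.atan2(y, x)
    return -math.pi if p >= math.pi else p


def pseudorotation_phase(r: Residue) -> float:
    """Sugar-pucker phase P of one residue; NaN if any ring atom is missing."""
    return pseudorotation_phase_from_taus(ring_torsions(r))


def torsion_matrix(
    chain: ResidueChain, angle_set: tuple[str, ...] = DEFAULT_ANGLE_SET
) -> TorsionMatrix:
    """Compute the torsion matrix of a chain for the requested angle set.

    ``angle_set`` must be a non-empty subset of the supported names, and its
    order fixes the column order; both compared structures must use the same
    set.
    """
    if not angle_set:
        raise ValueError("angle_set must not be empty")
    unknown = [a for a in angle_set if a not in DEFAULT_ANGLE_SET]
    if unknown:
        raise ValueError(f"unsupported angle type(s) {unknown}; choose from {DEFAULT_ANGLE_SET}")

    n = len(chain.residues)
    vals = np.full((n, len(angle_set)), UNDEFINED)
    for i, res in enumerate(chain.residues):
        bb = None
        for j, name in enumerate(angle_set):
            if name in BACKBONE_QUADRUPLES:
                if bb is None:
                    bb = backbone_torsions(chain, i)
                vals[i, j] = bb[name]
            elif name == "chi":
                vals[i, j] = chi_torsion(res)
            elif name == "P":
                vals[i, j] = pseudorotation_phase(res)
    flags = np.asarray(chain.break_flags, dtype=bool) if chain.break_flags else np.zeros(
        max(n - 1, 0), dtype=bool
    )
    return TorsionMatrix(
        values=vals,
        residue_labels=[r.label for r in chain.residues],
        angle_set=tuple(angle_set),
        break_flags=flags,
    )
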