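"""Synthetic RNA-like chains with torsions known by construction.

Chains are built atom-by-atom in internal coordinates (natural-extension
placement), so the backbone torsions alpha..zeta and the glycosidic torsion
chi of the result equal the requested values by construction; the ribose
ring comes from a rigid pucker template (C3'-endo, C2'-endo or planar)
attached to the backbone.  Bases are minimal stubs — just the glycosidic
nitrogen and the reference carbon that define chi.

The module also generates paired model/target instances at the
torsion-matrix level with a planted matching run, used as ground truth for
segment-search tests.  Note a property of the circular mean: a window of w
near-perfect residues plus one arbitrary residue has MCQ at most
atan2(k, w*k) ~ 1/w rad (k angles per residue), so with an 8-angle set and
thresholds of a few degrees, noise alone cannot stop a near-perfect planted
run from extending into its flanks.  Planted instances therefore carry
backbone breaks at the run boundaries — as real predicted models routinely
do — which makes the planted length exact for any threshold between the
inside and outside noise scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import nerf_place
from .mcq import TWO_PI
from .structure import Residue, ResidueChain, StructureModel, detect_chain_breaks
from .torsions import DEFAULT_ANGLE_SET, TorsionMatrix

__all__ = [
    "GeometryTemplate",
    "PlantedInstance",
    "A_FORM_TORSIONS",
    "SUGAR_PRESETS",
    "build_chain_from_torsions",
    "write_pdb",
    "write_mmcif",
    "random_torsion_matrix",
    "perturb_torsions",
    "make_planted_instance",
]


@dataclass(frozen=True)
class GeometryTemplate:
    """Idealized bond lengths (Angstrom) and bond angles (degrees).

    Round-number idealizations; the exact values are irrelevant to torsion
    round-trips, which only constrain dihedral angles.
    """

    bond_lengths: dict = field(
        default_factory=lambda: {
            "P-O5'": 1.60,
            "O5'-C5'": 1.44,
            "C5'-C4'": 1.51,
            "C4'-C3'": 1.52,
            "C3'-O3'": 1.42,
            "O3'-P": 1.60,
            "C1'-N": 1.47,
            "N-C": 1.37,
            "ring": 1.52,  # uniform endocyclic bond (pentagon side)
        }
    )
    bond_angles: dict = field(
        default_factory=lambda: {
            "P-O5'-C5'": 120.0,
            "O5'-C5'-C4'": 110.0,
            "C5'-C4'-C3'": 116.0,
            "C4'-C3'-O3'": 110.0,
            "C3'-O3'-P": 120.0,
            "O3'-P-O5'": 104.0,
            "O4'-C1'-N": 108.0,
            "C1'-N-C": 126.0,
        }
    )
    pucker_amplitude: float = 0.38  # out-of-plane displacement scale (Angstrom)

    def __post_init__(self):
        for k, v in self.bond_lengths.items():
            if not 0.5 < v < 3.0:
                raise ValueError(f"bond length {k}={v} outside (0.5, 3.0) A")
        for k, v in self.bond_angles.items():
            if not 60.0 < v < 180.0:
                raise ValueError(f"bond angle {k}={v} outside (60, 180) deg")


#: A-form-like default torsions (degrees).
A_FORM_TORSIONS = {
    "alpha": -68.0,
    "beta": 178.0,
    "gamma": 54.0,
    "delta": 82.0,
    "epsilon": -153.0,
    "zeta": -71.0,
    "chi": -158.0,
}

#: Sugar pucker presets: target pseudorotation phase in degrees (None = flat ring).
SUGAR_PRESETS = {"C3'-endo": 18.0, "C2'-endo": 162.0, "planar": None}

# Ring atoms in bonded order around the five-membered ring.
_RING_ORDER = ("C4'", "O4'", "C1'", "C2'", "C3'")

# Offset between the out-of-plane displacement phase of the pentagon model
# and the measured Altona-Sundaralingam phase for this ring geometry
# (P ~ displacement phase + 54 deg, nearly exactly linear).
_PHASE_OFFSET = 54.0

_PURINE_NAMES = {"A", "G"}


def _ring_template(preset: str, geom: GeometryTemplate) -> dict[str, np.ndarray]:
    """Rigid 5-ring + C5' stub realizing the preset pucker.

    A regular pentagon (side = ring bond length) is puckered by sinusoidal
    out-of-plane displacements; the displacement phase is chosen so the
    measured pseudorotation phase lands on the preset value.
    """
    try:
        target_phase = SUGAR_PRESETS[preset]
    except KeyError:
        raise ValueError(f"unknown sugar preset {preset!r}; choose from {sorted(SUGAR_PRESETS)}")
    side = geom.bond_lengths["ring"]
    radius = side / (2.0 * math.sin(math.pi / 5.0))
    q = 0.0 if target_phase is None else geom.pucker_amplitude
    phi = 0.0 if target_phase is None else math.radians(target_phase - _PHASE_OFFSET)

    pts: dict[str, np.ndarray] = {}
    for k, name in enumerate(_RING_ORDER):
        ang = 2.0 * math.pi * k / 5.0
        z = q * math.sqrt(2.0 / 5.0) * math.cos(phi + 4.0 * math.pi * k / 5.0)
        pts[name] = np.array([radius * math.cos(ang), radius * math.sin(ang), z])
    # C5' stub for attachment, with the same C5'-C4'/C5'-C4'-C3' geometry as
    # the backbone builder so the 3-point superposition is exact
    pts["C5'"] = nerf_place(
        pts["O4'"],
        pts["C3'"],
        pts["C4'"],
        geom.bond_lengths["C5'-C4'"],
        geom.bond_angles["C5'-C4'-C3'"],
        -115.0,  # exocyclic placement; fixed, arbitrary
    )
    return pts


def _kabsch_attach(template: dict[str, np.ndarray], anchors: dict[str, np.ndarray]):
    """Rigid transform mapping template anchor atoms onto placed anchors."""
    names = list(anchors)
    src = np.array([template[n] for n in names])
    dst = np.array([anchors[n] for n in names])
    src_c = src.mean(axis=0)
    dst_c = dst.mean(axis=0)
    h = (src - src_c).T @ (dst - dst_c)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return lambda p: rot @ (p - src_c) + dst_c


def _normalize_table(torsion_table, n: int) -> list[dict]:
    if isinstance(torsion_table, dict):
        return [dict(torsion_table) for _ in range(n)]
    table = [dict(row) for row in torsion_table]
    if len(table) != n:
        raise ValueError(f"torsion table has {len(table)} rows, expected {n}")
    return table


def build_chain_from_torsions(
    torsion_table,
    n: int | None = None,
    sequence: str | None = None,
    sugar_preset: str = "C3'-endo",
    geometry: GeometryTemplate | None = None,
    chain_id: str = "A",
    identifier: str = "synthetic",
) -> StructureModel:
    """Build a chain whose measured torsions equal the requested ones.

    Parameters
    ----------
    torsion_table:
        Either one dict of torsions in degrees (keys among alpha, beta,
        gamma, delta, epsilon, zeta, chi) applied to every residue, or a
        sequence of such dicts, one per residue.  A per-residue "sugar"
        key overrides ``sugar_preset``.
    n:
        Number of residues (required when a single dict is given).
    sequence:
        Residue names, e.g. "ACGU..."; cycled default "ACGU".
    """
    geom = geometry or GeometryTemplate()
    if n is None:
        if isinstance(torsion_table, dict):
            raise ValueError("n is required when torsion_table is a single dict")
        n = len(torsion_table)
    if n < 2:
        raise ValueError("need at least 2 residues")
    table = _normalize_table(torsion_table, n)
    if sequence is None:
        sequence = "".join("ACGU"[i % 4] for i in range(n))
    if len(sequence) != n:
        raise ValueError("sequence length must equal n")

    bl, ba = geom.bond_lengths, geom.bond_angles
    chain = ResidueChain(chain_id=chain_id)

    # seed frame of the first residue, in the z = 0 plane
    p = np.zeros(3)
    o5 = np.array([bl["P-O5'"], 0.0, 0.0])
    th = math.radians(ba["P-O5'-C5'"])
    c5 = o5 + bl["O5'-C5'"] * np.array([-math.cos(th), math.sin(th), 0.0])

    prev = None  # (C4', C3', O3') of previous residue
    for i in range(n):
        row = table[i]

        def tget(key, from_row=None):
            r = row if from_row is None else from_row
            return float(r.get(key, A_FORM_TORSIONS[key]))

        if prev is not None:
            # epsilon(i-1)/zeta(i-1) reach into residue i and place its P/O5'
            c4p, c3p, o3p = prev
            prev_row = table[i - 1]
            p = nerf_place(c4p, c3p, o3p, bl["O3'-P"], ba["C3'-O3'-P"], tget("epsilon", prev_row))
            o5 = nerf_place(c3p, o3p, p, bl["P-O5'"], ba["O3'-P-O5'"], tget("zeta", prev_row))
            c5 = nerf_place(o3p, p, o5, bl["O5'-C5'"], ba["P-O5'-C5'"], tget("alpha"))
        c4 = nerf_place(p, o5, c5, bl["C5'-C4'"], ba["O5'-C5'-C4'"], tget("beta"))
        c3 = nerf_place(o5, c5, c4, bl["C4'-C3'"], ba["C5'-C4'-C3'"], tget("gamma"))
        o3 = nerf_place(c5, c4, c3, bl["C3'-O3'"], ba["C4'-C3'-O3'"], tget("delta"))

        atoms = {"P": p, "O5'": o5, "C5'": c5, "C4'": c4, "C3'": c3, "O3'": o3}

        template = _ring_template(str(row.get("sugar", sugar_preset)), geom)
        xform = _kabsch_attach(template, {"C3'": c3, "C4'": c4, "C5'": c5})
        for name in ("O4'", "C1'", "C2'"):
            atoms[name] = xform(template[name])

        base = sequence[i]
        n_name, c_name = ("N9", "C4") if base in _PURINE_NAMES else ("N1", "C2")
        n_atom = nerf_place(
            atoms["C4'"], atoms["O4'"], atoms["C1'"], bl["C1'-N"], ba["O4'-C1'-N"], -120.0
        )
        atoms[n_name] = n_atom
        atoms[c_name] = nerf_place(
            atoms["O4'"], atoms["C1'"], n_atom, bl["N-C"], ba["C1'-N-C"], tget("chi")
        )

        chain.residues.append(
            Residue(chain_id=chain_id, seq_number=i + 1, insertion_code=" ", residue_name=base, atoms=atoms)
        )
        prev = (c4, c3, o3)

    # next-residue epsilon/zeta come from row i of the table, matching the
    # convention that epsilon(i)/zeta(i) reach into residue i+1
    detect_chain_breaks(chain)
    return StructureModel(identifier=identifier, chains=[chain], source_format="PDB")


# ---------------------------------------------------------------------------
# Serialization of fixtures
# ---------------------------------------------------------------------------


def _to_gemmi(s: StructureModel):
    import gemmi

    st = gemmi.Structure()
    st.name = s.identifier
    model = gemmi.Model("1")
    for ch in s.chains:
        gch = gemmi.Chain(ch.chain_id)
        for r in ch.residues:
            gr = gemmi.Residue()
            gr.name = r.residue_name
            gr.seqid = gemmi.SeqId(r.seq_number, r.insertion_code if r.insertion_code.strip() else " ")
            for name, pos in r.atoms.items():
                at = gemmi.Atom()
                at.name = name
                at.pos = gemmi.Position(*map(float, pos))
                at.element = gemmi.Element(name[0])
                at.occ = 1.0
                gr.add_atom(at)
            gch.add_residue(gr)
        model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(s: StructureModel, path) -> None:
    """Write a StructureModel as a standard PDB file (test fixtures)."""
    _to_gemmi(s).write_pdb(str(path))


def write_mmcif(s: StructureModel, path) -> None:
    """Write a StructureModel as mmCIF (test fixtures)."""
    _to_gemmi(s).make_mmcif_document().write_file(str(path))


# ---------------------------------------------------------------------------
# Matrix-level instances
# ---------------------------------------------------------------------------


def _wrap_to_pi(values: np.ndarray) -> np.ndarray:
    return np.mod(values + math.pi, TWO_PI) - math.pi


def _synthetic_labels(n: int) -> list[tuple[str, int, str, str]]:
    return [("A", i + 1, " ", "ACGU"[i % 4]) for i in range(n)]


def random_torsion_matrix(
    n: int,
    seed_or_rng,
    angle_set: tuple[str, ...] = DEFAULT_ANGLE_SET,
) -> TorsionMatrix:
    """Random torsion matrix, uniform over [-pi, pi), with the structural
    undefined pattern of a real chain (alpha of the first residue,
    epsilon/zeta of the last)."""
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) else np.random.default_rng(seed_or_rng)
    vals = rng.uniform(-math.pi, math.pi, size=(n, len(angle_set)))
    for j, name in enumerate(angle_set):
        if name == "alpha":
            vals[0, j] = math.nan
        elif name in ("epsilon", "zeta"):
            vals[-1, j] = math.nan
    return TorsionMatrix(values=vals, residue_labels=_synthetic_labels(n), angle_set=tuple(angle_set))


def perturb_torsions(
    m: TorsionMatrix,
    noise_degrees: float,
    region: tuple[int, int] | None = None,
    seed: int | np.random.Generator = 0,
    kind: str = "uniform",
) -> TorsionMatrix:
    """Copy of ``m`` with wrapped noise added to defined entries.

    ``region`` is a 1-based inclusive residue range (None = all rows).
    ``kind="uniform"`` draws offsets uniformly in +-noise; ``kind="constant"``
    adds exactly +noise to every defined entry (useful for closed-form MCQ
    checks).  Undefined entries and rows outside the region are untouched.
    """
    if noise_degrees < 0:
        raise ValueError("noise must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vals = m.values.copy()
    lo, hi = (0, m.n_residues) if region is None else (region[0] - 1, region[1])
    block = vals[lo:hi]
    defined = ~np.isnan(block)
    if kind == "uniform":
        noise = rng.uniform(-1.0, 1.0, size=block.shape) * math.radians(noise_degrees)
    elif kind == "constant":
        noise = np.full(block.shape, math.radians(noise_degrees))
    else:
        raise ValueError("kind must be 'uniform' or 'constant'")
    block[defined] = _wrap_to_pi(block[defined] + noise[defined])
    vals[lo:hi] = block
    return replace(m, values=vals, break_flags=m.break_flags.copy())


@dataclass
class PlantedInstance:
    """A model/target pair with an engineered matching run.

    The target is a clean random chain; the model reproduces it closely
    inside the planted run (inside noise), is heavily perturbed outside
    (outside noise), and has backbone breaks at the run boundaries.  At the
    stated threshold the longest feasible segment is exactly the planted run,
    verified against the exhaustive search at generation time.
    """

    model: TorsionMatrix
    target: TorsionMatrix
    planted_start: int  # 1-based
    planted_length: int
    threshold_degrees: float
    seed: int


def _apply_break(m: TorsionMatrix, flag_index: int) -> None:
    """Flag a break between rows flag_index and flag_index+1 (0-based) and
    blank the torsions whose quadruples would span it."""
    m.break_flags[flag_index] = True
    for j, name in enumerate(m.angle_set):
        if name in ("epsilon", "zeta"):
            m.values[flag_index, j] = math.nan
        elif name == "alpha":
            m.values[flag_index + 1, j] = math.nan


def make_planted_instance(
    n: int,
    planted_start: int,
    planted_length: int,
    inside_noise: float,
    outside_noise: float,
    seed: int,
    threshold_degrees: float | None = None,
    max_retries: int = 20,
) -> PlantedInstance:
    """Generate a model/target pair whose LCS equals ``planted_length``.

    Noise levels are in degrees; ``inside_noise`` must be strictly smaller
    than ``outside_noise``, and the default threshold sits between them
    (inside + 15% of the gap).  Generation is verified with
    :func:`rnalcs.search.brute_force_lcs` in both modes and retried with a
    derived sub-seed when a random fluke breaks the construction; a
    systematic failure raises ``RuntimeError``.
    """
    from .search import Mode, brute_force_lcs  # deferred: avoid import cycle

    if not 1 <= planted_start <= planted_start + planted_length - 1 <= n:
        raise ValueError("planted run must fit within [1, n]")
    if not inside_noise < outside_noise:
        raise ValueError("inside_noise must be strictly smaller than outside_noise")
    if threshold_degrees is None:
        threshold_degrees = inside_noise + 0.15 * (outside_noise - inside_noise)
    threshold = math.radians(threshold_degrees)

    lo = planted_start - 1  # 0-based first planted row
    hi = lo + planted_length  # one past last planted row

    for attempt in range(max_retries):
        rng = np.random.default_rng([seed, attempt])
        target = random_torsion_matrix(n, rng)
        model = perturb_torsions(target, inside_noise, region=(planted_start, hi), seed=rng)
        if lo > 0:
            model = perturb_torsions(model, outside_noise, region=(1, lo), seed=rng)
        if hi < n:
            model = perturb_torsions(model, outside_noise, region=(hi + 1, n), seed=rng)
        if lo > 0:
            _apply_break(model, lo - 1)
        if hi < n:
            _apply_break(model, hi - 1)

        ok = True
        for mode in (Mode.SEQUENCE_DEPENDENT, Mode.SEQUENCE_INDEPENDENT):
            res = brute_force_lcs(model, target, threshold, mode)
            if res.lcs != planted_length or any(
                s.model_start != planted_start or s.target_start != planted_start
                for s in res.segments
            ):
                ok = False
                break
        if ok:
            return PlantedInstance(
                model=model,
                target=target,
                planted_start=planted_start,
                planted_length=planted_length,
                threshold_degrees=threshold_degrees,
                seed=seed,
            )
    raise RuntimeError(
        f"could not plant a run of {planted_length} in {n} residues after "
        f"{max_retries} attempts (inside {inside_noise} deg, outside "
        f"{outside_noise} deg, threshold {threshold_degrees:.2f} deg)"
    )
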