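# Methods

## Torsion-space representation

A chain is reduced to an n × |T| matrix of angles, default
T = {α, β, γ, δ, ε, ζ, P, χ} (radians, canonical interval [−π, π)).

* α: O3′(i−1)–P(i)–O5′(i)–C5′(i); β: P–O5′–C5′–C4′; γ: O5′–C5′–C4′–C3′;
  δ: C5′–C4′–C3′–O3′; ε: C4′(i)–C3′(i)–O3′(i)–P(i+1);
  ζ: C3′(i)–O3′(i)–P(i+1)–O5′(i+1).
* χ: O4′–C1′–N9–C4 for purines, O4′–C1′–N1–C2 for pyrimidines. Modified
  residues are classified by which glycosidic nitrogen they carry; if
  neither is present χ is undefined.
* P: the Altona–Sundaralingam pseudorotation phase computed from the five
  endocyclic torsions τ0…τ4,
  `P = atan2((τ4 + τ1) − (τ3 + τ0), 2 τ2 (sin 36° + sin 72°))`.
  Both δ and P are kept in the default set: δ is the backbone's view of the
  sugar region, P the ring's own.

Any angle whose atom quadruple crosses a chain terminus, a flagged backbone
break, or a missing atom is *undefined* (stored as NaN so the whole matrix
pipeline stays vectorized). Degenerate geometry (collinear triples) is also
undefined rather than an error. The signed dihedral follows the IUPAC
convention; the anti-periplanar arrangement is reported as −π, the
canonical representative of ±π in [−π, π). A useful property worth stating
because it is often mis-remembered: the signed torsion is *invariant* under
reading the chain in the reverse direction (the sign encodes handedness,
not traversal) and is negated by mirror reflection.

## The MCQ distance

For equal-shape matrices, every position contributes
Δ ∈ [0, π] (0 if both undefined, π if exactly one undefined, circular
distance otherwise) and `MCQ = atan2(Σ sin Δ, Σ cos Δ)` ∈ [0, π]
(atan2(0,0) → 0 by convention, chosen for determinism and continuity; the
same convention is used in the phase formula above).

Counting both-undefined pairs as perfect agreement follows the piecewise
definition literally; it dilutes the mean when undefined entries are
plentiful. `mcq(..., both_undefined="skip")` excludes such pairs instead;
it is deliberately not the default.

**Dilution bound.** Because each residue contributes at most 8 unit
vectors, a window of w near-identical residues plus one arbitrary residue
has MCQ ≤ atan2(8, 8w) ≈ 1/w rad (the contaminating vectors have
sin Δ ≤ 1). At w = 12 that is ≈ 4.8°. Two consequences shape this package:
(i) a locally perfect region always "bleeds" into its flanks at thresholds
of ~10° unless a chain break stops it, and (ii) contamination at Δ = π is
*invisible* to the mean whenever good pairs outnumber bad ones
(sin π = 0, and the cosine sum stays positive), so adversarial test
constructions use Δ = π/2, which degrades the mean maximally.

## Segment search

Feasibility of a window length L = "some break-free model window of L
residues has MCQ ≤ threshold against a break-free target window" — the
identically-positioned window in sequence-dependent mode, any placement in
sequence-independent mode (recorded placement: minimum MCQ, ties to the
smallest target start). Comparison is `≤` on the threshold. Windows never
span a flagged break: continuity means a connected backbone.

The length schedule is divide and conquer formalized as bisection: probe
the whole structure first (min(n_model, n_target) when lengths differ); on
failure keep bounds (largest known-feasible, smallest known-infeasible) and
probe their midpoint rounded up until adjacent. Under monotone feasibility
this returns the exact maximum in O(log₂ n) probes. Each distinct length is
evaluated once; for a fixed residue pairing the per-position Δ values do
not depend on L, so every alignment diagonal is reduced once to cumulative
sin/cos sums and each window costs O(1). Total work: O(n log₂ n)
sequence-dependent, O(n² log₂ n) sequence-independent.

Feasibility is **not** guaranteed monotone in L — a sub-window's MCQ can
exceed its parent's near the threshold. The package therefore ships
`brute_force_lcs` (exhaustive, longest-first, the exact reference for
n ≲ 100) and `feasibility_profile` (per-length feasibility by direct
evaluation). The test suite compares bisection against the exhaustive
reference on >200 seeded instances and *reports* non-monotone cases (a few
per hundred at thresholds near the noise scale) instead of hiding them; on
those, bisection still returns an honestly feasible length, possibly short
of the true optimum. We deliberately do not "repair" the schedule, since
the schedule is part of the method's definition.

Reported per run: LCS, coverage = 100·LCS/n_target, actual MCQ and
locations of *all* co-optimal segments (ascending model start). LCS = 0 is
reported as "n/a" MCQ with empty locations.

## Structure input

gemmi parses PDB/mmCIF (auto-detected, .gz transparent). First coordinate
model only; hydrogens dropped; a residue counts as a nucleotide if it has
the ribose core C1′/C4′/O4′, which keeps name-conforming modified
nucleotides without a component dictionary. Alternate locations resolve to
the highest occupancy, ties to file order. Backbone breaks are flagged when
O3′(i)–P(i+1) > 2.5 Å (covalent ≈ 1.6 Å; cutoff configurable) or either
atom is absent. Residue identity is (chain, author number, insertion
code); reports use 1-based positions matching PDB numbering.

## Synthetic chains and planted instances

`build_chain_from_torsions` places atoms by natural-extension (NeRF)
internal coordinates, so requested backbone/χ torsions are met to ~1e−12
rad at build time; bond lengths/angles are round idealizations
(GeometryTemplate) because round-trips constrain only the dihedrals. The
ribose is a rigid pentagon template with sinusoidal out-of-plane
displacements (amplitude 0.38 Å) whose phase maps nearly linearly onto the
measured pseudorotation phase (offset ≈ 54° for this geometry); presets
C3′-endo (P ≈ 18°), C2′-endo (P ≈ 162°), planar. Bases are minimal
two-atom stubs — exactly the atoms χ needs.

File round-trip precision is format-limited: mmCIF reproduces torsions to
~1e−7 rad, while fixed-column PDB stores three decimals per coordinate, so
quantization alone can move a torsion by up to ≈ 4·√3·0.0005/1.2 ≈ 2.9e−3
rad; tests assert 1e−6 in memory and through mmCIF, and 3e−3 through PDB.

Planted instances (`make_planted_instance`) emulate a model that is
accurate in one region and disordered elsewhere: target = random torsions
(uniform, with the structural undefined pattern of a real chain); model =
target + uniform wrapped noise, small inside the planted run, large
outside, with backbone breaks at the run boundaries — as real predicted
models routinely have. The breaks are essential, not cosmetic: by the
dilution bound above, no outside-noise level can stop a near-perfect run
from extending by a residue at a ~10° threshold, so boundary breaks are
what makes the planted length exact. Default verification threshold when
none is given: inside + 15% of the noise gap — far below the expected MCQ
(≈ outside/2) of an all-outside window. Every instance is verified against
the exhaustive search in both modes at generation time and regenerated
from a derived sub-seed on a fluke (bounded retries, then an error).
Identical seeds reproduce instances bit for bit.

What the generator does *not* emulate: realistic torsion correlations
(A-form helicity, suites), base identity effects, missing atoms beyond
break blanking, or experimental coordinate error. Passing tests show the
algorithmic contract holds — metric fidelity, search exactness, planted
recovery — not that any particular MCQ threshold is biologically
meaningful for real models.

## Problem sizes and numerical choices

The test suite runs at n ≤ 50 (where the exhaustive reference is exact and
fast) with >200 seeded instances for the oracle comparison and 20 seeds
for planted recovery; the acceptance script uses n = 40 studies and a
60-instance oracle batch. These sizes were chosen to make the exhaustive
cross-checks cheap while staying in the regime the method targets
(structures of tens of residues). Ties among equal-MCQ placements go to
the smallest target start; co-optimal model windows are all reported.
Angles are radians internally; degrees appear only at the user boundary,
rounded to two decimals in reports (full precision kept internally).

## Known limitations

* Sequence-independent mode tries every placement of every window — O(n²
  log₂ n) is fine for hundreds of residues but not thousands.
* No multi-segment score, no sequence alignment, no reverse-orientation
  matching, no η/θ pseudo-torsions, no protein support.
* When length-feasibility is non-monotone the bisection answer can
  under-shoot the true optimum (use `brute_force_lcs` to audit small
  cases); the non-acceptance of this trade-off would change the method.
* The MCQ's dilution and π-blindness (above) are properties of the
  measure itself; interpret long segments at generous thresholds with the
  per-segment actual MCQ in hand.
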