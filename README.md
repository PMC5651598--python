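# rnalcs

Longest continuous segment search between RNA 3D structures in
torsion-angle space.

When a predicted RNA model is compared with its target structure, global
scores (RMSD and friends) hide *where* the prediction is right. `rnalcs`
answers the local question: **what is the longest stretch of consecutive
residues in the model whose conformation matches the target?** Conformation
is compared in torsion-angle space, so no superposition or alignment
optimization is involved. The tool is aimed at people who build or assess
RNA 3D models — e.g. evaluating blind-prediction submissions, locating
well-modelled motifs, or finding the weak region that drags a global score
down.

## The measure

Each residue is reduced to eight angles
T = {α, β, γ, δ, ε, ζ, P, χ}: the six backbone torsions, the glycosidic
torsion χ, and the sugar-pucker pseudorotation phase P
(Altona–Sundaralingam). A structure of n residues becomes an n × 8 matrix
of angles t_ij, with an explicit *undefined* state for angles broken by
chain termini, chain breaks or missing atoms.

Two equal-length segments S, S′ are compared by the Mean of Circular
Quantities:

```
MCQ(S, S′) = atan2( Σ_ij sin Δ(t_ij, t′_ij),  Σ_ij cos Δ(t_ij, t′_ij) )

Δ(t, t′) = 0                      if both undefined
         = π                      if exactly one undefined
         = min(diff, 2π − diff)   otherwise,  diff = |mod(t) − mod(t′)|
```

with mod into [0, 2π). MCQ lies in [0, π]; 0 means identical torsions, and
the larger the value the more the segments differ.

The **LCS** is the largest window length L for which some break-free model
window of L residues has MCQ ≤ threshold against a target window — either
the identically-positioned one (*sequence-dependent* mode, equal-length
structures) or any placement along the target (*sequence-independent*
mode). The search over L starts from the whole structure and bisects
between the largest known-feasible and smallest known-infeasible length
(midpoint rounded up), probing each length at most once: O(n log₂ n) work
sequence-dependent, O(n² log₂ n) sequence-independent. Reported per run:
LCS, target coverage (100·LCS/n_target), the actual MCQ of the optimal
segment(s), and their first/last residue numbers in both structures; all
co-optimal segments are listed.

## Worked example

The package can fabricate its own test structures (chains built from
prescribed torsion angles). Build a 16-nt target and a model whose
residues 7–12 have γ and χ rotated by 95°, then compare:

```python
import numpy as np
from rnalcs.synth import A_FORM_TORSIONS, build_chain_from_torsions, write_pdb

rng = np.random.default_rng(0)
table = [{k: float((v + rng.uniform(-25, 25) + 180) % 360 - 180)
          for k, v in A_FORM_TORSIONS.items()} for _ in range(16)]
write_pdb(build_chain_from_torsions(table, identifier="target"), "ex_target.pdb")
for i in range(6, 12):
    table[i]["gamma"] = (table[i]["gamma"] + 95 + 180) % 360 - 180
    table[i]["chi"]   = (table[i]["chi"]   - 95 + 180) % 360 - 180
write_pdb(build_chain_from_torsions(table, identifier="model"), "ex_model.pdb")
```

```
$ rnalcs --target ex_target.pdb --model ex_model.pdb --mode seq-dep --threshold 5
model:   ex_model (16 nt)
target:  ex_target (16 nt)
mode:    seq-dep
threshold: 5 deg
LCS:     8
coverage: 50.00%
segment 1: model 1-8, target 1-8, MCQ 3.83 deg
```

At a strict 5° threshold the best continuous match is 8 residues (50% of
the target) with an actual MCQ of 3.83°. A threshold sweep shows the
transition to global agreement:

```
$ rnalcs --target ex_target.pdb --model ex_model.pdb --mode seq-dep --sweep 5,10,15,20,25,30
 threshold   LCS  coverage      MCQ
        5°     8    50.00%     3.83
       10°    16   100.00%     5.95
       15°    16   100.00%     5.95
       ...
```

From 10° upward the whole 16-nt model fits under the threshold (its global
MCQ is 5.95°), so the entire structure is returned — larger thresholds
cannot shrink the answer. `--out report.csv` writes the same rows as CSV:

```
model_id,target_id,mode,threshold_degrees,lcs,coverage_percent,actual_mcq_degrees,model_start,model_end,target_start,target_end
ex_model,ex_target,seq-dep,15,16,100.00,5.95,1,16,1,16
```

The same machinery is available as a library (`rnalcs.lcs_search`,
`rnalcs.mcq`, `rnalcs.torsion_matrix`, …) for scripted analyses.

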