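# tsmode

Graph-based characterization of transition-state modes and reaction-coordinate
trajectories in internal coordinates.

## The problem

A transition state (TS) is a first-order saddle point with exactly one
imaginary vibrational frequency. The eigenvector of that mode is the local
direction of the reaction coordinate, but it is delivered as 3N Cartesian
numbers — not as chemistry. Verifying that a candidate TS actually connects
the intended reactant and product usually means an intrinsic reaction
coordinate (IRC) calculation costing hundreds to thousands of core hours.
`tsmode` answers the everyday question — *which bonds form or break, what
rotates, what inverts?* — in seconds, from nothing but the TS geometry and
its normal modes, with no prior knowledge of reactant or product.

The same machinery applies to full IRC or quick-reaction-coordinate (QRC)
trajectories, translating Cartesian frames into bond/angle/dihedral changes.

## How it works

1. **Graph perception.** Connectivity is assigned from interatomic distances
   against per-pair thresholds `f · (r_vdW(A) + r_vdW(B))`, with the factor
   `f ∈ [0.38, 0.7]` depending on the bond class (tight for H–X and
   covalent pairs, loose for metal–ligand). Pairs below 0.6 × threshold are
   accepted directly; borderline pairs must pass acute-angle (< 15° at
   metals, < 30° otherwise) and ring-diagonal checks. For TS geometries a
   second pass at 1.4 × the thresholds picks up partially formed/broken
   bonds. Bond orders and formal charges are then optimized by a beam
   search minimizing `Σ_atoms (w_v·Δvalence + w_q·|q|)` with `w_v > w_q`,
   Kekulé-seeded aromatic rings rewritten to order 1.5, and metal–ligand
   orders fixed at one.
2. **Internal coordinates.** Bonds, angles and dihedrals are enumerated from
   the (optionally reactant/product-augmented) graph topology.
3. **Displacement and screening.** The imaginary mode displaces the TS by
   ± a fixed amplitude (0.5 Å for the most-moving atom); internal-coordinate
   deltas between the two displaced frames are screened at 0.4 Å / 10° / 20°
   (bond / angle / dihedral), with one retry at half thresholds when nothing
   is flagged, and a secondary 0.2 Å threshold that pairs the partner event
   of a proton transfer.
4. **Filtering and classification.** Angle/dihedral changes touching atoms of
   a flagged bond change are dropped as geometric consequences; equivalent
   dihedrals about one axis reduce to the heaviest-terminal representative;
   pyramidal inversion is detected at 3-coordinate centers via the
   angle-sum/improper-dihedral criterion. The result is a versioned JSON
   report: changes, mode class (`bond_change | rotation | inversion | mixed |
   none`), graphs, and provenance for every event.

## Worked example

```python
from tsmode import analyze_ts
from tsmode.fixtures import make_model_ts

spec = make_model_ts("sn2")           # model substitution TS + synthetic mode
report = analyze_ts(spec.geometry, spec.modes)
print(report.mode_class)
for ch in report.changes:
    print(ch.classification, ch.coord.label(report.elements), round(ch.delta, 3))
```

prints

```
bond_change
bond_break C0-Cl4 1.5
bond_form C0-F5 -0.7
```

The model TS is a trigonal-planar CH₃ with an elongated C–Cl (2.3 Å) and an
incoming F (2.0 Å) on the opposite axial side. Both contacts exceed the
equilibrium bonding threshold and exist as coordinates only because of the
1.4 × TS pass. Between the reverse- and forward-displaced structures the
C–Cl distance grows by 1.5 Å (cleavage) and C–F shrinks by 0.7 Å
(formation); every angle involving C, Cl or F changed too, but those are
filtered as consequences of the bond events, so the report contains exactly
the two-event concerted substitution signature and nothing else.

The same pipeline is available from the shell:

```bash
tsmode fixtures sn2                    # writes sn2.xyz + sn2.modes
tsmode analyze sn2.xyz --modes sn2.modes --json report.json
tsmode traj path.xyz --strategy max_rmsd
```

Exit codes: 0 = classified, 3 = no imaginary frequency (not a TS),
4 = malformed input. See `examples/` for narrative scripts covering graph
perception, mode analysis and trajectory analysis.

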