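# Methods

This note documents the models, parameter choices and numerical conventions
behind `tsmode`, and what the bundled synthetic systems do and do not
demonstrate.

## Graph perception

**Distance model.** Two atoms A, B are candidate-bonded when
`d(A,B) < s · f(class) · (r_vdW(A) + r_vdW(B))`. The van der Waals radii are
the Alvarez (2013) consistent compilation, frozen for Z = 1–86 in
`tsmode.elements` so results cannot drift with external library versions.
The class factors are

| class | factor |
|---|---|
| H–X | 0.42 |
| nonmetal–nonmetal | 0.52 |
| metal–ligand | 0.65 |
| metal–metal | 0.70 |

all inside the 0.38–0.7 band, tighter for covalent contacts and looser for
metal coordination. They were fixed once against the ten-molecule
equilibrium library (every textbook bond perceived, no spurious pair within
20% of a threshold) and are user-configurable in `GraphConfig`. "Metal"
means s-block (except H), d-block, f-block, plus Al/Ga/In/Tl/Sn/Pb/Bi; the
flag controls the angle-validation class and bond-order pinning.

**Two-pass scheme.** The scale `s` is 1.0 in the first pass; for
transition-state geometries a second pass at `s = 1.4` adds (never removes)
bonds, capturing partially formed/broken bonds like the 2.0–2.3 Å axial
contacts of the model substitution TS. Pairs with
`d < 0.6 × threshold` are accepted outright; borderline pairs are validated
geometrically. The same 0.6 fraction applies to the scaled threshold in the
second pass — the alternative (direct-accept only at unscaled distances) was
considered and rejected as it makes second-pass acceptance depend on pass
ordering for no chemical gain.

**Geometric validation.** A candidate is rejected if (a) it forms an angle
below 15° (metal endpoint) / 30° (nonmetal) with an already-accepted bond at
either endpoint, or (b) it closes a 3-membered ring, or cuts the chord of an
existing 4-membered ring, while being longer than 1.2 × the mean of the
ring's existing bonds. The 1.2 ratio keeps genuine small rings (near-equal
sides) while rejecting square diagonals (ratio √2 ≈ 1.41). Candidates are
processed direct-accepts first, then by increasing distance, so short
genuine bonds anchor the angle tests for longer ones.

**Bond orders and formal charges.** On the fixed topology, non-metal bond
orders are optimized over {1, 2, 3} by beam search (width 8, iteration cap
200). The objective is
`Σ_atoms [ 4·dev(a) + |q(a)| ] + |Q_total − Σ q|`, where `dev` is the
distance of the atom's order sum to its nearest allowed valence and
`q = order_sum − nearest_allowed_valence` (so four-bonded N is +1,
one-bonded O is −1). Valence dominates charge (4 : 1). Metal–ligand bonds
stay at order one and do **not** count toward the ligand atom's valence
sum — the donor pair belongs to the ligand, which makes uniform C⁻≡O⁺ the
unique optimum for carbonyl ligands exactly as in free CO. Metals carry the
residual of the total charge. Each iteration expands the atoms with the
worst penalty contribution by ±1 on their incident bonds and keeps the
`beam_width` best patterns; ties break to the lexicographically smallest
order vector for determinism. Termination is reached when no candidate
improves on the incumbent best; hitting the iteration cap instead returns
the best-so-far with `bond_order_converged: false` in the graph metadata.

Aromatic candidates are 5–7-membered cycles (minimum cycle basis) of 2- or
3-connected C/N/O/S atoms within 0.15 Å of their best-fit plane. Even rings
are Kekulé-seeded with alternating single/double orders before the search;
rings whose alternation survives optimization are rewritten to uniform
order 1.5. Dative labels follow the rule: a metal–ligand bond is dative when
the donor atom's valence is already satisfied without it.

## Internal coordinates

Bonds are the graph's edge set, optionally united with reactant/product
graph edges (matched by atom index) so that a coordinate forming only at the
path ends still exists at the TS. Angles are all neighbor pairs at atoms of
degree ≥ 2 — including crowded metal sites, where downstream thresholds
rather than enumeration limits control noise. Dihedrals are all
`(i, j, k, l)` with `i ∈ N(j)\{k}`, `l ∈ N(k)\{j}`, deduplicated under the
canonical orientation (first index < last). "Nonredundant" here means
deduplicated, nothing more — no delocalized or natural-coordinate
construction is attempted, and no auxiliary coordinates are added for
near-linear angles (> 175° is merely unusual, not special-cased, because the
package reports changes rather than optimizing geometry).

Dihedrals use the standard atan2 plane-normal construction, signed in
(−180°, 180°]; dihedral differences are minimal circular differences, so a
170° → −170° change reads as +20°. Degenerate constructions (coincident
points, zero-length or collinear axes) raise a dedicated error rather than
returning NaN.

## Mode displacement

The imaginary mode (most negative frequency; all other negative frequencies
are reported as diagnostics) is normalized so its **largest per-atom norm is
one**, and the TS is displaced by ± amplitude × that field. The amplitude is
therefore the Cartesian travel, in Å, of the most-moving atom — an
interpretable convention, but a convention nonetheless: it is neither
mass-weighted nor 3N-normalized, and users matching another code's
displacements should rescale accordingly. The default amplitude of 0.5 Å
was chosen jointly with the default 0.4 Å bond threshold: the two are
coupled (half the amplitude roughly halves every delta), so they are exposed
together in the API and CLI. Parsing of vendor quantum-chemistry output is
deliberately out of core scope; any adapter that yields a geometry plus
(frequency, displacement) blocks — or writes the minimal text format — plugs
in.

## Screening, filtering, classification

Deltas between the reverse- and forward-displaced frames (or the two
selected trajectory frames) are screened at 0.4 Å / 10° / 20° for
bonds / angles / dihedrals. If — and only if — *nothing* is flagged, one
retry at 50% thresholds follows (`provenance: fallback`); the global
all-or-nothing trigger was chosen over per-kind fallback because a mode with
a genuine above-threshold event does not need rescue, and per-kind rescue
would reintroduce the small-amplitude noise the primary tier exists to
suppress. Proton transfers are frequently asymmetric along the mode, so each
flagged H-containing cleavage (formation) recruits its partner formation
(cleavage) on the same hydrogen at a secondary threshold of
0.5 × bond_thresh = 0.2 Å (`provenance: proton_pairing`); 0.5 mirrors the
fallback fraction.

Filtering drops every angle/dihedral change sharing an atom with a flagged
bond change (geometric consequence), then reduces dihedrals sharing a
rotation axis to the one with the heaviest terminal-atom pair (ties: larger
single terminal mass, then lowest indices). Ordering everywhere is
(kind, |Δ| descending, canonical atom tuple), making reports byte-identical
across runs.

Pyramidal inversion cannot appear as a threshold event — for a symmetric
out-of-plane mode the two displaced frames are mirror images and every bond
and angle delta cancels. It is detected directly at 3-coordinate centers
without flagged bond changes: inversion is reported when the sum of the
three bond angles crosses or touches 354° (planar = 360°) between frames,
**or** when the improper out-of-plane dihedral changes sign with a circular
change beyond the dihedral threshold. The sign-flip arm is what fires for a
symmetric inversion mode (both frames have equal angle sums); the angle-sum
arm covers asymmetric frames such as IRC segments.

Mode class: any bond event ⇒ `bond_change` (`mixed` if rotations or
inversions also survive); otherwise a torsion ⇒ `rotation`, an inversion ⇒
`inversion`, both ⇒ `mixed`; surviving angle-only changes (possible for
scissoring modes) also map to `mixed`; an empty list ⇒ `none`.

## Trajectory analysis

Frame pairs come either from the endpoints or from the maximum pairwise
Kabsch RMSD (all atoms, optimal translation + proper rotation; ties to the
earliest pair). Alignment matters because IRC frames can drift rigidly;
RMSD after superposition measures pure shape change. The graph is built,
with TS thresholds, on the frame nearest the midpoint of the cumulative
RMSD arc length — a TS proxy that is robust to paths that do not start at
the saddle — and augmented with both endpoint graphs.

## Synthetic systems

All test inputs are generated programmatically:

- **Substitution TS**: planar CH₃, axial Cl at 2.3 Å and F at 2.0 Å, axial
  carbon mode with counter-moving partners and a small H umbrella
  component. Expected: one cleavage + one formation, class `bond_change`.
- **Inversion TS**: planar NH₃, N out-of-plane mode with H counter-motion.
  Expected: one inversion at N.
- **Rotation TS**: eclipsed F–H₂C–CH₂–F, rigid torsion of one CH₂F group
  about the C–C axis (a hindered rotation against a stationary frame).
  Geometry gives a 42.6° F–C–C–F change at the default amplitude — above
  the 20° threshold — and 17.7° at 0.4 × amplitude, which lands between the
  fallback (10°) and primary tiers and so exercises threshold rescue with
  unchanged classification. A symmetric counter-torsion was deliberately
  not used: its delta is twice as large and never drops into the fallback
  window at reduced amplitude.
- **Equilibrium library**: water, methane, ethane, ethene, ethyne, benzene,
  ammonia, methanol, CO₂ and octahedral Cr(CO)₆ at textbook geometry, each
  with its reference edge/order set. Bond orders are cross-checked against
  exhaustive enumeration of all order patterns wherever ≤ 8 bonds are free.
- **Paths**: linear interpolation between the displaced pair, optionally
  with seeded random rigid motion per frame.

Every fixture carries a −500 cm⁻¹ imaginary frequency plus two positive
dummy modes so that mode selection is always exercised. Fixture geometry
parameters are package choices, tuned once so the study conditions hold
(elongated bonds appear only under TS scaling; default thresholds catch the
expected events at the default amplitude) and then frozen.

What passing these tests shows: the perception, enumeration, screening,
filtering and classification logic is correct on unambiguous inputs, and
its invariances (rigid motion, relabeling, forward/reverse swap, threshold
nesting) hold exactly. What it does not show: performance on crowded
organometallic TSs, strongly asynchronous transformations (where a single
displacement vector underdescribes the surface and late-forming bonds can
be missed), multi-event proton-relay chemistry, or the accuracy of the
radii/factor table across exotic bonding — those require real electronic-
structure data outside this package's test scope.

## Known limitations

- Normal-mode displacement is a linear probe; highly asynchronous or
  late-forming bond changes below the displacement threshold are reported
  partially by design (precision over exhaustive detection).
- The formal-charge scheme is bookkeeping, not electronic structure; only
  its ordering (via the penalty) is meaningful, and hypervalent/zwitterionic
  edge cases follow the nearest-allowed-valence rule rather than chemistry.
- Aromaticity handling covers planar 5–7-rings with Kekulé alternation;
  fused polycyclics keep whatever alternation the optimizer finds.
- No stereochemistry, no Wilson B-matrices, no geometry optimization, no
  thermochemistry.

## Report schema (version 1)

Top-level keys: `schema_version`, `mode_class`, `changes` (list of `kind`,
`atoms` (0-based), `elements`, `delta` (Å or degrees), `classification`,
`provenance`), `frames_used`, `extra_imaginaries` (cm⁻¹), `graphs` (per
graph: `atoms` with `index`/`element`/`formal_charge`, `bonds` with
`i`/`j`/`order`/`dative`, `adjacency`, `total_charge`, `metadata`), and
`file_paths`. Serialization is JSON with sorted keys; write → read → write
is byte-stable.
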