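"""Characterize a model substitution transition state from its imaginary mode.

The model TS is a trigonal-planar CH3 group with an elongated C-Cl bond
(2.3 A) on one axial side and an incoming F (2.0 A) on the other; the
imaginary mode moves the carbon along the axis.  Neither axial contact is a
bond at equilibrium thresholds -- the transition-state threshold pass (1.4x)
is what makes them internal coordinates at all.  The analysis reports
exactly two events: the C-Cl cleavage and the C-F formation.  The deltas are
the change in each bond length between the reverse- and forward-displaced
structures (0.5 A max-atom amplitude), and every angle change involving
those atoms is filtered out as a geometric consequence.
"""

from tsmode import analyze_ts
from tsmode.fixtures import make_model_ts

spec = make_model_ts("sn2")
report = analyze_ts(spec.geometry, spec.modes)

print("mode class:", report.mode_class)
for ch in report.changes:
    label = ch.coord.label(report.elements)
    unit = "A" if ch.coord.kind == "bond" else "deg"
    print(f"  {ch.classification:<11s} {label:<12s} "
          f"delta = {ch.delta:+.3f} {unit}  [{ch.provenance}]")
print("extra imaginary frequencies:", report.extra_imaginaries)
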