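"""Characterize a reaction-coordinate trajectory instead of a single mode.

Interpolates an 11-frame path through the hindered-rotation TS (eclipsed
F-CH2-CH2-F, one end group twisting against the other), applies a random
rigid rotation
and translation to every frame to mimic the drift of a real IRC, and runs
the trajectory analysis.  Frame selection uses the maximally diverse pair by
Kabsch RMSD, so the rigid motion does not affect the outcome: the single
reported event is the F-C-C-F torsion, after the eight equivalent dihedrals
sharing the C-C axis are reduced to the heaviest-terminal one.
"""

from tsmode import analyze_trajectory
from tsmode.fixtures import make_model_ts, make_path

spec = make_model_ts("rotation")
frames = make_path(spec, 11, rigid_motion_seed=42)
report = analyze_trajectory(frames, strategy="max_rmsd")

print("frames compared:", report.frames_used)
print("mode class:", report.mode_class)
for ch in report.changes:
    print(f"  {ch.classification:<9s} {ch.coord.label(report.elements):<16s} "
          f"delta = {ch.delta:+.1f} deg")
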