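"""Perceive a molecular graph from raw Cartesian coordinates.

Builds benzene from its textbook geometry, runs connectivity perception and
bond-order/formal-charge optimization, and prints the resulting edges.  The
six ring bonds come out at order 1.5 (aromatic), the C-H bonds at order 1,
and every formal charge is zero.
"""

from tsmode import build_graph
from tsmode.fixtures import make_equilibrium_molecule

geom, _ = make_equilibrium_molecule("benzene")
graph = build_graph(geom)

print(f"benzene: {graph.n_atoms} atoms, {len(graph.bonds)} bonds")
for b in graph.bonds:
    ei, ej = graph.elements[b.i], graph.elements[b.j]
    print(f"  {ei}{b.i:<2d}-{ej}{b.j:<2d} order {b.order}")
print("formal charges:", graph.formal_charges)
print("sum of |charges| (0 = clean Lewis structure):",
      sum(map(abs, graph.formal_charges)))
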