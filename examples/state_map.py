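"""A small [Mg2+] x I_MF state map on a reduced sheet.

Sweeps a 3 x 3 grid on a 16 x 16 network (fast, minutes); the full-scale
map uses the same API with the default network and a denser grid.
"""

import granulayer as gl
from granulayer.statemap import sweep

params = gl.default_params()
graph = gl.build_graph(gl.build_geometry(16, 16), seed=0, scheme="exact")
grid = sweep(graph, params, mg_values=[0.013, 1.2, 13.0],
             i_values=[8.0, 10.7, 22.7], duration=1.5, seeds=(0,))
cols = ["mg_mM", "i_pA", "rate", "oi", "pi", "state"]
print(grid.results[cols].round(3).to_string(index=False))
print("-> POT-representing (II) cells need functional NMDA (low/default "
      "Mg2+) at moderate granule rates; high Mg2+ with a large current "
      "fires uniformly (IV).  The synchronized-oscillation domain (I) "
      "needs the full 32x32 sheet: on this reduced sheet the volley "
      "rhythm does not survive the stronger edge effects.")
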