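"""Optimal-matching distances on hand-sized sequences.

Shows the cost rules on the home-care channel (K=3 ordinal levels plus the
nonresponse / incapacitated / dead overlay states) and how the edit
distance trades substitutions against insertions-deletions.
"""

import numpy as np

import caretraj as ct
from caretraj.costs import ext_index
from caretraj.model import DEAD, INCAP, NR
from caretraj.om import om_distance

specs = ct.default_channel_specs()
cm = ct.build_cost_model(specs)
hc = next(c for c in cm.channels if c.spec.name == "home_care")

print("home-care substitution costs (levels none/temporary/regular):")
print(f"  s(none, temporary) = {hc.sub[0, 1]:.3f}   # 2|dpos|/K = 2/3")
print(f"  s(none, regular)   = {hc.sub[0, 2]:.3f}")
print(f"  s(none, DEAD)      = {hc.sub[0, ext_index(hc.spec, DEAD)]:.3f}   # furthest state")
print(f"  s(regular, INCAP)  = {hc.sub[2, ext_index(hc.spec, INCAP)]:.3f}   # cost-equivalent")
print(f"  s(any, NR)         = {hc.sub[0, ext_index(hc.spec, NR)]:.3f}   # equidistant = indel")
print(f"  indel              = {hc.indel:.3f}   # half the maximum substitution")

a = [0, 2, 0, 2, 0]
b = [2, 0, 2, 0, 2]
d = om_distance(a, b, hc.sub, hc.indel)
print(f"\nOM({a}, {b}) = {d:.3f}")
# One deletion plus one insertion realigns the whole alternation (cost 2);
# substituting position-by-position would have cost 5 * 4/3 = 6.67, so the
# distance reflects shared ordering, not just pointwise disagreement.
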