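"""Enumerate the chambers of the tie hyperplane arrangement for Z/3Z.

Every chamber is a maximal region of weight vectors sharing one tropical
Jacobian; its rank lower-bounds the variety's dimension.  For Z/3Z there
are 92 chambers and the best rank is 9 — the ambient dimension, since
|G|^2 = 9 < 5*ell + 1 = 11 for this tiny group.
"""

import sunletdim as sd
from sunletdim.serialize import census_frame

G = sd.parse_group("Z3")
chambers = sd.enumerate_chambers(G)
c = sd.census(G, chambers)

print(census_frame(c, decimals=1).to_string(index=False))
print(f"total chambers: {c.total}")
print(f"maximum rank: {max(c.counts)} (ambient cap {G.order ** 2})")
# the four rank-7 chambers are the all-one-tree assignments: rank 3*ell+1
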