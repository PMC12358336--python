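"""Dimension of a larger level-1 network from the closed-form formula.

A level-1 semi-directed network decomposes across cut edges into trees
and sunlets, and for odd group order >= 5 its variety has dimension
ell*(m - c) + 1 with m edges and c cycles.  Here: a 5-taxon network with
one 3-cycle (10 edges) under a 5-state group-based model.
"""

import sunletdim as sd

G = sd.parse_group("Z5")
network = sd.NetworkCounts(n_leaves=5, m_edges=10, c_cycles=1)
dim = sd.level1_dimension(network, G.ell)
print(f"group {G} (ell = {G.ell}); network: {network.m_edges} edges, "
      f"{network.c_cycles} cycle(s), {network.n_leaves} leaves")
print(f"dimension = ell*(m - c) + 1 = {dim}")

# sanity: the 3-sunlet itself (6 edges, 1 cycle) recovers 5*ell + 1 = 21
sunlet = sd.NetworkCounts(n_leaves=3, m_edges=6, c_cycles=1)
print(f"3-sunlet check: {sd.level1_dimension(sunlet, G.ell)} = "
      f"{sd.expected_dimension_sunlet3(G.ell).expected}")
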