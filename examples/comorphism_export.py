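"""Export the 3-sunlet parameterization as polynomials.

Each model coordinate q_g (one per consistent leaf-labelling) maps to a
sum of two squarefree degree-5 monomials, one per displayed tree.  The
Macaulay2 dialect can be pasted into a CAS session for implicitization
experiments (fair warning: the elimination is infeasible already for
Z/5Z).
"""

import sunletdim as sd

G = sd.parse_group("Z2")
print(sd.export_comorphism(G, "plain"))
print(sd.export_comorphism(G, "macaulay2"))
# 4 generators for Z2: |G|^2 labellings, each a binomial of degree 5
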