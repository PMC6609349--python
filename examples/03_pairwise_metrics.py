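"""Pairwise inter-organism metrics from PM vectors and network structure.

Two toy organisms over a 3-metabolite panel: A produces everything well, B
has a deficiency in the second metabolite.  PM distance measures overall
dissimilarity; PM complementarity (directional) measures how much one
organism could supplement the other.  Seed sets identify the metabolites
each network must acquire from outside.
"""

import numpy as np

from producibility import (
    MetabolicNetwork,
    Metabolite,
    Reaction,
    pm_complementarity,
    pm_distance,
    seed_competition,
    seed_set,
)

pm_a = np.array([0.95, 0.90, 0.70])
pm_b = np.array([0.95, 0.10, 0.70])

print(f"PM distance(A, B)          = {pm_distance(pm_a, pm_b):.3f}")
print(f"PM complementarity(A -> B) = {pm_complementarity(pm_a, pm_b):.3f}")
print(f"PM complementarity(B -> A) = {pm_complementarity(pm_b, pm_a):.3f}")
# A can supplement B's deficient metabolite (0.31 of A's producibility mass),
# while B adds nothing to A.

org1 = MetabolicNetwork(
    [Metabolite("glc"), Metabolite("pyr"), Metabolite("ala")],
    [Reaction("R1", {"glc": -1.0, "pyr": 1.0}), Reaction("R2", {"pyr": -1.0, "ala": 1.0})],
)
org2 = MetabolicNetwork(
    [Metabolite("glc"), Metabolite("pyr")],
    [Reaction("R1", {"glc": -1.0, "pyr": 1.0})],
)
s1, s2 = seed_set(org1, "org1"), seed_set(org2, "org2")
print(f"seeds(org1) = {sorted(s1.seeds)}, seeds(org2) = {sorted(s2.seeds)}")
print(f"seed competition(org1 -> org2) = {seed_competition(s1, s2):.2f}")
# Both networks must take up glucose, so they compete for their single seed.
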