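"""Relationship structure of an extended twin family.

Builds a family of parents, MZ twins and a younger sib, and prints the
additive (2*Phi), dominance (Delta7) and household-sharing matrices that
parameterise the A/D/H/E covariance model.
"""

import numpy as np

from pedvar import IndividualRecord, PedigreeGraph, classify_pair, relationship_matrices

ped = PedigreeGraph(
    [
        IndividualRecord("father", "fam", sex="male", birth_year=1958),
        IndividualRecord("mother", "fam", sex="female", birth_year=1960),
        IndividualRecord("twin1", "fam", "father", "mother", "female", 1984,
                         mz_group="pair1"),
        IndividualRecord("twin2", "fam", "father", "mother", "female", 1984,
                         mz_group="pair1"),
        IndividualRecord("sib", "fam", "father", "mother", "male", 1988),
    ]
)
ages = {"twin1": 16, "twin2": 16, "sib": 12}  # minors share the parental household
mats = relationship_matrices(ped, ages)

np.set_printoptions(precision=3, suppress=True)
print("members:", mats.ids)
print("\nadditive sharing (2*Phi) — 1.0 between the MZ twins, 0.5 for")
print("parent-offspring and sib pairs, 0 for the spouses:")
print(mats.additive)
print("\ndominance sharing (Delta7) — 1.0 for MZ, 0.25 for full sibs:")
print(mats.dominance)
print("\nhousehold indicator — one block: spouses plus offspring aged <= 18:")
print(mats.household)
print("\npair labels:")
for i, j in [("twin1", "twin2"), ("twin1", "sib"), ("father", "twin1")]:
    print(f"  {i} - {j}: {classify_pair(ped, i, j)}")
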