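"""Map a cDNA substitution onto its protein consequence.

Builds a coding sequence whose residue 477 is histidine (codon CAC) and
annotates the substitution c.1429C>T: position 1429 is the first base of
codon 477, and C>T turns CAC (His) into TAC (Tyr).
"""

import autozyg as az

codons = ["ATG"] + ["GGC"] * 479
codons[476] = "CAC"  # residue 477
cds = az.CodingSequence(gene="CAMK2A", cds="".join(codons))

pc = az.annotate_cds_change(cds, position=1429, ref_base="C", alt_base="T")
print(f"c.1429C>T -> codon {pc.codon_index}: {pc.ref_aa} -> {pc.alt_aa}")
print(f"HGVS protein notation: {pc.hgvs_p()}")

# Recessive segregation of the same variant in a 7-member family: affected
# children homozygous T/T, parents obligate C/T carriers, unaffected
# children carriers or homozygous reference.
from autozyg.io import Individual, Pedigree, Sex, Status

family = Pedigree([
    Individual("I.1", None, None, Sex.MALE, Status.UNAFFECTED),
    Individual("I.2", None, None, Sex.FEMALE, Status.UNAFFECTED),
    Individual("II.1", "I.1", "I.2", Sex.UNKNOWN, Status.AFFECTED),
    Individual("II.2", "I.1", "I.2", Sex.UNKNOWN, Status.UNAFFECTED),
    Individual("II.3", "I.1", "I.2", Sex.UNKNOWN, Status.UNAFFECTED),
    Individual("II.4", "I.1", "I.2", Sex.UNKNOWN, Status.AFFECTED),
    Individual("II.5", "I.1", "I.2", Sex.UNKNOWN, Status.UNAFFECTED),
])
variant = az.Variant(
    chromosome="5", position_bp=149_602_589, gene="CAMK2A",
    cdna_change="c.1429C>T", protein_change="p.His477Tyr",
    member_genotypes={
        "I.1": ("C", "T"), "I.2": ("C", "T"),
        "II.1": ("T", "T"), "II.2": ("C", "T"), "II.3": ("C", "C"),
        "II.4": ("T", "T"), "II.5": ("C", "T"),
    },
)
print(f"segregates as fully penetrant recessive: "
      f"{az.check_recessive_segregation(variant, family)}")
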