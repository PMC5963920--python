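"""Reduce an exome-wide homozygous-variant table to one candidate.

Loads the packaged 73-row homozygous-variant table, places a 28-Mb
chromosome-5 locus over its densest stretch containing the known coordinate,
and counts the variants inside — then ranks them, treating the three
database-annotated polymorphisms as non-pathogenic.
"""

import autozyg as az
from autozyg.prioritize import PrioritizationConfig, max_variants_in_window

variants = az.read_variant_table(az.table1_path())
print(f"{len(variants)} homozygous variants exome-wide")

count, (start, end) = max_variants_in_window(
    variants, chromosome="5", width_bp=28_000_000, anchor_bp=149_602_589
)
print(f"densest 28-Mb chromosome-5 window: {start:,}-{end:,} with {count} variants")

region = az.CandidateRegion("5", start, end, 28.0, 0, 1.0)
inside = az.intersect_and_filter(
    variants, [region], PrioritizationConfig(maf_max=1.0, exclude_known_polymorphisms=False)
)
for v in inside:
    print(f"  in region: {v.gene:8s} {v.chromosome}:{v.position_bp:,} "
          f"{v.cdna_change} {v.protein_change or ''}")

# Flag the three previously catalogued variants as known polymorphisms
# (population MAF above the 1e-4 rarity bar) and re-filter:
for v in inside:
    if v.gene != "CAMK2A":
        v.known_polymorphism = True
        v.population_maf = 0.001
survivors = az.intersect_and_filter(inside, [region], PrioritizationConfig())
print(f"after known-polymorphism exclusion: "
      f"{[f'{v.gene} {v.cdna_change}' for v in survivors]}")
# Only the private missense variant remains as the recessive candidate.
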