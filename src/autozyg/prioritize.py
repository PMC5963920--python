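"""Recessive variant prioritization within mapped loci.

Reduces a table of homozygous exome variants to those inside candidate
autozygous regions, applies rarity filters (population MAF below a cutoff,
known-polymorphism exclusion), verifies recessive segregation against the
pedigree, and annotates coding consequences from a cDNA substitution.

A variant with no recorded population frequency *passes* the rarity filter:
for a private mutation, absence from the databases is itself the evidence of
rarity, and must not exclude the candidate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .exceptions import ConfigurationError, IncompleteSegregationData, ReferenceMismatchError
from .io import Pedigree, Status, Variant
from .mapping import CandidateRegion


@dataclass(frozen=True)
class PrioritizationConfig:
    """Rarity filters applied to in-region homozygous variants.

    ``maf_max`` is the exome-wide rarity cutoff (default 1%).
    ``known_polymorphism_maf`` is the separate, stricter threshold above
    which a database-annotated polymorphism is discarded as non-pathogenic
    (default 1e-4); the two thresholds are deliberately independent knobs.
    """

    maf_max: float = 0.01
    exclude_known_polymorphisms: bool = True
    known_polymorphism_maf: float = 1e-4
    require_zygosity: str = "hom"

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_max <= 1.0):
            raise ConfigurationError("maf_max must be in (0, 1]")


def intersect_and_filter(
    variants: list[Variant],
    regions: list[CandidateRegion],
    config: PrioritizationConfig,
) -> list[Variant]:
    """Variants inside any candidate region passing the rarity filters; order preserved."""
    out = []
    for v in variants:
        if not any(
            v.chromosome == r.chromosome and r.start_bp <= v.position_bp <= r.end_bp
            for r in regions
        ):
            continue
        if config.require_zygosity and v.zygosity_in_proband != config.require_zygosity:
            continue
        if v.population_maf is not None and v.population_maf >= config.maf_max:
            continue
        if (
            config.exclude_known_polymorphisms
            and v.known_polymorphism
            and (v.population_maf is None or v.population_maf > config.known_polymorphism_maf)
        ):
            continue
        out.append(v)
    return out


def check_recessive_segregation(variant: Variant, pedigree: Pedigree) -> bool:
    """Does the variant segregate as a fully penetrant recessive allele?

    True iff every affected individual is homozygous for the alternate
    allele, every genotyped parent of an affected is heterozygous, and no
    unaffected individual is homozygous alternate (heterozygous carriers are
    unaffected under the recessive model).  Raises
    :class:`IncompleteSegregationData` when any family member lacks a
    genotype — missing evidence, not counter-evidence.
    """
    genotypes = variant.member_genotypes or {}
    for ind in pedigree.individuals:
        if genotypes.get(ind.id) is None:
            raise IncompleteSegregationData(
                f"no genotype for family member {ind.id!r} at "
                f"{variant.chromosome}:{variant.position_bp}"
            )
    alt = variant.alt_allele
    if alt is None:
        raise IncompleteSegregationData(
            f"cannot determine alternate allele from {variant.cdna_change!r}"
        )

    def dose(iid: str) -> int:
        a, b = genotypes[iid]
        return (a == alt) + (b == alt)

    parent_ids = set()
    for ind in pedigree.individuals:
        if ind.status is Status.AFFECTED:
            if dose(ind.id) != 2:
                return False
            for p in pedigree.parents_of(ind.id):
                parent_ids.add(p.id)
    for pid in parent_ids:
        if dose(pid) != 1:
            return False
    for ind in pedigree.individuals:
        if ind.status is Status.UNAFFECTED and dose(ind.id) == 2:
            return False
    return True


def rank_variants(
    variants: list[Variant],
    pedigree: Pedigree | None = None,
) -> list[tuple[Variant, dict]]:
    """Order surviving variants: segregation-consistent first, then private
    (not a known polymorphism) first, then ascending MAF (absent MAF ranks as
    rarest), tie-broken by (chromosome, position).

    Returns (variant, annotation) pairs; the annotation records the
    segregation outcome (``True``/``False``/``None`` when unevaluable).
    """
    annotated = []
    for v in variants:
        seg: bool | None = None
        if pedigree is not None and v.member_genotypes:
            try:
                seg = check_recessive_segregation(v, pedigree)
            except IncompleteSegregationData:
                seg = None
        annotated.append((v, {"segregates": seg}))

    def key(item):
        v, ann = item
        seg = ann["segregates"]
        return (
            0 if seg is True else (1 if seg is None else 2),
            0 if not v.known_polymorphism else 1,
            -1.0 if v.population_maf is None else v.population_maf,
            v.chromosome,
            v.position_bp,
        )

    ranked = sorted(annotated, key=key)
    for rank, (_, ann) in enumerate(ranked, start=1):
        ann["rank"] = rank
    return ranked


def max_variants_in_window(
    variants: list[Variant],
    chromosome: str,
    width_bp: int,
    anchor_bp: int | None = None,
) -> tuple[int, tuple[int, int]]:
    """Densest closed window of ``width_bp`` on one chromosome.

    Returns (count, (start_bp, end_bp)) of the window containing the most
    variants; with ``anchor_bp`` the window is constrained to contain that
    position.  Used to place a mapped locus of known physical size over a
    variant table when its exact boundaries are not recorded.
    """
    positions = sorted(v.position_bp for v in variants if v.chromosome == chromosome)
    if anchor_bp is not None:
        lo, hi = anchor_bp - width_bp + 1, anchor_bp
    else:
        lo, hi = -(10**12), 10**12
    starts = sorted(
        {max(lo, min(hi, s)) for p in positions for s in (p, p - width_bp + 1)} | {lo}
    )
    best, best_win = 0, (lo, lo + width_bp - 1)
    for s in starts:
        count = sum(1 for p in positions if s <= p <= s + width_bp - 1)
        if count > best:
            best, best_win = count, (s, s + width_bp - 1)
    return best, best_win


# ---------------------------------------------------------------------------
# Coding-consequence annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodingSequence:
    """A gene's coding sequence (CDS), ATG..stop, length divisible by 3."""

    gene: str
    cds: str

    def __post_init__(self) -> None:
        cds = self.cds.upper()
        object.__setattr__(self, "cds", cds)
        if len(cds) % 3 != 0:
            raise ConfigurationError(f"CDS for {self.gene!r}: length {len(cds)} not divisible by 3")
        if not cds.startswith("ATG"):
            raise ConfigurationError(f"CDS for {self.gene!r} does not begin with ATG")
        if re.search(r"[^ACGT]", cds):
            raise ConfigurationError(f"CDS for {self.gene!r} contains non-ACGT characters")

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3


@dataclass(frozen=True)
class ProteinChange:
    ref_aa: str  # one-letter code
    codon_index: int  # 1-based residue number
    alt_aa: str  # one-letter code, '*' for stop

    def hgvs_p(self) -> str:
        """HGVS-style p. notation with three-letter residue names."""
        ref3 = seq3(self.ref_aa)
        alt3 = "Ter" if self.alt_aa == "*" else seq3(self.alt_aa)
        if self.ref_aa == self.alt_aa:
            return f"p.{ref3}{self.codon_index}="
        return f"p.{ref3}{self.codon_index}{alt3}"


def annotate_cds_change(
    cds: CodingSequence, position: int, ref_base: str, alt_base: str
) -> ProteinChange:
    """Protein consequence of a cDNA substitution ``c.<position><ref>><alt>``.

    ``position`` is the 1-based coordinate on the coding sequence; the codon
    index (residue number) is ``(position - 1) // 3 + 1``.
    """
    if not (1 <= position <= len(cds.cds)):
        raise IndexError(f"cDNA position {position} outside CDS of length {len(cds.cds)}")
    if cds.cds[position - 1] != ref_base.upper():
        raise ReferenceMismatchError(
            f"{cds.gene}: CDS has {cds.cds[position - 1]!r} at c.{position}, "
            f"not {ref_base!r}"
        )
    codon_index = (position - 1) // 3 + 1
    start = (codon_index - 1) * 3
    ref_codon = cds.cds[start : start + 3]
    offset = (position - 1) % 3
    alt_codon = ref_codon[:offset] + alt_base.upper() + ref_codon[offset + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    return ProteinChange(ref_aa=ref_aa, codon_index=codon_index, alt_aa=alt_aa)


def read_cds_fasta(path) -> dict[str, CodingSequence]:
    """One CDS per FASTA record; record ids are gene names."""
    from Bio import SeqIO

    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = CodingSequence(gene=rec.id, cds=str(rec.seq))
    return out
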