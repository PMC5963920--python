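"""Shared fixtures: tiny hand-built datasets and the packaged variant table."""

from __future__ import annotations

import numpy as np
import pytest

import autozyg as az
from autozyg.io import Individual, Marker, Pedigree, Sex, Status

# genotype shorthand used by build_dataset: one character per marker
_CALLS = {
    "A": ("A", "A"),
    "C": ("C", "C"),
    "G": ("G", "G"),
    "T": ("T", "T"),
    "e": ("A", "G"),  # heterozygous
    ".": ("0", "0"),  # missing
}


def build_dataset(
    sample_calls: dict[str, str],
    chromosome: str = "1",
    start_bp: int = 1_000_000,
    spacing_bp: int = 100_000,
) -> az.GenotypeDataset:
    """Dataset from per-sample genotype strings (see ``_CALLS`` shorthand)."""
    lengths = {len(s) for s in sample_calls.values()}
    assert len(lengths) == 1, "all samples need the same marker count"
    n = lengths.pop()
    markers = [
        Marker(id=f"m{i + 1}", chromosome=chromosome, position_bp=start_bp + i * spacing_bp)
        for i in range(n)
    ]
    samples = list(sample_calls)
    calls = np.empty((n, len(samples), 2), dtype="<U1")
    for si, s in enumerate(samples):
        for mi, ch in enumerate(sample_calls[s]):
            calls[mi, si] = _CALLS[ch]
    return az.GenotypeDataset(markers, samples, calls)


def sib_pedigree(affected: list[str], unaffected: list[str]) -> Pedigree:
    inds = [
        Individual("FA", None, None, Sex.MALE, Status.UNAFFECTED),
        Individual("MO", None, None, Sex.FEMALE, Status.UNAFFECTED),
    ]
    for iid in affected:
        inds.append(Individual(iid, "FA", "MO", Sex.UNKNOWN, Status.AFFECTED))
    for iid in unaffected:
        inds.append(Individual(iid, "FA", "MO", Sex.UNKNOWN, Status.UNAFFECTED))
    return Pedigree(inds)


@pytest.fixture(scope="session")
def table1_variants() -> list[az.Variant]:
    return az.read_variant_table(az.table1_path())


@pytest.fixture(scope="session")
def family7() -> Pedigree:
    """Seven-member nuclear family: parents, two affected and three
    unaffected children, mirroring a consanguineous sibship of five."""
    return Pedigree(
        [
            Individual("I.1", None, None, Sex.MALE, Status.UNAFFECTED),
            Individual("I.2", None, None, Sex.FEMALE, Status.UNAFFECTED),
            Individual("II.1", "I.1", "I.2", Sex.UNKNOWN, Status.AFFECTED),
            Individual("II.2", "I.1", "I.2", Sex.UNKNOWN, Status.UNAFFECTED),
            Individual("II.3", "I.1", "I.2", Sex.UNKNOWN, Status.UNAFFECTED),
            Individual("II.4", "I.1", "I.2", Sex.UNKNOWN, Status.AFFECTED),
            Individual("II.5", "I.1", "I.2", Sex.UNKNOWN, Status.UNAFFECTED),
        ]
    )


@pytest.fixture
def camk2a_variant(family7) -> az.Variant:
    """The chromosome-5 c.1429C>T missense candidate with a synthetic but
    recessive-consistent genotype assignment (the published pedigree figure's
    per-sibling genotypes are not machine-readable; carriers/homozygotes
    follow the recessive pattern it reports)."""
    return az.Variant(
        chromosome="5",
        position_bp=149_602_589,
        gene="CAMK2A",
        cdna_change="c.1429C>T",
        protein_change="p.His477Tyr",
        member_genotypes={
            "I.1": ("C", "T"),
            "I.2": ("C", "T"),
            "II.1": ("T", "T"),
            "II.2": ("C", "T"),
            "II.3": ("C", "C"),
            "II.4": ("T", "T"),
            "II.5": ("C", "T"),
        },
        population_maf=None,
        known_polymorphism=False,
    )


@pytest.fixture(scope="session")
def synthetic_camk2a_cds() -> az.CodingSequence:
    """Synthetic stand-in CDS: 477+ codons of glycine with codon 477 = CAC
    (histidine), so that c.1429 is the first base of residue 477."""
    codons = ["ATG"] + ["GGC"] * 479
    codons[476] = "CAC"  # residue 477
    return az.CodingSequence(gene="CAMK2A", cds="".join(codons))


def jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    lo, hi = max(a[0], b[0]), min(a[1], b[1])
    inter = max(0, hi - lo + 1)
    union = (a[1] - a[0] + 1) + (b[1] - b[0] + 1) - inter
    return inter / union
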