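"""Variant filtering, recessive segregation, coding-consequence annotation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import autozyg as az
from autozyg.exceptions import IncompleteSegregationData, ReferenceMismatchError
from autozyg.prioritize import PrioritizationConfig, max_variants_in_window


def _variant(chrom="5", pos=150_000_000, maf=None, known=False, zyg="hom", **kw):
    return az.Variant(
        chromosome=chrom,
        position_bp=pos,
        gene=kw.pop("gene", "G"),
        cdna_change=kw.pop("cdna_change", "c.10A>G"),
        population_maf=maf,
        known_polymorphism=known,
        zygosity_in_proband=zyg,
        **kw,
    )


WHOLE_GENOME = [az.CandidateRegion(str(c), 1, 300_000_000, 0, 0, 1.0) for c in
                list(range(1, 23))] + [az.CandidateRegion("X", 1, 300_000_000, 0, 0, 1.0)]


def test_densest_28mb_window_holds_four_variants(table1_variants):
    """A 28-Mb chromosome-5 locus containing the CAMK2A position can hold at
    most four of the table's variants."""
    count, window = max_variants_in_window(
        table1_variants, "5", 28_000_000, anchor_bp=149_602_589
    )
    assert count == 4
    region = az.CandidateRegion("5", window[0], window[1], 28.0, 0, 1.0)
    inside = az.intersect_and_filter(
        table1_variants, [region],
        PrioritizationConfig(exclude_known_polymorphisms=False, maf_max=1.0),
    )
    assert sorted(v.gene for v in inside) == ["C5orf4", "CAMK2A", "HAVCR1", "HAVCR1"]


def test_maf_filter():
    cfg = PrioritizationConfig(maf_max=0.01)
    common = _variant(maf=0.02)
    rare = _variant(pos=150_000_001, maf=0.001)
    absent = _variant(pos=150_000_002, maf=None)
    out = az.intersect_and_filter([common, rare, absent], WHOLE_GENOME, cfg)
    assert out == [rare, absent]  # absent MAF must pass: absence is evidence of rarity


def test_known_polymorphism_filter_uses_its_own_threshold():
    cfg = PrioritizationConfig(maf_max=0.01)
    flagged_common = _variant(maf=0.005, known=True)  # > 1e-4: dropped
    flagged_ultra_rare = _variant(pos=150_000_001, maf=5e-5, known=True)  # kept
    out = az.intersect_and_filter([flagged_common, flagged_ultra_rare], WHOLE_GENOME, cfg)
    assert out == [flagged_ultra_rare]


def test_empty_region_list_gives_empty_output(table1_variants):
    assert az.intersect_and_filter(table1_variants, [], PrioritizationConfig()) == []


def test_whole_genome_region_with_filters_off_is_identity(table1_variants):
    cfg = PrioritizationConfig(maf_max=1.0, exclude_known_polymorphisms=False)
    assert az.intersect_and_filter(table1_variants, WHOLE_GENOME, cfg) == table1_variants


def test_enabling_filters_never_increases_survivors(table1_variants):
    rng = np.random.default_rng(0)
    variants = []
    for v in table1_variants:
        variants.append(
            az.Variant(
                chromosome=v.chromosome, position_bp=v.position_bp, gene=v.gene,
                cdna_change=v.cdna_change,
                population_maf=float(rng.uniform(0, 0.05)) if rng.random() < 0.7 else None,
                known_polymorphism=bool(rng.random() < 0.4),
            )
        )
    lax = PrioritizationConfig(maf_max=1.0, exclude_known_polymorphisms=False)
    n_lax = len(az.intersect_and_filter(variants, WHOLE_GENOME, lax))
    for cfg in (
        PrioritizationConfig(maf_max=0.01, exclude_known_polymorphisms=False),
        PrioritizationConfig(maf_max=1.0, exclude_known_polymorphisms=True),
        PrioritizationConfig(),
    ):
        assert len(az.intersect_and_filter(variants, WHOLE_GENOME, cfg)) <= n_lax


# -- segregation ------------------------------------------------------------


def test_recessive_segregation_true(family7, camk2a_variant):
    assert az.check_recessive_segregation(camk2a_variant, family7) is True


@pytest.mark.parametrize(
    "member, genotype",
    [
        ("II.2", ("T", "T")),  # unaffected homozygous alternate
        ("II.1", ("C", "T")),  # affected heterozygous
        ("I.1", ("C", "C")),  # obligate carrier not heterozygous
    ],
)
def test_recessive_segregation_violations(family7, camk2a_variant, member, genotype):
    camk2a_variant.member_genotypes[member] = genotype
    assert az.check_recessive_segregation(camk2a_variant, family7) is False


def test_missing_genotype_is_not_false(family7, camk2a_variant):
    camk2a_variant.member_genotypes["II.3"] = None
    with pytest.raises(IncompleteSegregationData):
        az.check_recessive_segregation(camk2a_variant, family7)


def test_segregation_on_simulated_implant_and_perturbations():
    """The implanted causal variant always segregates; any single-genotype
    perturbation that breaks the recessive pattern is detected."""
    rng = np.random.default_rng(5)
    for seed in range(5):
        study = az.simulate_study(az.SimulationConfig(seed=seed, n_markers=500))
        v = study.causal_variant
        assert az.check_recessive_segregation(v, study.pedigree) is True
        alt = v.alt_allele
        ref = v.ref_allele
        for _ in range(10):
            member = str(rng.choice(study.pedigree.ids))
            original = v.member_genotypes[member]
            status = study.pedigree[member].status
            if status is az.Status.AFFECTED:
                v.member_genotypes[member] = (ref, alt)  # no longer hom-alt
            elif member in ("FA", "MO"):
                v.member_genotypes[member] = (ref, ref)  # carrier lost
            else:
                v.member_genotypes[member] = (alt, alt)  # unaffected hom-alt
            assert az.check_recessive_segregation(v, study.pedigree) is False
            v.member_genotypes[member] = original


def test_ranking_prefers_segregating_private_rare(family7, camk2a_variant):
    known = _variant(pos=149_000_000, maf=0.004, known=True, gene="K")
    rare = _variant(pos=149_100_000, maf=0.0001, known=False, gene="R")
    ranked = az.rank_variants([known, rare, camk2a_variant], family7)
    assert [v.gene for v, _ in ranked] == ["CAMK2A", "R", "K"]
    assert ranked[0][1]["segregates"] is True
    assert [a["rank"] for _, a in ranked] == [1, 2, 3]


# -- coding consequence -----------------------------------------------------


def test_his477tyr(synthetic_camk2a_cds):
    pc = az.annotate_cds_change(synthetic_camk2a_cds, 1429, "C", "T")
    assert (pc.ref_aa, pc.codon_index, pc.alt_aa) == ("H", 477, "Y")
    assert pc.hgvs_p() == "p.His477Tyr"


def test_first_position_is_codon_one(synthetic_camk2a_cds):
    pc = az.annotate_cds_change(synthetic_camk2a_cds, 1, "A", "G")
    assert pc.codon_index == 1


def test_synonymous_third_base(synthetic_camk2a_cds):
    # codon 2 is GGC (Gly); GGC -> GGT is synonymous
    pc = az.annotate_cds_change(synthetic_camk2a_cds, 6, "C", "T")
    assert pc.codon_index == 2 and pc.ref_aa == pc.alt_aa == "G"
    assert pc.hgvs_p() == "p.Gly2="


def test_reference_mismatch_and_bounds(synthetic_camk2a_cds):
    with pytest.raises(ReferenceMismatchError):
        az.annotate_cds_change(synthetic_camk2a_cds, 1429, "G", "T")
    with pytest.raises(IndexError):
        az.annotate_cds_change(synthetic_camk2a_cds, 10**6, "A", "G")


@settings(derandomize=True, max_examples=100, deadline=None)
@given(position=st.integers(1, 1440))
def test_codon_index_brackets_position(synthetic_camk2a_cds, position):
    ref = synthetic_camk2a_cds.cds[position - 1]
    pc = az.annotate_cds_change(synthetic_camk2a_cds, position, ref, "A")
    assert 3 * (pc.codon_index - 1) < position <= 3 * pc.codon_index


def test_cds_fasta_reader(tmp_path):
    p = tmp_path / "cds.fa"
    p.write_text(">GENE1\nATGGGCTAA\n")
    cds = az.read_cds_fasta(p)["GENE1"]
    assert cds.n_codons == 3
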