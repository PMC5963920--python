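"""Pedigree simulator: transmission model, construction guarantees, determinism."""

import filecmp

import numpy as np
import pytest

import autozyg as az
from autozyg.io import GeneticMap
from autozyg.simulate import Haplotype, draw_crossover_positions, meiosis


def _hap(alleles, origin, chrom="1"):
    n = len(alleles)
    return Haplotype(
        chromosome=chrom,
        positions_bp=np.linspace(1, 10_000_000, n).astype(int),
        alleles=np.asarray(alleles, dtype=np.int8),
        origins=np.full(n, origin, dtype=np.int16),
    )


def test_zero_genetic_length_transmits_one_haplotype_intact():
    gmap = GeneticMap(fallback_rate_cM_per_Mb=1e-12)
    h0, h1 = _hap([0] * 50, 0), _hap([1] * 50, 1)
    rng = np.random.default_rng(0)
    for _ in range(10):
        g = meiosis((h0, h1), gmap, rng)
        assert len(set(g.origins.tolist())) == 1


def test_crossover_count_matches_poisson_mean():
    """Mean crossover count over 10,000 draws at 1 Morgan is 1.0 within
    three standard errors (Haldane model)."""
    rng = np.random.default_rng(123)
    counts = np.array([len(draw_crossover_positions(100.0, rng)) for _ in range(10_000)])
    se = counts.std(ddof=1) / np.sqrt(len(counts))
    assert abs(counts.mean() - 1.0) <= 3 * se


def test_meiosis_deterministic_under_seed():
    gmap = GeneticMap()
    h0, h1 = _hap(np.arange(50) % 2, 0), _hap((np.arange(50) + 1) % 2, 1)
    a = meiosis((h0, h1), gmap, np.random.default_rng(42))
    b = meiosis((h0, h1), gmap, np.random.default_rng(42))
    assert np.array_equal(a.alleles, b.alleles) and np.array_equal(a.origins, b.origins)


def test_same_seed_gives_byte_identical_files(tmp_path):
    cfg = az.SimulationConfig(seed=9, n_markers=800)
    az.simulate_study(cfg).write(tmp_path / "a")
    az.simulate_study(cfg).write(tmp_path / "b")
    for name in ("study.ped", "study.map", "genetic_map.tsv", "variants.tsv", "truth.json"):
        assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False), name


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_causal_variant_construction_guarantees(seed):
    study = az.simulate_study(az.SimulationConfig(seed=seed, n_markers=1000))
    v = study.causal_variant
    alt = v.alt_allele
    for ind in study.pedigree.individuals:
        g = v.member_genotypes[ind.id]
        dose = (g[0] == alt) + (g[1] == alt)
        if ind.status is az.Status.AFFECTED:
            assert dose == 2
        elif ind.id in ("FA", "MO"):
            assert dose == 1
        else:
            assert dose < 2
    chrom, s, e = study.truth_regions[0]
    assert chrom == v.chromosome and s <= v.position_bp <= e


def test_dataset_satisfies_io_invariants():
    study = az.simulate_study(az.SimulationConfig(seed=3, n_markers=1000))
    ds = study.dataset
    for a, b in zip(ds.markers, ds.markers[1:]):
        if a.chromosome == b.chromosome:
            assert b.position_bp > a.position_bp
    assert all(s in study.pedigree for s in ds.samples)


def test_mendelian_consistency_without_error():
    """Absent injected error, every child call is explicable by one allele
    from each parent."""
    study = az.simulate_study(
        az.SimulationConfig(seed=5, n_markers=1500, genotyping_error_rate=0.0, missing_rate=0.0)
    )
    ds = study.dataset
    fa = ds.calls_for("FA")
    mo = ds.calls_for("MO")
    for child in ("C1", "C2", "C3", "C4", "C5"):
        cc = ds.calls_for(child)
        for i in range(ds.n_markers):
            a, b = cc[i]
            ok = (a in fa[i] and b in mo[i]) or (b in fa[i] and a in mo[i])
            assert ok, f"{child} marker {i}: {cc[i]} from {fa[i]} x {mo[i]}"


def test_truth_region_inside_each_affected_roh_when_noise_free():
    study = az.simulate_study(
        az.SimulationConfig(seed=8, genotyping_error_rate=0.0, missing_rate=0.0)
    )
    chrom, s, e = study.truth_regions[0]
    for ind in study.pedigree.affected():
        segs = az.call_roh(study.dataset, ind.id, az.ROHParams())
        assert any(
            seg.chromosome == chrom and seg.start_bp <= s and seg.end_bp >= e
            for seg in segs
        )


def test_truth_region_meets_minimum_genetic_length():
    for seed in (0, 1, 2, 3):
        cfg = az.SimulationConfig(seed=seed, n_markers=1000)
        study = az.simulate_study(cfg)
        chrom, s, e = study.truth_regions[0]
        cm = az.interpolate_genetic_position(study.genetic_map, chrom, e) - \
            az.interpolate_genetic_position(study.genetic_map, chrom, s)
        assert cm >= cfg.min_truth_length_cM


def test_autozygous_fraction_matches_first_cousin_inbreeding():
    """Mean autozygous genome fraction of independent first-cousin offspring
    approaches F = 1/16."""
    fr = az.autozygous_fraction_samples(200, az.SimulationConfig(n_markers=600), seed=21)
    se = fr.std(ddof=1) / np.sqrt(len(fr))
    assert abs(fr.mean() - 1 / 16) <= 3 * se


def test_invalid_configs_raise():
    with pytest.raises(az.ConfigurationError):
        az.SimulationConfig(causal_locus=("1", 10**12))
    with pytest.raises(az.ConfigurationError):
        az.SimulationConfig(causal_locus=("9", 100))
    with pytest.raises(az.ConfigurationError):
        az.SimulationConfig(missing_rate=1.5)
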