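"""Shared-autozygosity delineation, unaffected exclusion, length filtering."""

import numpy as np
import pytest

import autozyg as az
from autozyg.exceptions import ConfigurationError
from autozyg.mapping import MappingConfig
from autozyg.roh import ROHParams

from conftest import build_dataset, jaccard, sib_pedigree


def relaxed(**kw):
    defaults = dict(min_markers=1, max_het_in_run=0, max_missing_in_run=0, min_length_bp=0)
    defaults.update(kw)
    return ROHParams(**defaults)


def test_identical_homozygous_siblings_give_one_region():
    ds = build_dataset({"A1": "A" * 50, "A2": "A" * 50})
    ped = sib_pedigree(["A1", "A2"], [])
    (r,) = az.shared_autozygous_regions(ds, ped, relaxed())
    assert (r.start_bp, r.end_bp) == (ds.markers[0].position_bp, ds.markers[-1].position_bp)
    assert r.n_markers == 50 and r.concordance == 1.0


def test_discordant_homozygotes_split_region():
    """Affecteds homozygous for opposite alleles at one marker: identity is
    disproved there, yielding two regions."""
    a1 = "A" * 24 + "A" + "A" * 25
    a2 = "A" * 24 + "G" + "A" * 25
    ds = build_dataset({"A1": a1, "A2": a2})
    ped = sib_pedigree(["A1", "A2"], [])
    regions = az.shared_autozygous_regions(ds, ped, relaxed())
    assert len(regions) == 2
    assert regions[0].end_bp == ds.markers[23].position_bp
    assert regions[1].start_bp == ds.markers[25].position_bp


def test_heterozygous_affected_gives_nothing():
    ds = build_dataset({"A1": "e" * 50, "A2": "A" * 50})
    ped = sib_pedigree(["A1", "A2"], [])
    assert az.shared_autozygous_regions(ds, ped, relaxed()) == []


def test_no_affected_raises():
    ds = build_dataset({"U1": "A" * 10})
    ped = sib_pedigree([], ["U1"])
    with pytest.raises(ConfigurationError):
        az.shared_autozygous_regions(ds, ped, relaxed())


def test_region_requires_roh_support_of_every_affected():
    # A2's run is broken mid-way by a stretch of hets: the region must not
    # extend past A2's supported markers
    a1 = "A" * 60
    a2 = "A" * 30 + "e" * 5 + "A" * 25
    ds = build_dataset({"A1": a1, "A2": a2})
    ped = sib_pedigree(["A1", "A2"], [])
    regions = az.shared_autozygous_regions(ds, ped, relaxed(min_markers=10))
    assert [(r.n_markers) for r in regions] == [30, 25]


# -- unaffected exclusion ---------------------------------------------------


def _excl_config(**roh_kw):
    return MappingConfig(min_genetic_length_cM=0.001, roh_params=relaxed(**roh_kw))


def test_subtract_mode_trims_shared_interval():
    """Candidate spanning markers 0..59; unaffected homozygous-identical over
    markers 20..34: two flanking candidates remain."""
    calls = {"A1": "A" * 60, "A2": "A" * 60, "U1": "e" * 20 + "A" * 15 + "e" * 25}
    ds = build_dataset(calls)
    ped = sib_pedigree(["A1", "A2"], ["U1"])
    params = relaxed()
    regions = az.shared_autozygous_regions(ds, ped, params)
    out = az.exclude_unaffected(regions, ds, ped, _excl_config())
    assert [(r.start_bp, r.end_bp) for r in out] == [
        (ds.markers[0].position_bp, ds.markers[19].position_bp),
        (ds.markers[35].position_bp, ds.markers[59].position_bp),
    ]


def test_no_overlap_leaves_regions_unchanged():
    calls = {"A1": "A" * 40, "A2": "A" * 40, "U1": "e" * 40}
    ds = build_dataset(calls)
    ped = sib_pedigree(["A1", "A2"], ["U1"])
    regions = az.shared_autozygous_regions(ds, ped, relaxed())
    assert az.exclude_unaffected(regions, ds, ped, _excl_config()) == regions


def test_fully_shared_candidate_is_removed():
    calls = {"A1": "A" * 40, "A2": "A" * 40, "U1": "A" * 40}
    ds = build_dataset(calls)
    ped = sib_pedigree(["A1", "A2"], ["U1"])
    regions = az.shared_autozygous_regions(ds, ped, relaxed())
    assert az.exclude_unaffected(regions, ds, ped, _excl_config()) == []


def test_opposite_allele_homozygosity_does_not_exclude():
    """An unaffected homozygous for the *other* allele does not disprove
    linkage in the default same-allele mode, but does in any_hom mode."""
    calls = {"A1": "A" * 40, "A2": "A" * 40, "U1": "G" * 40}
    ds = build_dataset(calls)
    ped = sib_pedigree(["A1", "A2"], ["U1"])
    regions = az.shared_autozygous_regions(ds, ped, relaxed())
    assert az.exclude_unaffected(regions, ds, ped, _excl_config()) == regions
    strict = MappingConfig(
        min_genetic_length_cM=0.001, roh_params=relaxed(), unaffected_match="any_hom"
    )
    assert az.exclude_unaffected(regions, ds, ped, strict) == []


def test_drop_mode_discards_overlapped_candidates():
    calls = {"A1": "A" * 60, "A2": "A" * 60, "U1": "e" * 20 + "A" * 15 + "e" * 25}
    ds = build_dataset(calls)
    ped = sib_pedigree(["A1", "A2"], ["U1"])
    regions = az.shared_autozygous_regions(ds, ped, relaxed())
    cfg = MappingConfig(
        min_genetic_length_cM=0.001, roh_params=relaxed(), exclusion_mode="drop"
    )
    assert az.exclude_unaffected(regions, ds, ped, cfg) == []


def test_subtraction_matches_marker_oracle():
    """Random exclusion configurations: subtract-mode output equals direct
    closed-interval subtraction on the marker grid."""
    rng = np.random.default_rng(17)
    for _ in range(200):
        n = int(rng.integers(20, 80))
        # unaffected homozygous-identical on random intervals
        u = np.full(n, "e", dtype="<U1")
        for _k in range(int(rng.integers(0, 4))):
            a = int(rng.integers(0, n))
            b = min(n - 1, a + int(rng.integers(1, 15)))
            u[a : b + 1] = "A"
        calls = {"A1": "A" * n, "A2": "A" * n, "U1": "".join(u)}
        ds = build_dataset(calls)
        ped = sib_pedigree(["A1", "A2"], ["U1"])
        regions = az.shared_autozygous_regions(ds, ped, relaxed())
        out = az.exclude_unaffected(regions, ds, ped, _excl_config())
        # oracle: contiguous runs of non-excluded markers
        keep = u != "A"
        idx = np.flatnonzero(keep)
        expected = []
        if idx.size:
            splits = np.flatnonzero(np.diff(idx) > 1)
            for run in np.split(idx, splits + 1):
                expected.append(
                    (ds.markers[run[0]].position_bp, ds.markers[run[-1]].position_bp)
                )
        assert [(r.start_bp, r.end_bp) for r in out] == expected


# -- genetic length filter --------------------------------------------------


def _region(start_mb, end_mb):
    return az.CandidateRegion("1", int(start_mb * 1e6), int(end_mb * 1e6), 0.0, 10, 1.0)


def test_length_filter_boundary_convention():
    gmap = az.GeneticMap()  # 1 cM/Mb
    cfg = MappingConfig(min_genetic_length_cM=5.0)
    kept = az.filter_by_genetic_length(
        [_region(10, 14.9), _region(20, 25), _region(40, 68)], gmap, cfg
    )
    assert [(r.start_bp, r.end_bp) for r in kept] == [
        (20_000_000, 25_000_000),
        (40_000_000, 68_000_000),
    ]
    assert kept[0].genetic_length_cM == pytest.approx(5.0)
    assert kept[1].genetic_length_cM == pytest.approx(28.0)


def test_filter_output_sorted():
    gmap = az.GeneticMap()
    cfg = MappingConfig(min_genetic_length_cM=5.0)
    regions = [
        az.CandidateRegion("2", 1_000_000, 20_000_000, 0, 10, 1.0),
        az.CandidateRegion("1", 5_000_000, 30_000_000, 0, 10, 1.0),
    ]
    out = az.filter_by_genetic_length(regions, gmap, cfg)
    assert [r.chromosome for r in out] == ["1", "2"]


# -- pipeline-level properties ---------------------------------------------


def _covered(regions):
    return sum(r.length_bp for r in regions)


def test_each_stage_never_grows_covered_bp():
    for seed in range(5):
        study = az.simulate_study(az.SimulationConfig(seed=seed, n_markers=2000))
        cfg = MappingConfig()
        shared = az.shared_autozygous_regions(study.dataset, study.pedigree, cfg.roh_params)
        excl = az.exclude_unaffected(shared, study.dataset, study.pedigree, cfg)
        final = az.filter_by_genetic_length(excl, study.genetic_map, cfg)
        assert _covered(excl) <= _covered(shared)
        assert _covered(final) <= _covered(excl)


def test_surviving_regions_lie_in_affected_roh_coverage():
    study = az.simulate_study(az.SimulationConfig(seed=2, n_markers=2000))
    cfg = MappingConfig()
    regions, _ = az.map_regions(study.dataset, study.pedigree, study.genetic_map, cfg)
    for ind in study.pedigree.affected():
        segs = az.call_roh(study.dataset, ind.id, cfg.roh_params)
        for r in regions:
            covered = [
                s
                for s in segs
                if s.chromosome == r.chromosome
                and s.start_bp <= r.end_bp
                and s.end_bp >= r.start_bp
            ]
            # every region marker is inside the union of this affected's runs
            span = sorted((s.start_bp, s.end_bp) for s in covered)
            assert span and span[0][0] <= r.start_bp
            reach = span[0][1]
            for a, b in span[1:]:
                if a > reach + 1:
                    break
                reach = max(reach, b)
            assert reach >= r.end_bp


def test_single_run_containment_mode():
    """In single_run mode every surviving region is contained in one
    qualifying run of every affected individual."""
    study = az.simulate_study(
        az.SimulationConfig(seed=4, n_markers=2000, genotyping_error_rate=0.0, missing_rate=0.0)
    )
    cfg = MappingConfig(containment="single_run")
    regions, _ = az.map_regions(study.dataset, study.pedigree, study.genetic_map, cfg)
    assert regions
    for ind in study.pedigree.affected():
        segs = az.call_roh(study.dataset, ind.id, cfg.roh_params)
        for r in regions:
            assert any(
                s.chromosome == r.chromosome
                and s.start_bp <= r.start_bp
                and s.end_bp >= r.end_bp
                for s in segs
            )


def test_mapping_recovers_truth_region_noise_free():
    study = az.simulate_study(
        az.SimulationConfig(seed=6, genotyping_error_rate=0.0, missing_rate=0.0)
    )
    regions, _ = az.map_regions(
        study.dataset, study.pedigree, study.genetic_map, MappingConfig()
    )
    chrom, s, e = study.truth_regions[0]
    best = max(
        (jaccard((r.start_bp, r.end_bp), (s, e)) for r in regions if r.chromosome == chrom),
        default=0.0,
    )
    assert best >= 0.95
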