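"""Candidate autozygous locus delineation for a recessive trait.

The mapping assumes the trait is autosomal recessive and identical by
descent through a consanguineous loop: every affected sibling must be
homozygous for the *same* allele across the locus, and any unaffected member
sharing the same homozygous stretch disproves that stretch.  Biallelic SNP
arrays cannot distinguish identity-by-descent from identity-by-state
directly, so the operational surrogate is: shared allele-identical
homozygosity, refined by exclusion against unaffected members, and a minimum
genetic length (default 5 cM) to discard short chance runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError
from .io import GeneticMap, GenotypeDataset, Pedigree
from .roh import HET, HOM, MISS, ROHParams, call_roh, maximal_runs


@dataclass(frozen=True)
class CandidateRegion:
    chromosome: str
    start_bp: int
    end_bp: int
    genetic_length_cM: float = 0.0
    n_markers: int = 0
    concordance: float = 1.0

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass(frozen=True)
class MappingConfig:
    """Parameters of the locus-delineation pipeline.

    ``containment`` controls how affected ROH support is required: ``union``
    (default) accepts a region if every in-region marker lies in *some*
    qualifying run of every affected — robust to single bad calls splitting
    one long autozygous tract into overlapping runs; ``single_run`` demands
    one run of each affected covering the whole region.  ``unaffected_match``
    selects whether exclusion requires the unaffected member to match the
    affecteds' shared allele (``same_allele``, default) or merely be
    homozygous (``any_hom``).
    """

    min_genetic_length_cM: float = 5.0
    roh_params: ROHParams = field(default_factory=ROHParams)
    exclusion_mode: str = "subtract"  # or "drop"
    containment: str = "union"  # or "single_run"
    unaffected_match: str = "same_allele"  # or "any_hom"
    require_affected_identity: bool = True

    def __post_init__(self) -> None:
        if self.min_genetic_length_cM <= 0:
            raise ConfigurationError("min_genetic_length_cM must be > 0")
        if self.exclusion_mode not in {"subtract", "drop"}:
            raise ConfigurationError(f"unknown exclusion_mode {self.exclusion_mode!r}")
        if self.containment not in {"union", "single_run"}:
            raise ConfigurationError(f"unknown containment {self.containment!r}")
        if self.unaffected_match not in {"same_allele", "any_hom"}:
            raise ConfigurationError(f"unknown unaffected_match {self.unaffected_match!r}")


def _consensus_classes(
    dataset: GenotypeDataset, sample_ids: list[str], require_identity: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Joint call class across samples plus an identity-violation mask.

    The class is HOM iff all samples are homozygous for one shared allele,
    MISS if any sample is missing, HET otherwise.  A marker is a *violation*
    when two samples are homozygous for different alleles: unlike an
    isolated heterozygous call (tolerated by the run machinery as a likely
    genotyping error), discordant homozygotes positively disprove shared
    descent and always split a candidate region.
    """
    n = dataset.n_markers
    cls = np.full(n, HOM, dtype=np.int8)
    any_het = np.zeros(n, dtype=bool)
    any_miss = np.zeros(n, dtype=bool)
    discordant = np.zeros(n, dtype=bool)
    first_allele: np.ndarray | None = None
    for s in sample_ids:
        any_het |= dataset.is_het(s)
        any_miss |= dataset.is_missing(s)
        if require_identity:
            hom = dataset.is_hom(s)
            allele = np.where(hom, dataset.calls_for(s)[:, 0], "")
            if first_allele is None:
                first_allele = allele
            else:
                both = (first_allele != "") & (allele != "")
                discordant |= both & (first_allele != allele)
    cls[any_het | discordant] = HET
    cls[any_miss] = MISS
    return cls, discordant


def _coverage_mask(dataset: GenotypeDataset, sample_id: str, params: ROHParams, chrom: str) -> np.ndarray:
    """Boolean per-marker mask of the union of qualifying ROH runs on one chromosome."""
    sl = dataset.chromosome_slice(chrom)
    n = sl.stop - sl.start
    mask = np.zeros(n, dtype=bool)
    for seg in call_roh(dataset, sample_id, params):
        if seg.chromosome == chrom:
            mask[seg.start_idx : seg.end_idx + 1] = True
    return mask


def shared_autozygous_regions(
    dataset: GenotypeDataset,
    pedigree: Pedigree,
    params: ROHParams,
    containment: str = "union",
    require_identity: bool = True,
) -> list[CandidateRegion]:
    """Maximal regions homozygous-identical across all affected individuals.

    Regions are supported by qualifying ROH runs of every affected, split at
    identity violations (two affecteds homozygous for different alleles), and
    trimmed so that both ends fall on markers where all affecteds are
    homozygous for the same allele.
    """
    affected = [i.id for i in pedigree.affected() if i.id in dataset.samples]
    if not affected:
        raise ConfigurationError("no affected individuals with genotypes in the dataset")

    consensus, violation = _consensus_classes(dataset, affected, require_identity)
    regions: list[CandidateRegion] = []
    for chrom in dataset.chromosomes():
        sl = dataset.chromosome_slice(chrom)
        pos = np.array([m.position_bp for m in dataset.markers[sl]])
        cons = consensus[sl]
        viol = violation[sl]
        if containment == "union":
            support = np.ones(sl.stop - sl.start, dtype=bool)
            for s in affected:
                support &= _coverage_mask(dataset, s, params, chrom)
            intervals = _supported_consensus_runs(cons, support & ~viol)
        else:
            intervals = _single_run_regions(dataset, affected, params, chrom, cons, viol)
        for a, b in intervals:
            n_markers = b - a + 1
            span = int(pos[b] - pos[a] + 1)
            if n_markers < params.min_markers or span < params.min_length_bp:
                continue
            window = cons[a : b + 1]
            informative = int((window != MISS).sum())
            conc = float((window == HOM).sum() / informative) if informative else 0.0
            regions.append(
                CandidateRegion(
                    chromosome=chrom,
                    start_bp=int(pos[a]),
                    end_bp=int(pos[b]),
                    n_markers=n_markers,
                    concordance=conc,
                )
            )
    return regions


def _supported_consensus_runs(cons: np.ndarray, ok: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True stretches of ``ok``, ends snapped inward to consensus-HOM markers."""
    n = len(cons)
    intervals: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and ok[j + 1]:
            j += 1
        # snap ends inward to consensus-homozygous markers
        a, b = i, j
        while a <= b and cons[a] != HOM:
            a += 1
        while b >= a and cons[b] != HOM:
            b -= 1
        if a <= b:
            intervals.append((a, b))
        i = j + 1
    return intervals


def _single_run_regions(
    dataset: GenotypeDataset,
    affected: list[str],
    params: ROHParams,
    chrom: str,
    cons: np.ndarray,
    viol: np.ndarray,
) -> list[tuple[int, int]]:
    """Literal containment mode: intersect single runs of every affected.

    Takes all pairwise (tuple-wise) intersections of one qualifying run per
    affected, splits them at consensus violations, and keeps maximal results.
    """
    sl = dataset.chromosome_slice(chrom)
    per_sample: list[list[tuple[int, int]]] = []
    for s in affected:
        runs = [
            (seg.start_idx, seg.end_idx)
            for seg in call_roh(dataset, s, params)
            if seg.chromosome == chrom
        ]
        if not runs:
            return []
        per_sample.append(runs)

    candidates: list[tuple[int, int]] = [(0, sl.stop - sl.start - 1)]
    for runs in per_sample:
        nxt = []
        for a, b in candidates:
            for ra, rb in runs:
                lo, hi = max(a, ra), min(b, rb)
                if lo <= hi:
                    nxt.append((lo, hi))
        candidates = nxt
    # split at identity violations, snap ends to consensus hom
    pieces: list[tuple[int, int]] = []
    for a, b in candidates:
        for pa, pb in _supported_consensus_runs(cons[a : b + 1], ~viol[a : b + 1]):
            pieces.append((a + pa, a + pb))
    # maximal, deduplicated
    pieces = sorted(set(pieces))
    out: list[tuple[int, int]] = []
    for a, b in pieces:
        if any(a2 <= a and b <= b2 and (a2, b2) != (a, b) for a2, b2 in pieces):
            continue
        out.append((a, b))
    return out


def exclude_unaffected(
    regions: list[CandidateRegion],
    dataset: GenotypeDataset,
    pedigree: Pedigree,
    config: MappingConfig,
) -> list[CandidateRegion]:
    """Remove candidate stretches shared homozygously with any unaffected member.

    For each unaffected individual, markers where they are homozygous for the
    affecteds' shared allele (or merely homozygous, in ``any_hom`` mode) are
    assembled into qualifying runs with the same tolerances as ROH calling;
    the union of those runs is subtracted from each candidate (``subtract``)
    or used to discard overlapping candidates wholesale (``drop``).
    """
    unaffected = [i.id for i in pedigree.unaffected() if i.id in dataset.samples]
    if not unaffected or not regions:
        return list(regions)
    affected = [i.id for i in pedigree.affected() if i.id in dataset.samples]
    params = config.roh_params

    shared_allele = _shared_hom_allele(dataset, affected)

    out: list[CandidateRegion] = []
    for region in regions:
        sl = dataset.chromosome_slice(region.chromosome)
        pos = np.array([m.position_bp for m in dataset.markers[sl]])
        in_region = (pos >= region.start_bp) & (pos <= region.end_bp)
        idx = np.flatnonzero(in_region)
        if idx.size == 0:
            continue
        a0, b0 = int(idx[0]), int(idx[-1])
        excluded = np.zeros(b0 - a0 + 1, dtype=bool)
        for u in unaffected:
            cls = _match_classes(dataset, u, shared_allele, config.unaffected_match)[sl][a0 : b0 + 1]
            for ra, rb in maximal_runs(cls, params.max_het_in_run, params.max_missing_in_run):
                n_markers = rb - ra + 1
                span = int(pos[a0 + rb] - pos[a0 + ra] + 1)
                if n_markers < params.min_markers or span < params.min_length_bp:
                    continue
                excluded[ra : rb + 1] = True
        if not excluded.any():
            out.append(region)
            continue
        if config.exclusion_mode == "drop":
            continue
        cls, viol = _consensus_classes(dataset, affected, config.require_affected_identity)
        cons = cls[sl][a0 : b0 + 1]
        keep = ~excluded & ~viol[sl][a0 : b0 + 1]
        for pa, pb in _supported_consensus_runs(cons, keep):
            n_markers = pb - pa + 1
            span = int(pos[a0 + pb] - pos[a0 + pa] + 1)
            if n_markers < params.min_markers or span < params.min_length_bp:
                continue
            window = cons[pa : pb + 1]
            informative = int((window != MISS).sum())
            conc = float((window == HOM).sum() / informative) if informative else 0.0
            out.append(
                CandidateRegion(
                    chromosome=region.chromosome,
                    start_bp=int(pos[a0 + pa]),
                    end_bp=int(pos[a0 + pb]),
                    n_markers=n_markers,
                    concordance=conc,
                )
            )
    return out


def _shared_hom_allele(dataset: GenotypeDataset, affected: list[str]) -> np.ndarray:
    """Per-marker allele for which all affecteds are homozygous; '' where undefined."""
    allele: np.ndarray | None = None
    for s in affected:
        hom = dataset.is_hom(s)
        cur = np.where(hom, dataset.calls_for(s)[:, 0], "")
        allele = cur if allele is None else np.where(allele == cur, allele, "")
    if allele is None:
        allele = np.full(dataset.n_markers, "", dtype="<U1")
    return allele


def _match_classes(
    dataset: GenotypeDataset, sample_id: str, shared_allele: np.ndarray, mode: str
) -> np.ndarray:
    """Call classes for exclusion runs: HOM where the unaffected matches."""
    n = dataset.n_markers
    cls = np.full(n, HET, dtype=np.int8)
    hom = dataset.is_hom(sample_id)
    if mode == "any_hom":
        match = hom
    else:
        match = hom & (shared_allele != "") & (dataset.calls_for(sample_id)[:, 0] == shared_allele)
        # markers without a defined shared allele carry no evidence either way
        cls[shared_allele == ""] = MISS
    cls[match] = HOM
    cls[dataset.is_missing(sample_id)] = MISS
    return cls


def filter_by_genetic_length(
    regions: list[CandidateRegion],
    gmap: GeneticMap,
    config: MappingConfig,
) -> list[CandidateRegion]:
    """Annotate genetic lengths and keep regions of at least the minimum cM."""
    out = []
    for r in regions:
        cm = float(gmap.interpolate(r.chromosome, r.end_bp)) - float(
            gmap.interpolate(r.chromosome, r.start_bp)
        )
        if cm >= config.min_genetic_length_cM:
            out.append(
                CandidateRegion(
                    chromosome=r.chromosome,
                    start_bp=r.start_bp,
                    end_bp=r.end_bp,
                    genetic_length_cM=cm,
                    n_markers=r.n_markers,
                    concordance=r.concordance,
                )
            )
    return sorted(out, key=lambda r: (r.chromosome, r.start_bp))
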