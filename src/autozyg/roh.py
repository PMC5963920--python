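"""Runs of homozygosity (ROH) from array genotypes.

A run is a maximal stretch of consecutive markers that starts and ends on a
homozygous call and contains at most ``max_het_in_run`` heterozygous and
``max_missing_in_run`` missing calls; runs shorter than ``min_markers``
markers or spanning less than ``min_length_bp`` are discarded.  "Maximal"
means no qualifying stretch strictly contains it.  With nonzero tolerances
two maximal runs can overlap (e.g. ``hom het hom het hom`` with one het
allowed yields two runs sharing the middle marker); at zero tolerance runs
are provably disjoint.  This hard-count definition is deliberately simple —
it is exactly checkable against brute-force enumeration — in contrast to the
sliding-window density heuristics of array QC tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError
from .io import GenotypeDataset

HOM, HET, MISS = 0, 1, 2


@dataclass(frozen=True)
class ROHParams:
    """Run-calling tolerances.

    Defaults assume a dense array with ~99% call rate: one heterozygous call
    (genotyping error) and two missing calls tolerated per run, at least 25
    markers and 1 Mb of physical span.
    """

    min_markers: int = 25
    max_het_in_run: int = 1
    max_missing_in_run: int = 2
    min_length_bp: int = 1_000_000

    def __post_init__(self) -> None:
        if self.min_markers < 1:
            raise ConfigurationError("min_markers must be >= 1")
        if self.max_het_in_run < 0 or self.max_missing_in_run < 0 or self.min_length_bp < 0:
            raise ConfigurationError("ROH tolerances must be non-negative")


@dataclass(frozen=True)
class ROHSegment:
    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_markers: int
    n_het: int
    n_missing: int
    # marker indices into the chromosome-local grid, inclusive
    start_idx: int = field(compare=False, default=-1)
    end_idx: int = field(compare=False, default=-1)


def classify_calls(dataset: GenotypeDataset, sample_id: str) -> np.ndarray:
    """Per-marker call class for one sample: HOM=0, HET=1, MISS=2."""
    cls = np.full(dataset.n_markers, MISS, dtype=np.int8)
    cls[dataset.is_hom(sample_id)] = HOM
    cls[dataset.is_het(sample_id)] = HET
    return cls


def maximal_runs(cls: np.ndarray, max_het: int, max_missing: int) -> list[tuple[int, int]]:
    """All maximal qualifying runs over a call-class vector, as (start, end) index pairs.

    Two-pointer sweep: for each homozygous start the furthest in-budget right
    limit is non-decreasing, so each candidate window is computed in O(1)
    amortized; a window is maximal iff its snapped end exceeds every earlier
    window's end.
    """
    n = len(cls)
    is_hom = cls == HOM
    hom_idx = np.flatnonzero(is_hom)
    if len(hom_idx) == 0:
        return []
    # prev_hom[j] = largest hom index <= j
    prev_hom = np.maximum.accumulate(np.where(is_hom, np.arange(n), -1))

    runs: list[tuple[int, int]] = []
    het = 0
    miss = 0
    left = 0
    r = -1  # right edge of the in-budget window [left, r], inclusive
    last_end = -1
    for a in hom_idx:
        a = int(a)
        while left < a:
            if left <= r:
                het -= cls[left] == HET
                miss -= cls[left] == MISS
            left += 1
        if r < a - 1:
            r = a - 1  # window emptied; counts are zero
        # extend right as far as budgets allow
        while r + 1 < n:
            h = het + (cls[r + 1] == HET)
            m = miss + (cls[r + 1] == MISS)
            if h > max_het or m > max_missing:
                break
            r += 1
            het, miss = h, m
        b = int(prev_hom[r])
        # ends are non-decreasing in the start index, so a window is maximal
        # iff its end exceeds every earlier kept window's end
        if b > last_end:
            runs.append((a, b))
            last_end = b
    return runs


def call_roh(dataset: GenotypeDataset, sample_id: str, params: ROHParams) -> list[ROHSegment]:
    """Detect runs of homozygosity for one sample, per chromosome."""
    cls_all = classify_calls(dataset, sample_id)
    segments: list[ROHSegment] = []
    for chrom in dataset.chromosomes():
        sl = dataset.chromosome_slice(chrom)
        cls = cls_all[sl]
        pos = np.array([m.position_bp for m in dataset.markers[sl]])
        for a, b in maximal_runs(cls, params.max_het_in_run, params.max_missing_in_run):
            n_markers = b - a + 1
            span = int(pos[b] - pos[a] + 1)
            if n_markers < params.min_markers or span < params.min_length_bp:
                continue
            window = cls[a : b + 1]
            segments.append(
                ROHSegment(
                    sample_id=sample_id,
                    chromosome=chrom,
                    start_bp=int(pos[a]),
                    end_bp=int(pos[b]),
                    n_markers=n_markers,
                    n_het=int((window == HET).sum()),
                    n_missing=int((window == MISS).sum()),
                    start_idx=int(a),
                    end_idx=int(b),
                )
            )
    return segments


def brute_force_runs(cls: np.ndarray, max_het: int, max_missing: int) -> list[tuple[int, int]]:
    """Oracle: enumerate every qualifying window, keep the maximal ones.

    Quadratic; intended for small inputs in tests only.
    """
    n = len(cls)
    het = np.concatenate([[0], np.cumsum(cls == HET)])
    miss = np.concatenate([[0], np.cumsum(cls == MISS)])
    qualifying = [
        (a, b)
        for a in range(n)
        if cls[a] == HOM
        for b in range(a, n)
        if cls[b] == HOM
        and het[b + 1] - het[a] <= max_het
        and miss[b + 1] - miss[a] <= max_missing
    ]
    return [
        (a, b)
        for (a, b) in qualifying
        if not any((a2 <= a and b <= b2) and (a2, b2) != (a, b) for (a2, b2) in qualifying)
    ]


def write_roh_report(segments, path) -> None:
    from pathlib import Path

    lines = ["sample\tchromosome\tstart_bp\tend_bp\tn_markers\tn_het\tn_missing"]
    for s in segments:
        lines.append(
            f"{s.sample_id}\t{s.chromosome}\t{s.start_bp}\t{s.end_bp}"
            f"\t{s.n_markers}\t{s.n_het}\t{s.n_missing}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
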