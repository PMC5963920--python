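"""Consanguineous-pedigree genotype simulation with known ground truth.

Emulates the study design the mapping pipeline targets: a first-cousin
union (parents of the sibship share one pair of grandparents) with five
children, two of them affected by a recessive trait.  Founder haplotypes
are drawn marker-wise from an allele-frequency law (markers independent;
no linkage disequilibrium), transmission follows the Haldane model
(Poisson crossover counts per Morgan, no interference, positions uniform
in genetic distance), and one causal variant is implanted on a shared
grandparental haplotype.  Descent of the causal haplotype is forced by
rejection sampling over individual meioses — each conditioned meiosis is
redrawn until the gamete carries (or, for unaffected children, does not
doubly carry) the causal haplotype at the locus — which preserves the
recombination model's tract-length distribution exactly, because the
conditioning events are functions of disjoint meioses.

Every draw flows from one explicitly passed generator seeded once, so the
same seed reproduces byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import ConfigurationError, SimulationError
from .io import (
    GeneticMap,
    GenotypeDataset,
    Individual,
    Marker,
    Pedigree,
    Sex,
    Status,
    Variant,
    write_genetic_map,
    write_genotypes,
    write_variant_table,
)

_BASES = np.array(list("ACGT"))

# founder haplotype origin labels: shared grandparents A (0,1) and B (2,3),
# married-in founders E (4,5) and G (6,7)
_CAUSAL_ORIGIN = 0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic pedigree.

    Defaults: one 150-Mb chromosome with 5,000 markers (array-like density,
    ~30 kb spacing), founder minor-allele frequencies uniform on
    [0.05, 0.5], 0.2% genotyping error and 0.5% missingness per call
    (matching >99% array call rates), and a causal locus at the chromosome
    midpoint.
    """

    n_chromosomes: int = 1
    chromosome_length_bp: int = 150_000_000
    n_markers: int = 5_000
    maf_low: float = 0.05
    maf_high: float = 0.5
    genotyping_error_rate: float = 0.002
    missing_rate: float = 0.005
    pedigree_template: str = "first_cousin_union"
    causal_locus: tuple[str, int] | None = None
    n_background_variants: int = 70
    min_truth_length_cM: float = 5.0
    causal_margin_bp: int = 1_000_000
    seed: int = 0
    max_rejection_tries: int = 10_000

    def __post_init__(self) -> None:
        for r in (self.genotyping_error_rate, self.missing_rate):
            if not (0.0 <= r <= 1.0):
                raise ConfigurationError("rates must be in [0, 1]")
        if self.n_markers < 2:
            raise ConfigurationError("n_markers must be >= 2")
        if self.pedigree_template != "first_cousin_union":
            raise ConfigurationError(f"unknown pedigree template {self.pedigree_template!r}")
        if self.causal_locus is not None:
            chrom, bp = self.causal_locus
            if chrom not in {str(i + 1) for i in range(self.n_chromosomes)}:
                raise ConfigurationError(f"causal chromosome {chrom!r} not simulated")
            if not (1 <= bp <= self.chromosome_length_bp):
                raise ConfigurationError("causal position outside chromosome bounds")

    def resolved_causal_locus(self) -> tuple[str, int]:
        if self.causal_locus is not None:
            return self.causal_locus
        return "1", self.chromosome_length_bp // 2


@dataclass
class Haplotype:
    """One chromosome copy: allele indices (0=ref, 1=alt) plus the founder
    haplotype label each segment descends from."""

    chromosome: str
    positions_bp: np.ndarray
    alleles: np.ndarray
    origins: np.ndarray


@dataclass
class SyntheticStudy:
    pedigree: Pedigree
    dataset: GenotypeDataset
    variant_table: list[Variant]
    truth_regions: list[tuple[str, int, int]]
    causal_variant: Variant
    genetic_map: GeneticMap
    config: SimulationConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "ped": out / "study.ped",
            "map": out / "study.map",
            "genetic_map": out / "genetic_map.tsv",
            "variants": out / "variants.tsv",
            "truth": out / "truth.json",
        }
        write_genotypes(self.pedigree, self.dataset, paths["ped"], paths["map"])
        write_genetic_map(self.genetic_map, paths["genetic_map"])
        write_variant_table(self.variant_table, paths["variants"])
        truth = {
            "truth_regions": [
                {"chromosome": c, "start_bp": s, "end_bp": e}
                for c, s, e in self.truth_regions
            ],
            "causal_variant": {
                "chromosome": self.causal_variant.chromosome,
                "position_bp": self.causal_variant.position_bp,
                "gene": self.causal_variant.gene,
                "cdna_change": self.causal_variant.cdna_change,
            },
            "seed": self.config.seed,
        }
        paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
        return paths


# ---------------------------------------------------------------------------
# Transmission model
# ---------------------------------------------------------------------------


def draw_crossover_positions(length_cM: float, rng: np.random.Generator) -> np.ndarray:
    """Crossover positions (cM) under the Haldane model: Poisson count with
    mean ``length_cM / 100`` Morgans, positions uniform."""
    if length_cM <= 0:
        return np.empty(0)
    k = rng.poisson(length_cM / 100.0)
    return np.sort(rng.uniform(0.0, length_cM, size=k))


def meiosis(
    parent_haplotypes: tuple[Haplotype, Haplotype],
    gmap: GeneticMap,
    rng: np.random.Generator,
    chromosome_length_bp: int | None = None,
) -> Haplotype:
    """One gamete from a pair of parental haplotypes.

    Crossovers are placed over the full chromosome ``[1, chromosome_length_bp]``
    (or the marker span when no length is given) in genetic distance; the
    gamete switches between the two parental copies at each crossover, with
    the starting copy equally likely.
    """
    h0, h1 = parent_haplotypes
    chrom = h0.chromosome
    pos = h0.positions_bp
    cm = np.asarray(gmap.interpolate(chrom, pos), dtype=float)
    if chromosome_length_bp is not None:
        cm_lo = float(gmap.interpolate(chrom, 1))
        cm_hi = float(gmap.interpolate(chrom, chromosome_length_bp))
    else:
        cm_lo, cm_hi = float(cm[0]), float(cm[-1])
    xovers = draw_crossover_positions(cm_hi - cm_lo, rng) + cm_lo
    start = int(rng.integers(2))
    which = (start + np.searchsorted(xovers, cm, side="right")) % 2
    alleles = np.where(which == 0, h0.alleles, h1.alleles)
    origins = np.where(which == 0, h0.origins, h1.origins)
    return Haplotype(chromosome=chrom, positions_bp=pos, alleles=alleles, origins=origins)


class _DiploidGenome:
    """Paternal/maternal haplotype per chromosome."""

    def __init__(self, chromosomes: list[tuple[Haplotype, Haplotype]]):
        self.chromosomes = chromosomes


@dataclass
class _Grid:
    chromosome: str
    positions_bp: np.ndarray  # marker positions plus the causal coordinate
    marker_mask: np.ndarray  # True where the grid point is an array marker
    ref: np.ndarray  # reference base per marker grid point
    alt: np.ndarray
    mafs: np.ndarray


def _make_grids(config: SimulationConfig, rng: np.random.Generator) -> list[_Grid]:
    causal_chrom, causal_bp = config.resolved_causal_locus()
    grids = []
    for ci in range(config.n_chromosomes):
        chrom = str(ci + 1)
        positions = _distinct_sorted_positions(
            config.n_markers, config.chromosome_length_bp, rng
        )
        marker_mask = np.ones(len(positions), dtype=bool)
        if chrom == causal_chrom and causal_bp not in positions:
            i = int(np.searchsorted(positions, causal_bp))
            positions = np.insert(positions, i, causal_bp)
            marker_mask = np.insert(marker_mask, i, False)
        n = len(positions)
        ref_idx = rng.integers(0, 4, size=n)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
        mafs = rng.uniform(config.maf_low, config.maf_high, size=n)
        grids.append(
            _Grid(
                chromosome=chrom,
                positions_bp=positions,
                marker_mask=marker_mask,
                ref=_BASES[ref_idx],
                alt=_BASES[alt_idx],
                mafs=mafs,
            )
        )
    return grids


def _distinct_sorted_positions(n: int, length_bp: int, rng: np.random.Generator) -> np.ndarray:
    if n > length_bp:
        raise ConfigurationError("more markers than base pairs")
    pos = np.unique(rng.integers(1, length_bp + 1, size=int(n * 1.2) + 16))
    while len(pos) < n:
        extra = rng.integers(1, length_bp + 1, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def _founder(grids: list[_Grid], origin_pair: tuple[int, int], rng: np.random.Generator) -> _DiploidGenome:
    chroms = []
    for g in grids:
        haps = []
        for origin in origin_pair:
            alleles = (rng.random(len(g.positions_bp)) < g.mafs).astype(np.int8)
            haps.append(
                Haplotype(
                    chromosome=g.chromosome,
                    positions_bp=g.positions_bp,
                    alleles=alleles,
                    origins=np.full(len(g.positions_bp), origin, dtype=np.int16),
                )
            )
        chroms.append((haps[0], haps[1]))
    return _DiploidGenome(chroms)


def _gamete(
    parent: _DiploidGenome,
    gmap: GeneticMap,
    rng: np.random.Generator,
    config: SimulationConfig,
    condition: tuple[int, int, bool] | None = None,
) -> list[Haplotype]:
    """One gamete (per-chromosome haplotypes); optionally conditioned so the
    origin at grid index ``q`` of chromosome ``ci`` equals (or differs from)
    the causal founder haplotype, by rejection."""
    out: list[Haplotype] = []
    for ci, (h0, h1) in enumerate(parent.chromosomes):
        if condition is not None and condition[0] == ci:
            _, q, want_causal = condition
            for attempt in range(config.max_rejection_tries):
                hap = meiosis((h0, h1), gmap, rng, config.chromosome_length_bp)
                carries = hap.origins[q] == _CAUSAL_ORIGIN
                if carries == want_causal:
                    break
            else:
                raise SimulationError(
                    "rejection sampling failed to satisfy the causal-descent "
                    f"condition after {config.max_rejection_tries} tries"
                )
            out.append(hap)
        else:
            out.append(meiosis((h0, h1), gmap, rng, config.chromosome_length_bp))
    return out


def _child(pat: list[Haplotype], mat: list[Haplotype]) -> _DiploidGenome:
    return _DiploidGenome(list(zip(pat, mat)))


def _descend_first_cousin_pedigree(
    grids: list[_Grid],
    gmap: GeneticMap,
    rng: np.random.Generator,
    config: SimulationConfig,
    causal: tuple[int, int] | None,
) -> dict[str, _DiploidGenome]:
    """Simulate the loop A×B -> C, D; C×E -> father; D×G -> mother; 5 children.

    When ``causal = (chromosome index, grid index)``, descent of founder
    haplotype 0 of grandparent A to both affected children (C1, C4) is forced
    and double descent to the unaffected children is forbidden.
    """
    gp_a = _founder(grids, (0, 1), rng)
    gp_b = _founder(grids, (2, 3), rng)
    spouse_e = _founder(grids, (4, 5), rng)
    spouse_g = _founder(grids, (6, 7), rng)

    cond = None if causal is None else (causal[0], causal[1], True)
    # C and D are siblings (children of A and B); each must transmit the
    # causal grandparental haplotype down to one parent of the sibship
    sib_c = _child(_gamete(gp_a, gmap, rng, config, cond), _gamete(gp_b, gmap, rng, config))
    sib_d = _child(_gamete(gp_a, gmap, rng, config, cond), _gamete(gp_b, gmap, rng, config))
    father = _child(_gamete(sib_c, gmap, rng, config, cond), _gamete(spouse_e, gmap, rng, config))
    mother = _child(_gamete(sib_d, gmap, rng, config, cond), _gamete(spouse_g, gmap, rng, config))

    genomes: dict[str, _DiploidGenome] = {"FA": father, "MO": mother}
    for name, affected in (("C1", True), ("C2", False), ("C3", False), ("C4", True), ("C5", False)):
        if causal is None:
            genomes[name] = _child(
                _gamete(father, gmap, rng, config), _gamete(mother, gmap, rng, config)
            )
            continue
        ci, q = causal
        if affected:
            genomes[name] = _child(
                _gamete(father, gmap, rng, config, (ci, q, True)),
                _gamete(mother, gmap, rng, config, (ci, q, True)),
            )
        else:
            for attempt in range(config.max_rejection_tries):
                pat = _gamete(father, gmap, rng, config)
                mat = _gamete(mother, gmap, rng, config)
                both = (
                    pat[ci].origins[q] == _CAUSAL_ORIGIN
                    and mat[ci].origins[q] == _CAUSAL_ORIGIN
                )
                if not both:
                    break
            else:
                raise SimulationError("could not draw a non-homozygous unaffected child")
            genomes[name] = _child(pat, mat)
    return genomes


def _family_pedigree() -> Pedigree:
    children = [
        ("C1", Status.AFFECTED),
        ("C2", Status.UNAFFECTED),
        ("C3", Status.UNAFFECTED),
        ("C4", Status.AFFECTED),
        ("C5", Status.UNAFFECTED),
    ]
    inds = [
        Individual("FA", None, None, Sex.MALE, Status.UNAFFECTED),
        Individual("MO", None, None, Sex.FEMALE, Status.UNAFFECTED),
    ]
    inds += [Individual(cid, "FA", "MO", Sex.UNKNOWN, st) for cid, st in children]
    return Pedigree(inds)


def simulate_study(config: SimulationConfig | None = None) -> SyntheticStudy:
    """Generate a full synthetic study: genotypes, variant table, ground truth."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    gmap = GeneticMap()  # constant 1 cM/Mb
    grids = _make_grids(config, rng)

    causal_chrom, causal_bp = config.resolved_causal_locus()
    ci = int(causal_chrom) - 1
    q = int(np.searchsorted(grids[ci].positions_bp, causal_bp))
    assert grids[ci].positions_bp[q] == causal_bp

    # redraw the whole descent until the identifiable truth region reaches
    # the minimum mappable genetic length and the causal locus is interior
    # to it by at least one ROH-resolution unit: an implant the design
    # cannot in principle detect or resolve does not constitute a study
    for attempt in range(200):
        genomes = _descend_first_cousin_pedigree(grids, gmap, rng, config, (ci, q))
        truth_region = _identifiable_causal_region(grids[ci], genomes, q)
        chrom, s_bp, e_bp = truth_region
        length_cm = float(gmap.interpolate(chrom, e_bp)) - float(gmap.interpolate(chrom, s_bp))
        margin = min(causal_bp - s_bp, e_bp - causal_bp)
        if length_cm >= config.min_truth_length_cM and margin >= config.causal_margin_bp:
            break
    else:
        raise SimulationError(
            "could not realize an identifiable causal region of at least "
            f"{config.min_truth_length_cM} cM in 200 pedigree draws"
        )
    pedigree = _family_pedigree()
    samples = [i.id for i in pedigree.individuals]

    dataset = _emit_dataset(grids, genomes, samples, config, rng)
    causal_variant, background = _emit_variants(grids, genomes, samples, config, rng, ci, q)
    variants = sorted(
        background + [causal_variant], key=lambda v: (int(v.chromosome), v.position_bp)
    )

    # emit an anchor file so the implied constant-rate map round-trips
    anchors = {
        g.chromosome: [
            (1, float(gmap.interpolate(g.chromosome, 1))),
            (
                config.chromosome_length_bp,
                float(gmap.interpolate(g.chromosome, config.chromosome_length_bp)),
            ),
        ]
        for g in grids
    }
    return SyntheticStudy(
        pedigree=pedigree,
        dataset=dataset,
        variant_table=variants,
        truth_regions=[truth_region],
        causal_variant=causal_variant,
        genetic_map=GeneticMap(anchors),
        config=config,
    )


def _emit_dataset(
    grids: list[_Grid],
    genomes: dict[str, _DiploidGenome],
    samples: list[str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> GenotypeDataset:
    markers: list[Marker] = []
    call_blocks: list[np.ndarray] = []
    for ci, g in enumerate(grids):
        midx = np.flatnonzero(g.marker_mask)
        for k, gi in enumerate(midx):
            markers.append(
                Marker(
                    id=f"chr{g.chromosome}_m{k + 1}",
                    chromosome=g.chromosome,
                    position_bp=int(g.positions_bp[gi]),
                )
            )
        block = np.empty((len(midx), len(samples), 2), dtype="<U1")
        bases = np.stack([g.ref[midx], g.alt[midx]], axis=1)  # (n_markers, 2)
        for si, s in enumerate(samples):
            pat, mat = genomes[s].chromosomes[ci]
            a = pat.alleles[midx].copy()
            b = mat.alleles[midx].copy()
            # genotyping error: flip one allele of the call
            err = rng.random(len(midx)) < config.genotyping_error_rate
            which = rng.integers(2, size=len(midx))
            a[err & (which == 0)] ^= 1
            b[err & (which == 1)] ^= 1
            block[:, si, 0] = bases[np.arange(len(midx)), a]
            block[:, si, 1] = bases[np.arange(len(midx)), b]
            miss = rng.random(len(midx)) < config.missing_rate
            block[miss, si, :] = "0"
        call_blocks.append(block)
    calls = np.concatenate(call_blocks, axis=0)
    return GenotypeDataset(markers, samples, calls)


_TRUTH_EXCLUSION_MIN_BP = 1_000_000  # unaffected tracts below array ROH resolution do not trim


def _identifiable_causal_region(
    grid: _Grid, genomes: dict[str, _DiploidGenome], q: int
) -> tuple[str, int, int]:
    """The mappable ground-truth interval around the causal locus.

    The affecteds' shared causal-haplotype tract, minus any stretch (>= 1 Mb)
    where an unaffected sibling is also autozygous for the causal haplotype:
    such flanks are shared with healthy members and are, by design, removed
    by the exclusion stage of any correct mapping — they carry no mapping
    information.  Computed on noise-free haplotype origins.
    """
    ci = int(grid.chromosome) - 1
    pos = grid.positions_bp
    mask = np.ones(len(pos), dtype=bool)
    for child in ("C1", "C4"):
        pat, mat = genomes[child].chromosomes[ci]
        mask &= (pat.origins == _CAUSAL_ORIGIN) & (mat.origins == _CAUSAL_ORIGIN)
    assert mask[q], "causal-descent conditioning must make both affecteds autozygous"
    for child in ("C2", "C3", "C5"):
        pat, mat = genomes[child].chromosomes[ci]
        shared = (pat.origins == _CAUSAL_ORIGIN) & (mat.origins == _CAUSAL_ORIGIN)
        for a, b in _true_runs(shared):
            if pos[b] - pos[a] + 1 >= _TRUTH_EXCLUSION_MIN_BP:
                mask[a : b + 1] = False
    assert mask[q], "unaffected children cannot be homozygous causal at the locus"
    a = q
    while a > 0 and mask[a - 1]:
        a -= 1
    b = q
    while b + 1 < len(mask) and mask[b + 1]:
        b += 1
    return grid.chromosome, int(pos[a]), int(pos[b])


def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1)
    return [(int(r[0]), int(r[-1])) for r in np.split(idx, splits + 1)]


def _origin_at(genome: _DiploidGenome, ci: int, grid: _Grid, bp: int) -> tuple[int, int]:
    i = int(np.clip(np.searchsorted(grid.positions_bp, bp), 0, len(grid.positions_bp) - 1))
    pat, mat = genome.chromosomes[ci]
    return int(pat.origins[i]), int(mat.origins[i])


def _emit_variants(
    grids: list[_Grid],
    genomes: dict[str, _DiploidGenome],
    samples: list[str],
    config: SimulationConfig,
    rng: np.random.Generator,
    causal_ci: int,
    causal_q: int,
) -> tuple[Variant, list[Variant]]:
    causal_grid = grids[causal_ci]
    causal_bp = int(causal_grid.positions_bp[causal_q])
    ref, alt = "C", "T"
    causal_genotypes = {}
    for s in samples:
        p, m = _origin_at(genomes[s], causal_ci, causal_grid, causal_bp)
        causal_genotypes[s] = (
            alt if p == _CAUSAL_ORIGIN else ref,
            alt if m == _CAUSAL_ORIGIN else ref,
        )
    causal = Variant(
        chromosome=causal_grid.chromosome,
        position_bp=causal_bp,
        gene="GENE_CAUSAL",
        cdna_change=f"c.1429{ref}>{alt}",
        protein_change=None,
        zygosity_in_proband="hom",
        member_genotypes=causal_genotypes,
        population_maf=None,  # never observed in databases
        known_polymorphism=False,
    )

    background: list[Variant] = []
    for k in range(config.n_background_variants):
        ci = int(rng.integers(config.n_chromosomes))
        g = grids[ci]
        bp = int(rng.integers(1, config.chromosome_length_bp + 1))
        maf = float(rng.uniform(config.maf_low, config.maf_high))
        # which founder haplotypes carry the alternate allele
        carriers = rng.random(8) < maf
        vref, valt = ("A", "G") if rng.random() < 0.5 else ("G", "A")
        genotypes = {}
        for s in samples:
            p, m = _origin_at(genomes[s], ci, g, bp)
            genotypes[s] = (
                valt if carriers[p] else vref,
                valt if carriers[m] else vref,
            )
        proband = genotypes["C1"]
        zyg = "hom" if (proband[0] == proband[1] == valt) else "het"
        background.append(
            Variant(
                chromosome=g.chromosome,
                position_bp=bp,
                gene=f"GENE{k + 1}",
                cdna_change=f"c.{3 * k + 2}{vref}>{valt}",
                protein_change=None,
                zygosity_in_proband=zyg,
                member_genotypes=genotypes,
                population_maf=maf,
                known_polymorphism=True,
            )
        )
    return causal, background


def autozygous_fraction_samples(
    n_offspring: int,
    config: SimulationConfig | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Autozygous genome fraction of independent first-cousin offspring.

    The whole pedigree (grandparents down) is redrawn for each offspring, so
    the sample mean estimates the unconditional inbreeding coefficient
    F = 1/16 of first-cousin matings.  Fractions are measured as the share
    of markers at which the two haplotype origins coincide.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    gmap = GeneticMap()
    fractions = np.empty(n_offspring)
    for i in range(n_offspring):
        grids = _make_grids(config, rng)
        genomes = _descend_first_cousin_pedigree(grids, gmap, rng, config, causal=None)
        auto = total = 0
        child = _child(
            _gamete(genomes["FA"], gmap, rng, config),
            _gamete(genomes["MO"], gmap, rng, config),
        )
        for pat, mat in child.chromosomes:
            auto += int((pat.origins == mat.origins).sum())
            total += len(pat.origins)
        fractions[i] = auto / total
    return fractions
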