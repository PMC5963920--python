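"""Text-dialect readers/writers and core data containers.

The package speaks plain-text dialects throughout: whitespace-separated
PED/MAP for pedigree + array genotypes, TSV for genetic maps and variant
tables, and a BED-like TSV for candidate regions.  All genomic coordinates
are 1-based and intervals are closed ``[start_bp, end_bp]``; the BED-like
output states this in a header comment rather than silently shifting to
0-based half-open.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, PedigreeError

MISSING_ALLELE = "0"
VALID_ALLELES = frozenset("ACGT")


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Status(enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


_SEX_FROM_PED = {"1": Sex.MALE, "2": Sex.FEMALE}
_SEX_TO_PED = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_STATUS_FROM_PED = {"2": Status.AFFECTED, "1": Status.UNAFFECTED}
_STATUS_TO_PED = {Status.AFFECTED: "2", Status.UNAFFECTED: "1", Status.UNKNOWN: "0"}


@dataclass(frozen=True)
class Individual:
    id: str
    father_id: str | None
    mother_id: str | None
    sex: Sex = Sex.UNKNOWN
    status: Status = Status.UNKNOWN


@dataclass
class Pedigree:
    """A family: individuals with parent links and affection status.

    Parent ids either resolve to members of the pedigree or are ``None``
    (founders); the parent graph must be acyclic and ids unique.
    """

    individuals: list[Individual]

    def __post_init__(self) -> None:
        ids = [ind.id for ind in self.individuals]
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise PedigreeError(f"duplicate individual id {i!r}")
            seen.add(i)
        self._by_id = {ind.id: ind for ind in self.individuals}
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(iid: str) -> None:
            if state.get(iid) == 1:
                return
            if state.get(iid) == 0:
                raise PedigreeError(f"pedigree parent graph has a cycle through {iid!r}")
            state[iid] = 0
            ind = self._by_id[iid]
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid in self._by_id:
                    visit(pid)
            state[iid] = 1

        for ind in self.individuals:
            visit(ind.id)

    def __contains__(self, iid: str) -> bool:
        return iid in self._by_id

    def __getitem__(self, iid: str) -> Individual:
        return self._by_id[iid]

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def affected(self) -> list[Individual]:
        return [i for i in self.individuals if i.status is Status.AFFECTED]

    def unaffected(self) -> list[Individual]:
        return [i for i in self.individuals if i.status is Status.UNAFFECTED]

    def parents_of(self, iid: str) -> list[Individual]:
        ind = self._by_id[iid]
        out = []
        for pid in (ind.father_id, ind.mother_id):
            if pid is not None and pid in self._by_id:
                out.append(self._by_id[pid])
        return out


@dataclass(frozen=True)
class Marker:
    id: str
    chromosome: str
    position_bp: int
    genetic_pos_cM: float | None = None

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise FormatError(
                f"marker {self.id!r}: position_bp must be >= 1, got {self.position_bp}"
            )


class GenotypeDataset:
    """Marker-by-sample diploid calls from a SNP array.

    ``calls`` is an ``(n_markers, n_samples, 2)`` array of single-character
    alleles over ``{A, C, G, T}`` with ``"0"`` as the missing code; a call
    with any missing allele is treated as entirely missing.  Markers are kept
    sorted by position within each chromosome (chromosomes in first-appearance
    order), with strictly increasing positions.
    """

    def __init__(self, markers: Sequence[Marker], samples: Sequence[str], calls: np.ndarray):
        calls = np.asarray(calls, dtype="<U1")
        if calls.shape != (len(markers), len(samples), 2):
            raise FormatError(
                f"calls shape {calls.shape} does not match "
                f"{len(markers)} markers x {len(samples)} samples"
            )
        bad = ~np.isin(calls, list(VALID_ALLELES | {MISSING_ALLELE}))
        if bad.any():
            sym = calls[bad].flat[0]
            raise FormatError(f"unknown allele symbol {sym!r}")
        # normalize half-missing calls to fully missing
        miss = (calls == MISSING_ALLELE).any(axis=2)
        calls = calls.copy()
        calls[miss] = MISSING_ALLELE

        order = _sorted_marker_order(markers)
        self.markers: list[Marker] = [markers[i] for i in order]
        self.samples: list[str] = list(samples)
        self.calls: np.ndarray = calls[order]
        _check_strictly_increasing(self.markers)
        self._sample_index = {s: i for i, s in enumerate(self.samples)}
        if len(self._sample_index) != len(self.samples):
            raise FormatError("duplicate sample id in dataset")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self._sample_index[sample_id]
        except KeyError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def chromosomes(self) -> list[str]:
        out: list[str] = []
        for m in self.markers:
            if not out or out[-1] != m.chromosome:
                out.append(m.chromosome)
        return out

    def chromosome_slice(self, chromosome: str) -> slice:
        idx = [i for i, m in enumerate(self.markers) if m.chromosome == chromosome]
        if not idx:
            return slice(0, 0)
        return slice(idx[0], idx[-1] + 1)

    def calls_for(self, sample_id: str) -> np.ndarray:
        return self.calls[:, self.sample_index(sample_id), :]

    def is_missing(self, sample_id: str) -> np.ndarray:
        c = self.calls_for(sample_id)
        return (c == MISSING_ALLELE).any(axis=1)

    def is_hom(self, sample_id: str) -> np.ndarray:
        c = self.calls_for(sample_id)
        return (c[:, 0] == c[:, 1]) & (c[:, 0] != MISSING_ALLELE)

    def is_het(self, sample_id: str) -> np.ndarray:
        c = self.calls_for(sample_id)
        return (c[:, 0] != c[:, 1]) & (c != MISSING_ALLELE).all(axis=1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.markers == other.markers
            and self.samples == other.samples
            and bool(np.array_equal(self.calls, other.calls))
        )


def _sorted_marker_order(markers: Sequence[Marker]) -> list[int]:
    chrom_rank: dict[str, int] = {}
    for m in markers:
        chrom_rank.setdefault(m.chromosome, len(chrom_rank))
    return sorted(range(len(markers)), key=lambda i: (chrom_rank[markers[i].chromosome], markers[i].position_bp))


def _check_strictly_increasing(markers: Sequence[Marker]) -> None:
    for a, b in zip(markers, markers[1:]):
        if a.chromosome == b.chromosome and b.position_bp <= a.position_bp:
            raise FormatError(
                f"markers {a.id!r} and {b.id!r} on chromosome {a.chromosome!r} "
                f"are not strictly increasing in position"
            )


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------


class GeneticMap:
    """bp <-> cM anchors with piecewise-linear interpolation.

    Outside the anchored range positions are extrapolated at the nearest
    interval's local rate.  A chromosome with no anchors falls back to a
    constant ``fallback_rate_cM_per_Mb`` (default 1.0, the genome-wide
    average), which keeps genetic-length filters usable without a map file.
    """

    def __init__(
        self,
        anchors: Mapping[str, Sequence[tuple[float, float]]] | None = None,
        fallback_rate_cM_per_Mb: float = 1.0,
    ):
        if fallback_rate_cM_per_Mb <= 0:
            raise FormatError("fallback rate must be positive")
        self.fallback_rate_cM_per_Mb = float(fallback_rate_cM_per_Mb)
        self.anchors: dict[str, np.ndarray] = {}
        for chrom, pts in (anchors or {}).items():
            arr = np.asarray(sorted((float(bp), float(cm)) for bp, cm in pts), dtype=float)
            if arr.size and np.any(np.diff(arr[:, 1]) < 0):
                raise FormatError(f"genetic map for chromosome {chrom!r}: cM not non-decreasing")
            if arr.size:
                self.anchors[chrom] = arr

    def interpolate(self, chromosome: str, position_bp) -> np.ndarray | float:
        """cM position(s) for one or many bp positions; total function."""
        pos = np.atleast_1d(np.asarray(position_bp, dtype=float))
        arr = self.anchors.get(chromosome)
        if arr is None or len(arr) == 0:
            cm = pos * self.fallback_rate_cM_per_Mb / 1e6
        elif len(arr) == 1:
            bp0, cm0 = arr[0]
            cm = cm0 + (pos - bp0) * self.fallback_rate_cM_per_Mb / 1e6
        else:
            bp, cms = arr[:, 0], arr[:, 1]
            cm = np.interp(pos, bp, cms)
            # linear extrapolation at the terminal interval rates
            lo = pos < bp[0]
            hi = pos > bp[-1]
            if lo.any():
                r = (cms[1] - cms[0]) / (bp[1] - bp[0])
                cm[lo] = cms[0] + (pos[lo] - bp[0]) * r
            if hi.any():
                r = (cms[-1] - cms[-2]) / (bp[-1] - bp[-2])
                cm[hi] = cms[-1] + (pos[hi] - bp[-1]) * r
        if np.isscalar(position_bp) or np.ndim(position_bp) == 0:
            return float(cm[0])
        return cm


def interpolate_genetic_position(gmap: GeneticMap, chromosome: str, position_bp: int) -> float:
    """Genetic position in cM for a single bp coordinate."""
    return float(gmap.interpolate(chromosome, position_bp))


def read_genetic_map(path: str | Path, fallback_rate_cM_per_Mb: float = 1.0) -> GeneticMap:
    """Read a TSV of (chromosome, position_bp, cM) anchors; header optional."""
    anchors: dict[str, list[tuple[float, float]]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{ln}: expected 3 tab-separated columns")
        if ln == 1 and not _is_number(fields[1]):
            continue  # header row
        try:
            anchors.setdefault(fields[0], []).append((float(fields[1]), float(fields[2])))
        except ValueError as e:
            raise FormatError(f"{path}:{ln}: {e}") from None
    return GeneticMap(anchors, fallback_rate_cM_per_Mb)


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> None:
    lines = ["chromosome\tposition_bp\tcM"]
    for chrom, arr in gmap.anchors.items():
        for bp, cm in arr:
            lines.append(f"{chrom}\t{int(bp)}\t{cm:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# PED / MAP
# ---------------------------------------------------------------------------


def read_genotypes(ped_path: str | Path, map_path: str | Path) -> tuple[Pedigree, GenotypeDataset]:
    """Read a whitespace-separated PED + MAP pair.

    MAP rows: chromosome, marker id, genetic position (cM; ``0`` for unknown),
    bp position.  PED rows: family, individual, father, mother, sex (1/2/0),
    status (2=affected/1=unaffected/0=unknown), then two allele columns per
    MAP marker (``0`` = missing).  Markers are re-sorted per chromosome with
    calls permuted consistently.
    """
    markers: list[Marker] = []
    for ln, line in enumerate(Path(map_path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split()
        if len(f) != 4:
            raise FormatError(f"{map_path}:{ln}: expected 4 columns, got {len(f)}")
        try:
            gpos = float(f[2])
            bp = int(f[3])
        except ValueError:
            raise FormatError(f"{map_path}:{ln}: non-numeric position") from None
        markers.append(
            Marker(id=f[1], chromosome=f[0], position_bp=bp, genetic_pos_cM=gpos if gpos > 0 else None)
        )

    individuals: list[Individual] = []
    rows: list[np.ndarray] = []
    seen_ids: set[str] = set()
    for ln, line in enumerate(Path(ped_path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split()
        if len(f) != 6 + 2 * len(markers):
            raise FormatError(
                f"{ped_path}:{ln}: expected {6 + 2 * len(markers)} columns "
                f"({len(markers)} markers), got {len(f)}"
            )
        _, iid, fid, mid, sex, status = f[:6]
        if iid in seen_ids:
            raise FormatError(f"{ped_path}:{ln}: duplicate individual id {iid!r}")
        seen_ids.add(iid)
        individuals.append(
            Individual(
                id=iid,
                father_id=None if fid == "0" else fid,
                mother_id=None if mid == "0" else mid,
                sex=_SEX_FROM_PED.get(sex, Sex.UNKNOWN),
                status=_STATUS_FROM_PED.get(status, Status.UNKNOWN),
            )
        )
        alleles = f[6:]
        for a in alleles:
            if a != MISSING_ALLELE and a not in VALID_ALLELES:
                raise FormatError(f"{ped_path}:{ln}: unknown allele symbol {a!r}")
        rows.append(np.array(alleles, dtype="<U1").reshape(len(markers), 2))

    pedigree = Pedigree(individuals)
    calls = (
        np.stack(rows, axis=1)
        if rows
        else np.empty((len(markers), 0, 2), dtype="<U1")
    )
    dataset = GenotypeDataset(markers, [ind.id for ind in individuals], calls)
    return pedigree, dataset


def write_genotypes(
    pedigree: Pedigree,
    dataset: GenotypeDataset,
    ped_path: str | Path,
    map_path: str | Path,
    family_id: str = "FAM1",
) -> None:
    map_lines = [
        f"{m.chromosome}\t{m.id}\t{m.genetic_pos_cM if m.genetic_pos_cM is not None else 0}\t{m.position_bp}"
        for m in dataset.markers
    ]
    Path(map_path).write_text("\n".join(map_lines) + ("\n" if map_lines else ""))

    ped_lines = []
    for ind in pedigree.individuals:
        if ind.id not in dataset.samples:
            continue
        calls = dataset.calls_for(ind.id)
        fields = [
            family_id,
            ind.id,
            ind.father_id or "0",
            ind.mother_id or "0",
            _SEX_TO_PED[ind.sex],
            _STATUS_TO_PED[ind.status],
        ]
        fields.extend(calls.reshape(-1).tolist())
        ped_lines.append(" ".join(fields))
    Path(ped_path).write_text("\n".join(ped_lines) + ("\n" if ped_lines else ""))


# ---------------------------------------------------------------------------
# Variant table
# ---------------------------------------------------------------------------

_HGVS_SUB = re.compile(r"^c\.(\d+)\s*([ACGT])\s*>\s*([ACGT])$")


@dataclass
class Variant:
    """One row of a homozygous-variant table (exome-filter output)."""

    chromosome: str
    position_bp: int
    gene: str
    cdna_change: str
    protein_change: str | None = None
    zygosity_in_proband: str = "hom"
    member_genotypes: dict[str, tuple[str, str] | None] | None = None
    population_maf: float | None = None
    known_polymorphism: bool = False

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise FormatError(f"variant position must be >= 1, got {self.position_bp}")
        if self.population_maf is not None and not (0.0 <= self.population_maf <= 1.0):
            raise FormatError(f"population MAF {self.population_maf} outside [0, 1]")

    def cdna_substitution(self) -> tuple[int, str, str] | None:
        """(position, ref, alt) for a simple c.NNNX>Y substitution, else None."""
        m = _HGVS_SUB.match(self.cdna_change.replace(" ", "").replace(" ", ""))
        if not m:
            return None
        return int(m.group(1)), m.group(2), m.group(3)

    @property
    def alt_allele(self) -> str | None:
        sub = self.cdna_substitution()
        return sub[2] if sub else None

    @property
    def ref_allele(self) -> str | None:
        sub = self.cdna_substitution()
        return sub[1] if sub else None


_COLUMN_ALIASES = {
    "chr": "chromosome",
    "chrom": "chromosome",
    "chromosome": "chromosome",
    "position": "position_bp",
    "pos": "position_bp",
    "position_bp": "position_bp",
    "gene": "gene",
    "cdna variant": "cdna_change",
    "cdna_change": "cdna_change",
    "cdna": "cdna_change",
    "protein variant": "protein_change",
    "protein_change": "protein_change",
    "protein": "protein_change",
    "maf": "population_maf",
    "population_maf": "population_maf",
    "known_polymorphism": "known_polymorphism",
    "known polymorphism": "known_polymorphism",
    "zygosity": "zygosity_in_proband",
}

_TRUE_STRINGS = {"1", "true", "yes", "y"}


def read_variant_table(tsv_path: str | Path) -> list[Variant]:
    """Read a variant TSV (Table-1-style headers accepted), order preserved.

    Per-member genotype columns are named ``gt_<individual id>`` with cells
    like ``C/T`` (``./.`` or empty = untyped).
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    colmap: dict[str, str] = {}
    gt_cols: list[str] = []
    for c in df.columns:
        key = c.strip().lower()
        if key.startswith("gt_"):
            gt_cols.append(c)
        elif key in _COLUMN_ALIASES:
            colmap[_COLUMN_ALIASES[key]] = c
    for required in ("chromosome", "position_bp", "gene", "cdna_change"):
        if required not in colmap:
            raise FormatError(f"{tsv_path}: missing required column {required!r}")

    variants: list[Variant] = []
    for ln, row in df.iterrows():
        pos_raw = str(row[colmap["position_bp"]]).replace(",", "").strip()
        try:
            pos = int(pos_raw)
        except ValueError:
            raise FormatError(
                f"{tsv_path}: row {ln + 2}: non-integer position {pos_raw!r}"
            ) from None
        maf = None
        if "population_maf" in colmap:
            cell = str(row[colmap["population_maf"]]).strip()
            if cell:
                maf = float(cell)
        known = False
        if "known_polymorphism" in colmap:
            known = str(row[colmap["known_polymorphism"]]).strip().lower() in _TRUE_STRINGS
        genotypes: dict[str, tuple[str, str] | None] | None = None
        if gt_cols:
            genotypes = {}
            for c in gt_cols:
                member = c[3:]
                cell = str(row[c]).strip()
                if not cell or cell in {"./.", ".", "0/0"}:
                    genotypes[member] = None
                else:
                    a, _, b = cell.partition("/")
                    genotypes[member] = (a.strip(), b.strip())
        protein = None
        if "protein_change" in colmap:
            cell = str(row[colmap["protein_change"]]).strip()
            protein = cell or None
        variants.append(
            Variant(
                chromosome=str(row[colmap["chromosome"]]).strip(),
                position_bp=pos,
                gene=str(row[colmap["gene"]]).strip(),
                cdna_change=str(row[colmap["cdna_change"]]).strip(),
                protein_change=protein,
                zygosity_in_proband=(
                    str(row[colmap["zygosity_in_proband"]]).strip() or "hom"
                    if "zygosity_in_proband" in colmap
                    else "hom"
                ),
                member_genotypes=genotypes,
                population_maf=maf,
                known_polymorphism=known,
            )
        )
    return variants


def write_variant_table(
    variants: Iterable[Variant],
    path: str | Path,
    annotations: Mapping[int, Mapping[str, object]] | None = None,
) -> None:
    """Write variants as TSV; ``annotations`` adds extra columns keyed by row index."""
    variants = list(variants)
    members: list[str] = []
    for v in variants:
        for m in v.member_genotypes or {}:
            if m not in members:
                members.append(m)
    ann_cols: list[str] = []
    for a in (annotations or {}).values():
        for k in a:
            if k not in ann_cols:
                ann_cols.append(k)
    header = ["chromosome", "position_bp", "gene", "cdna_change", "protein_change",
              "population_maf", "known_polymorphism"]
    header += [f"gt_{m}" for m in members] + ann_cols
    lines = ["\t".join(header)]
    for i, v in enumerate(variants):
        row = [
            v.chromosome,
            str(v.position_bp),
            v.gene,
            v.cdna_change,
            v.protein_change or "",
            "" if v.population_maf is None else repr(v.population_maf),
            "true" if v.known_polymorphism else "false",
        ]
        for m in members:
            g = (v.member_genotypes or {}).get(m)
            row.append("./." if g is None else f"{g[0]}/{g[1]}")
        ann = (annotations or {}).get(i, {})
        row += ["" if ann.get(c) is None else str(ann.get(c, "")) for c in ann_cols]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Region output
# ---------------------------------------------------------------------------


def write_regions(regions, path: str | Path) -> None:
    """BED-like TSV of candidate regions; 1-based closed intervals."""
    lines = [
        "# 1-based, closed intervals [start_bp, end_bp]",
        "chromosome\tstart_bp\tend_bp\tgenetic_length_cM\tn_markers\tconcordance",
    ]
    for r in regions:
        lines.append(
            f"{r.chromosome}\t{r.start_bp}\t{r.end_bp}\t{r.genetic_length_cM:.4f}"
            f"\t{r.n_markers}\t{r.concordance:.4f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_regions(path: str | Path) -> list:
    """Read a BED-like candidate-region TSV written by :func:`write_regions`.

    Accepts a minimal 3-column (chromosome, start_bp, end_bp) file as well;
    intervals are 1-based closed.
    """
    from .mapping import CandidateRegion

    regions = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 3:
            raise FormatError(f"{path}:{ln}: expected at least 3 tab-separated columns")
        if ln <= 2 and not _is_number(f[1]):
            continue  # header row
        regions.append(
            CandidateRegion(
                chromosome=f[0],
                start_bp=int(f[1]),
                end_bp=int(f[2]),
                genetic_length_cM=float(f[3]) if len(f) > 3 and f[3] else 0.0,
                n_markers=int(f[4]) if len(f) > 4 and f[4] else 0,
                concordance=float(f[5]) if len(f) > 5 and f[5] else 1.0,
            )
        )
    return regions


def normalize_chromosome(label: str) -> str:
    """Strip a ``chr`` prefix and uppercase X/Y/MT; used only when enabled in config."""
    s = label.strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s.upper() if s.lower() in {"x", "y", "mt", "m"} else s
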