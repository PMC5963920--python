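"""autozyg: autozygosity mapping and recessive-variant prioritization.

Maps a recessive disease locus in a consanguineous nuclear family from
SNP-array genotypes — runs of homozygosity per individual, shared
allele-identical regions across affected siblings, exclusion of stretches
shared with unaffected members, a minimum genetic length — and prioritizes
homozygous rare variants inside the mapped loci down to a single recessive
candidate.  A pedigree simulator with Haldane-model recombination provides
ground-truth test beds.
"""

from importlib import resources

__version__ = "0.1.0"

from .exceptions import (
    AutozygError,
    ConfigurationError,
    FormatError,
    IncompleteSegregationData,
    PedigreeError,
    ReferenceMismatchError,
    SimulationError,
)
from .io import (
    GeneticMap,
    GenotypeDataset,
    Individual,
    Marker,
    Pedigree,
    Sex,
    Status,
    Variant,
    interpolate_genetic_position,
    read_genetic_map,
    read_genotypes,
    read_regions,
    read_variant_table,
    write_genetic_map,
    write_genotypes,
    write_regions,
    write_variant_table,
)
from .mapping import (
    CandidateRegion,
    MappingConfig,
    exclude_unaffected,
    filter_by_genetic_length,
    shared_autozygous_regions,
)
from .pipeline import MappingReport, map_regions, run_pipeline
from .prioritize import (
    CodingSequence,
    PrioritizationConfig,
    ProteinChange,
    annotate_cds_change,
    check_recessive_segregation,
    intersect_and_filter,
    max_variants_in_window,
    rank_variants,
    read_cds_fasta,
)
from .roh import ROHParams, ROHSegment, call_roh
from .simulate import (
    Haplotype,
    SimulationConfig,
    SyntheticStudy,
    autozygous_fraction_samples,
    draw_crossover_positions,
    meiosis,
    simulate_study,
)


def table1_path():
    """Path to the packaged homozygous-variant table (exome study fixture)."""
    return resources.files("autozyg.data").joinpath("table1.tsv")
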