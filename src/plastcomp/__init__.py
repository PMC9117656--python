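"""plastcomp: comparative chloroplast-genome analysis toolkit.

Quadripartite (LSC/IRa/SSC/IRb) structure determination, SSR and
dispersed-repeat scanning, alignment-based SNP/InDel calling stratified by
annotation class, SNP-density hotspot discovery, species-discriminating
marker search, a light neighbor-joining phylogeny, and a plastome simulator
that produces ground-truthed synthetic data for all of the above.
"""

from importlib import resources

import pandas as pd

from .plastome_io import (
    AnnotatedGenome,
    Feature,
    Msa,
    derive_igs,
    read_fasta,
    read_genbank,
    read_msa,
    revcomp,
    write_fasta,
    write_genbank,
    write_msa,
)
from .quadripartite import (
    NoQuadripartiteStructure,
    QuadripartiteStructure,
    detect_inverted_repeat,
    gc_content,
    partition_table,
    ssc_summary_by_subgenus,
)
from .ssr import (
    SSRRecord,
    annotate_ssrs,
    discriminating_combinations,
    find_ssrs,
    marker_matrix,
    minimal_universal_marker_set,
    ssr_composition_stats,
)
from .repeats import (
    RepeatLocus,
    RepeatRecord,
    cluster_repeat_loci,
    find_repeats,
    symmetry_report,
)
from .variants import (
    IndelEvent,
    VariantTable,
    build_consensus,
    call_variants,
    indel_events,
    longest_indels,
    pairwise_differences,
)
from .hotspots import HotspotRegion, merge_hotspots, scan_windows, screen_markers
from .phylo import (
    is_monophyletic,
    neighbor_joining,
    nj_tree,
    p_distance,
    read_newick,
    write_newick,
)
from .simulate import (
    GroundTruth,
    SimulationConfig,
    SimulationResult,
    hotspot_demo_config,
    mini_config,
    preset_tree,
    replay,
    simulate,
)

__version__ = "0.1.0"


def load_reference_table() -> pd.DataFrame:
    """The published per-genome summary table (lengths, GC, subgenus) shipped
    with the package; the input for subgenus-level SSC statistics."""
    with resources.files("plastcomp").joinpath("data/amaranthus_plastomes.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
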