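"""Design intronless (or first-intron-only) mammalian transgenes.

Intronless transgenes express poorly unless GC content at synonymous
sites is raised, and exonic splice enhancers (ESEs) left near former
intron positions may be unhelpful once the introns are gone.  This
package removes introns from a gene body (optionally retaining the
first), stochastically recodes synonymous sites toward a GC3 target and
an ESE-density target near the removed junctions, protects restriction
sites, refuses to introduce blacklisted motifs, and selects the best of
a cloud of recoded variants.
"""

from .ese_motifs import (
    EseDensity,
    EseSet,
    ese_match_count,
    list_ese_sets,
    load_ese_set,
    overlapping_windows,
)
from .gene_io import (
    GeneError,
    GeneRecord,
    ProcessedGene,
    parse_fasta,
    parse_genbank,
    remove_introns,
    write_gene_fasta,
    write_outputs,
)
from .optimizer import (
    DesignConfig,
    SitePlan,
    Variant,
    VariantCloud,
    build_site_plan,
    find_restriction_matches,
    generate_cloud,
    generate_variant,
    score_variant,
    vicinity_density,
)
from .scoring import (
    GcTargetModel,
    ese_score,
    fit_position_curves,
    gc_score,
    selection_probabilities,
    synonymous_candidates,
    translate,
)
from .synthetic import ToyGeneSpec, make_cds, make_toy_gene, make_training_corpus

__version__ = "0.1.0"


def design(
    gene: GeneRecord, config: DesignConfig, model: GcTargetModel | None = None
) -> tuple[VariantCloud, SitePlan, ProcessedGene]:
    """End-to-end design: splice, plan, generate the cloud.

    ``model`` defaults to the packaged model for the configured
    strategy.  Returns the cloud (``cloud.best`` is the winning
    variant), the site plan and the processed gene.
    """
    if model is None:
        model = default_model(config.gc_strategy)
    processed = remove_introns(gene, keep_first=config.keep_first_intron)
    plan = build_site_plan(processed, config)
    cloud = generate_cloud(processed, plan, model, config)
    return cloud, plan, processed


def default_model(strategy: str) -> GcTargetModel:
    """The packaged GcTargetModel for a strategy name."""
    if strategy == "one_two_exon":
        return GcTargetModel.default_one_two_exon()
    if strategy == "human_usage":
        return GcTargetModel.default_human_usage()
    if strategy == "max_gc":
        return GcTargetModel.max_gc()
    if strategy == "ese_only":
        return GcTargetModel.ese_only()
    raise ValueError(f"unknown GC strategy {strategy!r}")
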