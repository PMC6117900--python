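"""High-level orchestration: genomes in, barcodes out; reads in, calls out."""

from __future__ import annotations

import logging
from dataclasses import dataclass

from . import barcode_builder, cog_metrics, genome_io, orthology

log = logging.getLogger(__name__)


@dataclass
class BarcodePipelineResult:
    barcode_set: barcode_builder.BarcodeSet
    stats: list[cog_metrics.CogStats]
    core_cogs: list[orthology.COG]
    accessory_cogs: list[orthology.COG]
    selected_core_ids: list[str]


def build_barcodes(
    genomes: list[genome_io.Genome],
    requested_length: int,
    accessory_fraction: float = barcode_builder.DEFAULT_ACCESSORY_FRACTION,
    e_cutoff: float = orthology.DEFAULT_E_CUTOFF,
    keep_partial: bool = False,
) -> BarcodePipelineResult:
    """The barcode-generation pipeline.

    Extract complete CDS, cluster them into COGs, codon-align and score the
    core COGs, then concatenate top-scoring genes (plus greedy accessory
    cover) into one barcode per genome.
    """
    genes_by_genome = {
        g.genome_id: genome_io.extract_cds(g, keep_partial=keep_partial)
        for g in genomes
    }
    gene_index = {
        gene.gene_id: gene
        for genes in genes_by_genome.values()
        for gene in genes
    }
    core, accessory = orthology.cluster_cogs(
        genomes, e_cutoff=e_cutoff, genes_by_genome=genes_by_genome
    )
    log.info("clustered %d core and %d accessory COGs", len(core), len(accessory))
    stats = []
    for cog in core:
        try:
            aln = cog_metrics.codon_align_cog(cog, gene_index.__getitem__)
        except cog_metrics.FrameErrorInCOG as exc:
            log.warning("skipping COG: %s", exc)
            continue
        products = ";".join(
            sorted({gene_index[g].product for g in cog.gene_ids if gene_index[g].product})
        )
        stats.append(cog_metrics.score_cog(aln, products=products))
    barcode_set = barcode_builder.assemble_barcodes(
        stats,
        core,
        accessory,
        gene_index.__getitem__,
        requested_length,
        accessory_fraction,
        genome_ids=sorted(genes_by_genome),
    )
    selected = sorted(
        {
            seg.cog_id
            for b in barcode_set.barcodes.values()
            for seg in b.segments
            if seg.origin == "core"
        }
    )
    return BarcodePipelineResult(
        barcode_set=barcode_set,
        stats=stats,
        core_cogs=core,
        accessory_cogs=accessory,
        selected_core_ids=selected,
    )
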