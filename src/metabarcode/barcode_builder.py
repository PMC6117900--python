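"""Barcode assembly: concatenate top-scoring genes into per-genome barcodes.

Core COGs are taken in descending suitability-score order (ties: smaller
COG id first) and every genome's member gene is appended to that genome's
barcode, stopping at the first COG whose inclusion brings the *minimum*
per-genome core length to the target.  Accessory genes are then added by a
greedy cover - repeatedly picking the accessory COG carried by the largest
number of genomes still below their accessory budget - until every genome
meets its budget or the families are exhausted.  Genes are concatenated
without spacers; because genes come in whole units the realized lengths
overshoot the requested ones by at most one gene, and the realized values
are reported rather than trimmed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

from .cog_metrics import CogStats
from .genome_io import GeneRecord
from .orthology import COG

log = logging.getLogger(__name__)

DEFAULT_ACCESSORY_FRACTION = 0.3  # 70% core / 30% accessory split


@dataclass(frozen=True)
class BarcodeSegment:
    gene_id: str
    cog_id: str
    start: int  # 0-based within the barcode
    end: int  # half-open
    origin: str  # 'core' or 'accessory'
    product: str = ""


@dataclass
class Barcode:
    genome_id: str
    sequence: str = ""
    segments: list[BarcodeSegment] = field(default_factory=list)

    def append(self, gene: GeneRecord, cog_id: str, origin: str) -> None:
        start = len(self.sequence)
        self.sequence += gene.nt_seq
        self.segments.append(
            BarcodeSegment(
                gene_id=gene.gene_id,
                cog_id=cog_id,
                start=start,
                end=len(self.sequence),
                origin=origin,
                product=gene.product,
            )
        )

    @property
    def core_length(self) -> int:
        return sum(s.end - s.start for s in self.segments if s.origin == "core")

    @property
    def accessory_length(self) -> int:
        return sum(s.end - s.start for s in self.segments if s.origin == "accessory")


@dataclass
class BarcodeSet:
    barcodes: dict[str, Barcode]
    requested_length: int
    accessory_fraction: float

    @property
    def lengths(self) -> dict[str, int]:
        return {g: len(b.sequence) for g, b in self.barcodes.items()}

    def sequences(self) -> dict[str, str]:
        return {g: b.sequence for g, b in self.barcodes.items()}


def rank_cogs(stats: list[CogStats]) -> list[CogStats]:
    """Descending score, ties broken by ascending COG id."""
    return sorted(stats, key=lambda s: (-s.score, s.cog_id))


def assemble_core_barcode(
    stats: list[CogStats],
    target_core_length: int,
    cogs_by_id: dict[str, COG],
    gene_lookup: Callable[[str], GeneRecord],
    genome_ids: list[str] | None = None,
) -> BarcodeSet:
    """Greedy concatenation of top-scoring core genes.

    The same COGs, in the same order, are used for every genome; the
    stopping rule watches the minimum per-genome length so that every
    barcode reaches ``target_core_length`` (or a warning is emitted when
    the core genome is too small).
    """
    if genome_ids is None:
        first = cogs_by_id[stats[0].cog_id] if stats else None
        genome_ids = sorted(first.members) if first else []
    barcodes = {g: Barcode(genome_id=g) for g in genome_ids}
    if target_core_length > 0:
        for stat in rank_cogs(stats):
            cog = cogs_by_id[stat.cog_id]
            for genome_id in genome_ids:
                gene = gene_lookup(cog.single_member(genome_id))
                barcodes[genome_id].append(gene, cog.cog_id, "core")
            if min(b.core_length for b in barcodes.values()) >= target_core_length:
                break
        else:
            if stats:
                log.warning(
                    "requested length unreachable: all %d core COGs used, min core length %d < %d",
                    len(stats),
                    min(b.core_length for b in barcodes.values()),
                    target_core_length,
                )
    return BarcodeSet(
        barcodes=barcodes,
        requested_length=target_core_length,
        accessory_fraction=0.0,
    )


def select_accessory_genes(
    accessory_cogs: list[COG],
    target_accessory_length: int,
    gene_lookup: Callable[[str], GeneRecord],
    genome_ids: list[str],
) -> dict[str, list[str]]:
    """Greedy cover of per-genome accessory budgets.

    Each round picks the accessory COG present in the largest number of
    genomes still below their budget (ties: longer maximum member gene,
    then lexicographically smaller COG id); the COG then contributes its
    member gene to *every* genome carrying it.  Genomes without accessory
    genes keep core-only barcodes.
    """
    selected: dict[str, list[str]] = {g: [] for g in genome_ids}
    if not accessory_cogs:
        log.warning("no accessory genes available")
        return selected
    if target_accessory_length <= 0:
        return selected
    fill = {g: 0 for g in genome_ids}

    def member_gene(cog: COG, genome_id: str) -> GeneRecord:
        return gene_lookup(sorted(cog.members[genome_id])[0])

    remaining = list(accessory_cogs)
    while remaining:
        needy = {g for g in genome_ids if fill[g] < target_accessory_length}
        if not needy:
            break

        def priority(cog: COG):
            coverage = sum(1 for g in cog.members if g in needy)
            longest = max(len(member_gene(cog, g)) for g in cog.members)
            return (-coverage, -longest, cog.cog_id)

        remaining.sort(key=priority)
        best = remaining.pop(0)
        if not any(g in needy for g in best.members):
            break  # nothing left that helps a needy genome
        for genome_id in sorted(best.members):
            if genome_id not in selected:
                continue
            gene = member_gene(best, genome_id)
            selected[genome_id].append(gene.gene_id)
            fill[genome_id] += len(gene)
    uncovered = [g for g in genome_ids if fill[g] < target_accessory_length]
    if uncovered:
        log.warning("accessory budget not met for: %s", ", ".join(uncovered))
    return selected


def assemble_barcodes(
    stats: list[CogStats],
    core_cogs: list[COG],
    accessory_cogs: list[COG],
    gene_lookup: Callable[[str], GeneRecord],
    requested_length: int,
    accessory_fraction: float = DEFAULT_ACCESSORY_FRACTION,
    genome_ids: list[str] | None = None,
) -> BarcodeSet:
    """Full barcode assembly: core then accessory portions.

    ``target_core_length = (1 - accessory_fraction) * requested_length``;
    the remainder is the per-genome accessory budget.
    """
    if not 0 <= accessory_fraction < 1:
        raise ValueError("accessory_fraction must be in [0, 1)")
    cogs_by_id = {c.cog_id: c for c in core_cogs}
    if genome_ids is None:
        genome_ids = sorted(core_cogs[0].members) if core_cogs else []
    target_core = int(round((1.0 - accessory_fraction) * requested_length))
    bs = assemble_core_barcode(stats, target_core, cogs_by_id, gene_lookup, genome_ids)
    target_accessory = requested_length - target_core
    acc_by_genome = select_accessory_genes(
        accessory_cogs, target_accessory, gene_lookup, genome_ids
    )
    acc_cog_of_gene = {
        gene_id: cog.cog_id
        for cog in accessory_cogs
        for gene_id in cog.gene_ids
    }
    for genome_id in genome_ids:
        for gene_id in acc_by_genome[genome_id]:
            gene = gene_lookup(gene_id)
            bs.barcodes[genome_id].append(gene, acc_cog_of_gene[gene_id], "accessory")
    bs.requested_length = requested_length
    bs.accessory_fraction = accessory_fraction
    return bs


def write_barcode_outputs(bs: BarcodeSet, out_dir: str | Path) -> dict[str, Path]:
    """Write the multi-FASTA plus one per-barcode segment info file.

    Info files report 1-based inclusive coordinates, matching the GenBank
    convention used everywhere in reported output.
    """
    if not bs.barcodes or all(not b.sequence for b in bs.barcodes.values()):
        raise ValueError("empty BarcodeSet: nothing to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta_path = out_dir / "barcodes.fasta"
    paths: dict[str, Path] = {"fasta": fasta_path}
    with open(fasta_path, "w") as fasta:
        for genome_id in sorted(bs.barcodes):
            barcode = bs.barcodes[genome_id]
            fasta.write(f">{genome_id}\n")
            for i in range(0, len(barcode.sequence), 60):
                fasta.write(barcode.sequence[i : i + 60] + "\n")
            info_path = out_dir / f"{genome_id}.info.tsv"
            with open(info_path, "w") as info:
                info.write(
                    "barcode_id\tsegment_index\tgene_id\tstart\tend\torigin\tproduct\n"
                )
                for idx, seg in enumerate(barcode.segments, 1):
                    info.write(
                        f"{genome_id}\t{idx}\t{seg.gene_id}\t{seg.start + 1}\t{seg.end}\t{seg.origin}\t{seg.product}\n"
                    )
            paths[genome_id] = info_path
    return paths


def read_barcode_fasta(path: str | Path) -> dict[str, str]:
    """Read barcodes back from a multi-FASTA written by this module."""
    from Bio import SeqIO

    with open(path) as handle:
        return {r.id: str(r.seq).upper() for r in SeqIO.parse(handle, "fasta")}
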