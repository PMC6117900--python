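"""Orthologous-gene clustering via reciprocal best hits.

Genes from every pair of genomes are compared at the protein level; a pair
of genes is a reciprocal best hit (RBH) when each is the other's top-scoring
match with an expectation value below the cut-off (default 1e-4).  RBH pairs
from all genome pairs are merged by transitive closure (union-find) into
clusters of orthologous genes (COGs).  A COG that contains exactly one gene
from every input genome is a *core* COG; every other cluster - including
genes that never found a reciprocal partner - belongs to the accessory
genome.  Clusters holding in-paralogs (two or more genes from one genome)
are never core, because a core COG must contribute exactly one sequence per
genome to the downstream codon alignment and barcode concatenation.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass

from . import _align
from .genome_io import GeneRecord, Genome

log = logging.getLogger(__name__)

DEFAULT_E_CUTOFF = 1e-4


@dataclass(frozen=True)
class ProteinHit:
    """Similarity evidence for one query/subject protein pair."""

    query_id: str
    subject_id: str
    raw_score: float
    e_value: float
    identities: int
    positives: int
    aligned_length: int


@dataclass
class COG:
    """A cluster of orthologous genes across the input genomes."""

    cog_id: str
    members: dict[str, list[str]]  # genome_id -> gene_ids (usually one)
    is_core: bool

    @property
    def gene_ids(self) -> list[str]:
        return [g for genes in self.members.values() for g in genes]

    def single_member(self, genome_id: str) -> str:
        genes = self.members[genome_id]
        if len(genes) != 1:
            raise ValueError(f"{self.cog_id}: {genome_id} has {len(genes)} members")
        return genes[0]

    @property
    def n_genomes(self) -> int:
        return len(self.members)


DEFAULT_SEED_K = 4
DEFAULT_MIN_SHARED_KMERS = 4


def _kmer_index(genes: list[GeneRecord], k: int) -> dict[str, set[int]]:
    index: dict[str, set[int]] = defaultdict(set)
    for j, gene in enumerate(genes):
        for kmer in _align.kmer_set(gene.aa_seq, k):
            index[kmer].add(j)
    return index


def _candidates(
    query: GeneRecord, index: dict[str, set[int]], k: int, min_shared: int
) -> list[int]:
    """Subject indices sharing enough distinct k-mers with the query.

    Counting *distinct* shared k-mer types keeps the criterion symmetric
    in query and subject, which the reciprocal search relies on.
    """
    counts: Counter[int] = Counter()
    for kmer in _align.kmer_set(query.aa_seq, k):
        for j in index.get(kmer, ()):
            counts[j] += 1
    return [j for j, c in counts.items() if c >= min_shared]


def _traceback_stats(aligner, aa_q: str, aa_s: str) -> tuple[int, int, int]:
    alignment = aligner.align(aa_q, aa_s)[0]
    gapped_q, gapped_s = _align.aligned_strings(alignment)
    return _align.alignment_stats(gapped_q, gapped_s)


def pairwise_protein_search(
    queries: list[GeneRecord],
    subjects: list[GeneRecord],
    e_cutoff: float = DEFAULT_E_CUTOFF,
    k: int = DEFAULT_SEED_K,
    min_shared_kmers: int = DEFAULT_MIN_SHARED_KMERS,
) -> list[ProteinHit]:
    """Search every query protein against the subject set.

    The built-in backend is a k-mer-seeded Smith-Waterman: only subjects
    sharing at least ``min_shared_kmers`` distinct amino-acid ``k``-mers
    with the query are aligned (BLOSUM62, gap 11/1), and hits are kept when
    the Karlin-Altschul expectation value is at or below ``e_cutoff``.
    Hits are returned sorted per query by descending raw score, with ties
    broken by more identities, then lexicographically smaller subject id.
    """
    if not queries or not subjects:
        log.warning("pairwise_protein_search: empty input, no hits")
        return []
    aligner = _align.protein_aligner("local")
    index = _kmer_index(subjects, k)
    hits: list[ProteinHit] = []
    for query in queries:
        query_hits = []
        for j in _candidates(query, index, k, min_shared_kmers):
            subject = subjects[j]
            raw = aligner.score(query.aa_seq, subject.aa_seq)
            e_value = _align.evalue(raw, len(query.aa_seq), len(subject.aa_seq))
            if e_value > e_cutoff:
                continue
            identities, positives, aligned_length = _traceback_stats(
                aligner, query.aa_seq, subject.aa_seq
            )
            query_hits.append(
                ProteinHit(
                    query_id=query.gene_id,
                    subject_id=subject.gene_id,
                    raw_score=raw,
                    e_value=e_value,
                    identities=identities,
                    positives=positives,
                    aligned_length=aligned_length,
                )
            )
        query_hits.sort(key=lambda h: (-h.raw_score, -h.identities, h.subject_id))
        hits.extend(query_hits)
    return hits


def best_hits(hits: list[ProteinHit]) -> dict[str, ProteinHit]:
    """Top hit per query under the deterministic tie rule."""
    best: dict[str, ProteinHit] = {}
    for hit in hits:
        current = best.get(hit.query_id)
        if current is None or (
            (-hit.raw_score, -hit.identities, hit.subject_id)
            < (-current.raw_score, -current.identities, current.subject_id)
        ):
            best[hit.query_id] = hit
    return best


def _best_side(
    scored: dict[tuple[int, int], float],
    genes_q: list[GeneRecord],
    genes_s: list[GeneRecord],
    axis: int,
    aligner,
) -> dict[int, int]:
    """Best partner per query index from a symmetric score table.

    ``axis`` 0 treats the first tuple element as the query.  Ties in raw
    score fall back to more identities, then the smaller subject gene id;
    identities are only computed for the tied pairs.
    """
    by_query: dict[int, list[tuple[int, float]]] = defaultdict(list)
    for (i, j), raw in scored.items():
        q, s = (i, j) if axis == 0 else (j, i)
        by_query[q].append((s, raw))
    best: dict[int, int] = {}
    for q, partners in by_query.items():
        top = max(raw for _, raw in partners)
        tied = sorted(s for s, raw in partners if raw == top)
        if len(tied) == 1:
            best[q] = tied[0]
            continue
        q_gene = genes_q[q]

        def tie_key(s: int):
            s_gene = genes_s[s]
            identities, _, _ = _traceback_stats(aligner, q_gene.aa_seq, s_gene.aa_seq)
            return (-identities, s_gene.gene_id)

        best[q] = min(tied, key=tie_key)
    return best


def reciprocal_best_hits(
    genome_a: Genome,
    genome_b: Genome,
    e_cutoff: float = DEFAULT_E_CUTOFF,
    genes_a: list[GeneRecord] | None = None,
    genes_b: list[GeneRecord] | None = None,
    k: int = DEFAULT_SEED_K,
    min_shared_kmers: int = DEFAULT_MIN_SHARED_KMERS,
) -> list[tuple[str, str]]:
    """Gene pairs that are each other's best protein match across two genomes.

    The local-alignment score is symmetric, so each candidate pair is
    scored once and both directions' best hits are read off the same
    table.
    """
    genes_a = genome_a.genes if genes_a is None else genes_a
    genes_b = genome_b.genes if genes_b is None else genes_b
    if not genes_a or not genes_b:
        return []
    aligner = _align.protein_aligner("local")
    index_b = _kmer_index(genes_b, k)
    scored: dict[tuple[int, int], float] = {}
    for i, query in enumerate(genes_a):
        for j in _candidates(query, index_b, k, min_shared_kmers):
            subject = genes_b[j]
            raw = aligner.score(query.aa_seq, subject.aa_seq)
            e_value = _align.evalue(raw, len(query.aa_seq), len(subject.aa_seq))
            if e_value <= e_cutoff:
                scored[(i, j)] = raw
    best_ab = _best_side(scored, genes_a, genes_b, 0, aligner)
    best_ba = _best_side(scored, genes_b, genes_a, 1, aligner)
    pairs = []
    for i, j in sorted(best_ab.items()):
        if best_ba.get(j) == i:
            pairs.append((genes_a[i].gene_id, genes_b[j].gene_id))
    return pairs


class _UnionFind:
    def __init__(self):
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        parent = self.parent.setdefault(x, x)
        if parent != x:
            self.parent[x] = parent = self.find(parent)
        return parent

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic root choice
            if ra < rb:
                self.parent[rb] = ra
            else:
                self.parent[ra] = rb


def cluster_cogs(
    genomes: list[Genome],
    e_cutoff: float = DEFAULT_E_CUTOFF,
    genes_by_genome: dict[str, list[GeneRecord]] | None = None,
) -> tuple[list[COG], list[COG]]:
    """Partition all genes into core and accessory COGs.

    ``genes_by_genome`` lets the caller pass pre-filtered CDS lists (see
    :func:`metabarcode.genome_io.extract_cds`); by default every parsed gene
    is used.  Every input gene ends up in exactly one cluster.
    """
    if genes_by_genome is None:
        genes_by_genome = {g.genome_id: g.genes for g in genomes}
    gene_to_genome = {
        gene.gene_id: genome_id
        for genome_id, genes in genes_by_genome.items()
        for gene in genes
    }
    if len(genomes) < 2:
        log.warning("cluster_cogs: single genome, all genes are accessory")
        accessory = [
            COG(cog_id="", members={gene_to_genome[g]: [g]}, is_core=False)
            for g in sorted(gene_to_genome)
        ]
        return [], _assign_ids([], accessory)[1]

    uf = _UnionFind()
    for genome_a, genome_b in itertools.combinations(
        sorted(genomes, key=lambda g: g.genome_id), 2
    ):
        pairs = reciprocal_best_hits(
            genome_a,
            genome_b,
            e_cutoff,
            genes_a=genes_by_genome[genome_a.genome_id],
            genes_b=genes_by_genome[genome_b.genome_id],
        )
        for a, b in pairs:
            uf.union(a, b)

    components: dict[str, list[str]] = defaultdict(list)
    for gene_id in sorted(gene_to_genome):
        components[uf.find(gene_id)].append(gene_id)

    n_genomes = len(genes_by_genome)
    core: list[COG] = []
    accessory: list[COG] = []
    for gene_ids in components.values():
        members: dict[str, list[str]] = defaultdict(list)
        for gene_id in gene_ids:
            members[gene_to_genome[gene_id]].append(gene_id)
        members = {k: sorted(v) for k, v in sorted(members.items())}
        is_core = len(members) == n_genomes and all(
            len(v) == 1 for v in members.values()
        )
        cog = COG(cog_id="", members=members, is_core=is_core)
        (core if is_core else accessory).append(cog)
    return _assign_ids(core, accessory)


def _assign_ids(core: list[COG], accessory: list[COG]) -> tuple[list[COG], list[COG]]:
    def sort_key(cog: COG):
        return min(cog.gene_ids)

    core.sort(key=sort_key)
    accessory.sort(key=sort_key)
    for i, cog in enumerate(core, 1):
        cog.cog_id = f"COG{i:05d}"
    for i, cog in enumerate(accessory, 1):
        cog.cog_id = f"ACC{i:05d}"
    return core, accessory
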