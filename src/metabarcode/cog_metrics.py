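"""Codon alignment of core COGs and the three divergence axes X, Y, Z.

Each core COG is aligned at the protein level and the gaps are threaded
back onto the codons, so that gap columns always appear as triplets.  From
every genome pair in the alignment three statistics are computed over the
ungapped aligned codon pairs:

* ``X`` - the fraction of nucleotide substitutions that are *sense*
  (non-synonymous): a substitution is counted as sense when the codon it
  sits in translates differently between the two rows (in codons carrying
  several substitutions every differing nucleotide is counted, and the
  codon's classification applies to all of them);
* ``Y`` - protein-level divergence, 1 minus the fraction of identical
  aligned amino-acid pairs;
* ``Z`` - ``(positives - identities) / identities`` where positives are
  aligned amino-acid pairs with a positive BLOSUM62 score (identities
  included), the BLAST "Positives" statistic.

X and Y are fractions on [0, 1].  A COG's suitability for barcoding is
``score = X * (1 - X) * (1 - Y) / (Z + 1)`` with X, Y, Z averaged over all
genome pairs; the score is maximal (0.25) for a perfectly conserved protein
(Y = Z = 0) whose substitutions are half sense, half silent (X = 0.5), i.e.
a gene conserved enough to align reliably but still under moderate positive
selection.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Callable

from Bio.Data import CodonTable

from . import _align
from .genome_io import GeneRecord
from .orthology import COG

log = logging.getLogger(__name__)


class FrameErrorInCOG(ValueError):
    pass


@dataclass
class CodonAlignment:
    """Gapped nucleotide rows of one core COG, gaps in codon triplets."""

    cog_id: str
    rows: dict[str, str]  # genome_id -> gapped nucleotide sequence

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))


@dataclass
class PairStats:
    x: float
    y: float
    z: float
    n_substitutions: int
    identities: int
    positives: int
    aligned_codons: int
    degenerate: bool  # identities == 0, z defined as 0


@dataclass
class CogStats:
    cog_id: str
    X: float
    Y: float
    Z: float
    score: float
    n_pairs: int
    degenerate: bool = False
    products: str = ""


def _codon_table(table: int = 11) -> dict[str, str]:
    ct = CodonTable.unambiguous_dna_by_id[table]
    mapping = dict(ct.forward_table)
    for stop in ct.stop_codons:
        mapping[stop] = "*"
    return mapping


_CODON_TO_AA = _codon_table(11)


def translate_codon(codon: str) -> str:
    """Single-codon translation; N-containing or unknown codons give X."""
    return _CODON_TO_AA.get(codon, "X")


# ---------------------------------------------------------------------------
# built-in progressive (center-star) protein aligner
# ---------------------------------------------------------------------------

def _pairwise_global(a: str, b: str) -> tuple[str, str]:
    aligner = _align.protein_aligner("global")
    alignment = aligner.align(a, b)[0]
    return _align.aligned_strings(alignment)


def center_star_msa(seqs: dict[str, str]) -> dict[str, str]:
    """Progressive multiple alignment by the center-star heuristic.

    The center is the sequence with the largest summed global alignment
    score against all others (ties: lexicographically smallest key); every
    other sequence is aligned to the center and the pairwise gap patterns
    are merged under the once-a-gap-always-a-gap rule.
    """
    keys = sorted(seqs)
    if len(keys) == 1:
        return dict(seqs)
    aligner = _align.protein_aligner("global")
    totals = {k: 0.0 for k in keys}
    for a, b in itertools.combinations(keys, 2):
        s = aligner.score(seqs[a], seqs[b])
        totals[a] += s
        totals[b] += s
    center = min(keys, key=lambda k: (-totals[k], k))
    center_seq = seqs[center]
    n = len(center_seq)

    pairwise: dict[str, tuple[str, str]] = {}
    insertions = [0] * (n + 1)  # inserted columns before center position i
    for key in keys:
        if key == center:
            continue
        gapped_c, gapped_s = _pairwise_global(center_seq, seqs[key])
        pairwise[key] = (gapped_c, gapped_s)
        pos = 0
        run = 0
        for c in gapped_c:
            if c == "-":
                run += 1
            else:
                insertions[pos] = max(insertions[pos], run)
                run = 0
                pos += 1
        insertions[n] = max(insertions[n], run)

    rows: dict[str, str] = {}
    out = []
    for i in range(n):
        out.append("-" * insertions[i])
        out.append(center_seq[i])
    out.append("-" * insertions[n])
    rows[center] = "".join(out)

    for key in keys:
        if key == center:
            continue
        gapped_c, gapped_s = pairwise[key]
        out = []
        pos = 0
        pending = []  # subject chars inserted before the next center position
        for c, s in zip(gapped_c, gapped_s):
            if c == "-":
                pending.append(s)
            else:
                out.append("".join(pending) + "-" * (insertions[pos] - len(pending)))
                pending = []
                out.append(s)
                pos += 1
        out.append("".join(pending) + "-" * (insertions[n] - len(pending)))
        rows[key] = "".join(out)

    lengths = {len(r) for r in rows.values()}
    assert len(lengths) == 1, "center-star merge produced ragged rows"
    return rows


def codon_align_cog(
    cog: COG,
    gene_lookup: Callable[[str], GeneRecord],
    msa: Callable[[dict[str, str]], dict[str, str]] = center_star_msa,
) -> CodonAlignment:
    """Protein-align a core COG and thread the gaps back onto codons.

    The ``msa`` backend is pluggable; the built-in center-star aligner is
    the default.  A terminal stop codon, when present, is kept as the final
    ungapped column triple so that degapping a row reproduces the member
    gene's nucleotide sequence exactly.
    """
    genes = {genome_id: gene_lookup(cog.single_member(genome_id)) for genome_id in cog.members}
    proteins = {}
    for genome_id, gene in genes.items():
        if len(gene.nt_seq) % 3 != 0 or not gene.aa_seq:
            raise FrameErrorInCOG(f"{cog.cog_id}: {gene.gene_id} does not translate cleanly")
        proteins[genome_id] = gene.aa_seq
    aligned = msa(proteins)

    any_stop = any(
        len(g.nt_seq) == 3 * (len(g.aa_seq) + 1) for g in genes.values()
    )
    rows: dict[str, str] = {}
    for genome_id, gapped_aa in aligned.items():
        gene = genes[genome_id]
        codons = [gene.nt_seq[i : i + 3] for i in range(0, len(gene.nt_seq), 3)]
        has_stop = len(codons) == len(gene.aa_seq) + 1
        it = iter(codons[: len(gene.aa_seq)])
        parts = ["---" if aa == "-" else next(it) for aa in gapped_aa]
        if any_stop:
            parts.append(codons[-1] if has_stop else "---")
        rows[genome_id] = "".join(parts)
    return CodonAlignment(cog_id=cog.cog_id, rows=rows)


# ---------------------------------------------------------------------------
# divergence statistics
# ---------------------------------------------------------------------------

def pairwise_divergence_stats(
    aln: CodonAlignment,
    genome_i: str,
    genome_j: str,
    matrix=None,
) -> PairStats:
    """X, Y, Z for one genome pair of a codon alignment.

    Columns with a gap on either side, stop codons and N-containing codons
    are excluded.  With no substitutions X is defined as 0; with zero
    identities Z is defined as 0 and the pair flagged degenerate.
    """
    if matrix is None:
        matrix = _align.blosum62()
    row_i, row_j = aln.rows[genome_i], aln.rows[genome_j]
    n_sense = n_silent = 0
    identities = positives = aligned = 0
    for k in range(0, len(row_i), 3):
        ci, cj = row_i[k : k + 3], row_j[k : k + 3]
        if "-" in ci or "-" in cj or "N" in ci or "N" in cj:
            continue
        ai, aj = translate_codon(ci), translate_codon(cj)
        if ai == "*" or aj == "*" or ai == "X" or aj == "X":
            continue
        aligned += 1
        if ai == aj:
            identities += 1
        if matrix[ai, aj] > 0:
            positives += 1
        diffs = sum(1 for a, b in zip(ci, cj) if a != b)
        if diffs:
            if ai == aj:
                n_silent += diffs
            else:
                n_sense += diffs
    if aligned == 0:
        raise ValueError(f"{aln.cog_id}: no aligned codons between {genome_i} and {genome_j}")
    total_subs = n_sense + n_silent
    x = n_sense / total_subs if total_subs else 0.0
    y = 1.0 - identities / aligned
    degenerate = identities == 0
    z = 0.0 if degenerate else (positives - identities) / identities
    return PairStats(
        x=x,
        y=y,
        z=z,
        n_substitutions=total_subs,
        identities=identities,
        positives=positives,
        aligned_codons=aligned,
        degenerate=degenerate,
    )


def suitability_score(x: float, y: float, z: float) -> float:
    """The barcoding suitability score ``X (1 - X) (1 - Y) / (Z + 1)``."""
    return x * (1.0 - x) * (1.0 - y) / (z + 1.0)


def score_cog(aln: CodonAlignment, products: str = "") -> CogStats:
    """Average the pairwise axes over all genome pairs and score the COG."""
    pairs = list(itertools.combinations(sorted(aln.rows), 2))
    stats = [pairwise_divergence_stats(aln, a, b) for a, b in pairs]
    n = len(stats)
    x = sum(s.x for s in stats) / n
    y = sum(s.y for s in stats) / n
    z = sum(s.z for s in stats) / n
    return CogStats(
        cog_id=aln.cog_id,
        X=x,
        Y=y,
        Z=z,
        score=suitability_score(x, y, z),
        n_pairs=n,
        degenerate=any(s.degenerate for s in stats),
        products=products,
    )


def write_stats_table(stats: list[CogStats], path) -> None:
    """Optional per-COG tab-separated stats table."""
    with open(path, "w") as handle:
        handle.write("cog_id\tX\tY\tZ\tscore\tn_pairs\tproducts\n")
        for s in stats:
            handle.write(
                f"{s.cog_id}\t{s.X:.6f}\t{s.Y:.6f}\t{s.Z:.6f}\t{s.score:.6f}\t{s.n_pairs}\t{s.products}\n"
            )
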