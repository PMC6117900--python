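"""Metagenomic read binning against barcode sequences.

The engine aligns every read locally against every barcode (seeded
Smith-Waterman; match +1, mismatch -2, gap open -5, gap extend -2, one best
hit per read/barcode pair), then applies a cascade of scores:

1.  an adaptive score filter ``S'`` computed from the pre-filter pool
    statistics (mean hit score S, mean read length L, number of aligned
    reads N)::

        S' = S + (L - S) / (1 + e^(3 (L - S) / (S lg N)))
               - 10 (ln((2 S + 100) / (L + 100)) - 1)

    hits scoring below S' are discarded;
2.  the pool-level *alignment specificity*
    ``a = 1 - (N_matches - N_aligned) / (N_aligned (N_barcodes - 1))`` -
    1 when every aligned read matches a single barcode, 0 when every read
    matches all of them;
3.  per-read *specificity* ``r_spec = (N_barcodes - n_hit)/(N_barcodes - 1)``
    and *vicinity* ``r_vic``: from the matrix of Jaccard distances between
    the barcodes' post-filter read sets, a read hitting several barcodes
    gets ``10 * max_distance_among_its_barcodes / max_matrix_distance``
    (0 for single-barcode reads) - reads shared by *closely related*
    barcodes are spared the promiscuity penalty;
4.  per-read scores::

        ReadScore1 = (raw/len) * (r_spec + e^(r_spec*r_vic) + 1) / (r_spec + e^r_vic + 1)
        ReadScore2 = a * (N_reads|barcode / N_reads) * (raw/len)
                       * (r_spec + 1.5^(r_spec*r_vic) + 1) / (r_spec + 1.5^r_vic + 1)

5.  per-barcode scores, for flavour s in {1, 2}::

        BarcodeScore_s,i = (1 + sum_{reads->i} ReadScore_s)
                           / (1 + 3 L_i T_i / (4 sum_j L_j)) - 1

    where ``T_i`` is the sum of length-normalized raw scores of the reads
    aligned to barcode i.  The ratio structure makes the scores invariant
    under a uniform rescaling of all barcode lengths.  A barcode is called
    present when BarcodeScore1 >= cutoff1 (default 2.3) *and*
    BarcodeScore2 >= cutoff2 (default 0.5); the boundary counts as present.

Normalizing the score sums by read length and summing them per barcode
(rather than over the whole pool), and taking ``N_reads`` in ReadScore2 as
the number of *aligned* reads, are the interpretation choices under which
both default cut-offs act as meaningful detection thresholds; both are
switchable (``score_sum_mode``, ``nreads_mode``) and discussed in
docs/methods.md.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from . import _align
from .barcode_builder import BarcodeSet

log = logging.getLogger(__name__)

DEFAULT_CUTOFF1 = 2.3
DEFAULT_CUTOFF2 = 0.5
DEFAULT_MIN_SCORE = 30.0
DEFAULT_SEED_K = 13

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadHit:
    """Best local alignment of one read against one barcode."""

    read_id: str
    barcode_id: str
    raw_score: float
    read_length: int
    e_value: float = 0.0

    @property
    def normalized_score(self) -> float:
        return self.raw_score / self.read_length


@dataclass
class AlignmentPool:
    """All hits plus the summary statistics feeding the score cascade."""

    hits: list[ReadHit]
    n_barcodes: int
    n_reads_total: int  # reads in the input metagenome
    # pre-filter statistics feeding the S' formula
    S: float = 0.0  # mean raw score over hits
    L: float = 0.0  # mean length of aligned reads
    N: int = 0  # number of aligned reads
    sprime: float | None = None
    a_specificity: float | None = None

    @property
    def n_aligned_reads(self) -> int:
        return len({h.read_id for h in self.hits})

    @property
    def n_matches(self) -> int:
        return len(self.hits)

    @classmethod
    def from_hits(
        cls, hits: list[ReadHit], n_barcodes: int, n_reads_total: int
    ) -> "AlignmentPool":
        pool = cls(hits=list(hits), n_barcodes=n_barcodes, n_reads_total=n_reads_total)
        if hits:
            pool.S = sum(h.raw_score for h in hits) / len(hits)
            lengths = {}
            for h in hits:
                lengths[h.read_id] = h.read_length
            pool.L = sum(lengths.values()) / len(lengths)
            pool.N = len(lengths)
        return pool


@dataclass
class ReadAssessment:
    read_id: str
    barcodes_hit: set[str]
    r_specificity: float = 0.0
    r_vicinity: float = 0.0


@dataclass
class BarcodeCall:
    barcode_id: str
    barcode_length: int
    n_reads: int
    score1: float
    score2: float
    present: bool = False


@dataclass
class BinningResult:
    calls: dict[str, BarcodeCall]
    cutoff1: float
    cutoff2: float
    pool: AlignmentPool
    assessments: dict[str, ReadAssessment] = field(default_factory=dict)

    def present_ids(self) -> list[str]:
        return sorted(b for b, c in self.calls.items() if c.present)


# ---------------------------------------------------------------------------
# read alignment
# ---------------------------------------------------------------------------

def _parse_reads(path: str | Path) -> Iterable[tuple[str, str]]:
    from Bio import SeqIO

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as handle:
        first = handle.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    with open(path) as handle:
        for record in SeqIO.parse(handle, fmt):
            yield record.id, str(record.seq).upper()


class BarcodeIndex:
    """Exact k-mer index over the barcode set for seed-and-extend alignment."""

    def __init__(self, barcodes: dict[str, str], k: int = DEFAULT_SEED_K):
        self.k = k
        self.barcodes = barcodes
        self.index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for barcode_id, seq in barcodes.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" not in kmer:
                    self.index[kmer].append((barcode_id, i))

    def seed_diagonals(self, read: str, stride: int = 1) -> dict[str, list[int]]:
        """Per barcode, the sorted seed diagonals (barcode pos - read pos)."""
        k = self.k
        get = self.index.get
        diagonals: dict[str, list[int]] = defaultdict(list)
        for i in range(0, len(read) - k + 1, stride):
            entries = get(read[i : i + k])
            if entries:
                for barcode_id, pos in entries:
                    diagonals[barcode_id].append(pos - i)
        for diags in diagonals.values():
            diags.sort()
        return diagonals


def _gapless_diagonal_score(read: str, barcode: str, diag: int) -> float:
    """Best local gapless segment score (+1/-2) along one alignment diagonal."""
    lo = max(0, diag)
    hi = min(len(barcode), diag + len(read))
    if hi <= lo:
        return 0.0
    b = np.frombuffer(barcode[lo:hi].encode(), dtype=np.uint8)
    r = np.frombuffer(read[lo - diag : hi - diag].encode(), dtype=np.uint8)
    vals = np.where(b == r, 1.0, -2.0)
    cum = np.concatenate(([0.0], np.cumsum(vals)))
    run_min = np.minimum.accumulate(cum)
    return float(np.max(cum[1:] - run_min[:-1]))


def _cluster_diagonals(diags: list[int], band: int) -> list[tuple[int, int, int]]:
    """Group sorted diagonals into (min, max, n_seeds) clusters within ``band``."""
    clusters = []
    start = prev = diags[0]
    count = 1
    for d in diags[1:]:
        if d - prev <= band:
            prev = d
            count += 1
        else:
            clusters.append((start, prev, count))
            start = prev = d
            count = 1
    clusters.append((start, prev, count))
    return clusters


def align_reads_to_barcodes(
    reads: str | Path | Iterable[tuple[str, str]],
    barcodes: BarcodeSet | dict[str, str],
    k: int = DEFAULT_SEED_K,
    min_score: float = DEFAULT_MIN_SCORE,
    band: int = 32,
    seed_stride: int = 2,
) -> tuple[list[ReadHit], int]:
    """Align reads against all barcodes; returns (hits, total reads seen).

    At most one hit (the best-scoring local alignment over both strands) is
    kept per (read, barcode) pair, and only when the raw score reaches
    ``min_score``.  Exact ``k``-mer seeds (sampled every ``seed_stride``
    read positions) are grouped into diagonal clusters; a cluster whose
    seeds agree on a single diagonal - the generic case for
    substitution-only divergence - is scored by a vectorized gapless
    Smith-Waterman along that diagonal, while disagreeing diagonals
    (indel signal) fall back to the full affine-gap dynamic programming
    over the implied barcode window padded by ``band``.
    """
    if isinstance(barcodes, BarcodeSet):
        barcode_seqs = barcodes.sequences()
    else:
        barcode_seqs = dict(barcodes)
    if not barcode_seqs:
        raise ValueError("empty barcode set")
    if isinstance(reads, (str, Path)):
        reads = _parse_reads(reads)
    index = BarcodeIndex(barcode_seqs, k=k)
    aligner = _align.nucleotide_aligner("local")
    hits: list[ReadHit] = []
    n_reads = 0
    for read_id, seq in reads:
        n_reads += 1
        best: dict[str, float] = {}
        for strand_seq in (seq, revcomp(seq)):
            for barcode_id, diags in index.seed_diagonals(strand_seq, seed_stride).items():
                barcode = barcode_seqs[barcode_id]
                score = 0.0
                for dmin, dmax, _count in _cluster_diagonals(diags, band):
                    if dmin == dmax:
                        s = _gapless_diagonal_score(strand_seq, barcode, dmin)
                    else:
                        lo = max(0, dmin - band)
                        hi = min(len(barcode), dmax + len(strand_seq) + band)
                        if hi - lo < index.k:
                            continue
                        s = aligner.score(barcode[lo:hi], strand_seq)
                    score = max(score, s)
                if score >= min_score and score > best.get(barcode_id, -1.0):
                    best[barcode_id] = score
        for barcode_id, score in best.items():
            hits.append(
                ReadHit(
                    read_id=read_id,
                    barcode_id=barcode_id,
                    raw_score=score,
                    read_length=len(seq),
                    e_value=_align.evalue(score, len(seq), len(barcode_seqs[barcode_id])),
                )
            )
    return hits, n_reads


# ---------------------------------------------------------------------------
# the score cascade
# ---------------------------------------------------------------------------

def compute_sprime(S: float, L: float, N: int) -> float:
    """The adaptive score cut-off S' from the pool statistics.

    ``lg`` is the base-10 logarithm.  Defined for N >= 2 (lg N > 0) and
    S > 0.
    """
    if S <= 0:
        raise ValueError("mean alignment score S must be positive")
    if N < 2:
        raise ValueError("S' needs at least two aligned reads (lg N > 0)")
    lg_n = math.log10(N)
    middle = (L - S) / (1.0 + math.exp(3.0 * (L - S) / (S * lg_n)))
    last = 10.0 * (math.log((2.0 * S + 100.0) / (L + 100.0)) - 1.0)
    return S + middle - last


def apply_sprime_filter(pool: AlignmentPool) -> AlignmentPool:
    """Drop hits scoring below S'; pool statistics stay the pre-filter ones.

    With fewer than two aligned reads the filter is skipped (the formula's
    ``lg N`` denominator vanishes) and a warning is emitted.
    """
    if pool.N < 2:
        log.warning("S' filter skipped: fewer than two aligned reads")
        return pool
    sprime = compute_sprime(pool.S, pool.L, pool.N)
    kept = [h for h in pool.hits if h.raw_score >= sprime]
    if pool.hits and not kept:
        # degenerate regime: when S approaches L (near-perfect alignments)
        # the formula rises above every hit score and would empty the pool;
        # filtering nothing is the only sensible behaviour there
        log.warning(
            "S'=%.2f exceeds every hit score (S=%.2f ~ L=%.2f); filter skipped",
            sprime,
            pool.S,
            pool.L,
        )
        kept = list(pool.hits)
    filtered = AlignmentPool(
        hits=kept,
        n_barcodes=pool.n_barcodes,
        n_reads_total=pool.n_reads_total,
        S=pool.S,
        L=pool.L,
        N=pool.N,
        sprime=sprime,
    )
    log.info(
        "S' filter: S=%.2f L=%.2f N=%d -> S'=%.3f, %d/%d hits kept",
        pool.S,
        pool.L,
        pool.N,
        sprime,
        len(kept),
        len(pool.hits),
    )
    return filtered


def compute_alignment_specificity(
    n_aligned_reads: int, n_matches: int, n_barcodes: int
) -> float:
    """Pool-level alignment specificity on [0, 1]."""
    if n_aligned_reads < 1:
        raise ValueError("alignment specificity needs at least one aligned read")
    if n_barcodes < 2:
        log.warning("alignment specificity degenerate with a single barcode; defined as 1")
        return 1.0
    a = 1.0 - (n_matches - n_aligned_reads) / (n_aligned_reads * (n_barcodes - 1))
    return min(1.0, max(0.0, a))


def compute_read_specificity(n_barcodes_hit: int, n_barcodes: int) -> float:
    """Per-read specificity: 1 for one barcode, 0 for all of them."""
    if not 1 <= n_barcodes_hit <= n_barcodes:
        raise ValueError("barcodes_hit outside [1, n_barcodes]")
    if n_barcodes < 2:
        log.warning("read specificity degenerate with a single barcode; defined as 1")
        return 1.0
    return (n_barcodes - n_barcodes_hit) / (n_barcodes - 1)


def jaccard_distance_matrix(
    reads_by_barcode: dict[str, set[str]]
) -> dict[tuple[str, str], float]:
    """Pairwise ``1 - |A & B| / |A | B|`` over the barcodes' read sets.

    Pairs whose union is empty get distance 0 (both barcodes unhit).
    """
    ids = sorted(reads_by_barcode)
    matrix: dict[tuple[str, str], float] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            union = reads_by_barcode[a] | reads_by_barcode[b]
            if not union:
                d = 0.0
            else:
                d = 1.0 - len(reads_by_barcode[a] & reads_by_barcode[b]) / len(union)
            matrix[(a, b)] = matrix[(b, a)] = d
    return matrix


def compute_vicinity(
    reads_by_barcode: dict[str, set[str]]
) -> dict[str, float]:
    """Per-read vicinity coefficients on [0, 10].

    A read aligned to a single barcode gets 0.  Otherwise the maximum
    Jaccard distance among the read's barcodes is scaled by 10 over the
    maximum distance in the whole matrix; a degenerate all-zero matrix
    gives every read 0.
    """
    matrix = jaccard_distance_matrix(reads_by_barcode)
    max_matrix = max(matrix.values(), default=0.0)
    barcodes_by_read: dict[str, list[str]] = defaultdict(list)
    for barcode_id, read_ids in reads_by_barcode.items():
        for read_id in read_ids:
            barcodes_by_read[read_id].append(barcode_id)
    vicinity: dict[str, float] = {}
    for read_id, barcode_ids in barcodes_by_read.items():
        if len(barcode_ids) < 2 or max_matrix == 0.0:
            vicinity[read_id] = 0.0
            continue
        subset_max = max(
            matrix[(a, b)]
            for i, a in enumerate(barcode_ids)
            for b in barcode_ids[i + 1 :]
        )
        # divide first: subset_max <= max_matrix so the ratio is <= 1.0 in
        # floating point and the bound r_vicinity <= 10 holds exactly
        vicinity[read_id] = 10.0 * (subset_max / max_matrix)
    return vicinity


def read_score1(norm_score: float, r_spec: float, r_vic: float) -> float:
    factor = (r_spec + math.exp(r_spec * r_vic) + 1.0) / (
        r_spec + math.exp(r_vic) + 1.0
    )
    return norm_score * factor


def read_score2(
    norm_score: float,
    r_spec: float,
    r_vic: float,
    a_specificity: float,
    n_reads_barcode: int,
    n_reads: int,
) -> float:
    factor = (r_spec + 1.5 ** (r_spec * r_vic) + 1.0) / (
        r_spec + 1.5 ** r_vic + 1.0
    )
    return a_specificity * (n_reads_barcode / n_reads) * norm_score * factor


def barcode_score(
    sum_read_scores: float,
    barcode_length: int,
    sum_norm_scores: float,
    total_barcode_length: int,
) -> float:
    """One barcode score from its read-score sum and the normalization term."""
    denom = 1.0 + (3.0 * barcode_length * sum_norm_scores) / (
        4.0 * total_barcode_length
    )
    return (1.0 + sum_read_scores) / denom - 1.0


def compute_barcode_scores(
    pool: AlignmentPool,
    barcode_lengths: dict[str, int],
    cutoff1: float = DEFAULT_CUTOFF1,
    cutoff2: float = DEFAULT_CUTOFF2,
    nreads_mode: str = "aligned",
    score_sum_mode: str = "per_barcode",
) -> BinningResult:
    """Run the full score cascade on a (post-filter) alignment pool.

    ``nreads_mode`` chooses the denominator of ReadScore2's abundance
    factor: the number of aligned reads (``"aligned"``, default) or all
    reads in the metagenome (``"total"``).  ``score_sum_mode`` chooses the
    normalized-score sum in the barcode-score denominator: over the reads
    aligned to that barcode (``"per_barcode"``, default) or over the whole
    pool (``"global"``).
    """
    if not barcode_lengths:
        raise ValueError("no barcodes configured")
    if nreads_mode not in ("aligned", "total"):
        raise ValueError(f"unknown nreads_mode {nreads_mode!r}")
    if score_sum_mode not in ("per_barcode", "global"):
        raise ValueError(f"unknown score_sum_mode {score_sum_mode!r}")

    hits_by_barcode: dict[str, list[ReadHit]] = defaultdict(list)
    reads_by_barcode: dict[str, set[str]] = {b: set() for b in barcode_lengths}
    for hit in pool.hits:
        hits_by_barcode[hit.barcode_id].append(hit)
        reads_by_barcode[hit.barcode_id].add(hit.read_id)

    n_aligned = pool.n_aligned_reads
    if n_aligned:
        a_spec = compute_alignment_specificity(
            n_aligned, pool.n_matches, pool.n_barcodes
        )
    else:
        a_spec = 1.0
    pool.a_specificity = a_spec

    barcodes_by_read: dict[str, set[str]] = defaultdict(set)
    for hit in pool.hits:
        barcodes_by_read[hit.read_id].add(hit.barcode_id)
    vicinity = compute_vicinity(reads_by_barcode)
    assessments = {
        read_id: ReadAssessment(
            read_id=read_id,
            barcodes_hit=barcodes,
            r_specificity=compute_read_specificity(len(barcodes), pool.n_barcodes),
            r_vicinity=vicinity.get(read_id, 0.0),
        )
        for read_id, barcodes in barcodes_by_read.items()
    }

    if nreads_mode == "aligned":
        n_reads_denom = max(n_aligned, 1)
    else:
        n_reads_denom = max(pool.n_reads_total, 1)

    total_length = sum(barcode_lengths.values())
    global_norm_sum = sum(
        max(h.normalized_score for h in hits)
        for hits in _hits_by_read(pool.hits).values()
    )

    calls: dict[str, BarcodeCall] = {}
    for barcode_id in sorted(barcode_lengths):
        hits = hits_by_barcode.get(barcode_id, [])
        sum1 = 0.0
        sum2 = 0.0
        norm_sum = 0.0
        for hit in hits:
            assessment = assessments[hit.read_id]
            norm = hit.normalized_score
            norm_sum += norm
            sum1 += read_score1(norm, assessment.r_specificity, assessment.r_vicinity)
            sum2 += read_score2(
                norm,
                assessment.r_specificity,
                assessment.r_vicinity,
                a_spec,
                len(reads_by_barcode[barcode_id]),
                n_reads_denom,
            )
        t_i = norm_sum if score_sum_mode == "per_barcode" else global_norm_sum
        score1 = barcode_score(sum1, barcode_lengths[barcode_id], t_i, total_length)
        score2 = barcode_score(sum2, barcode_lengths[barcode_id], t_i, total_length)
        calls[barcode_id] = BarcodeCall(
            barcode_id=barcode_id,
            barcode_length=barcode_lengths[barcode_id],
            n_reads=len(reads_by_barcode[barcode_id]),
            score1=score1,
            score2=score2,
        )
    result = BinningResult(
        calls=calls,
        cutoff1=cutoff1,
        cutoff2=cutoff2,
        pool=pool,
        assessments=assessments,
    )
    classify(result, cutoff1, cutoff2)
    return result


def _hits_by_read(hits: Sequence[ReadHit]) -> dict[str, list[ReadHit]]:
    by_read: dict[str, list[ReadHit]] = defaultdict(list)
    for hit in hits:
        by_read[hit.read_id].append(hit)
    return by_read


def classify(
    result: BinningResult,
    cutoff1: float = DEFAULT_CUTOFF1,
    cutoff2: float = DEFAULT_CUTOFF2,
) -> BinningResult:
    """Present iff BarcodeScore1 >= cutoff1 and BarcodeScore2 >= cutoff2."""
    result.cutoff1 = cutoff1
    result.cutoff2 = cutoff2
    for call in result.calls.values():
        call.present = call.score1 >= cutoff1 and call.score2 >= cutoff2
    return result


def bin_reads(
    reads: str | Path | Iterable[tuple[str, str]],
    barcodes: BarcodeSet | dict[str, str],
    cutoff1: float = DEFAULT_CUTOFF1,
    cutoff2: float = DEFAULT_CUTOFF2,
    min_score: float = DEFAULT_MIN_SCORE,
    k: int = DEFAULT_SEED_K,
    nreads_mode: str = "aligned",
    score_sum_mode: str = "per_barcode",
) -> BinningResult:
    """End-to-end binning: align, S'-filter, score, classify."""
    if isinstance(barcodes, BarcodeSet):
        barcode_seqs = barcodes.sequences()
    else:
        barcode_seqs = dict(barcodes)
    hits, n_reads = align_reads_to_barcodes(reads, barcode_seqs, k=k, min_score=min_score)
    pool = AlignmentPool.from_hits(hits, n_barcodes=len(barcode_seqs), n_reads_total=n_reads)
    pool = apply_sprime_filter(pool)
    lengths = {b: len(s) for b, s in barcode_seqs.items()}
    return compute_barcode_scores(
        pool,
        lengths,
        cutoff1=cutoff1,
        cutoff2=cutoff2,
        nreads_mode=nreads_mode,
        score_sum_mode=score_sum_mode,
    )
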