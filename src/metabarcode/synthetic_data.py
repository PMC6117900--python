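"""Synthetic genome families and artificial metagenomes with known truth.

The generator replaces real genome panels and an external read simulator
for testing and validation.  A *family* is a set of bacterial-like genomes
sharing single-copy core gene families at a controlled divergence, plus
genome-specific accessory families:

* an ancestral gene is drawn per family with uniform codon usage over the
  61 sense codons, an ATG start and a single terminal stop;
* each genome receives a copy mutated to the family's divergence target by
  placing single-nucleotide substitutions that are either amino-acid
  changing or synonymous, at the requested sense/silent ratio; with
  target pairwise protein identity ``p`` each copy diverges from the
  ancestor at roughly ``(1 - p)/2`` of its codons, so two copies meet the
  target in expectation;
* accessory families are assigned to genome subsets by a presence
  probability; genes are embedded in random intergenic background on
  random strands, in a per-genome random order.

Metagenomes are shotgun read sets: each read picks a genome by abundance,
a uniform start, a strand at random and a length from a normal
distribution truncated to [200, 350] bp (mean 275, sd 25 by default); an
optional uniform substitution error rate can be applied.  Reads left over
after the requested abundances (which may sum to < 1) come from a
*background* genome generated as an extra family member that never
receives a barcode, so false-positive behaviour is exercised.  All
randomness is driven by a single seed; reruns are byte-identical.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import truncnorm

from .cog_metrics import translate_codon
from .genome_io import GeneRecord, Genome, translate_cds, write_genbank

log = logging.getLogger(__name__)

_SENSE_CODONS = sorted(
    "".join(t)
    for t in itertools.product("ACGT", repeat=3)
    if translate_codon("".join(t)) != "*"
)
_STOP = "TAA"
_NT = "ACGT"


@dataclass
class FamilySpec:
    """Parameters of one synthetic genome family."""

    n_genomes: int = 8
    n_core_families: int = 50
    n_accessory_families: int = 20
    gene_length_mean: int = 900  # bp, forced to a multiple of 3
    gene_length_sd: int = 150
    protein_identity: float = 0.8  # target mean pairwise identity
    nonsyn_fraction: float = 0.5  # sense substitutions / all substitutions
    accessory_presence: float = 0.5
    spacer_length: int = 100  # mean intergenic spacer, bp
    n_background_genomes: int = 0  # extra family members for off-target reads
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.protein_identity <= 1.0:
            raise ValueError("protein_identity must be in (0, 1]")
        if not 0.0 < self.nonsyn_fraction <= 1.0:
            raise ValueError("nonsyn_fraction must be in (0, 1]")
        # each copy diverges (1-p)/2 from the ancestor; more than ~60% of
        # codons mutated per copy cannot be placed at distinct positions
        if (1.0 - self.protein_identity) / 2.0 > 0.6:
            raise ValueError("protein_identity target below the achievable floor")


@dataclass
class FamilyTruth:
    """Which gene of which genome belongs to which family."""

    core_families: dict[str, dict[str, str]]  # family_id -> genome_id -> gene_id
    accessory_families: dict[str, dict[str, str]]

    def n_core(self) -> int:
        return len(self.core_families)


@dataclass
class SampleTruth:
    """Composition of one artificial metagenome."""

    abundances: dict[str, float]
    n_reads: int
    read_length_mean: float = 275.0
    read_length_sd: float = 25.0
    read_length_min: int = 200
    read_length_max: int = 350
    error_rate: float = 0.0
    seed: int = 0
    realized_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        total = sum(self.abundances.values())
        if total > 1.0 + 1e-9:
            raise ValueError("abundances sum to more than 1")
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")


# ---------------------------------------------------------------------------
# gene-level mutation machinery
# ---------------------------------------------------------------------------

def _random_gene(rng: np.random.Generator, n_codons: int) -> str:
    codons = rng.choice(_SENSE_CODONS, size=n_codons - 2)
    return "ATG" + "".join(codons) + _STOP


def _nonsyn_change(rng: np.random.Generator, codon: str) -> str | None:
    """A single-nt change of ``codon`` altering the amino acid, avoiding stops."""
    aa = translate_codon(codon)
    options = []
    for pos in range(3):
        for nt in _NT:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            maa = translate_codon(mutant)
            if maa != aa and maa != "*":
                options.append(mutant)
    if not options:
        return None
    return options[rng.integers(len(options))]


def _syn_change(rng: np.random.Generator, codon: str) -> str | None:
    """A single-nt synonymous change of ``codon``, if one exists."""
    aa = translate_codon(codon)
    options = []
    for pos in range(3):
        for nt in _NT:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            if translate_codon(mutant) == aa:
                options.append(mutant)
    if not options:
        return None
    return options[rng.integers(len(options))]


def mutate_copy(
    rng: np.random.Generator,
    ancestral: str,
    aa_divergence: float,
    nonsyn_fraction: float,
) -> str:
    """Mutate one genome's copy of an ancestral gene.

    ``aa_divergence`` is the fraction of codons receiving an amino-acid
    changing substitution; synonymous substitutions are added at other
    codons to realize the requested sense/silent ratio.  Start and stop
    codons are left untouched.
    """
    codons = [ancestral[i : i + 3] for i in range(0, len(ancestral), 3)]
    mutable = list(range(1, len(codons) - 1))  # keep ATG and stop fixed
    n_nonsyn = int(round(aa_divergence * len(mutable)))
    n_syn = int(round(n_nonsyn * (1.0 - nonsyn_fraction) / nonsyn_fraction))
    order = rng.permutation(len(mutable))
    targets = [mutable[i] for i in order]
    placed_nonsyn = placed_syn = 0
    for idx in targets:
        if placed_nonsyn < n_nonsyn:
            mutant = _nonsyn_change(rng, codons[idx])
            if mutant is not None:
                codons[idx] = mutant
                placed_nonsyn += 1
                continue
        if placed_syn < n_syn:
            mutant = _syn_change(rng, codons[idx])
            if mutant is not None:
                codons[idx] = mutant
                placed_syn += 1
        if placed_nonsyn >= n_nonsyn and placed_syn >= n_syn:
            break
    return "".join(codons)


def _random_spacer(rng: np.random.Generator, mean: int) -> str:
    length = int(rng.integers(mean // 2, mean * 3 // 2 + 1)) if mean > 0 else 0
    return "".join(rng.choice(list(_NT), size=length)) if length else ""


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


# ---------------------------------------------------------------------------
# family simulation
# ---------------------------------------------------------------------------

def simulate_genome_family(spec: FamilySpec) -> tuple[list[Genome], FamilyTruth]:
    """Generate a family of related genomes plus its orthology truth table.

    The returned list includes ``spec.n_background_genomes`` extra members
    (ids suffixed ``BG``) meant to donate off-target reads; they carry the
    same core families and are otherwise ordinary genomes.
    """
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_genomes + spec.n_background_genomes
    genome_ids = [f"GEN{i + 1:02d}" for i in range(spec.n_genomes)] + [
        f"GEN{spec.n_genomes + i + 1:02d}BG" for i in range(spec.n_background_genomes)
    ]
    aa_div = (1.0 - spec.protein_identity) / 2.0

    def gene_length() -> int:
        n_codons = max(60, int(round(rng.normal(spec.gene_length_mean, spec.gene_length_sd) / 3)))
        return n_codons

    core_truth: dict[str, dict[str, str]] = {}
    accessory_truth: dict[str, dict[str, str]] = {}
    genes_per_genome: dict[str, list[tuple[str, str, str]]] = {g: [] for g in genome_ids}
    # (family_id, locus_tag, sequence)

    for fam_idx in range(spec.n_core_families):
        family_id = f"fam_core{fam_idx + 1:04d}"
        ancestral = _random_gene(rng, gene_length())
        core_truth[family_id] = {}
        for genome_id in genome_ids:
            copy = mutate_copy(rng, ancestral, aa_div, spec.nonsyn_fraction)
            genes_per_genome[genome_id].append((family_id, "", copy))

    for fam_idx in range(spec.n_accessory_families):
        family_id = f"fam_acc{fam_idx + 1:04d}"
        ancestral = _random_gene(rng, gene_length())
        carriers = [g for g in genome_ids if rng.random() < spec.accessory_presence]
        if not carriers:
            carriers = [genome_ids[int(rng.integers(n_total))]]
        accessory_truth[family_id] = {}
        for genome_id in genome_ids:
            if genome_id in carriers:
                copy = mutate_copy(rng, ancestral, aa_div, spec.nonsyn_fraction)
                genes_per_genome[genome_id].append((family_id, "", copy))

    genomes: list[Genome] = []
    for genome_id in genome_ids:
        entries = genes_per_genome[genome_id]
        order = rng.permutation(len(entries))
        sequence_parts: list[str] = []
        genes: list[GeneRecord] = []
        position = 0
        replicon_id = f"{genome_id}_chr"
        for rank, entry_idx in enumerate(order, 1):
            family_id, _tag, gene_seq = entries[entry_idx]
            spacer = _random_spacer(rng, spec.spacer_length)
            sequence_parts.append(spacer)
            position += len(spacer)
            strand = "+" if rng.random() < 0.5 else "-"
            genomic = gene_seq if strand == "+" else _revcomp(gene_seq)
            sequence_parts.append(genomic)
            locus_tag = f"g{rank:04d}"
            gene = GeneRecord(
                gene_id=f"{genome_id}|{locus_tag}",
                replicon_id=replicon_id,
                start=position,
                end=position + len(gene_seq),
                strand=strand,
                nt_seq=gene_seq,
                aa_seq=translate_cds(gene_seq),
                product=family_id,
            )
            genes.append(gene)
            position += len(gene_seq)
            truth = core_truth if family_id.startswith("fam_core") else accessory_truth
            truth[family_id][genome_id] = gene.gene_id
        sequence_parts.append(_random_spacer(rng, spec.spacer_length))
        genome = Genome(
            genome_id=genome_id,
            replicons=[(replicon_id, "".join(sequence_parts))],
            genes=genes,
        )
        genomes.append(genome)
    return genomes, FamilyTruth(core_families=core_truth, accessory_families=accessory_truth)


def write_family(genomes: list[Genome], truth: FamilyTruth, out_dir: str | Path) -> Path:
    """Write each genome as GenBank plus the truth table as JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for genome in genomes:
        write_genbank(genome, out_dir / f"{genome.genome_id}.gbk")
    truth_path = out_dir / "family_truth.json"
    with open(truth_path, "w") as handle:
        json.dump(
            {
                "core_families": truth.core_families,
                "accessory_families": truth.accessory_families,
            },
            handle,
            indent=1,
            sort_keys=True,
        )
    return truth_path


# ---------------------------------------------------------------------------
# metagenome simulation
# ---------------------------------------------------------------------------

def simulate_metagenome(
    genomes: list[Genome],
    truth: SampleTruth,
    background_id: str | None = None,
    out_fasta: str | Path | None = None,
) -> tuple[list[tuple[str, str]], SampleTruth]:
    """Draw shotgun reads from the genomes according to the sample truth.

    Reads left over after the requested abundances are drawn from
    ``background_id`` (required when the abundances sum below 1).  Read
    headers carry the provenance ``read<i>|<genome>|<replicon>|<start>|<strand>``.
    Returns the reads and the truth updated with realized per-genome counts.
    """
    rng = np.random.default_rng(truth.seed)
    by_id = {g.genome_id: g for g in genomes}
    ids = sorted(truth.abundances)
    probs = [truth.abundances[g] for g in ids]
    leftover = 1.0 - sum(probs)
    if leftover > 1e-9:
        if background_id is None:
            raise ValueError("abundances sum below 1 but no background genome given")
        ids.append(background_id)
        probs.append(leftover)
    for genome_id in ids:
        if genome_id not in by_id:
            raise KeyError(f"unknown genome {genome_id!r}")

    a = (truth.read_length_min - truth.read_length_mean) / truth.read_length_sd
    b = (truth.read_length_max - truth.read_length_mean) / truth.read_length_sd
    lengths = truncnorm.rvs(
        a,
        b,
        loc=truth.read_length_mean,
        scale=truth.read_length_sd,
        size=truth.n_reads,
        random_state=rng,
    )
    lengths = np.rint(lengths).astype(int)
    np.clip(lengths, truth.read_length_min, truth.read_length_max, out=lengths)
    choices = rng.choice(len(ids), size=truth.n_reads, p=np.array(probs) / sum(probs))

    reads: list[tuple[str, str]] = []
    counts = {g: 0 for g in ids}
    for i in range(truth.n_reads):
        genome = by_id[ids[choices[i]]]
        length = int(lengths[i])
        replicon_id, seq = genome.replicons[
            int(rng.integers(len(genome.replicons)))
        ]
        if length > len(seq):  # read longer than the replicon: clamp
            length = len(seq)
        start = int(rng.integers(0, len(seq) - length + 1))
        fragment = seq[start : start + length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            fragment = _revcomp(fragment)
        if truth.error_rate > 0.0:
            fragment = _apply_errors(rng, fragment, truth.error_rate)
        read_id = f"read{i + 1}|{genome.genome_id}|{replicon_id}|{start + 1}|{strand}"
        reads.append((read_id, fragment))
        counts[genome.genome_id] += 1
    truth.realized_counts = counts
    if out_fasta is not None:
        out_fasta = Path(out_fasta)
        out_fasta.parent.mkdir(parents=True, exist_ok=True)
        with open(out_fasta, "w") as handle:
            for read_id, seq in reads:
                handle.write(f">{read_id}\n{seq}\n")
    return reads, truth


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    chars = list(seq)
    n_err = rng.binomial(len(chars), rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(chars), size=n_err, replace=False)
    for pos in positions:
        current = chars[pos]
        alternatives = [c for c in _NT if c != current]
        chars[pos] = alternatives[int(rng.integers(3))]
    return "".join(chars)


def write_truth(truth: SampleTruth, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as handle:
        json.dump(
            {
                "abundances": truth.abundances,
                "n_reads": truth.n_reads,
                "realized_counts": truth.realized_counts,
                "error_rate": truth.error_rate,
                "seed": truth.seed,
            },
            handle,
            indent=1,
            sort_keys=True,
        )
    return path


def read_truth(path: str | Path) -> SampleTruth:
    with open(path) as handle:
        data = json.load(handle)
    truth = SampleTruth(
        abundances=data["abundances"],
        n_reads=data["n_reads"],
        error_rate=data.get("error_rate", 0.0),
        seed=data.get("seed", 0),
    )
    truth.realized_counts = data.get("realized_counts", {})
    return truth
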