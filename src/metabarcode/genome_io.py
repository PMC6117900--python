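"""Genome input: parse annotated genomes, extract and translate coding sequences.

The pipeline consumes complete, annotated bacterial genomes.  Two input
flavours are supported:

* GenBank flat files (possibly multi-record and/or gzip-compressed), the
  format users of the barcode generator are expected to upload;
* a plain FASTA file accompanied by a tab-separated CDS coordinate table
  (columns: ``replicon_id  start  end  strand  locus_tag  [product]``,
  coordinates 1-based inclusive as in GenBank feature locations).

Internally all coordinates are 0-based half-open; only *reported* locations
(info files) use the 1-based inclusive convention.  Gene identifiers are
``<genome_id>|<locus_tag>``, falling back to ``<genome_id>|cds<ordinal>``
when a locus tag is absent, which keeps them collision-free and stable
across reruns.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

log = logging.getLogger(__name__)

_VALID_NT = set("ACGT")


class GenomeFormatError(ValueError):
    """The input file could not be parsed in the requested format."""


class EmptyAnnotationError(ValueError):
    """The input parsed but contained no CDS features."""


class FrameError(ValueError):
    """A coding sequence whose length is not a multiple of three."""


def normalize_nt(seq: str) -> str:
    """Uppercase and restrict the alphabet to A, C, G, T, N.

    Any IUPAC ambiguity code other than N is itself normalized to N; the
    divergence statistics downstream treat N-containing codons as
    uninformative.
    """
    s = seq.upper()
    if set(s) <= _VALID_NT:
        return s
    return "".join(c if c in _VALID_NT else "N" for c in s)


@dataclass(frozen=True)
class GeneRecord:
    """One annotated CDS: coding-strand nucleotides plus its translation."""

    gene_id: str
    replicon_id: str
    start: int  # 0-based
    end: int  # half-open
    strand: str  # '+' or '-'
    nt_seq: str
    aa_seq: str
    product: str = ""

    @property
    def genome_id(self) -> str:
        return self.gene_id.split("|", 1)[0]

    def __len__(self) -> int:
        return len(self.nt_seq)


@dataclass
class Genome:
    """A parsed genome: replicon sequences plus the CDS records found on them."""

    genome_id: str
    replicons: list[tuple[str, str]] = field(default_factory=list)
    genes: list[GeneRecord] = field(default_factory=list)

    @property
    def length(self) -> int:
        return sum(len(s) for _, s in self.replicons)

    def replicon_seq(self, replicon_id: str) -> str:
        for rid, seq in self.replicons:
            if rid == replicon_id:
                return seq
        raise KeyError(replicon_id)


def translate_cds(nt_seq: str, table: int = 11) -> str:
    """Translate a coding sequence with the bacterial code by default.

    The terminal stop (if present) is stripped; codons containing N
    translate to X.  Raises :class:`FrameError` if the length is not a
    multiple of three.
    """
    if len(nt_seq) % 3 != 0:
        raise FrameError(f"CDS length {len(nt_seq)} is not a multiple of 3")
    aa = str(Seq(nt_seq).translate(table=table))
    if aa.endswith("*"):
        aa = aa[:-1]
    return aa


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _gene_from_location(
    genome_id: str,
    replicon_id: str,
    replicon_seq: str,
    start: int,
    end: int,
    strand: str,
    locus_tag: str,
    product: str,
    table: int,
) -> GeneRecord:
    if not (0 <= start < end <= len(replicon_seq)):
        raise GenomeFormatError(
            f"CDS {locus_tag!r} interval [{start}, {end}) outside replicon "
            f"{replicon_id!r} of length {len(replicon_seq)}"
        )
    nt = replicon_seq[start:end]
    if strand == "-":
        nt = _revcomp(nt)
    aa = ""
    if len(nt) % 3 == 0:
        aa = translate_cds(nt, table=table)
    return GeneRecord(
        gene_id=f"{genome_id}|{locus_tag}",
        replicon_id=replicon_id,
        start=start,
        end=end,
        strand=strand,
        nt_seq=nt,
        aa_seq=aa,
        product=product,
    )


def _read_genbank(path: Path, genome_id: str, table: int) -> Genome:
    genome = Genome(genome_id=genome_id)
    ordinal = 0
    with _open_maybe_gzip(path) as handle:
        try:
            records = list(SeqIO.parse(handle, "genbank"))
        except Exception as exc:  # malformed flat file
            raise GenomeFormatError(f"{path}: not parseable as GenBank ({exc})") from exc
    if not records:
        raise GenomeFormatError(f"{path}: no GenBank records found")
    for record in records:
        replicon_seq = normalize_nt(str(record.seq))
        genome.replicons.append((record.id, replicon_seq))
        for feature in record.features:
            if feature.type != "CDS":
                continue
            ordinal += 1
            quals = feature.qualifiers
            locus_tag = quals.get("locus_tag", [f"cds{ordinal}"])[0]
            product = quals.get("product", [""])[0]
            strand = "-" if feature.location.strand == -1 else "+"
            try:
                gene = _gene_from_location(
                    genome_id,
                    record.id,
                    replicon_seq,
                    int(feature.location.start),
                    int(feature.location.end),
                    strand,
                    locus_tag,
                    product,
                    table,
                )
            except GenomeFormatError as exc:
                raise GenomeFormatError(f"{path}: {exc}") from exc
            genome.genes.append(gene)
    return genome


def _read_fasta_with_table(
    path: Path, table_path: Path, genome_id: str, table: int
) -> Genome:
    genome = Genome(genome_id=genome_id)
    with _open_maybe_gzip(path) as handle:
        records = list(SeqIO.parse(handle, "fasta"))
    if not records:
        raise GenomeFormatError(f"{path}: no FASTA records found")
    seqs = {r.id: normalize_nt(str(r.seq)) for r in records}
    genome.replicons = [(r.id, seqs[r.id]) for r in records]
    with open(table_path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise GenomeFormatError(
                    f"{table_path}:{lineno}: expected >=5 tab-separated columns"
                )
            replicon_id, start1, end1, strand, locus_tag = parts[:5]
            product = parts[5] if len(parts) > 5 else ""
            if replicon_id not in seqs:
                raise GenomeFormatError(
                    f"{table_path}:{lineno}: unknown replicon {replicon_id!r}"
                )
            gene = _gene_from_location(
                genome_id,
                replicon_id,
                seqs[replicon_id],
                int(start1) - 1,
                int(end1),
                strand,
                locus_tag,
                product,
                table,
            )
            genome.genes.append(gene)
    return genome


def read_genome_file(
    path: str | Path,
    format: str = "genbank",
    genome_id: str | None = None,
    cds_table: str | Path | None = None,
    table: int = 11,
) -> Genome:
    """Parse one genome file into a :class:`Genome`.

    Parameters
    ----------
    path:
        GenBank flat file (``format="genbank"``, gzip accepted) or FASTA
        file (``format="fasta+table"``).
    genome_id:
        Label used as the prefix of every gene identifier.  Defaults to the
        file stem (without ``.gz``/extension).
    cds_table:
        Required for ``fasta+table``: tab-separated CDS coordinates.
    table:
        NCBI genetic code id used for translation (11 = bacterial).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if genome_id is None:
        stem = path.name
        for suffix in (".gz", ".gb", ".gbk", ".gbff", ".fasta", ".fa", ".fna"):
            if stem.endswith(suffix):
                stem = stem[: -len(suffix)]
        genome_id = stem
    if format == "genbank":
        genome = _read_genbank(path, genome_id, table)
    elif format == "fasta+table":
        if cds_table is None:
            raise ValueError("format 'fasta+table' requires cds_table=")
        genome = _read_fasta_with_table(path, Path(cds_table), genome_id, table)
    else:
        raise ValueError(f"unknown genome format {format!r}")
    if not genome.genes:
        raise EmptyAnnotationError(f"{path}: no CDS features found")
    log.info("%s: parsed %d replicons, %d CDS", genome_id, len(genome.replicons), len(genome.genes))
    return genome


def start_codons(table: int = 11) -> frozenset[str]:
    return frozenset(CodonTable.unambiguous_dna_by_id[table].start_codons)


def extract_cds(
    genome: Genome,
    drop_pseudo: bool = True,  # kept for interface symmetry; pseudo CDS carry no translation
    keep_partial: bool = False,
    table: int = 11,
) -> list[GeneRecord]:
    """Return the CDS records passing the completeness filter.

    A complete CDS has a length that is a multiple of three, no internal
    stop codon and (unless ``keep_partial``) begins with a start codon of
    the genetic code in use.  Excluded records are logged with the reason.
    """
    starts = start_codons(table)
    kept: list[GeneRecord] = []
    for gene in genome.genes:
        reason = _exclusion_reason(gene, starts, keep_partial, table)
        if reason is None:
            kept.append(gene)
        else:
            log.info("excluded %s: %s", gene.gene_id, reason)
    return kept


def _exclusion_reason(
    gene: GeneRecord, starts: frozenset[str], keep_partial: bool, table: int
) -> str | None:
    if len(gene.nt_seq) % 3 != 0:
        return "length not multiple of 3"
    aa_full = str(Seq(gene.nt_seq).translate(table=table))
    body = aa_full[:-1] if aa_full.endswith("*") else aa_full
    if "*" in body:
        return "internal stop"
    if not keep_partial and gene.nt_seq[:3] not in starts:
        return "no start codon"
    return None


def write_genbank(genome: Genome, path: str | Path) -> Path:
    """Write a :class:`Genome` back out as a GenBank flat file.

    Used by the simulator so that generated families can be consumed by
    :func:`read_genome_file` exactly like user-supplied genomes.
    """
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    path = Path(path)
    records = []
    for replicon_id, seq in genome.replicons:
        record = SeqRecord(
            Seq(seq),
            id=replicon_id,
            name=replicon_id[:16],
            description=f"{genome.genome_id} synthetic replicon",
            annotations={"molecule_type": "DNA", "topology": "linear"},
        )
        for gene in genome.genes:
            if gene.replicon_id != replicon_id:
                continue
            locus_tag = gene.gene_id.split("|", 1)[1]
            feature = SeqFeature(
                FeatureLocation(gene.start, gene.end, strand=1 if gene.strand == "+" else -1),
                type="CDS",
                qualifiers={
                    "locus_tag": [locus_tag],
                    "product": [gene.product or "hypothetical protein"],
                    "transl_table": ["11"],
                },
            )
            record.features.append(feature)
        records.append(record)
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "genbank")
    return path


def read_genome_dir(
    directory: str | Path, table: int = 11
) -> list[Genome]:
    """Read every GenBank file (``*.gb``, ``*.gbk``, ``*.gbff``, gzipped too) in a directory."""
    directory = Path(directory)
    suffixes = (".gb", ".gbk", ".gbff", ".gb.gz", ".gbk.gz", ".gbff.gz")
    paths = sorted(p for p in directory.iterdir() if p.name.endswith(suffixes))
    if not paths:
        raise FileNotFoundError(f"no GenBank files in {directory}")
    return [read_genome_file(p, table=table) for p in paths]
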