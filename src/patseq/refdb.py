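"""Extended 3'-UTR mapping database and genome coordinate mapping.

PAT-seq tags query the mRNA-poly(A) junction, which for most transcripts lies
inside or a short distance downstream of the annotated 3'-UTR (downstream
sites arise from inefficient transcription termination).  The mapping
reference is therefore not the whole genome but the set of 3'-UTRs, each
extended at its 3' end by a fixed number of nucleotides (default 500) and
stored as the *reverse complement* of the genomic-sense extended UTR, so that
tag reads align to it in their sequenced orientation.

Database coordinates run 3'->5' with respect to the transcript: position 0 of
a record is the 3'-most base of the extended span and the last position is the
5' end of the annotated UTR.  Every record carries an exact, bijective affine
map between database positions and genomic positions; :meth:`ExtendedUtrRecord.
db_to_genome` and :meth:`ExtendedUtrRecord.genome_to_db` are inverses.

All internal coordinates are 0-based half-open.  GFF3 I/O converts to 1-based
closed intervals at the boundary; BED I/O is passed through unchanged.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigurationError, InputError

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """A gene's annotated 3'-UTR interval and its mapping extension.

    ``utr_start``/``utr_end`` are genomic, 0-based half-open.  ``extension``
    is the requested downstream extension in nt; the realized extension may be
    shorter near a chromosome end.
    """

    gene_id: str
    chromosome: str
    strand: str
    utr_start: int
    utr_end: int
    extension: int = 500

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ConfigurationError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.utr_start < self.utr_end:
            raise ConfigurationError(
                f"{self.gene_id}: empty or negative UTR interval "
                f"[{self.utr_start},{self.utr_end})"
            )
        if self.extension < 0:
            raise ConfigurationError(f"{self.gene_id}: negative extension")

    @property
    def utr_length(self) -> int:
        return self.utr_end - self.utr_start


@dataclass(frozen=True)
class ExtendedUtrRecord:
    """One database entry: reverse complement of the extended 3'-UTR.

    ``span_start``/``span_end`` delimit the extended genomic span (0-based
    half-open).  ``db_sequence`` is oriented so that database position 0
    corresponds to the 3'-most genomic base of the extended span in the
    transcript sense.
    """

    gene_id: str
    chromosome: str
    strand: str
    span_start: int
    span_end: int
    utr_length: int
    db_sequence: str

    @property
    def db_length(self) -> int:
        return self.span_end - self.span_start

    @property
    def realized_extension(self) -> int:
        return self.db_length - self.utr_length

    def db_to_genome(self, db_position: int) -> tuple[str, int, str]:
        """Map a database position to (chromosome, genomic position, strand)."""
        if not 0 <= db_position < self.db_length:
            raise InputError(
                f"{self.gene_id}: db position {db_position} outside "
                f"[0,{self.db_length})"
            )
        if self.strand == "+":
            gpos = self.span_end - 1 - db_position
        else:
            gpos = self.span_start + db_position
        return self.chromosome, gpos, self.strand

    def genome_to_db(self, genomic_position: int) -> int:
        """Inverse of :meth:`db_to_genome`."""
        if not self.span_start <= genomic_position < self.span_end:
            raise InputError(
                f"{self.gene_id}: genomic position {genomic_position} outside "
                f"span [{self.span_start},{self.span_end})"
            )
        if self.strand == "+":
            return self.span_end - 1 - genomic_position
        return genomic_position - self.span_start


def build_extended_utr_db(
    annotation: Iterable[GeneModel],
    genome: Mapping[str, str],
    extension: int = 500,
) -> list[ExtendedUtrRecord]:
    """Build the reverse-complemented extended-UTR database.

    Each UTR is extended by up to ``extension`` nt downstream in the
    strand-aware sense (higher coordinates on '+', lower on '-'), truncated at
    chromosome ends.  Extensions are deliberately *not* truncated at
    neighbouring genes; overlapping records are permitted and ambiguity is
    resolved at the mapping stage (multimapped tags are excluded).
    """
    records: list[ExtendedUtrRecord] = []
    for gene in annotation:
        if gene.chromosome not in genome:
            raise InputError(f"{gene.gene_id}: unknown chromosome {gene.chromosome!r}")
        chrom_seq = genome[gene.chromosome]
        if gene.utr_end > len(chrom_seq):
            raise InputError(
                f"{gene.gene_id}: UTR extends past end of {gene.chromosome}"
            )
        if gene.strand == "+":
            span_start = gene.utr_start
            span_end = min(gene.utr_end + extension, len(chrom_seq))
            genomic_sense = chrom_seq[span_start:span_end]
            db_seq = reverse_complement(genomic_sense)
        else:
            span_start = max(gene.utr_start - extension, 0)
            span_end = gene.utr_end
            # transcript-sense sequence is revcomp(genomic); the database
            # stores its reverse complement, i.e. the forward genomic slice
            db_seq = chrom_seq[span_start:span_end]
        records.append(
            ExtendedUtrRecord(
                gene_id=gene.gene_id,
                chromosome=gene.chromosome,
                strand=gene.strand,
                span_start=span_start,
                span_end=span_end,
                utr_length=gene.utr_length,
                db_sequence=db_seq.upper(),
            )
        )
    return records


# ---------------------------------------------------------------------------
# File I/O


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(recs, str(path), "fasta")


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chromosome}\tpatseq\tthree_prime_UTR\t{g.utr_start + 1}\t"
                f"{g.utr_end}\t.\t{g.strand}\t.\tID=utr_{g.gene_id};gene_id={g.gene_id}\n"
            )


def write_bed(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chromosome}\t{g.utr_start}\t{g.utr_end}\t{g.gene_id}\t0\t{g.strand}\n"
            )


def read_gff3(path: str | Path, extension: int = 500) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "three_prime_UTR":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("gene_id") or attrs.get("ID")
            if gene_id is None:
                raise InputError(f"GFF3 record without gene_id/ID: {line.rstrip()}")
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chromosome=fields[0],
                    strand=fields[6],
                    utr_start=int(fields[3]) - 1,
                    utr_end=int(fields[4]),
                    extension=extension,
                )
            )
    return genes


def read_bed(path: str | Path, extension: int = 500) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            genes.append(
                GeneModel(
                    gene_id=fields[3],
                    chromosome=fields[0],
                    strand=fields[5] if len(fields) > 5 else "+",
                    utr_start=int(fields[1]),
                    utr_end=int(fields[2]),
                    extension=extension,
                )
            )
    return genes


def read_utr_annotation(path: str | Path, extension: int = 500) -> list[GeneModel]:
    """Dispatch on file extension: .gff/.gff3 vs .bed."""
    suffix = Path(path).suffix.lower()
    if suffix in (".gff", ".gff3"):
        return read_gff3(path, extension)
    if suffix == ".bed":
        return read_bed(path, extension)
    raise InputError(f"unrecognized annotation format: {path}")


def write_db_fasta(
    records: Iterable[ExtendedUtrRecord], fasta_path: str | Path, map_path: str | Path
) -> None:
    """Write database sequences plus the sidecar TSV coordinate map."""
    records = list(records)
    recs = [
        SeqRecord(Seq(r.db_sequence), id=r.gene_id, description="") for r in records
    ]
    SeqIO.write(recs, str(fasta_path), "fasta")
    with open(map_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["gene_id", "chromosome", "strand", "span_start", "span_end", "utr_length"]
        )
        for r in records:
            writer.writerow(
                [r.gene_id, r.chromosome, r.strand, r.span_start, r.span_end, r.utr_length]
            )


def read_db_fasta(
    fasta_path: str | Path, map_path: str | Path
) -> list[ExtendedUtrRecord]:
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    records = []
    with open(map_path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            records.append(
                ExtendedUtrRecord(
                    gene_id=row["gene_id"],
                    chromosome=row["chromosome"],
                    strand=row["strand"],
                    span_start=int(row["span_start"]),
                    span_end=int(row["span_end"]),
                    utr_length=int(row["utr_length"]),
                    db_sequence=seqs[row["gene_id"]],
                )
            )
    return records
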