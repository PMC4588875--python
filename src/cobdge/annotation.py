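"""Gene models, FASTA/GFF3 I/O and interval utilities.

Coordinates are GFF3-style 1-based inclusive at every public interface;
helpers that slice python strings convert locally.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Transcript:
    id: str
    exons: list[tuple[int, int]] = field(default_factory=list)  # 1-based inclusive, genomic order

    def spliced_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


@dataclass
class Gene:
    id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int  # 1-based inclusive
    end: int
    transcripts: list[Transcript] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.id}: strand must be + or -, got {self.strand!r}")
        if self.start > self.end:
            raise ValueError(f"gene {self.id}: start {self.start} > end {self.end}")


@dataclass
class GeneAnnotation:
    """Collection of gene models on a genome."""

    genes: dict[str, Gene] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def add(self, gene: Gene) -> None:
        self.genes[gene.id] = gene

    def spliced_sequence(self, gene: Gene, transcript: Transcript, genome: dict[str, str]) -> str:
        """Mature transcript sequence: exons concatenated in genomic order,
        reverse-complemented for minus-strand genes."""
        chrom_seq = genome[gene.chrom]
        parts = [chrom_seq[s - 1 : e] for s, e in sorted(transcript.exons)]
        seq = "".join(parts)
        return revcomp(seq) if gene.strand == "-" else seq

    # ---- GFF3 ----

    def to_gff3(self, path: str, chrom_lengths: dict[str, int] | None = None) -> None:
        lines = ["##gff-version 3"]
        if chrom_lengths:
            for chrom, length in sorted(chrom_lengths.items()):
                lines.append(f"##sequence-region {chrom} 1 {length}")
        for gene in sorted(self.genes.values(), key=lambda g: (g.chrom, g.start)):
            lines.append(
                f"{gene.chrom}\tcobdge\tgene\t{gene.start}\t{gene.end}\t.\t{gene.strand}\t.\tID={gene.id}"
            )
            for tx in gene.transcripts:
                tx_start = min(s for s, _ in tx.exons)
                tx_end = max(e for _, e in tx.exons)
                lines.append(
                    f"{gene.chrom}\tcobdge\tmRNA\t{tx_start}\t{tx_end}\t.\t{gene.strand}\t.\t"
                    f"ID={tx.id};Parent={gene.id}"
                )
                for i, (s, e) in enumerate(sorted(tx.exons), 1):
                    lines.append(
                        f"{gene.chrom}\tcobdge\texon\t{s}\t{e}\t.\t{gene.strand}\t.\t"
                        f"ID={tx.id}.exon{i};Parent={tx.id}"
                    )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def from_gff3(cls, path: str) -> "GeneAnnotation":
        db = gffutils.create_db(
            path, dbfn=":memory:", force=True, keep_order=True, merge_strategy="error"
        )
        ann = cls()
        for g in db.features_of_type("gene"):
            gene = Gene(id=g.id, chrom=g.seqid, strand=g.strand, start=g.start, end=g.end)
            for t in db.children(g, featuretype="mRNA"):
                tx = Transcript(id=t.id)
                for ex in db.children(t, featuretype="exon", order_by="start"):
                    tx.exons.append((ex.start, ex.end))
                gene.transcripts.append(tx)
            ann.add(gene)
        return ann


def extend_gene_bounds(
    annotation: GeneAnnotation,
    chrom_lengths: dict[str, int],
    extension: int = 300,
) -> dict[str, tuple[int, int]]:
    """Widen each gene interval by ``extension`` nt on both sides, clamped to
    [1, chromosome length].

    UTRs of poorly annotated genomes are often missing from gene models; the
    3'-anchored expression tags frequently fall just outside the annotated
    bounds, so gene intervals are extended (default 300 nt) before tags are
    assigned to genes.
    """
    out: dict[str, tuple[int, int]] = {}
    for gene in annotation:
        length = chrom_lengths[gene.chrom]
        out[gene.id] = (max(1, gene.start - extension), min(length, gene.end + extension))
    return out


# ---- FASTA ----


def write_fasta(genome: dict[str, str], path: str) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def chrom_lengths(genome: dict[str, str]) -> dict[str, int]:
    return {chrom: len(seq) for chrom, seq in genome.items()}
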