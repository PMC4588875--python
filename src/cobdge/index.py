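"""Placement of 21-nt tags on a genome with at most one mismatch.

The index is a pigeonhole scheme: every genomic 21-mer window is keyed by its
first 10 nt and by its last 11 nt. A query with at most one substitution must
match one of the two halves exactly, so the union of the two half-lookups,
verified by a Hamming check, is complete for the <=1-mismatch contract.
Minus-strand placements come from querying the reverse complement; positions
are always reported as 1-based starts on plus-strand coordinates.
"""

from __future__ import annotations

from collections import defaultdict
from typing import NamedTuple

from .annotation import GeneAnnotation, revcomp

TAG_LEN = 21
_HALF = 10  # first seed 10 nt, second seed 11 nt
_VALID = set("ACGT")


class Placement(NamedTuple):
    chrom: str
    position: int  # 1-based start of the 21-mer on + strand coordinates
    strand: str
    mismatches: int


class TagIndex:
    """Exact-and-one-mismatch lookup of 21-mers against a genome."""

    def __init__(self, genome: dict[str, str], max_mismatches: int = 1):
        if not genome:
            raise ValueError("genome is empty")
        if max_mismatches not in (0, 1):
            raise ValueError("max_mismatches must be 0 or 1")
        self.genome = {c: s.upper() for c, s in genome.items()}
        self.max_mismatches = max_mismatches
        self._left: dict[str, list[tuple[str, int]]] = defaultdict(list)
        self._right: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom, seq in sorted(self.genome.items()):
            for p in range(len(seq) - TAG_LEN + 1):
                self._left[seq[p : p + _HALF]].append((chrom, p))
                self._right[seq[p + _HALF : p + TAG_LEN]].append((chrom, p))

    def _forward_hits(self, tag: str) -> list[tuple[str, int, int]]:
        cands = set(self._left.get(tag[:_HALF], ()))
        cands.update(self._right.get(tag[_HALF:], ()))
        hits = []
        for chrom, p in cands:
            window = self.genome[chrom][p : p + TAG_LEN]
            mm = sum(a != b for a, b in zip(window, tag))
            if mm <= self.max_mismatches:
                hits.append((chrom, p, mm))
        return hits


def match_tag(tag: str, index: TagIndex) -> list[Placement]:
    """All placements of a 21-mer on either strand with <=1 mismatch, ordered
    by (chrom, position, strand). Tags with non-ACGT characters match nothing.
    """
    if len(tag) != TAG_LEN:
        raise ValueError(f"tag must be {TAG_LEN} nt, got {len(tag)}")
    tag = tag.upper()
    if not set(tag) <= _VALID:
        return []
    placements = [
        Placement(chrom, p + 1, "+", mm) for chrom, p, mm in index._forward_hits(tag)
    ]
    placements += [
        Placement(chrom, p + 1, "-", mm)
        for chrom, p, mm in index._forward_hits(revcomp(tag))
    ]
    return sorted(placements, key=lambda h: (h.chrom, h.position, h.strand))


def build_tag_index(genome: dict[str, str], max_mismatches: int = 1) -> TagIndex:
    return TagIndex(genome, max_mismatches=max_mismatches)


def build_transcript_tag_set(
    annotation: GeneAnnotation, genome: dict[str, str]
) -> dict[str, set[tuple[str, str]]]:
    """Every CATG-anchored 21-mer of every spliced transcript.

    Tags that failed genomic placement are looked up here to recover tags that
    straddle exon-exon junctions of the mature mRNA. Keys are 21-mers starting
    with CATG; values are the (gene, transcript) pairs carrying the k-mer.
    """
    out: dict[str, set[tuple[str, str]]] = defaultdict(set)
    for gene in annotation:
        for tx in gene.transcripts:
            seq = annotation.spliced_sequence(gene, tx, genome)
            pos = seq.find("CATG")
            while pos != -1:
                if len(seq) - pos >= TAG_LEN:
                    out[seq[pos : pos + TAG_LEN]].add((gene.id, tx.id))
                pos = seq.find("CATG", pos + 1)
    return dict(out)
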