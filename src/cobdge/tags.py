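"""Clean-tag extraction from raw FASTQ reads.

A raw DGE read is sequenced without the CATG anchor: adapter removal must
leave exactly the 17 nt of cDNA downstream of the anchor. "CATG" is then
restored electronically at the 5' end, giving the canonical 21-nt tag.
Clean-tag criteria: exactly 21 nt, no ambiguous base (N), and a per-library
count of at least two.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

ANCHOR = "CATG"
CDNA_LEN = 17
TAG_LEN = 21


@dataclass
class CleanTagTable:
    """Per-library table of clean 21-nt tags and their counts."""

    library_id: str
    counts: dict[str, int] = field(default_factory=dict)
    total_raw_reads: int = 0
    total_clean_reads: int = 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            sorted(self.counts.items()), columns=["tag", "count"]
        )
        return df

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str, library_id: str) -> "CleanTagTable":
        df = pd.read_csv(path, sep="\t", dtype={"tag": str, "count": int})
        counts = dict(zip(df["tag"], df["count"]))
        return cls(
            library_id=library_id,
            counts=counts,
            total_raw_reads=sum(counts.values()),
            total_clean_reads=sum(counts.values()),
        )


def strip_adapter(
    read: str,
    adapter: str,
    seed_length: int = 7,
    no_adapter_fallback: bool = True,
) -> str | None:
    """Return the 17-nt cDNA fragment preceding the 3' adapter, or None.

    The adapter is located by exact match of its leading ``seed_length``-mer;
    a fragment is accepted only if it is exactly 17 nt. When the adapter is
    absent and ``no_adapter_fallback`` is on, the first 17 nt are taken
    (reads longer than fragment+adapter can run past the adapter copy).
    """
    if not adapter:
        raise ValueError("adapter sequence must be non-empty")
    if not read:
        return None
    seed = adapter[: min(seed_length, len(adapter))]
    pos = read.find(seed)
    if pos != -1:
        return read[:pos] if pos == CDNA_LEN else None
    if no_adapter_fallback and len(read) >= CDNA_LEN:
        return read[:CDNA_LEN]
    return None


def extract_clean_tags(
    fastq_path: str,
    adapter: str,
    library_id: str | None = None,
    min_count: int = 2,
    seed_length: int = 7,
    no_adapter_fallback: bool = True,
) -> CleanTagTable:
    """Convert one FASTQ library into its clean-tag table.

    Accepted 17-nt fragments are prefixed with CATG; tags containing N and
    tags seen fewer than ``min_count`` times in the library are discarded.
    """
    if library_id is None:
        library_id = fastq_path.rsplit("/", 1)[-1].rsplit(".", 1)[0]
    raw = 0
    counter: Counter[str] = Counter()
    try:
        with open(fastq_path) as fh:
            for title, seq, _qual in FastqGeneralIterator(fh):
                raw += 1
                frag = strip_adapter(
                    seq.upper(), adapter, seed_length=seed_length,
                    no_adapter_fallback=no_adapter_fallback,
                )
                if frag is None or "N" in frag:
                    continue
                counter[ANCHOR + frag] += 1
    except ValueError as exc:
        raise ValueError(
            f"malformed FASTQ record around read {raw + 1} in {fastq_path}: {exc}"
        ) from exc
    counts = {tag: n for tag, n in counter.items() if n >= min_count}
    return CleanTagTable(
        library_id=library_id,
        counts=counts,
        total_raw_reads=raw,
        total_clean_reads=sum(counts.values()),
    )
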