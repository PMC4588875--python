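"""Tag-to-gene assignment, gene quantification, TPTM and preferential calls.

Assignment rules: a tag's genomic placements are intersected with the
(300-nt-extended) gene intervals on the matching strand; tags with no genomic
placement are looked up in the transcript tag set to recover junction tags.
Tags hitting 1-3 distinct genes are assigned with fraction 1/k each; tags
hitting more than three genes are removed; tags hitting none are unmapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .annotation import GeneAnnotation
from .index import TAG_LEN, TagIndex, match_tag
from .tags import CleanTagTable

ASSIGNED = "assigned"
DROPPED = "dropped_too_many_genes"
UNMAPPED = "unmapped"

MAX_GENES = 3


@dataclass
class TagOutcome:
    status: str  # assigned | dropped_too_many_genes | unmapped
    count: int
    genes: list[tuple[str, float]] = field(default_factory=list)  # (gene, fraction)


@dataclass
class TagAssignment:
    """Outcome of assigning one library's clean tags to genes."""

    library_id: str
    outcomes: dict[str, TagOutcome] = field(default_factory=dict)

    def reads(self, status: str) -> int:
        return sum(o.count for o in self.outcomes.values() if o.status == status)

    def summary(self) -> dict[str, int]:
        return {s: self.reads(s) for s in (ASSIGNED, DROPPED, UNMAPPED)}


class _GeneLookup:
    """Per (chrom, strand) sorted extended intervals for containment queries."""

    def __init__(self, annotation: GeneAnnotation, extended: Mapping[str, tuple[int, int]]):
        self._by_key: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
        for gene in annotation:
            lo, hi = extended[gene.id]
            self._by_key.setdefault((gene.chrom, gene.strand), []).append((lo, hi, gene.id))
        for lst in self._by_key.values():
            lst.sort()

    def containing(self, chrom: str, strand: str, start: int, end: int) -> list[str]:
        out = []
        for lo, hi, gid in self._by_key.get((chrom, strand), ()):
            if lo > start:
                break
            if hi >= end:
                out.append(gid)
        return out


def assign_tags(
    clean_tags: CleanTagTable,
    index: TagIndex,
    annotation: GeneAnnotation,
    extended: Mapping[str, tuple[int, int]],
    tx_tags: Mapping[str, set[tuple[str, str]]],
) -> TagAssignment:
    """Assign every clean tag of one library to genes.

    Multiple placements inside the same gene count once (gene-set semantics);
    the fraction divides by the number of distinct genes, not placements.
    """
    ann_chroms = {g.chrom for g in annotation}
    if not ann_chroms <= set(index.genome):
        missing = sorted(ann_chroms - set(index.genome))
        raise ValueError(f"annotation chromosomes absent from genome index: {missing}")
    lookup = _GeneLookup(annotation, extended)
    result = TagAssignment(library_id=clean_tags.library_id)
    for tag, count in clean_tags.counts.items():
        placements = match_tag(tag, index)
        if placements:
            genes: set[str] = set()
            for chrom, pos, strand, _mm in placements:
                genes.update(lookup.containing(chrom, strand, pos, pos + TAG_LEN - 1))
        else:
            genes = {gene for gene, _tx in tx_tags.get(tag, ())}
        k = len(genes)
        if k == 0:
            result.outcomes[tag] = TagOutcome(UNMAPPED, count)
        elif k <= MAX_GENES:
            frac = 1.0 / k
            result.outcomes[tag] = TagOutcome(
                ASSIGNED, count, [(g, frac) for g in sorted(genes)]
            )
        else:
            result.outcomes[tag] = TagOutcome(DROPPED, count)
    return result


def quantify_genes(
    assignments: Mapping[str, TagAssignment], gene_ids: Iterable[str]
) -> pd.DataFrame:
    """Gene x library matrix of (fractional) sense-strand tag counts.

    A gene's expression is the sum over its assigned tags of count x fraction;
    genes with no tags appear with count 0.
    """
    gene_ids = list(gene_ids)
    data = {}
    for lib, assignment in assignments.items():
        col = dict.fromkeys(gene_ids, 0.0)
        for outcome in assignment.outcomes.values():
            if outcome.status != ASSIGNED:
                continue
            for gene, frac in outcome.genes:
                col[gene] = col.get(gene, 0.0) + outcome.count * frac
        data[lib] = col
    return pd.DataFrame(data, index=gene_ids)


def tptm_normalize(counts: pd.DataFrame, denominators: pd.Series) -> pd.DataFrame:
    """Transcripts per ten million reads: count / denominator * 1e7.

    The denominator defaults (in the pipeline) to the library's total
    clean-read count; per-library zero denominators are rejected by name.
    """
    zero = [lib for lib in counts.columns if denominators.get(lib, 0) <= 0]
    if zero:
        raise ValueError(f"zero/missing TPTM denominator for libraries: {zero}")
    return counts / denominators.reindex(counts.columns) * 1e7


def group_tptm(
    counts: pd.DataFrame, denominators: pd.Series, design: pd.Series, group: str
) -> pd.Series:
    """Group-level TPTM from pooled replicates: summed counts over summed
    denominators, times 1e7."""
    libs = [s for s in counts.columns if design.get(s) == group]
    if not libs:
        raise ValueError(f"group {group!r} has no libraries in the design")
    denom = float(denominators.reindex(libs).sum())
    if denom <= 0:
        raise ValueError(f"group {group!r} has zero total denominator")
    return counts[libs].sum(axis=1) / denom * 1e7


def call_preferential(
    counts: pd.DataFrame,
    denominators: pd.Series,
    design: pd.Series,
    contrast: tuple[str, str],
    threshold: float = 10.0,
    per_replicate: bool = False,
) -> dict[str, list[str]]:
    """Presence/absence calls: a gene is preferentially expressed in one group
    when its pooled TPTM there is at least ``threshold`` and exactly zero in
    the other group.

    With ``per_replicate`` the zero requirement applies to every replicate
    library individually instead of the pooled group.
    """
    ga, gb = contrast
    ta = group_tptm(counts, denominators, design, ga)
    tb = group_tptm(counts, denominators, design, gb)
    if per_replicate:
        libs_a = [s for s in counts.columns if design.get(s) == ga]
        libs_b = [s for s in counts.columns if design.get(s) == gb]
        zero_a = (counts[libs_a] == 0).all(axis=1)
        zero_b = (counts[libs_b] == 0).all(axis=1)
    else:
        zero_a = ta == 0
        zero_b = tb == 0
    pref_a = counts.index[(ta >= threshold) & zero_b]
    pref_b = counts.index[(tb >= threshold) & zero_a]
    return {ga: list(pref_a), gb: list(pref_b)}
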