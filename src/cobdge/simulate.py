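"""Ground-truth tag-seq simulator.

Emulates an NlaIII-anchored digital gene expression experiment: a toy genome
with annotated (optionally spliced) genes, a 2-tissue x 2-nitrogen x 3-replicate
expression design, and raw FASTQ libraries in which each read carries the 17 nt
of cDNA sequenced downstream of the 3'-most CATG site of a transcript, followed
by the 3' sequencing adapter.  Every stage of the analysis pipeline can be
validated against the saved truth tables.

All randomness flows from ``SimulationConfig.seed`` through
``numpy.random.SeedSequence`` children, so identical configs give byte-identical
outputs.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation import Gene, GeneAnnotation, Transcript, revcomp, write_fasta

TAG_LEN = 21  # CATG + 17 bp of sequenced cDNA
ANCHOR = "CATG"
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_GROUPS = ("cob_ON", "cob_LN", "floret_ON", "floret_LN")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated DGE experiment.

    ``library_depth`` defaults to 2e5 reads per library, a down-scaled stand-in
    for a multi-million-read HiSeq tag library; ``dispersion`` is the
    negative-binomial phi in Var = mu + phi*mu^2.
    """

    n_genes: int = 300
    gene_length: tuple[int, int] = (300, 800)  # spliced transcript length range, nt
    intergenic_gap: tuple[int, int] = (400, 700)  # nt between gene bodies
    groups: tuple[str, ...] = DEFAULT_GROUPS
    replicates_per_group: int = 3
    de_fraction: float = 0.0
    fold_change: float = 4.0
    dispersion: float = 0.1
    library_depth: int = 200_000
    error_rate: float = 0.001
    adapter_seq: str = "TCGTATGCCGTCTTCTGCTTG"
    read_length: int = 35
    seed: int = 0
    de_contrast: tuple[str, str] = ("cob_ON", "floret_ON")
    n_exclusive: int = 0  # genes expressed in one contrast group, absent in the other
    n_junction_genes: int = 0  # genes whose canonical tag spans an exon-exon junction
    two_exon_fraction: float = 0.3
    intron_length: tuple[int, int] = (60, 120)
    abundance_sigma: float = 1.0  # log-normal spread of baseline abundances

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.gene_length[0] < 25:
            raise ValueError("gene_length min must be >= 25 nt to host CATG + 17 nt")
        for lo, hi in (self.gene_length, self.intergenic_gap, self.intron_length):
            if lo <= 0 or hi < lo:
                raise ValueError("ranges must be positive with min <= max")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if self.fold_change <= 1.0:
            raise ValueError("fold_change must be > 1")
        if self.dispersion < 0.0:
            raise ValueError("dispersion must be >= 0")
        if "N" in self.adapter_seq.upper() or not self.adapter_seq:
            raise ValueError("adapter_seq must be non-empty and contain no N")
        for g in self.de_contrast:
            if g not in self.groups:
                raise ValueError(f"de_contrast group {g!r} not in groups")

    @property
    def samples(self) -> list[str]:
        return [f"{g}_r{i + 1}" for g in self.groups for i in range(self.replicates_per_group)]

    def design(self) -> pd.Series:
        """Sample -> group mapping."""
        return pd.Series(
            {f"{g}_r{i + 1}": g for g in self.groups for i in range(self.replicates_per_group)},
            name="group",
        )


@dataclass
class GroundTruth:
    """Per-gene truth for one simulation.

    ``abundance`` holds group-mean relative abundances (columns sum to 1);
    ``tag`` is the canonical 21-nt CATG-anchored tag of each gene.
    """

    abundance: pd.DataFrame  # genes x groups, columns sum to 1
    de_flag: pd.Series  # bool
    de_direction: pd.Series  # +1 up in contrast B, -1 down, 0 ns
    true_fold: pd.Series  # ratio B/A for DE genes, 1.0 otherwise
    tag: pd.Series  # canonical 21-mer per gene
    exclusive_group: pd.Series  # group label where the gene is expressed, '' otherwise
    contrast: tuple[str, str]


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _erase_anchor(arr: np.ndarray, lo: int, rng: np.random.Generator) -> None:
    """Destroy every CATG occurrence starting at index >= lo (in place)."""
    anchor = np.frombuffer(ANCHOR.encode(), dtype=np.uint8)
    changed = True
    while changed:
        changed = False
        seq = arr.tobytes()
        pos = seq.find(ANCHOR.encode(), lo)
        while pos != -1:
            j = pos + int(rng.integers(0, 4))
            alt = _BASES[_BASES != arr[j]]
            arr[j] = alt[int(rng.integers(0, 3))]
            changed = True
            pos = seq.find(ANCHOR.encode(), pos + 1)
        # loop again in case mutations created a new CATG


def generate_genome(config: SimulationConfig) -> tuple[dict[str, str], GeneAnnotation]:
    """Build a single-chromosome toy genome and its annotation.

    Each gene carries one transcript whose 3'-most 21 nt are CATG + 17 nt:
    the canonical tag. Strands are random. A configurable fraction of genes is
    split into two exons; the first ``n_junction_genes`` of those have the
    intron inserted inside the tag so the tag only exists on the spliced
    transcript, never contiguously in the genome.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    chrom = "chr1"
    pieces: list[np.ndarray] = []
    pos = 0  # 0-based running cursor
    ann = GeneAnnotation()
    n_two_exon = max(
        config.n_junction_genes, int(round(config.two_exon_fraction * config.n_genes))
    )
    anchor_bytes = np.frombuffer(ANCHOR.encode(), dtype=np.uint8)

    gap0 = int(rng.integers(config.intergenic_gap[0], config.intergenic_gap[1] + 1))
    pieces.append(_random_seq(rng, gap0))
    pos += gap0

    for i in range(config.n_genes):
        gid = f"gene{i + 1:04d}"
        length = int(rng.integers(config.gene_length[0], config.gene_length[1] + 1))
        tx = _random_seq(rng, length)
        # plant the canonical tag as the transcript's final 21 nt and make its
        # CATG the 3'-most anchor site
        tag_start = length - TAG_LEN
        tx[tag_start : tag_start + 4] = anchor_bytes
        _erase_anchor(tx, tag_start + 1, rng)
        tag = tx[tag_start:].tobytes().decode()

        two_exon = i < n_two_exon
        junction_gene = i < config.n_junction_genes
        if two_exon:
            if junction_gene:
                # splice site inside the tag: 8-13 nt of the tag on the 2nd exon
                cut = length - int(rng.integers(8, 14))
            else:
                cut = int(rng.integers(30, max(31, tag_start - 5)))
            intron = _random_seq(
                rng, int(rng.integers(config.intron_length[0], config.intron_length[1] + 1))
            )
            _erase_anchor(intron, 0, rng)  # keep anchor sites transcript-only
            pre = np.concatenate([tx[:cut], intron, tx[cut:]])
            exon_sense = [(0, cut), (cut + len(intron), len(pre))]  # 0-based half-open, sense
        else:
            pre = tx
            exon_sense = [(0, length)]

        strand = "+" if rng.random() < 0.5 else "-"
        g_arr = pre if strand == "+" else np.frombuffer(
            revcomp(pre.tobytes().decode()).encode(), dtype=np.uint8
        ).copy()
        g_start = pos  # 0-based
        pieces.append(g_arr)
        pos += len(g_arr)
        # genomic exon intervals (1-based inclusive)
        exons: list[tuple[int, int]] = []
        for s, e in exon_sense:
            if strand == "+":
                exons.append((g_start + s + 1, g_start + e))
            else:
                L = len(pre)
                exons.append((g_start + (L - e) + 1, g_start + (L - s)))
        tx_rec = Transcript(id=f"{gid}.t1", exons=sorted(exons))
        gene = Gene(
            id=gid, chrom=chrom, strand=strand,
            start=g_start + 1, end=g_start + len(g_arr), transcripts=[tx_rec],
        )
        gene._canonical_tag = tag  # type: ignore[attr-defined]  # carried to truth assignment
        ann.add(gene)

        gap = int(rng.integers(config.intergenic_gap[0], config.intergenic_gap[1] + 1))
        pieces.append(_random_seq(rng, gap))
        pos += gap

    genome = {chrom: np.concatenate(pieces).tobytes().decode()}
    return genome, ann


def assign_expression_truth(annotation: GeneAnnotation, config: SimulationConfig) -> GroundTruth:
    """Draw baseline abundances and plant differential / exclusive expression.

    floor(de_fraction * n_genes) genes are differentially expressed between the
    contrast groups, half up (ties to up) and half down, with the group-mean
    ratio exactly equal to ``fold_change``: the DE genes' abundances are fixed
    and the remaining free genes are rescaled so each group still sums to 1.
    """
    genes = [g.id for g in annotation]
    n = len(genes)
    if n == 0:
        raise ValueError("annotation is empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    w = np.exp(rng.normal(0.0, config.abundance_sigma, size=n))
    w /= w.sum()
    base = pd.Series(w, index=genes)

    n_de = int(math.floor(config.de_fraction * n))
    n_up = (n_de + 1) // 2
    order = rng.permutation(n)
    de_idx = order[:n_de]
    excl_idx = order[n_de : n_de + config.n_exclusive]

    de_flag = pd.Series(False, index=genes)
    de_dir = pd.Series(0, index=genes, dtype=int)
    true_fold = pd.Series(1.0, index=genes)
    exclusive = pd.Series("", index=genes)

    ga, gb = config.de_contrast
    abundance = pd.DataFrame({g: base.copy() for g in config.groups})

    f = config.fold_change
    for k, j in enumerate(de_idx):
        gid = genes[j]
        de_flag[gid] = True
        if k < n_up:
            de_dir[gid] = 1
            abundance.loc[gid, gb] = base[gid] * f
            true_fold[gid] = f
        else:
            de_dir[gid] = -1
            abundance.loc[gid, gb] = base[gid] / f
            true_fold[gid] = 1.0 / f
    for k, j in enumerate(excl_idx):
        gid = genes[j]
        off = gb if k % 2 == 0 else ga
        on = ga if off == gb else gb
        abundance.loc[gid, off] = 0.0
        exclusive[gid] = on

    # rescale free genes so each group's abundances sum to 1 while planted
    # ratios stay exact
    fixed = de_flag | (exclusive != "")
    for grp in config.groups:
        col = abundance[grp]
        fixed_mass = col[fixed].sum()
        free_mass = col[~fixed].sum()
        if free_mass <= 0 or fixed_mass >= 1.0 and free_mass == 0:
            raise ValueError("no free genes left to renormalize group abundances")
        abundance.loc[~fixed, grp] = col[~fixed] * (1.0 - fixed_mass) / free_mass

    tags = pd.Series({g.id: g._canonical_tag for g in annotation})  # type: ignore[attr-defined]
    return GroundTruth(
        abundance=abundance, de_flag=de_flag, de_direction=de_dir,
        true_fold=true_fold, tag=tags, exclusive_group=exclusive,
        contrast=(ga, gb),
    )


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, phi: float
) -> np.ndarray:
    """NB(mu, phi) draws with Var = mu + phi mu^2 (Poisson when phi = 0)."""
    mean = np.asarray(mean, dtype=float)
    if phi == 0.0:
        return rng.poisson(mean)
    lam = np.where(mean > 0, rng.gamma(1.0 / phi, np.maximum(mean, 1e-300) * phi), 0.0)
    return rng.poisson(lam)


def simulate_counts(
    truth: GroundTruth, config: SimulationConfig, seed_offset: int = 2
) -> pd.DataFrame:
    """Per-gene true tag counts for every library (genes x samples)."""
    design = config.design()
    cols = {}
    for k, (sample, group) in enumerate(design.items()):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, seed_offset, k]))
        mean = truth.abundance[group].to_numpy() * config.library_depth
        cols[sample] = _nb_counts(rng, mean, config.dispersion)
    return pd.DataFrame(cols, index=truth.abundance.index)


def _apply_errors(reads: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    """Per-base substitution errors in place; an error never keeps the base."""
    if rate <= 0:
        return
    mask = rng.random(reads.shape) < rate
    n_err = int(mask.sum())
    if n_err == 0:
        return
    # shift each erroneous base by 1-3 positions in the ACGT alphabet
    lut = np.full(256, 0, dtype=np.uint8)
    for i, b in enumerate(_BASES):
        lut[b] = i
    idx = lut[reads[mask]]
    reads[mask] = _BASES[(idx + rng.integers(1, 4, size=n_err)) % 4]


def simulate_library(
    truth: GroundTruth,
    group: str,
    config: SimulationConfig,
    fastq_path: str,
    rng: np.random.Generator,
) -> pd.Series:
    """Write one raw FASTQ library for ``group`` and return the per-gene truth
    counts that were emitted.

    Each read is the 17-nt tag suffix (sequence 3' of the gene's CATG anchor,
    sense strand, no leading CATG) followed by the 3' adapter, truncated or
    A-padded to ``read_length``, with substitution errors at ``error_rate``.
    """
    if config.library_depth <= 0:
        raise ValueError("library_depth must be > 0")
    if group not in truth.abundance.columns:
        raise ValueError(f"group {group!r} not present in truth")
    mean = truth.abundance[group].to_numpy() * config.library_depth
    counts = _nb_counts(rng, mean, config.dispersion)
    genes = truth.abundance.index

    lib_id = os.path.basename(fastq_path).rsplit(".", 1)[0]
    templates = []
    for gid in genes:
        suffix = truth.tag[gid][4:]  # 17 nt sequenced downstream of CATG
        read = (suffix + config.adapter_seq + "A" * config.read_length)[: config.read_length]
        templates.append(np.frombuffer(read.encode(), dtype=np.uint8))
    template_arr = np.vstack(templates)
    reads = np.repeat(template_arr, counts, axis=0).copy()
    _apply_errors(reads, config.error_rate, rng)

    qual = "I" * config.read_length
    with open(fastq_path, "w") as fh:
        for i in range(reads.shape[0]):
            fh.write(f"@{lib_id}_{i + 1}\n{reads[i].tobytes().decode()}\n+\n{qual}\n")
    return pd.Series(counts, index=genes, name=lib_id)


def simulate_dataset(config: SimulationConfig, outdir: str) -> dict[str, object]:
    """Full simulation: genome.fa, genes.gff3, one FASTQ per sample, truth
    tables and the design table. Returns the in-memory objects and paths."""
    os.makedirs(outdir, exist_ok=True)
    genome, ann = generate_genome(config)
    truth = assign_expression_truth(ann, config)

    fasta = os.path.join(outdir, "genome.fa")
    gff = os.path.join(outdir, "genes.gff3")
    write_fasta(genome, fasta)
    ann.to_gff3(gff, chrom_lengths={c: len(s) for c, s in genome.items()})

    design = config.design()
    fastqs: dict[str, str] = {}
    truth_counts = {}
    for k, (sample, group) in enumerate(design.items()):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2, k]))
        path = os.path.join(outdir, f"reads_{sample}.fastq")
        truth_counts[sample] = simulate_library(truth, group, config, path, rng)
        fastqs[sample] = path
    truth_counts_df = pd.DataFrame(truth_counts)

    truth_counts_df.rename_axis("gene").to_csv(os.path.join(outdir, "truth_counts.tsv"), sep="\t")
    truth_de = pd.DataFrame(
        {
            "de_flag": truth.de_flag,
            "de_direction": truth.de_direction,
            "true_fold": truth.true_fold,
            "exclusive_group": truth.exclusive_group,
            "tag": truth.tag,
        }
    )
    truth_de.rename_axis("gene").to_csv(os.path.join(outdir, "truth_de.tsv"), sep="\t")
    design.rename_axis("sample").to_csv(os.path.join(outdir, "design.tsv"), sep="\t")

    return {
        "genome": genome,
        "annotation": ann,
        "truth": truth,
        "truth_counts": truth_counts_df,
        "design": design,
        "fasta": fasta,
        "gff3": gff,
        "fastqs": fastqs,
    }
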