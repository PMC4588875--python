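"""End-to-end orchestration of the DGE analysis and small report utilities."""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from .annotation import GeneAnnotation, chrom_lengths, extend_gene_bounds, read_fasta
from .assign import assign_tags, call_preferential, quantify_genes, tptm_normalize
from .de import DESettings, de_contrast, estimate_common_dispersion, ln_specific_genes, tmm_factors, venn_partition
from .enrich import fisher_enrichment, read_term_annotation
from .index import TagIndex, build_transcript_tag_set
from .tags import extract_clean_tags

log = logging.getLogger("cobdge")


@dataclass
class PipelineConfig:
    genome_fasta: str
    annotation_gff3: str
    fastqs: dict[str, str]  # sample -> FASTQ path
    design: dict[str, str]  # sample -> group
    outdir: str
    adapter: str
    contrasts: dict[str, tuple[str, str]] = field(default_factory=dict)  # name -> (A, B)
    venn_pairs: list[tuple[str, str]] = field(default_factory=list)  # contrast-name pairs
    ln_specific: tuple[str, str, str] | None = None  # (LN, LP, LK) contrast names
    terms_tsv: str | None = None
    enrich_contrast: str | None = None  # DE genes of this contrast vs all genes
    extension: int = 300
    min_count: int = 2
    preferential_threshold: float = 10.0
    settings: DESettings = field(default_factory=DESettings)
    dispersion: float | None = None  # fixed phi; estimated when None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        settings = DESettings(**raw.pop("settings", {}))
        contrasts = {k: tuple(v) for k, v in raw.pop("contrasts", {}).items()}
        venn = [tuple(p) for p in raw.pop("venn_pairs", [])]
        lns = raw.pop("ln_specific", None)
        return cls(
            settings=settings, contrasts=contrasts, venn_pairs=venn,
            ln_specific=tuple(lns) if lns else None, **raw,
        )


def ddct_relative_expression(
    ct_target_sample: float,
    ct_reference_sample: float,
    ct_target_calibrator: float,
    ct_reference_calibrator: float,
) -> float:
    """Comparative C_T relative expression: 2^-(ddCT).

    ddCT = (CT_target - CT_reference) in the sample minus the same difference
    in the calibrator; the reference is the internal-control gene.
    """
    ddct = (ct_target_sample - ct_reference_sample) - (
        ct_target_calibrator - ct_reference_calibrator
    )
    return float(2.0 ** (-ddct))


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Execute extract -> index -> assign -> quantify -> TPTM -> DE ->
    preferential -> Venn -> LN-specific -> enrichment; write all tables plus a
    machine-readable manifest. Deterministic for a fixed config."""
    os.makedirs(config.outdir, exist_ok=True)
    manifest: dict[str, object] = {
        "version": __version__, "seed": config.seed, "stages": {},
    }

    current = {"stage": "setup"}

    def stage(name):
        current["stage"] = name
        log.info("stage %s ...", name)
        return time.time()

    try:
        t0 = stage("extract")
        clean = {}
        for sample, path in config.fastqs.items():
            table = extract_clean_tags(path, config.adapter, library_id=sample,
                                       min_count=config.min_count)
            table.to_tsv(os.path.join(config.outdir, f"tags_{sample}.tsv"))
            clean[sample] = table
        manifest["stages"]["extract"] = {
            "seconds": round(time.time() - t0, 2),
            "raw_reads": {s: t.total_raw_reads for s, t in clean.items()},
            "clean_reads": {s: t.total_clean_reads for s, t in clean.items()},
        }

        t0 = stage("index")
        genome = read_fasta(config.genome_fasta)
        ann = GeneAnnotation.from_gff3(config.annotation_gff3)
        lengths = chrom_lengths(genome)
        index = TagIndex(genome)
        extended = extend_gene_bounds(ann, lengths, extension=config.extension)
        tx_tags = build_transcript_tag_set(ann, genome)
        manifest["stages"]["index"] = {
            "seconds": round(time.time() - t0, 2),
            "genes": len(ann), "transcript_tags": len(tx_tags),
        }

        t0 = stage("assign")
        assignments = {
            s: assign_tags(t, index, ann, extended, tx_tags) for s, t in clean.items()
        }
        summary = pd.DataFrame({s: a.summary() for s, a in assignments.items()}).T
        summary.rename_axis("library").to_csv(
            os.path.join(config.outdir, "assignment_summary.tsv"), sep="\t"
        )
        manifest["stages"]["assign"] = {
            "seconds": round(time.time() - t0, 2),
            "tallies": {s: a.summary() for s, a in assignments.items()},
        }

        t0 = stage("quantify")
        gene_ids = [g.id for g in ann]
        counts = quantify_genes(assignments, gene_ids)
        counts.rename_axis("gene").to_csv(os.path.join(config.outdir, "counts.tsv"), sep="\t")
        denominators = pd.Series({s: t.total_clean_reads for s, t in clean.items()})
        tptm = tptm_normalize(counts, denominators)
        tptm.rename_axis("gene").to_csv(os.path.join(config.outdir, "tptm.tsv"), sep="\t")
        manifest["stages"]["quantify"] = {"seconds": round(time.time() - t0, 2)}

        design = pd.Series(config.design)
        results: dict[str, pd.DataFrame] = {}
        t0 = stage("de")
        for name, contrast in config.contrasts.items():
            res = de_contrast(counts, design, tuple(contrast),
                              settings=config.settings, phi=config.dispersion)
            res.rename_axis("gene").to_csv(
                os.path.join(config.outdir, f"de_{name}.tsv"), sep="\t"
            )
            results[name] = res
        manifest["stages"]["de"] = {
            "seconds": round(time.time() - t0, 2),
            "de_calls": {n: int((r["call"] != "ns").sum()) for n, r in results.items()},
        }

        t0 = stage("preferential")
        for name, contrast in config.contrasts.items():
            pref = call_preferential(counts, denominators, design, tuple(contrast),
                                     threshold=config.preferential_threshold)
            rows = [
                {"gene": g, "preferential_in": grp} for grp, gs in pref.items() for g in gs
            ]
            pd.DataFrame(rows, columns=["gene", "preferential_in"]).to_csv(
                os.path.join(config.outdir, f"preferential_{name}.tsv"), sep="\t", index=False
            )
        manifest["stages"]["preferential"] = {"seconds": round(time.time() - t0, 2)}

        for name_a, name_b in config.venn_pairs:
            venn = venn_partition(results[name_a], results[name_b])
            rows = [
                {"direction": d, f"{name_a}_only": v[0], "shared": v[1], f"{name_b}_only": v[2]}
                for d, v in venn.items()
            ]
            pd.DataFrame(rows).to_csv(
                os.path.join(config.outdir, f"venn_{name_a}_vs_{name_b}.tsv"),
                sep="\t", index=False,
            )

        if config.ln_specific is not None:
            n_ln, n_lp, n_lk = config.ln_specific
            genes = ln_specific_genes(results[n_ln], results[n_lp], results[n_lk],
                                      settings=config.settings)
            pd.DataFrame({"gene": genes}).to_csv(
                os.path.join(config.outdir, "ln_specific.tsv"), sep="\t", index=False
            )
            manifest["stages"]["ln_specific"] = {"genes": len(genes)}

        if config.terms_tsv and config.enrich_contrast:
            terms, labels = read_term_annotation(config.terms_tsv)
            res = results[config.enrich_contrast]
            study = list(res.index[res["call"] != "ns"])
            if study:
                enr = fisher_enrichment(study, list(res.index), terms, labels)
                enr.to_csv(os.path.join(config.outdir, "enrichment.tsv"), sep="\t")
                manifest["stages"]["enrichment"] = {"terms_tested": len(enr)}
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {current['stage']!r}: {exc}") from exc

    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {"manifest": manifest, "counts": counts, "tptm": tptm, "de": results}
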