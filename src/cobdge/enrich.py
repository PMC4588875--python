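"""Classic Fisher / hypergeometric term over-representation.

Tests each term's annotated genes for over-representation in a study set
against a population (gene universe), with one-sided upper-tail p-values and
Benjamini-Hochberg correction across the tested terms. Annotations must be
pre-propagated along the ontology graph; no graph traversal is done here.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

from .de import bh_adjust


def read_term_annotation(path: str) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read a term<TAB>gene[<TAB>label] file into term -> genes and labels."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str).fillna("")
    terms: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    for row in df.itertuples(index=False):
        term, gene = row[0], row[1]
        terms.setdefault(term, set()).add(gene)
        if len(row) > 2 and row[2]:
            labels[term] = row[2]
    return terms, labels


def fisher_enrichment(
    study: Iterable[str],
    population: Iterable[str],
    terms: Mapping[str, set[str]],
    labels: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of ``study`` within ``population``.

    For a term with K annotated genes in the population of size N and k hits
    in the study of size n, p = P[X >= k] for X ~ Hypergeom(N, K, n). Terms
    with no annotated population gene are skipped. Returns a frame sorted by
    p with columns k, n, K, N, fold_enrichment, p, fdr.
    """
    study_set = set(study)
    pop_set = set(population)
    stray = sorted(study_set - pop_set)
    if stray:
        raise ValueError(f"study genes missing from population: {stray}")
    n = len(study_set)
    big_n = len(pop_set)
    rows = []
    for term in sorted(terms):
        annotated = terms[term] & pop_set
        big_k = len(annotated)
        if big_k == 0:
            continue
        k = len(annotated & study_set)
        p = float(hypergeom.sf(k - 1, big_n, big_k, n))
        fold = (k / n) / (big_k / big_n) if n > 0 else float("nan")
        rows.append(
            {
                "term": term,
                "label": (labels or {}).get(term, ""),
                "k": k,
                "n": n,
                "K": big_k,
                "N": big_n,
                "fold_enrichment": fold,
                "p": min(p, 1.0),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["term", "label", "k", "n", "K", "N", "fold_enrichment", "p", "fdr"]
        ).set_index("term")
    df = pd.DataFrame(rows).set_index("term")
    df["fdr"] = bh_adjust(df["p"])
    return df.sort_values("p")
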