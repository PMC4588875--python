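"""Differential expression for tag count matrices.

Between-library normalization uses the trimmed mean of M-values (TMM); a
single common negative-binomial dispersion phi (Var = mu + phi mu^2) is
estimated by conditional maximum likelihood on library-size-equalized
pseudo-counts; two-group testing is the conditional NB exact test, with
Benjamini-Hochberg control across genes. A gene is called differentially
expressed when FDR < 0.05 and the (pseudo-count-shrunk) fold change is at
least 2-fold.

The conditional distribution used by the exact test: for n_A and n_B
libraries of equal effective size with common per-library mean and dispersion
phi, the group-A sum X given the two-group total s follows a beta-binomial
with parameters alpha = n_A/phi, beta = n_B/phi (binomial
p = n_A/(n_A+n_B) in the Poisson limit phi -> 0). The two-sided p-value sums
the probabilities of all splits no more probable than the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

_REL_TIE_TOL = 1e-7  # splits with probability <= (1 + tol) * p_obs are counted


@dataclass
class DESettings:
    fdr_threshold: float = 0.05
    min_fold: float = 2.0
    ln_specific_p: float = 0.01
    trim_m: float = 0.30
    trim_a: float = 0.05
    prior_cpm: float = 0.5  # pseudo-fraction on the counts-per-million scale
    double_two_sided: bool = False  # doubled smaller tail instead of minlike

    def __post_init__(self) -> None:
        for name in ("fdr_threshold", "ln_specific_p"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.min_fold < 1.0:
            raise ValueError("min_fold must be >= 1")


@dataclass
class DispersionEstimate:
    phi: float
    method: str = "qCML-common"


# ---------------------------------------------------------------- TMM


def _upper_quartile(col: np.ndarray, lib_size: float) -> float:
    return float(np.quantile(col / lib_size, 0.75))


def tmm_factors(
    counts: pd.DataFrame,
    lib_sizes: pd.Series | None = None,
    ref_library: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    M (log-ratio) and A (log-abundance) values are computed on library-size
    scaled counts against a reference library; genes with a zero in either
    library are excluded; genes in the upper/lower ``trim_m`` tails of M and
    ``trim_a`` tails of A are trimmed; the factor is 2 to the
    inverse-variance-weighted mean of the remaining M values. The reference
    defaults to the library whose upper quartile of scaled counts is closest
    to the mean upper quartile.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two libraries")
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    lib_sizes = lib_sizes.reindex(counts.columns).astype(float)
    if (lib_sizes <= 0).any():
        bad = list(lib_sizes.index[lib_sizes <= 0])
        raise ValueError(f"libraries with non-positive total: {bad}")

    if ref_library is None:
        uq = {c: _upper_quartile(counts[c].to_numpy(float), lib_sizes[c]) for c in counts.columns}
        mean_uq = float(np.mean(list(uq.values())))
        ref_library = min(uq, key=lambda c: (abs(uq[c] - mean_uq), c))

    ref = counts[ref_library].to_numpy(float)
    n_ref = float(lib_sizes[ref_library])
    factors = {}
    for col in counts.columns:
        obs = counts[col].to_numpy(float)
        n_obs = float(lib_sizes[col])
        if col == ref_library:
            factors[col] = 1.0
            continue
        keep = (obs > 0) & (ref > 0)
        o, r = obs[keep], ref[keep]
        m = np.log2((o / n_obs) / (r / n_ref))
        a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
        w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
        n = m.size
        if n == 0:
            factors[col] = 1.0
            continue
        # double trimming by rank, matching the classic definition
        lo_m = np.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rank_m = pd.Series(m).rank(method="average").to_numpy()
        rank_a = pd.Series(a).rank(method="average").to_numpy()
        sel = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not sel.any() or not np.isfinite(w[sel]).all() or (w[sel] == 0).any():
            factors[col] = 1.0
            continue
        f = np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel])
        factors[col] = float(2.0**f) if np.isfinite(f) else 1.0
    fac = pd.Series(factors).reindex(counts.columns)
    fac /= np.exp(np.log(fac).mean())  # geometric mean 1
    return fac


def effective_lib_sizes(
    counts: pd.DataFrame, factors: pd.Series, lib_sizes: pd.Series | None = None
) -> pd.Series:
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    return lib_sizes.reindex(counts.columns).astype(float) * factors.reindex(counts.columns)


def _pseudo_counts(counts: pd.DataFrame, eff_sizes: pd.Series) -> tuple[pd.DataFrame, float]:
    """Scale every library to the geometric-mean effective size."""
    common = float(np.exp(np.log(eff_sizes).mean()))
    pseudo = counts * (common / eff_sizes)
    return pseudo, common


# ------------------------------------------------- common dispersion (qCML)


def _group_cond_loglik(y: np.ndarray, phi: float) -> float:
    """Summed conditional log-likelihood of replicate pseudo-counts ``y``
    (genes x replicates, equal effective sizes) given their row totals,
    keeping only phi-dependent terms."""
    n = y.shape[1]
    z = y.sum(axis=1)
    if phi <= 0:
        return float(np.sum(-z * np.log(n)))
    r = 1.0 / phi
    ll = (
        gammaln(y + r).sum(axis=1)
        - n * gammaln(r)
        + gammaln(n * r)
        - gammaln(z + n * r)
    )
    return float(ll.sum())


def estimate_common_dispersion(
    counts: pd.DataFrame,
    design: pd.Series,
    factors: pd.Series | None = None,
    lib_sizes: pd.Series | None = None,
    phi_max: float = 5.0,
) -> DispersionEstimate:
    """Common NB dispersion by conditional maximum likelihood.

    Libraries are equalized to a common effective size; within every group
    with >= 2 replicates the likelihood of the counts conditional on the
    per-gene group total is summed over genes and groups and maximized over
    phi in [0, phi_max] (coarse grid, then bounded refinement).
    """
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    if factors is None:
        factors = tmm_factors(counts, lib_sizes=lib_sizes)
    eff = effective_lib_sizes(counts, factors, lib_sizes)
    pseudo, _ = _pseudo_counts(counts, eff)

    groups = []
    for group in pd.unique(design.reindex(counts.columns)):
        libs = [c for c in counts.columns if design.get(c) == group]
        if len(libs) >= 2:
            groups.append(pseudo[libs].to_numpy(float))
    if not groups:
        raise ValueError(
            "no group has >= 2 replicates; supply a dispersion value explicitly"
        )

    def neg_ll(phi: float) -> float:
        return -sum(_group_cond_loglik(y, phi) for y in groups)

    grid = np.concatenate([[0.0], np.geomspace(1e-4, phi_max, 40)])
    vals = np.array([neg_ll(p) for p in grid])
    k = int(np.argmin(vals))
    if k == 0:
        lo, hi = 0.0, grid[1]
    elif k == len(grid) - 1:
        lo, hi = grid[k - 1], phi_max
    else:
        lo, hi = grid[k - 1], grid[k + 1]
    res = minimize_scalar(neg_ll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-6})
    phi = float(res.x) if res.fun <= vals[k] else float(grid[k])
    if phi < 1e-5:
        phi = 0.0
    return DispersionEstimate(phi=phi)


# ---------------------------------------------------------- exact test


def _cond_logpmf(s: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """log P(X = x | X + Y = s) for x = 0..s under the null."""
    x = np.arange(s + 1, dtype=float)
    if phi <= 0:
        p = n_a / (n_a + n_b)
        lp = (
            gammaln(s + 1) - gammaln(x + 1) - gammaln(s - x + 1)
            + x * np.log(p) + (s - x) * np.log1p(-p)
        )
        return lp
    alpha = n_a / phi
    beta = n_b / phi
    lp = (
        gammaln(x + alpha) - gammaln(x + 1)
        + gammaln(s - x + beta) - gammaln(s - x + 1)
    )
    return lp - logsumexp(lp)


def exact_nb_pvalue(
    sum_a: int, sum_b: int, n_a: int, n_b: int, phi: float,
    double_two_sided: bool = False,
) -> float:
    """Two-sided conditional exact p-value for one gene.

    ``sum_a``/``sum_b`` are the group sums of equalized pseudo-counts. The
    default two-sided rule sums all splits with probability at most that of
    the observed split; ``double_two_sided`` doubles the smaller tail instead.
    """
    if sum_a < 0 or sum_b < 0:
        raise ValueError("negative counts")
    s = int(sum_a) + int(sum_b)
    if s == 0:
        return 1.0
    lp = _cond_logpmf(s, n_a, n_b, phi)
    obs = lp[int(sum_a)]
    if double_two_sided:
        lower = logsumexp(lp[: int(sum_a) + 1])
        upper = logsumexp(lp[int(sum_a) :])
        p = 2.0 * min(np.exp(lower), np.exp(upper))
    else:
        keep = lp <= obs + np.log1p(_REL_TIE_TOL)
        p = float(np.exp(logsumexp(lp[keep])))
    return min(p, 1.0)


def nb_exact_test(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    eff_sizes: pd.Series,
    phi: float,
    double_two_sided: bool = False,
) -> pd.Series:
    """Per-gene conditional NB exact p-values for two groups of libraries.

    All libraries are scaled to the geometric-mean effective size, the
    per-group pseudo-count sums are rounded, and the beta-binomial (or
    binomial, phi = 0) conditional distribution of the group-A sum given the
    total is enumerated.
    """
    if (counts_a.to_numpy() < 0).any() or (counts_b.to_numpy() < 0).any():
        raise ValueError("negative counts")
    if phi < 0:
        raise ValueError("phi must be >= 0")
    all_counts = pd.concat([counts_a, counts_b], axis=1)
    pseudo, _ = _pseudo_counts(all_counts, eff_sizes.reindex(all_counts.columns))
    a = pseudo[counts_a.columns].sum(axis=1).round().astype(int)
    b = pseudo[counts_b.columns].sum(axis=1).round().astype(int)
    n_a, n_b = counts_a.shape[1], counts_b.shape[1]
    pvals = {}
    for gene in all_counts.index:
        pvals[gene] = exact_nb_pvalue(
            int(a[gene]), int(b[gene]), n_a, n_b, phi,
            double_two_sided=double_two_sided,
        )
    return pd.Series(pvals, name="p")


def bh_adjust(pvalues: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up FDR values."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return pvalues
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    adj = multipletests(arr, method="fdr_bh")[1]
    if isinstance(pvalues, pd.Series):
        return pd.Series(adj, index=pvalues.index, name="fdr")
    return adj


# ---------------------------------------------------------- calling


def de_contrast(
    counts: pd.DataFrame,
    design: pd.Series,
    contrast: tuple[str, str],
    settings: DESettings | None = None,
    phi: float | None = None,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Full two-group analysis for contrast (A, B); log2 fold change is B vs A.

    Returns a gene-indexed frame with cpm_<A>, cpm_<B>, log2_fc, p, fdr, call.
    """
    settings = settings or DESettings()
    ga, gb = contrast
    libs_a = [c for c in counts.columns if design.get(c) == ga]
    libs_b = [c for c in counts.columns if design.get(c) == gb]
    if not libs_a or not libs_b:
        raise ValueError(f"contrast groups {contrast} not both present in design")
    sub = counts[libs_a + libs_b]
    lib_sizes = sub.sum(axis=0)
    if factors is None:
        factors = tmm_factors(sub, lib_sizes=lib_sizes,
                              trim_m=settings.trim_m, trim_a=settings.trim_a)
    else:
        factors = factors.reindex(sub.columns)
    eff = effective_lib_sizes(sub, factors, lib_sizes)
    if phi is None:
        phi = estimate_common_dispersion(sub, design, factors=factors,
                                         lib_sizes=lib_sizes).phi

    pseudo, common = _pseudo_counts(sub, eff)
    cpm_a = pseudo[libs_a].mean(axis=1) / common * 1e6
    cpm_b = pseudo[libs_b].mean(axis=1) / common * 1e6
    log2_fc = np.log2((cpm_b + settings.prior_cpm) / (cpm_a + settings.prior_cpm))

    p = nb_exact_test(sub[libs_a], sub[libs_b], eff, phi,
                      double_two_sided=settings.double_two_sided)
    fdr = bh_adjust(p)
    res = pd.DataFrame(
        {
            f"cpm_{ga}": cpm_a,
            f"cpm_{gb}": cpm_b,
            "log2_fc": log2_fc,
            "p": p,
            "fdr": fdr,
        }
    )
    res["phi"] = phi
    return call_de(res, settings)


def call_de(results: pd.DataFrame, settings: DESettings | None = None) -> pd.DataFrame:
    """Attach the up/down/ns call: FDR below threshold AND at least
    ``min_fold`` change (|log2 FC| >= log2(min_fold))."""
    settings = settings or DESettings()
    lfc_gate = np.log2(settings.min_fold)
    sig = results["fdr"] < settings.fdr_threshold
    call = np.where(
        sig & (results["log2_fc"] >= lfc_gate), "up",
        np.where(sig & (results["log2_fc"] <= -lfc_gate), "down", "ns"),
    )
    out = results.copy()
    out["call"] = call
    return out


def ln_specific_genes(
    de_ln: pd.DataFrame,
    de_lp: pd.DataFrame,
    de_lk: pd.DataFrame,
    settings: DESettings | None = None,
) -> list[str]:
    """Genes responding specifically to low nitrogen.

    A gene qualifies when its low-N contrast has p below ``ln_specific_p``
    and, in each of the low-P and low-K contrasts, it is either not
    significant at that p or changes in the opposite direction.
    """
    settings = settings or DESettings()
    if not (de_ln.index.equals(de_lp.index) and de_ln.index.equals(de_lk.index)):
        raise ValueError("the three contrast tables must share one gene universe")
    alpha = settings.ln_specific_p
    out = []
    for gene in de_ln.index:
        if de_ln.loc[gene, "p"] >= alpha:
            continue
        sign_ln = np.sign(de_ln.loc[gene, "log2_fc"])
        ok = True
        for other in (de_lp, de_lk):
            if other.loc[gene, "p"] < alpha and np.sign(other.loc[gene, "log2_fc"]) == sign_ln:
                ok = False
                break
        if ok:
            out.append(gene)
    return out


def venn_partition(
    de_a: pd.DataFrame | list[tuple[str, str]],
    de_b: pd.DataFrame | list[tuple[str, str]],
) -> dict[str, tuple[int, int, int]]:
    """(A-only, shared, B-only) gene counts per direction for two DE tables."""

    def _sets(de) -> dict[str, set[str]]:
        if isinstance(de, pd.DataFrame):
            return {
                d: set(de.index[de["call"] == d]) for d in ("up", "down")
            }
        out: dict[str, set[str]] = {"up": set(), "down": set()}
        for gene, direction in de:
            out[direction].add(gene)
        return out

    sa, sb = _sets(de_a), _sets(de_b)
    return {
        d: (len(sa[d] - sb[d]), len(sa[d] & sb[d]), len(sb[d] - sa[d]))
        for d in ("up", "down")
    }
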