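"""TMM factors, common dispersion, conditional exact test, BH, calls."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import betabinom, binom

from cobdge.de import (
    DESettings,
    bh_adjust,
    call_de,
    de_contrast,
    estimate_common_dispersion,
    exact_nb_pvalue,
    ln_specific_genes,
    nb_exact_test,
    tmm_factors,
    venn_partition,
)


def _nb(rng, mu, phi, shape=None):
    if phi == 0:
        return rng.poisson(mu, shape)
    lam = rng.gamma(1.0 / phi, np.asarray(mu) * phi, shape)
    return rng.poisson(lam)


# ------------------------------------------------------------------ TMM


def test_tmm_identical_and_scaled_libraries():
    rng = np.random.default_rng(0)
    base = rng.poisson(50, 400).astype(float) + 1
    counts = pd.DataFrame({"L1": base, "L2": base})
    assert np.allclose(tmm_factors(counts), 1.0)
    counts2 = pd.DataFrame({"L1": base, "L2": base * 2})
    assert np.allclose(tmm_factors(counts2), 1.0)  # library size absorbs doubling


def _tmm_oracle(counts, ref_col, obs_col, trim_m=0.30, trim_a=0.05):
    """Straight-line transcription of the trimmed-mean-of-M-values formula."""
    obs = counts[obs_col].to_numpy(float)
    ref = counts[ref_col].to_numpy(float)
    n_obs, n_ref = obs.sum(), ref.sum()
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep] / n_obs, ref[keep] / n_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    w = (n_obs - obs[keep]) / (n_obs * obs[keep]) + (n_ref - ref[keep]) / (n_ref * ref[keep])
    n = len(m)
    lo_m, lo_a = np.floor(n * trim_m) + 1, np.floor(n * trim_a) + 1
    rm = pd.Series(m).rank().to_numpy()
    ra = pd.Series(a).rank().to_numpy()
    sel = (rm >= lo_m) & (rm <= n + 1 - lo_m) & (ra >= lo_a) & (ra <= n + 1 - lo_a)
    return 2 ** (np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel]))


def test_tmm_composition_shift_matches_direct_formula():
    rng = np.random.default_rng(3)
    base = rng.poisson(100, 500).astype(float) + 1
    shifted = base.copy()
    shifted[0] += 60_000  # one dominant gene in library B
    counts = pd.DataFrame({"A": base, "B": shifted})
    f = tmm_factors(counts, ref_library="A")
    raw_b = _tmm_oracle(counts, "A", "B")
    expected = pd.Series({"A": 1.0, "B": raw_b})
    expected /= np.exp(np.log(expected).mean())
    assert f["B"] < f["A"]
    assert np.allclose(f, expected.reindex(f.index), rtol=1e-12)


def test_tmm_matches_edger_reference():
    """Independent cross-check of the normalization against the Bioconductor
    implementation on a composition-shift fixture."""
    rng = np.random.default_rng(42)
    mu = np.exp(rng.normal(4, 1, 200))
    counts = pd.DataFrame({f"s{i}": rng.poisson(mu * (1 + (i >= 3))) for i in range(6)})
    counts.iloc[0, 3:] += 20_000
    csv = "/tmp/_tmm_check.csv"
    counts.to_csv(csv)
    script = (
        "suppressMessages(library(edgeR));"
        f"x <- read.csv('{csv}', row.names=1);"
        "f <- calcNormFactors(DGEList(counts=x), method='TMM')$samples$norm.factors;"
        "cat(sprintf('%.8f', f), sep='\\n')"
    )
    out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True,
                         check=True)
    ref = np.array([float(v) for v in out.stdout.split()])
    mine = tmm_factors(counts).to_numpy()
    assert np.allclose(mine, ref, atol=2e-4)


def test_tmm_rejects_single_or_empty_library():
    with pytest.raises(ValueError):
        tmm_factors(pd.DataFrame({"L1": [1.0, 2.0]}))
    counts = pd.DataFrame({"L1": [1.0, 2.0], "L2": [0.0, 0.0]})
    with pytest.raises(ValueError, match="L2"):
        tmm_factors(counts)


# ------------------------------------------------------- dispersion


def test_dispersion_poisson_data_estimates_near_zero():
    rng = np.random.default_rng(0)
    mu = np.exp(rng.normal(4, 1, 2000))
    counts = pd.DataFrame({f"s{i}": rng.poisson(mu) for i in range(6)})
    design = pd.Series({f"s{i}": "A" if i < 3 else "B" for i in range(6)})
    est = estimate_common_dispersion(counts, design)
    assert est.phi <= 0.02


def test_dispersion_single_gene_identical_replicates_is_zero():
    counts = pd.DataFrame({"s1": [40], "s2": [40], "s3": [40]})
    design = pd.Series({"s1": "A", "s2": "A", "s3": "A"})
    assert estimate_common_dispersion(counts, design).phi == 0.0


def test_dispersion_requires_replicates():
    counts = pd.DataFrame({"s1": [10], "s2": [12]})
    design = pd.Series({"s1": "A", "s2": "B"})
    with pytest.raises(ValueError, match="dispersion"):
        estimate_common_dispersion(counts, design)


def test_dispersion_recovery_small():
    rng = np.random.default_rng(7)
    mu = np.exp(rng.normal(4.5, 1, 1500))
    counts = pd.DataFrame({f"s{i}": _nb(rng, mu, 0.2) for i in range(6)})
    design = pd.Series({f"s{i}": "A" if i < 3 else "B" for i in range(6)})
    est = estimate_common_dispersion(counts, design)
    assert 0.14 <= est.phi <= 0.26


# ------------------------------------------------------- exact test


def test_exact_symmetric_mode_is_one():
    assert exact_nb_pvalue(5, 5, 1, 1, 0.0) == 1.0


def test_exact_extreme_split_closed_form():
    # split (0, 10), 1 library per group, phi = 0: binomial enumeration gives
    # 2 * (1/2)^10 for the two extreme outcomes = 2^-9
    assert abs(exact_nb_pvalue(0, 10, 1, 1, 0.0) - 2.0 ** -9) < 1e-15


def test_exact_label_swap_symmetry():
    for phi in (0.0, 0.2):
        p1 = exact_nb_pvalue(3, 17, 3, 3, phi)
        p2 = exact_nb_pvalue(17, 3, 3, 3, phi)
        assert abs(p1 - p2) < 1e-12


def test_exact_zero_total_is_one():
    assert exact_nb_pvalue(0, 0, 3, 3, 0.5) == 1.0


def test_exact_rejects_negative_and_bad_phi():
    with pytest.raises(ValueError):
        exact_nb_pvalue(-1, 3, 2, 2, 0.1)
    counts = pd.DataFrame({"a": [1], "b": [2]})
    with pytest.raises(ValueError):
        nb_exact_test(counts[["a"]], counts[["b"]],
                      pd.Series({"a": 10.0, "b": 10.0}), -0.1)


@pytest.mark.parametrize("phi", [0.0, 0.3])
@pytest.mark.parametrize("n_a,n_b", [(3, 3), (2, 4)])
def test_exact_matches_conditional_enumeration(phi, n_a, n_b):
    """The implementation must reproduce direct enumeration of the
    conditional split distribution (binomial / beta-binomial)."""
    for s in (1, 2, 7, 30, 61):
        if phi == 0:
            pmf = binom.pmf(np.arange(s + 1), s, n_a / (n_a + n_b))
        else:
            pmf = betabinom.pmf(np.arange(s + 1), s, n_a / phi, n_b / phi)
        for a in range(s + 1):
            want = pmf[pmf <= pmf[a] * (1 + 1e-7)].sum()
            got = exact_nb_pvalue(a, s - a, n_a, n_b, phi)
            assert abs(got - min(want, 1.0)) < 1e-10


def test_scaling_counts_preserves_normalization_and_never_uncalls():
    """Multiplying all counts (hence library sizes) by 10 leaves TMM factors
    and fold changes unchanged; the exact test only gains evidence, so every
    gene called at 1x stays called with the same direction at 10x."""
    rng = np.random.default_rng(1)
    mu = np.exp(rng.normal(4, 1, 300))
    counts = pd.DataFrame({f"s{i}": rng.poisson(mu) for i in range(6)})
    counts.iloc[:15, 3:] *= 8
    design = pd.Series({f"s{i}": "A" if i < 3 else "B" for i in range(6)})
    assert np.allclose(tmm_factors(counts), tmm_factors(counts * 10))
    r1 = de_contrast(counts, design, ("A", "B"), phi=0.05)
    r2 = de_contrast(counts * 10, design, ("A", "B"), phi=0.05)
    assert np.allclose(r1["log2_fc"], r2["log2_fc"], atol=5e-3)
    called = r1.index[r1["call"] != "ns"]
    assert (r1.loc[called, "call"] == r2.loc[called, "call"]).all()


# ------------------------------------------------------- BH and calls


def test_bh_closed_forms():
    assert np.allclose(bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03])
    assert np.allclose(bh_adjust(np.array([0.2])), [0.2])
    assert np.allclose(bh_adjust(np.array([1.0, 1.0, 1.0])), 1.0)


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
def test_bh_is_permutation_equivariant_and_bounded(pvals):
    p = np.array(pvals)
    adj = bh_adjust(p)
    assert ((adj >= p - 1e-12) & (adj <= 1.0 + 1e-12)).all()
    perm = np.random.default_rng(0).permutation(len(p))
    assert np.allclose(bh_adjust(p[perm]), adj[perm])


@pytest.mark.parametrize(
    "fdr,lfc,expected",
    [(0.01, 2.0, "up"), (0.01, 0.5, "ns"), (0.06, 3.0, "ns"),
     (0.01, -1.0, "down"), (0.04, 1.0, "up")],
)
def test_call_de_thresholds(fdr, lfc, expected):
    df = pd.DataFrame({"log2_fc": [lfc], "fdr": [fdr], "p": [fdr]}, index=["g"])
    assert call_de(df)["call"].iloc[0] == expected


def _de_frame(rows):
    return pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))],
                        columns=["p", "log2_fc"])


@pytest.mark.parametrize(
    "ln,lp,lk,included",
    [
        ((0.005, 1.0), (0.5, 0.2), (0.8, 0.1), True),  # no response under LP/LK
        ((0.005, 1.0), (0.001, 1.0), (0.8, 0.1), False),  # same-direction LP response
        ((0.005, 1.0), (0.001, -1.0), (0.2, 0.3), True),  # opposite LP response
        ((0.05, 1.0), (0.5, 0.2), (0.8, 0.1), False),  # not significant under LN
    ],
)
def test_ln_specific_rule(ln, lp, lk, included):
    genes = ln_specific_genes(_de_frame([ln]), _de_frame([lp]), _de_frame([lk]))
    assert (genes == ["g0"]) is included


def test_ln_specific_requires_shared_universe():
    a = _de_frame([(0.005, 1.0)])
    b = _de_frame([(0.5, 0.2), (0.5, 0.2)])
    with pytest.raises(ValueError):
        ln_specific_genes(a, b, a)


def test_venn_partition():
    a = [("a", "up"), ("b", "up"), ("c", "up"), ("x", "down")]
    b = [("b", "up"), ("c", "up"), ("d", "up")]
    v = venn_partition(a, b)
    assert v["up"] == (1, 2, 1)
    assert v["down"] == (1, 0, 0)
    assert venn_partition(a, a)["up"] == (0, 3, 0)
    assert venn_partition(a, [])["up"] == (3, 0, 0)


def test_settings_validation():
    with pytest.raises(ValueError):
        DESettings(fdr_threshold=0.0)
    with pytest.raises(ValueError):
        DESettings(min_fold=0.5)
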