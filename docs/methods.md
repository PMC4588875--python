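# Methods

## Tag model

An NlaIII DGE library represents each transcript by the 21-nt tag anchored at
a CATG site: the enzyme recognizes CATG, and the downstream tagging enzyme
cuts 17 bp 3′ of it, so the informative sequence is CATG + 17 bp. Sequencers
read only the 17 bp (plus the 3′ adapter); the anchor is restored
electronically during extraction. The canonical tag of a transcript is taken
at its **3′-most** CATG site — the standard outcome of the DGE chemistry,
where the most 3′-distal anchoring site survives the bead capture. The
simulator enforces this by construction; alternative upstream sites exist in
transcripts but carry no reads by default.

## Clean-tag rules

A read yields a clean tag when (i) the 3′ adapter is found (exact match of
its leading 7-mer) leaving exactly 17 nt, or no adapter is found and the
first 17 nt are taken (fallback mode, on by default); (ii) the fragment
contains no `N`; and (iii) the assembled 21-nt tag is seen at least twice in
the library. The minimum-count filter is applied per library, after
clustering reads into unique tags and before any mapping; a pooled variant
exists behind a flag but is not the default. No quality-based filtering is
performed; simulated qualities are a constant `I`.

## Placement and assignment

Tags are placed on both strands of the genome allowing at most one
substitution. The index stores every 21-mer window twice, keyed by its first
10 nt and last 11 nt: one substitution leaves at least one half exact, so the
union of the two half lookups followed by a Hamming verification is complete.
Correctness is asserted against a brute-force scan (set equality over random
genomes with planted 0/1/2-mismatch queries). Exact hits are not preferred
over one-mismatch hits; only the bound is enforced.

Tags with **zero** genomic placements are looked up among the CATG-anchored
21-mers of spliced transcripts (exons concatenated, minus-strand
reverse-complemented). This recovers tags that straddle exon–exon junctions
of mature mRNA, which the contiguous genomic matcher cannot see. The lookup
is exact-match; at the error rates considered, a junction tag with a
sequencing error is simply left unmapped.

Gene intervals are extended by 300 nt on each side (clamped to the
chromosome) before assignment, compensating for missing UTR annotation; a
placement counts toward a gene only when the full 21-mer lies inside the
extended interval **on the gene's strand** (tags are sense-strand sequences).
Distinct genes are counted, not placements: a tag with two placements inside
one gene contributes once. Tags hitting 1–3 genes are assigned fractionally
(1/k each); more than three genes ⇒ removed; zero ⇒ unmapped. The identity
`clean = assigned + dropped + unmapped` holds exactly per library and is
checked in the tests and in the run manifest.

## Expression units

TPTM = count / denominator × 10⁷. The denominator is the library's total
clean-read count (the unit is "per ten million *reads*"); using
total-assigned tags instead is available behind a flag for sensitivity
analysis. Preferential expression ("present here, absent there") requires
pooled group TPTM ≥ 10 in one group and exactly 0 in the other; "sample" is
interpreted as the pooled replicate group, with a stricter
every-replicate-zero mode behind a flag.

## Differential expression

**Normalization.** TMM factors with 30 % trimming on M-values and 5 % on
A-values, inverse-asymptotic-variance weights, reference library chosen by
closest upper quartile to the mean; factors are rescaled to geometric mean 1.
The implementation was cross-checked against the Bioconductor reference on a
composition-shift fixture (agreement ≈ 1e-5).

**Dispersion.** One common NB dispersion φ (Var = μ + φμ²) shared by all
genes, estimated by conditional maximum likelihood: libraries are scaled to
the geometric-mean effective size (linear pseudo-count scaling rather than
quantile equalization — an intentional simplification), and within each group
with ≥ 2 replicates the likelihood of the counts conditional on the per-gene
total (which removes the unknown gene means) is summed over genes and
maximized on φ ∈ [0, 5] by a coarse geometric grid plus bounded refinement.
φ = 0 (Poisson) is an admissible boundary estimate. Tag-wise or trended
dispersion is out of scope. Parameter recovery: φ̂ ≈ 0.200 at φ_true = 0.2
with 2000 genes, 3 + 3 libraries at 2 × 10⁵ reads.

**Exact test.** For groups of n_A and n_B libraries at equal effective size
with common mean and dispersion, the group-A sum conditional on the two-group
total s is beta-binomial(s, α = n_A/φ, β = n_B/φ) — independent of the mean —
and binomial(s, n_A/(n_A+n_B)) in the Poisson limit. The two-sided p-value is
the "minimum-likelihood" sum: all splits whose probability is at most that of
the observed split (with a 1 + 1e-7 relative tie tolerance, the convention of
exact tests); a doubled-smaller-tail variant is available behind a flag.
Group sums of pseudo-counts are rounded to integers before enumeration. The
implementation matches independent enumeration via the analytic beta-binomial
pmf to < 1e-10 for all totals ≤ 200.

**Calling.** BH step-up FDR across genes; called up/down when FDR < 0.05 and
|log₂FC| ≥ 1. Fold changes are computed on pseudo-count group means per
million with a 0.5 pseudo-fraction added to both groups, so zero counts give
finite, shrunk fold changes; the 2-fold gate applies to this shrunk value for
stability at low counts. The low-nitrogen-specificity rule uses raw p-values
(threshold 0.01), not FDR, requiring opposite sign or non-significance in the
low-P and low-K contrasts.

## Enrichment

Classic one-sided hypergeometric over-representation per term, BH-corrected
across terms (the correction choice is this package's; raw p-values are also
emitted). Annotations must arrive pre-propagated; no ontology-graph
traversal or decorrelation (weight/elim) scoring is performed, so p-values
are not comparable to weighted-algorithm outputs.

## Simulator

The generator emulates the 2 tissues × 2 nitrogen levels × 3 replicates
design. Defaults: 300 genes of 300–800 nt on one chromosome with 400–700 nt
gaps (gaps exceed the 300-nt extension, so extended neighbours never overlap
a gene body), ~30 % two-exon genes, library depth 2 × 10⁵ reads (a
deliberately down-scaled stand-in for multi-million-read libraries; all
rate-like results are depth-calibrated where it matters), NB dispersion
φ = 0.1 (a field-typical value for biological replicates; no empirical value
was available to adopt), substitution error rate 10⁻³ (HiSeq-like), 35-nt
reads, Illumina-style 3′ adapter.

Baseline relative abundances are log-normal (σ = 1) normalized per group.
⌊de_fraction × n⌋ genes are differentially expressed between the designated
contrast pair, half up / half down (ties to up) at exactly the configured
fold: the planted genes' abundances are held fixed and only the free genes
are rescaled so each group still sums to 1 — so planted ratios are exact
while the free genes absorb a small common compositional factor, which TMM
removes. Group-exclusive genes (abundance 0 in one contrast group) exercise
the preferential-expression caller. Junction genes place the intron inside
the tag so the tag exists only on the spliced transcript. Counts are
gamma-Poisson (Var = μ + φμ²); reads are the 17-nt tag suffix + adapter,
padded with A to 35 nt, with uniform substitution errors that never keep the
original base. All randomness flows from one seed through per-stage
`SeedSequence` children; outputs are byte-reproducible.

What the simulator does **not** model: PCR duplicates, quality-score error
profiles, positional error bias, alternative CATG-site usage, antisense
transcription, incomplete digestion, polymorphism between sample and
reference. Passing tests therefore demonstrate the correctness of the
*pipeline logic and statistics* under idealized read generation, not
robustness to every artefact of real libraries.

## Numerical and design notes

- Coordinates are GFF3 1-based inclusive at all interfaces.
- An all-zero library is an error for TMM; a zero TPTM denominator is an
  error naming the library.
- Scaling all counts by a constant leaves TMM factors and fold changes
  unchanged; exact-test p-values legitimately shrink (more counts, more
  information), so the called set grows monotonically rather than staying
  fixed.
- With no replicated group the dispersion cannot be estimated; the estimator
  raises and a φ must be supplied.
- The exact test's minlike two-sided definition makes the symmetric mode
  (equal splits, equal designs) give p = 1 exactly.
- Problem sizes used in the validation suite (2000 genes, 3 vs 3, depth
  2 × 10⁵, 3–10 seeds per statistic) were chosen as the smallest designs at
  which the calibration and recovery statistics are stable.
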