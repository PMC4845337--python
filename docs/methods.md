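# Methods

This note documents the models, algorithms and numerical choices behind
`estssr`, and what the synthetic-data generators do and do not emulate.

## SSR detection

A microsatellite is modelled as a *maximal perfect* tandem repeat: a region
of period `m` (2 ≤ m ≤ 10) whose motif is *primitive* (not itself a whole
repetition of a shorter string) with at least `min_units` full copies
(default 5 for every motif class). Imperfect (interrupted) repeats are not
modelled; an interrupted array appears as separate runs, each judged against
`min_units` on its own.

The scanner marks, for each period `m`, every position `j` with
`s[j] == s[j+m]`; a maximal run of marks `[a, b)` corresponds to a periodic
region `[a, b+m)`. One locus is reported per run, **anchored at the run's
leftmost base**, with `repeat_count = floor((b+m−a)/m)` and
`end = start + m·repeat_count`. This anchoring convention (the one used by
the standard mining tools) resolves the ambiguity that a periodicity run
whose length is not a multiple of `m` supports several phase-shifted
"maximal" repeats; anchoring leftmost makes the reported locus unique per
`(run, m)` and is what the planted-truth generator guarantees. Primitivity
of the anchored motif prevents double counting of the same region under a
composite motif length (a `(AT)₆` array is never also reported as
`(ATAT)₃`). Motif classes are canonicalized to the lexicographically
smallest rotation of the motif or its reverse complement, so (GA)ₙ, (AG)ₙ,
(TC)ₙ and (CT)ₙ are one class.

Ambiguity characters: by default any non-ACGT base breaks repeat runs
(`n_policy="break_run"`); a stricter policy drops the whole transcript.
Coordinates are 0-based half-open throughout, so
`end − start = motif_len × repeat_count` and flank lengths are plain
differences.

Summaries count a transcript once per motif-length class it carries and
report both per-class transcript counts and per-class locus counts;
published summary tables that assign each transcript to a single class can
be reproduced through the totalizer entry point (`summarize_counts`), which
accepts per-class counts directly. SSR density is total bases divided by
locus count (kb per SSR), reported as absent (not zero) when no loci exist.

## PAL selection

A Potentially Amplifiable Locus must have strictly more than `min_flank`
(default 50) bp of flank on *each* side — the "> 50 bp" rule is read
literally as ≥ 51 — and at least `min_units_pal` (default 8) repeat units,
a deliberately stricter bar than the mining threshold so that both the
all-SSR and the PAL sections of a summary table come from one mining pass.
Redundancy removal is exact: records sharing canonical motif and both flank
sequences are collapsed, later copies being marked `redundant_of` the first.
A similarity-based (isoform-collapsing) redundancy rule would require an
alignment step and an identity threshold the workflow does not define; the
exact rule is transparent and conservative.

## Fragment-size binning

Raw capillary sizes are clustered by single linkage with a gap rule: sorted
sizes start a new bin wherever the inter-size gap exceeds `min_gap`
(default half the repeat unit), and each bin is labelled with the rounded
mean of its members. The binner is permutation-invariant, idempotent on
already-binned ladder-spaced integers, and the bin count is non-increasing
in `min_gap`. Proprietary binning tools fit per-locus offsets by least
squares; this gap rule is a transparent substitute that recovers the true
ladder exactly whenever noise never closes the inter-allele gap below
`min_gap`. Note the caveat that at very large sample sizes extreme noise
draws shrink the observed gap, so `min_gap` should stay well above the
noise scale but below the repeat unit minus it (the genotype simulator uses
`repeat_unit/4` for this reason).

## Per-locus statistics

With `n` scored individuals, allele counts `aᵢ` (Σaᵢ = 2n), genotype counts
`n_ij` and `h` heterozygotes:

* `Ho = h / n`.
* `He = (2n/(2n−1)) (1 − Σ pᵢ²)`, `pᵢ = aᵢ/2n` — the unbiased
  (small-sample-corrected) gene diversity; the plug-in form is available
  via `unbiased=False`.
* **Exact HWE test.** Conditional on the allele counts, a genotype table
  has probability `P = n! Πᵢ aᵢ! 2^h / ((2n)! Π_{i≤j} n_ij!)` (Levene's
  distribution). The p-value is the probability-test ("no more probable
  than observed") tail: Σ P over tables with `P ≤ P_obs`, ties counted
  within a relative tolerance of 10⁻¹². Method `auto` enumerates all
  tables when their number is within `enum_table_limit` (10⁶) and
  otherwise samples tables from the exact conditional null by randomly
  pairing the fixed gamete multiset, with
  `p = (1 + #{P_t ≤ P_obs}) / (reps + 1)`. Random pairing is an unbiased
  i.i.d. sampler of the same null — a deliberate simplification relative
  to Markov-chain approaches, exact at the cost of more draws. All
  probabilities are computed in log space (`lgamma`); enumerated
  probabilities sum to 1 within 10⁻⁹, which the tests assert. The test is
  undefined (reported as a dash) for monomorphic loci.
* **Null-allele frequency.** One non-amplifying allele of frequency `r`
  under HWE: visible heterozygote (i,j) probability `2pᵢpⱼ`, apparent
  homozygote (i) `pᵢ² + 2pᵢr`, blank `r²`. By default the likelihood is
  conditioned on visibility (probabilities divided by `1 − r²`), because
  in practice failed amplifications are indistinguishable from other
  missingness; optionally missing calls can be treated as null
  homozygotes. Fitted by EM — apparent homozygotes split into true vs
  null-carrying with posterior weights `pᵢ : 2r`, blanks imputed as
  `n r²/(1−r²)` under the conditional model — with the observed-data
  log-likelihood non-decreasing, convergence at Δlog L < 10⁻⁸ or 10⁴
  iterations. Because EM approaches the `r = 0` boundary only
  sublinearly, the boundary candidate (plug-in frequencies, `r = 0`) is
  evaluated explicitly and returned when it fits at least as well, so
  equilibrium data give exactly 0. The estimate matches a 10⁻³-grid
  likelihood search within 2×10⁻³ on small tables (asserted in tests).
* **Genotypic disequilibrium.** Genotype × genotype contingency table over
  individuals scored at both loci; statistic is the log-likelihood-ratio
  `G`; null distribution by permuting one locus's genotype column
  (default 10⁴ seeded permutations); `p = (1 + #{G_perm ≥ G_obs}) /
  (perms + 1)`. A permutation G-test replaces a Markov-chain Fisher exact
  test: both sample the same conditional null, and the permutation
  version is simpler to seed and audit. Under independence its rejection
  rate at α = 0.05 is calibrated (asserted to lie in [0.03, 0.07] over
  1,000 simulated pairs).
* **Bonferroni.** Threshold `α/k` over the `k` defined p-values; undefined
  entries (failed or monomorphic loci) are skipped, not counted in `k`.

Sample SDs everywhere use the n−1 denominator.

## Panel reports

Per species, each locus is P (≥ 2 alleles), M (1 allele) or F (failed / not
genotyped). Panel means and SDs of Na, Ho, He are computed **over
polymorphic loci only** — including monomorphic loci would drag the allele
number mean toward 1 and does not reproduce published panel summaries — and
the allele-number range is likewise over polymorphic loci. A marker is
transferable when its status is P or M in every non-source species. Display
rounding follows the field convention: allele numbers to 1 decimal,
heterozygosities to 2.

## Synthetic data

`simulate_transcriptome` draws log-normal transcript lengths (default
median 880 bp, σ = 0.72 — mean ≈ 1.14 kb, the study-scale average of
128 Mb over 112,477 transcripts), i.i.d. bases at fixed GC content (0.45),
and plants one SSR in a configurable fraction of transcripts (default
0.385, the published SSR-bearing proportion) with motif lengths drawn from
the published dinucleotide-dominated spectrum and repeat counts from a
geometric distribution truncated at 5 units (mean 7). Planted repeats are
flanked by guard bases chosen to differ from the motif's edge bases, so
the truth coordinates are exactly what the leftmost-anchored maximal
scanner must report. Background sequence can contain chance SSRs; truth
tables list planted loci only, so recall is measured against them while
chance loci are validated against the brute-force oracle.

`simulate_genotypes` draws, per individual and locus, two gametes from the
augmented frequency vector (visible alleles on a `base + k·unit` size
ladder, plus a null allele at frequency `r`): the second gamete copies the
first with probability `F` (inbreeding/Wahlund homozygote excess,
`P(homozygote i) = pᵢ² + F pᵢ(1−pᵢ)`), null/null pairs become missing
calls, null/visible pairs appear as visible homozygotes, Gaussian noise
(default SD 0.15 bp) perturbs each fragment size, and the gap binner maps
sizes back to integer alleles. Default sample sizes are the study's
(21/20/18 individuals across three species). This is exactly the
generative model the null-allele estimator assumes; model-mismatch
scenarios (size-dependent dropout, allele-specific amplification bias,
scoring error) are not simulated, so parameter-recovery results here bound
estimator correctness, not robustness to real-world artefacts. Likewise
the transcriptome generator has uniform base composition and no isoform
structure, so PAL redundancy behaviour on real assemblies (isoform
duplicates with slightly differing flanks) is exercised only through the
exact-duplicate rule.

All randomness flows from a single top-level seed through named substreams
(`transcriptome.*`, `genotypes.*`), so each stage regenerates independently
and byte-identically.

## Problem sizes and runtime choices

The validation battery runs at sizes chosen to give stable estimates while
remaining quick: 10,000 scanner-vs-oracle sequences (≤ 500 bp) in the test
suite and 3,000 in the acceptance script; 2,000 HWE tables at n = 21 for
type-I calibration; 1,000 locus pairs × 1,000 permutations for LD
calibration; n = 1,000 individuals for null-allele recovery (r ∈ {0, 0.1,
0.2} × 3 seeds). Monte Carlo HWE uses 50,000 draws when compared against
enumeration (3-SE agreement band). Enumeration is the default for every
table whose count fits in 10⁶; at n = 21 with up to ~5 alleles this is
always the case.

## Known limitations

* Only perfect repeats are mined; compound and interrupted SSR annotation
  is out of scope.
* The exact test implements the probability (two-sided) variant only; the
  U-score heterozygote-deficit test is not provided.
* The LD test conditions on observed genotype classes; very sparse tables
  (n ≈ 20 with many classes) make it conservative.
* Redundancy among PALs is exact-duplicate only.
* Binning assumes locus-wise unimodal clusters separated by near-ladder
  gaps; severely overlapping allele size distributions defeat any
  one-dimensional binner.
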