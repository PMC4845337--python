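"""Per-locus and pairwise population-genetic statistics for microsatellites.

Implements the standard single-population characterization toolkit:

* allele/genotype tallies per locus;
* observed heterozygosity and the small-sample-corrected (unbiased) expected
  heterozygosity ``He = 2n/(2n-1) * (1 - sum p_i^2)``;
* the exact Hardy-Weinberg probability test on Levene's conditional
  distribution of genotype tables given allele counts, with full enumeration
  for small tables and conditional Monte Carlo (random gamete pairing) for
  large ones;
* maximum-likelihood estimation of a null (non-amplifying) allele frequency
  by EM under HWE with one null allele;
* a permutation G-test of genotypic disequilibrium between locus pairs;
* sequential-free Bonferroni correction.

The exact-test p-value is the "probability test": the total conditional
probability of all genotype tables (same allele counts) no more probable
than the observed one,

    P(table) = n! * prod_i a_i! * 2^h / ((2n)! * prod_{i<=j} n_ij!),

where ``a_i`` are allele counts and ``h`` the number of heterozygotes.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "LocusGenotypeCounts",
    "LocusStats",
    "TestConfig",
    "MonomorphicLocusError",
    "AllMissingError",
    "tally",
    "observed_het",
    "expected_het",
    "hwe_exact_test",
    "null_allele_ml",
    "genotypic_ld_test",
    "bonferroni",
    "locus_stats",
]


class MonomorphicLocusError(ValueError):
    """Statistic undefined for a locus with a single allele."""


class AllMissingError(ValueError):
    """Locus has no scored genotypes."""


@dataclass(frozen=True)
class LocusGenotypeCounts:
    """Genotype and allele tallies at one locus (missing calls excluded).

    ``genotype_counts`` keys are sorted allele pairs; ``allele_counts`` must
    be consistent with them (each genotype contributes two gametes).
    """

    n: int
    allele_counts: dict[int, int]
    genotype_counts: dict[tuple[int, int], int]

    def __post_init__(self) -> None:
        if sum(self.genotype_counts.values()) != self.n:
            raise ValueError("genotype counts do not sum to n")
        derived: Counter = Counter()
        for (a, b), c in self.genotype_counts.items():
            derived[a] += c
            derived[b] += c
        if dict(derived) != {k: v for k, v in self.allele_counts.items() if v}:
            raise ValueError("allele counts inconsistent with genotype counts")

    @property
    def h(self) -> int:
        """Number of heterozygous individuals."""
        return sum(c for (a, b), c in self.genotype_counts.items() if a != b)

    @property
    def num_alleles(self) -> int:
        return len(self.allele_counts)

    @property
    def size_range(self) -> tuple[int, int]:
        ks = list(self.allele_counts)
        return (min(ks), max(ks))

    @classmethod
    def from_genotypes(cls, pairs: Iterable[tuple[int, int]]) -> "LocusGenotypeCounts":
        gc: Counter = Counter()
        ac: Counter = Counter()
        n = 0
        for a, b in pairs:
            a, b = (a, b) if a <= b else (b, a)
            gc[(a, b)] += 1
            ac[a] += 1
            ac[b] += 1
            n += 1
        return cls(n, dict(ac), dict(gc))


@dataclass(frozen=True)
class LocusStats:
    """One row of a marker-panel summary table, for one locus in one species."""

    locus_name: str
    n: int
    size_range: tuple[int, int]
    Na: int
    Ho: float
    He: float
    p_hwe: float | None
    null_freq: float | None
    status: str  # polymorphic | monomorphic | failed


@dataclass(frozen=True)
class TestConfig:
    """Knobs for the stochastic tests; every random draw flows from ``seed``."""

    hwe_method: str = "auto"  # auto | enumerate | monte_carlo
    mc_reps: int = 100_000
    enum_table_limit: int = 1_000_000
    ld_permutations: int = 10_000
    alpha: float = 0.05
    seed: int = 0

    __test__ = False  # not a pytest class, despite the name

    def __post_init__(self) -> None:
        if self.hwe_method not in ("auto", "enumerate", "monte_carlo"):
            raise ValueError(f"unknown hwe_method {self.hwe_method!r}")
        if self.mc_reps < 1000 or self.ld_permutations < 1000:
            raise ValueError("mc_reps and ld_permutations must be >= 1000")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


def tally(matrix: GenotypeMatrix, locus: str) -> LocusGenotypeCounts:
    """Tally genotypes at ``locus``, excluding missing calls.

    Raises :class:`AllMissingError` when every call is missing (a failed
    locus in this species).
    """
    pairs = [c for c in matrix.column(locus) if c is not MISSING]
    if not pairs:
        raise AllMissingError(f"locus {locus!r}: all calls missing")
    return LocusGenotypeCounts.from_genotypes(pairs)


def observed_het(c: LocusGenotypeCounts) -> float:
    """Observed heterozygosity ``h / n``."""
    if c.n < 1:
        raise ValueError("n must be >= 1")
    return c.h / c.n


def expected_het(c: LocusGenotypeCounts, unbiased: bool = True) -> float:
    """Expected heterozygosity (gene diversity).

    With ``unbiased`` (default), applies Nei's small-sample correction:
    ``(2n / (2n - 1)) * (1 - sum p_i^2)``; otherwise the plug-in form.
    """
    if c.n < 2:
        raise ValueError("n must be >= 2")
    two_n = 2 * c.n
    p = np.array(list(c.allele_counts.values()), dtype=float) / two_n
    het = 1.0 - float(np.sum(p * p))
    if unbiased:
        het *= two_n / (two_n - 1)
    return het


# ---------------------------------------------------------------------------
# Exact HWE probability test

_REL_TIE_TOL = 1e-12  # tables with P equal to P(obs) within this relative
                      # tolerance are counted in the tail


def _log_table_prob_const(allele_counts: Sequence[int]) -> float:
    """log of the table-independent factor n! * prod a_i! / (2n)!."""
    two_n = sum(allele_counts)
    n = two_n // 2
    return (
        math.lgamma(n + 1)
        + sum(math.lgamma(a + 1) for a in allele_counts)
        - math.lgamma(two_n + 1)
    )


def _log_table_prob_var(n_ij: dict[tuple[int, int], int]) -> float:
    """Table-dependent factor: h*log 2 - sum log n_ij!."""
    h = sum(c for (a, b), c in n_ij.items() if a != b)
    return h * math.log(2.0) - sum(math.lgamma(c + 1) for c in n_ij.values())


class _EnumLimitExceeded(Exception):
    pass


def _enumerate_log_probs(allele_counts: Sequence[int], limit: int) -> list[float]:
    """Log conditional probabilities of every genotype table with the given
    allele counts (Levene's distribution). Raises :class:`_EnumLimitExceeded`
    past ``limit`` tables.

    The recursion distributes each allele's remaining gametes over its
    homozygote and the heterozygotes with later alleles.
    """
    k = len(allele_counts)
    counts = list(allele_counts)
    const = _log_table_prob_const(counts)
    out: list[float] = []
    log2 = math.log(2.0)

    # var-part accumulated incrementally: h*log2 - sum lgamma(n_ij + 1)
    def rec_allele(i: int, rem: list[int], acc: float) -> None:
        if i == k:
            out.append(const + acc)
            if len(out) > limit:
                raise _EnumLimitExceeded
            return
        # distribute rem[i] gametes of allele i among (i,i) pairs and
        # heterozygotes (i,j), j > i; all of allele i's gametes must be used
        def rec_pair(j: int, left: int, acc2: float, rem2: list[int]) -> None:
            if j == k:
                if left == 0:
                    rec_allele(i + 1, rem2, acc2)
                return
            # n_ij heterozygotes use one gamete of i and one of j
            hi = min(left, rem2[j]) if j < k - 1 else min(left, rem2[j])
            lo = 0 if j < k - 1 else (left if left <= rem2[j] else -1)
            if lo < 0:
                return  # cannot place the remaining gametes
            for nij in range(lo, hi + 1):
                rem2[j] -= nij
                rec_pair(
                    j + 1,
                    left - nij,
                    acc2 + nij * log2 - math.lgamma(nij + 1),
                    rem2,
                )
                rem2[j] += nij
        # n_ii homozygotes use two gametes of allele i
        for nii in range(rem[i] // 2 + 1):
            left = rem[i] - 2 * nii
            rem2 = list(rem)
            rem2[i] = 0
            rec_pair(i + 1, left, acc - math.lgamma(nii + 1), rem2)
    rec_allele(0, counts, 0.0)
    return out


def _sample_tables_log_probs(
    allele_counts_map: dict[int, int], reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Log probabilities of ``reps`` tables drawn from Levene's conditional
    null by randomly pairing the fixed gamete multiset."""
    alleles = []
    for a, c in allele_counts_map.items():
        alleles.extend([a] * c)
    gametes = np.array(alleles)
    const = _log_table_prob_const(list(allele_counts_map.values()))
    two_n = gametes.size
    out = np.empty(reps)
    log2 = math.log(2.0)
    for r in range(reps):
        rng.shuffle(gametes)
        left = gametes[0 : two_n : 2]
        right = gametes[1 : two_n : 2]
        lo = np.minimum(left, right)
        hi = np.maximum(left, right)
        pairs = Counter(zip(lo.tolist(), hi.tolist()))
        h = sum(c for (a, b), c in pairs.items() if a != b)
        var = h * log2 - sum(math.lgamma(c + 1) for c in pairs.values())
        out[r] = const + var
    return out


def _count_tables(allele_counts: Sequence[int], limit: int) -> int:
    """Number of genotype tables consistent with the allele counts, capped
    at ``limit + 1`` (dynamic programming over gamete distribution)."""
    try:
        return len(_enumerate_log_probs(allele_counts, limit))
    except _EnumLimitExceeded:
        return limit + 1


def hwe_exact_test(c: LocusGenotypeCounts, cfg: TestConfig | None = None) -> float:
    """Exact Hardy-Weinberg probability-test p-value.

    The p-value is the total conditional probability, given the observed
    allele counts, of genotype tables no more probable than the observed
    one. ``cfg.hwe_method`` selects full enumeration, conditional Monte
    Carlo (``p = (1 + #{P_t <= P_obs}) / (reps + 1)``), or ``auto`` (count
    the tables first, enumerate when feasible).

    Raises :class:`MonomorphicLocusError` for Na < 2 (the statistic is
    undefined there and reported as a dash in panel tables).
    """
    cfg = cfg or TestConfig()
    if c.num_alleles < 2:
        raise MonomorphicLocusError("HWE test undefined for a monomorphic locus")
    counts = list(c.allele_counts.values())
    obs = _log_table_prob_const(counts) + _log_table_prob_var(c.genotype_counts)

    method = cfg.hwe_method
    if method == "auto":
        n_tables = _count_tables(counts, cfg.enum_table_limit)
        method = "enumerate" if n_tables <= cfg.enum_table_limit else "monte_carlo"

    if method == "enumerate":
        logps = np.array(_enumerate_log_probs(counts, cfg.enum_table_limit))
        # tail: P(table) <= P(obs), with ties within relative tolerance
        thresh = obs + math.log1p(_REL_TIE_TOL)
        tail = logps[logps <= thresh]
        return float(np.exp(tail).sum())

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x48574531]))
    logps = _sample_tables_log_probs(c.allele_counts, cfg.mc_reps, rng)
    thresh = obs + math.log1p(_REL_TIE_TOL)
    hits = int(np.sum(logps <= thresh))
    return (1 + hits) / (cfg.mc_reps + 1)


# ---------------------------------------------------------------------------
# Null-allele maximum likelihood (EM)


def null_allele_ml(
    c: LocusGenotypeCounts,
    include_missing_as_blanks: bool = False,
    n_blank: int = 0,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> tuple[float, dict[int, float]]:
    """ML estimate of a null-allele frequency from homozygote excess.

    Model: HWE with visible alleles at frequencies ``p_i`` and one null
    allele at frequency ``r`` (``sum p_i + r = 1``). Class probabilities:
    visible heterozygote (i, j): ``2 p_i p_j``; apparent homozygote (i):
    ``p_i^2 + 2 p_i r`` (true homozygotes plus null carriers); blank
    (no amplification): ``r^2``.

    With ``include_missing_as_blanks`` the ``n_blank`` missing calls are
    modelled as null homozygotes; otherwise (default) the likelihood is
    conditioned on an individual being visible (class probabilities divided
    by ``1 - r^2``), matching data where failed amplifications cannot be
    distinguished from other missingness.

    Fitted by EM: apparent homozygotes of allele i split into true
    homozygotes vs null heterozygotes with posterior weights
    ``p_i : 2r``; under the conditional model the unseen blank count is
    imputed as ``n r^2 / (1 - r^2)``. Returns ``(r_hat, visible_freqs)``
    with the visible frequencies renormalized over ``1 - r_hat``
    (they sum to ``1 - r_hat``). The observed-data log-likelihood is
    non-decreasing across iterations.

    Raises :class:`MonomorphicLocusError` for Na < 2.
    """
    if c.num_alleles < 2:
        raise MonomorphicLocusError("null-allele estimate undefined for Na < 2")
    alleles = sorted(c.allele_counts)
    idx = {a: i for i, a in enumerate(alleles)}
    k = len(alleles)
    hom_obs = np.zeros(k)
    het_gamete = np.zeros(k)  # gametes of each allele carried in visible hets
    n_het = 0
    for (a, b), cnt in c.genotype_counts.items():
        if a == b:
            hom_obs[idx[a]] += cnt
        else:
            het_gamete[idx[a]] += cnt
            het_gamete[idx[b]] += cnt
            n_het += cnt
    n_vis = c.n
    blanks = float(n_blank) if include_missing_as_blanks else None

    # init: plug-in visible freqs scaled by (1 - r0), small r0
    r = 0.05
    p = np.array([c.allele_counts[a] for a in alleles], dtype=float)
    p = p / p.sum() * (1 - r)

    def loglik(p: np.ndarray, r: float) -> float:
        hom_p = p * p + 2 * p * r
        ll = float(np.dot(hom_obs, np.log(np.maximum(hom_p, 1e-300))))
        # visible-het terms: sum over het classes cnt*log(2 p_a p_b)
        for (a, b), cnt in c.genotype_counts.items():
            if a != b:
                ll += cnt * math.log(max(2 * p[idx[a]] * p[idx[b]], 1e-300))
        if blanks is not None:
            if blanks > 0:
                ll += blanks * math.log(max(r * r, 1e-300))
        else:
            ll -= n_vis * math.log(max(1 - r * r, 1e-300))
        return ll

    ll_old = loglik(p, r)
    history = [ll_old]
    for _ in range(max_iter):
        # E-step
        with np.errstate(divide="ignore", invalid="ignore"):
            w_true = np.where(p + 2 * r > 0, p / (p + 2 * r), 1.0)
        hom_true = hom_obs * w_true          # true homozygotes of allele i
        hom_null = hom_obs * (1 - w_true)    # null/visible heterozygotes
        if blanks is not None:
            b_exp = blanks
            total = n_vis + blanks
        else:
            b_exp = n_vis * (r * r) / max(1 - r * r, 1e-12)
            total = n_vis + b_exp
        # M-step: gamete counts over 2*total gametes
        vis_gam = het_gamete + 2 * hom_true + hom_null
        null_gam = hom_null.sum() + 2 * b_exp
        denom = 2 * total
        p = vis_gam / denom
        r = null_gam / denom
        ll_new = loglik(p, r)
        history.append(ll_new)
        if abs(ll_new - ll_old) < tol:
            break
        ll_old = ll_new
    # EM approaches the r = 0 boundary only sublinearly; test the boundary
    # candidate (plug-in visible frequencies, no null) explicitly and take
    # it when it fits at least as well, so no-homozygote-excess data return
    # exactly r = 0
    if blanks is None or blanks == 0:
        p0 = np.array([c.allele_counts[a] for a in alleles], dtype=float)
        p0 = p0 / p0.sum()
        ll0 = loglik(p0, 0.0)
        if ll0 >= history[-1] - 1e-9:
            history.append(ll0)
            p, r = p0, 0.0
    null_allele_ml.last_loglik_history = history  # inspectable audit trail
    freqs = {a: float(p[idx[a]]) for a in alleles}
    return float(max(r, 0.0)), freqs


# ---------------------------------------------------------------------------
# Genotypic disequilibrium (permutation G-test)


def _g_statistic(table: np.ndarray) -> float:
    """Log-likelihood-ratio G for an r x c contingency table."""
    total = table.sum()
    if total == 0:
        return 0.0
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows * cols / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(table / expected), 0.0)
    return 2.0 * float(terms.sum())


def genotypic_ld_test(
    matrix: GenotypeMatrix, locus_a: str, locus_b: str, cfg: TestConfig | None = None
) -> float:
    """Permutation test of genotypic disequilibrium between two loci.

    Builds the genotype x genotype contingency table over individuals with
    calls at both loci, uses the log-likelihood-ratio G as the statistic,
    and permutes one locus's genotype column (``cfg.ld_permutations`` times,
    seeded) for the null: ``p = (1 + #{G_perm >= G_obs}) / (perms + 1)``.

    Raises ``ValueError`` when either locus shows fewer than two distinct
    genotypes among the jointly scored individuals.
    """
    cfg = cfg or TestConfig()
    col_a = matrix.column(locus_a)
    col_b = matrix.column(locus_b)
    pairs = [(a, b) for a, b in zip(col_a, col_b) if a is not MISSING and b is not MISSING]
    if not pairs:
        raise ValueError("no individuals scored at both loci")
    ga = sorted({a for a, _ in pairs})
    gb = sorted({b for _, b in pairs})
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("fewer than 2 distinct genotypes at one locus")
    ia = {g: i for i, g in enumerate(ga)}
    ib = {g: i for i, g in enumerate(gb)}
    codes_a = np.array([ia[a] for a, _ in pairs])
    codes_b = np.array([ib[b] for _, b in pairs])
    ra, rb = len(ga), len(gb)

    def table(bcodes: np.ndarray) -> np.ndarray:
        return np.bincount(codes_a * rb + bcodes, minlength=ra * rb).reshape(ra, rb)

    g_obs = _g_statistic(table(codes_b))
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x4C4454]))
    hits = 0
    for _ in range(cfg.ld_permutations):
        perm = rng.permutation(codes_b)
        if _g_statistic(table(perm)) >= g_obs - 1e-12:
            hits += 1
    return (1 + hits) / (cfg.ld_permutations + 1)


# ---------------------------------------------------------------------------


def bonferroni(
    pvals: Sequence[float | None], alpha: float = 0.05
) -> tuple[list[bool | None], float | None]:
    """Standard Bonferroni correction.

    Undefined entries (None/NaN) are skipped; the corrected threshold is
    ``alpha / k`` over the ``k`` defined p-values, and each defined p gets a
    flag ``p <= threshold``. Returns ``(flags, threshold)``; with no defined
    p-values the threshold is None and all flags are None.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    defined = [
        p for p in pvals if p is not None and not (isinstance(p, float) and math.isnan(p))
    ]
    k = len(defined)
    if k == 0:
        return [None] * len(pvals), None
    thr = alpha / k
    flags: list[bool | None] = []
    for p in pvals:
        if p is None or (isinstance(p, float) and math.isnan(p)):
            flags.append(None)
        else:
            flags.append(p <= thr)
    return flags, thr


def locus_stats(
    matrix: GenotypeMatrix,
    locus: str,
    cfg: TestConfig | None = None,
    estimate_null: bool = True,
) -> LocusStats:
    """Full per-locus summary row: Na, size range, Ho, He, HWE p, null-allele r.

    A locus with every call missing is reported with status "failed";
    monomorphic loci carry He = 0 and undefined p_hwe/null_freq.
    """
    cfg = cfg or TestConfig()
    try:
        c = tally(matrix, locus)
    except AllMissingError:
        return LocusStats(locus, 0, (0, 0), 0, float("nan"), float("nan"), None, None, "failed")
    if c.num_alleles == 1:
        return LocusStats(
            locus, c.n, c.size_range, 1, observed_het(c), 0.0, None, None, "monomorphic"
        )
    p = hwe_exact_test(c, cfg)
    r = null_allele_ml(c)[0] if estimate_null else None
    return LocusStats(
        locus,
        c.n,
        c.size_range,
        c.num_alleles,
        observed_het(c),
        expected_het(c),
        p,
        r,
        "polymorphic",
    )
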