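"""Independent oracles and small generators shared across the test suite.

Everything here deliberately avoids the library's own scanning/EM code
paths: the SSR oracle checks every (start, motif_len) candidate by direct
string comparison, and the null-allele oracle maximizes the likelihood on
an explicit grid.
"""

from __future__ import annotations

import math

import numpy as np

_ACGT = set("ACGT")


def is_primitive(motif: str) -> bool:
    n = len(motif)
    return not any(
        n % d == 0 and motif == motif[:d] * (n // d) for d in range(1, n)
    )


def brute_force_ssrs(seq: str, min_units: int = 5, lo: int = 2, hi: int = 10):
    """All maximal primitive tandem repeats, by exhaustive per-start checks.

    A locus is anchored at the leftmost base of its periodicity run
    (seq[start-1] != seq[start+m-1], or start == 0 / a non-ACGT break) and
    extended copy by copy via direct slice comparison.
    """
    seq = seq.upper()
    L = len(seq)
    out = []
    for m in range(lo, hi + 1):
        for start in range(0, L - m * min_units + 1):
            motif = seq[start : start + m]
            if not _ACGT.issuperset(motif) or not is_primitive(motif):
                continue
            if start > 0 and seq[start - 1] == seq[start + m - 1]:
                continue
            count = 1
            while seq[start + count * m : start + (count + 1) * m] == motif:
                count += 1
            if count >= min_units:
                out.append((start, m, count))
    return sorted(out)


def random_seq_with_repeats(rng: np.random.Generator, max_len: int = 500) -> str:
    """Random test sequence: sometimes pure-random, sometimes low-complexity
    or with an explicit planted repeat, so positives actually occur."""
    L = int(rng.integers(20, max_len + 1))
    mode = rng.integers(0, 3)
    if mode == 0:
        return "".join(rng.choice(list("ACGT"), size=L))
    if mode == 1:  # two-letter alphabet: dense in tandem repeats
        letters = rng.choice(list("ACGT"), size=2, replace=False)
        return "".join(rng.choice(letters, size=L))
    seq = list(rng.choice(list("ACGT"), size=L))
    m = int(rng.integers(2, 7))
    count = int(rng.integers(4, 9))
    motif = "".join(rng.choice(list("ACGT"), size=m))
    span = m * count
    if span + 2 < L:
        start = int(rng.integers(1, L - span - 1))
        seq[start : start + span] = list(motif * count)
    return "".join(seq)


def grid_null_oracle(hom1: int, hom2: int, het: int, step: float = 1e-3):
    """Brute-force grid maximization of the conditional null-allele
    likelihood for a 2-visible-allele table. Returns (r, p1, p2)."""
    best = (-math.inf, 0.0, 0.0)
    n_r = int(round(0.6 / step))
    n_p = int(round(1.0 / step))
    for ri in range(n_r):
        r = ri * step
        denom = 1 - r * r
        for pi in range(1, n_p):
            p1 = (pi * step) * (1 - r)
            p2 = (1 - r) - p1
            if p2 <= 0:
                continue
            ll = 0.0
            if hom1:
                ll += hom1 * math.log((p1 * p1 + 2 * p1 * r) / denom)
            if hom2:
                ll += hom2 * math.log((p2 * p2 + 2 * p2 * r) / denom)
            if het:
                ll += het * math.log(2 * p1 * p2 / denom)
            if ll > best[0]:
                best = (ll, r, p1)
    return best[1], best[2]


def simulate_hwe_table(rng: np.random.Generator, n: int, freqs):
    """Multinomial genotype draw under exact Hardy-Weinberg proportions."""
    freqs = np.asarray(freqs, dtype=float)
    k = freqs.size
    classes = [(i, j) for i in range(k) for j in range(i, k)]
    probs = np.array(
        [freqs[i] * freqs[j] * (1 if i == j else 2) for i, j in classes]
    )
    counts = rng.multinomial(n, probs)
    pairs = []
    for (i, j), c in zip(classes, counts):
        pairs.extend([(i + 1, j + 1)] * c)
    return pairs
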