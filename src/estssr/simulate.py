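"""Synthetic transcriptomes and genotype matrices with ground truth.

Two generators stand in for the study-scale raw data a marker-development
project starts from:

* :func:`simulate_transcriptome` emulates a de novo assembled transcriptome
  (log-normal lengths, fixed GC content) with perfect SSRs planted at known
  coordinates. Guard bases flanking each planted repeat differ from the
  motif's edge bases, so the planted coordinates are exactly what a maximal
  scanner must report.
* :func:`simulate_genotypes` emulates capillary genotyping of a marker
  panel: diploid genotypes drawn under an inbreeding/Wahlund parameter F
  (P(homozygote i) = p_i^2 + F p_i (1 - p_i)), with an optional null allele
  mixed into the gamete pool (null/null -> missing call, null/visible ->
  apparent homozygote), Gaussian fragment-size noise, and gap-rule binning
  back to integer alleles.

Every draw flows from one top-level seed through named substreams, so the
transcriptome, genotype and noise stages can be regenerated independently.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genotypes import MISSING, GenotypeMatrix, bin_alleles
from .mining import Transcript, is_primitive

__all__ = [
    "TranscriptomeSpec",
    "LocusSimSpec",
    "GenotypeSimSpec",
    "PlantedSSR",
    "GenotypeTruth",
    "simulate_transcriptome",
    "simulate_genotypes",
    "default_transcriptome_spec",
    "default_genotype_spec",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible RNG substream derived from (seed, name)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


# ---------------------------------------------------------------------------
# Transcriptome


@dataclass(frozen=True)
class PlantedSSR:
    transcript_id: str
    motif: str
    motif_len: int
    repeat_count: int
    start: int
    end: int


@dataclass
class TranscriptomeSpec:
    """Conditions for the synthetic transcriptome.

    Defaults emulate a MiSeq spleen-transcriptome assembly scaled to test
    size: log-normal transcript lengths (median 880 bp, sigma 0.72, giving
    a mean near 1.14 kb, the study-scale 128 Mb / 112,477 average), GC 0.45,
    an SSR planted in ~38 % of transcripts, a dinucleotide-dominated
    motif-length spectrum matching the published per-class proportions, and
    repeat counts from a geometric distribution truncated at 5 units.
    """

    n_transcripts: int = 200
    length_median: float = 880.0
    length_sigma: float = 0.72
    gc_content: float = 0.45
    ssr_plant_rate: float = 0.385
    motif_length_weights: dict[int, float] = field(
        default_factory=lambda: {
            2: 35697 / 43269,
            3: 6905 / 43269,
            4: 549 / 43269,
            5: 32 / 43269,
            6: 23 / 43269,
            7: 5 / 43269,
            8: 15 / 43269,
            9: 26 / 43269,
            10: 17 / 43269,
        }
    )
    repeat_count_min: int = 5
    repeat_count_mean: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.motif_length_weights.values())
        if not np.isclose(total, 1.0):
            self.motif_length_weights = {
                k: v / total for k, v in self.motif_length_weights.items()
            }
        if self.repeat_count_min < 5:
            raise ValueError("planted repeat counts must be >= 5 units")
        if not (0.0 < self.gc_content < 1.0):
            raise ValueError("gc_content must be in (0, 1)")


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=probs)]


def _random_primitive_motif(rng: np.random.Generator, m: int) -> str:
    while True:
        motif = "".join("ACGT"[i] for i in rng.integers(0, 4, size=m))
        if is_primitive(motif):
            return motif


def _truncated_geometric(rng: np.random.Generator, lo: int, mean: float) -> int:
    # geometric on {lo, lo+1, ...} with the requested mean
    p = 1.0 / max(mean - lo + 1, 1.000001)
    return lo + rng.geometric(p) - 1


def simulate_transcriptome(
    spec: TranscriptomeSpec,
) -> tuple[list[Transcript], list[PlantedSSR]]:
    """Generate transcripts with planted SSRs and their exact truth records.

    Reproducible under ``spec.seed``; a transcript drawn too short to host
    its planted repeat plus guard bases has its length resampled.
    """
    rng_len = substream(spec.seed, "transcriptome.lengths")
    rng_seq = substream(spec.seed, "transcriptome.sequence")
    rng_ssr = substream(spec.seed, "transcriptome.ssr")
    mlens = sorted(spec.motif_length_weights)
    weights = np.array([spec.motif_length_weights[m] for m in mlens])
    weights = weights / weights.sum()

    transcripts: list[Transcript] = []
    truth: list[PlantedSSR] = []
    for i in range(spec.n_transcripts):
        tid = f"SYN{i + 1:06d}"
        plant = rng_ssr.random() < spec.ssr_plant_rate
        motif = count = None
        if plant:
            m = int(mlens[rng_ssr.choice(len(mlens), p=weights)])
            motif = _random_primitive_motif(rng_ssr, m)
            count = _truncated_geometric(rng_ssr, spec.repeat_count_min, spec.repeat_count_mean)
        while True:
            length = int(round(spec.length_median * np.exp(spec.length_sigma * rng_len.standard_normal())))
            need = (len(motif) * count + 4) if plant else 1
            if length >= max(need, 30):
                break
        seq = _random_seq(rng_seq, length, spec.gc_content)
        if plant:
            m = len(motif)
            span = m * count
            # guarded offset: >= 1 base on each side for the guards
            start = int(rng_ssr.integers(1, length - span))
            repeat = np.frombuffer((motif * count).encode(), dtype=np.uint8)
            seq[start : start + span] = repeat
            # guards break the periodicity on both sides
            left_bad = motif[-1]
            right_bad = motif[0]
            seq[start - 1] = ord(_other_base(rng_ssr, left_bad))
            if start + span < length:
                seq[start + span] = ord(_other_base(rng_ssr, right_bad))
            truth.append(PlantedSSR(tid, motif, m, count, start, start + span))
        transcripts.append(Transcript(tid, seq.tobytes().decode("ascii")))
    return transcripts, truth


def _other_base(rng: np.random.Generator, avoid: str) -> str:
    choices = [b for b in "ACGT" if b != avoid]
    return choices[int(rng.integers(0, len(choices)))]


# ---------------------------------------------------------------------------
# Genotypes


@dataclass(frozen=True)
class LocusSimSpec:
    """One simulated marker: visible alleles on a fragment-size ladder.

    ``visible_freqs[k]`` is the frequency of allele ``base_size + k *
    repeat_unit``; together with ``null_freq`` they must sum to 1.
    """

    name: str
    base_size: int
    repeat_unit: int
    visible_freqs: tuple[float, ...]
    null_freq: float = 0.0

    def __post_init__(self) -> None:
        total = sum(self.visible_freqs) + self.null_freq
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"{self.name}: frequencies sum to {total}, not 1")

    @property
    def allele_sizes(self) -> list[int]:
        return [self.base_size + k * self.repeat_unit for k in range(len(self.visible_freqs))]


@dataclass
class GenotypeSimSpec:
    species_label: str = "SimSpecies"
    n_individuals: int = 21
    loci: tuple[LocusSimSpec, ...] = ()
    f_is: float = 0.0
    missing_rate: float = 0.0
    size_noise_sd: float = 0.15
    bin_min_gap: float | None = None  # default repeat_unit/4: single-linkage
    # merging is robust as long as extreme noise draws cannot close the
    # inter-allele gap below this, which unit/4 guarantees for noise SDs
    # well under a quarter repeat unit even at very large sample sizes
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_is < 1.0):
            raise ValueError("f_is must be in [0, 1)")


@dataclass(frozen=True)
class GenotypeTruth:
    """Pre-noise truth for one call; allele size -1 encodes the null allele."""

    individual: str
    locus: str
    allele1: int
    allele2: int
    observed_missing: bool


def simulate_genotypes(
    spec: GenotypeSimSpec,
) -> tuple[GenotypeMatrix, list[GenotypeTruth]]:
    """Draw a diploid genotype matrix with controlled HWE departure and nulls.

    Per individual and locus, gametes are drawn from the augmented frequency
    vector (visible alleles + null): the first gamete at its frequencies,
    the second identical to the first with probability ``f_is`` (inbreeding
    / Wahlund homozygote excess), otherwise independent. A null/null pair
    is recorded as missing; null/visible appears as a visible homozygote.
    Gaussian noise (``size_noise_sd`` bp) is added to each visible fragment
    and the raw sizes are binned back to integer alleles per locus with the
    gap rule. ``missing_rate`` then masks calls at random. Reproducible
    under ``spec.seed``.
    """
    rng_gt = substream(spec.seed, "genotypes.draws")
    rng_noise = substream(spec.seed, "genotypes.noise")
    rng_miss = substream(spec.seed, "genotypes.missing")

    ids = [f"{spec.species_label}_{i + 1:03d}" for i in range(spec.n_individuals)]
    n = spec.n_individuals
    columns: dict[str, list] = {}
    truth: list[GenotypeTruth] = []

    for locus in spec.loci:
        sizes = locus.allele_sizes
        freqs = np.array(list(locus.visible_freqs) + [locus.null_freq])
        freqs = freqs / freqs.sum()
        k_null = len(sizes)  # index of the null allele
        first = rng_gt.choice(len(freqs), size=n, p=freqs)
        ibd = rng_gt.random(n) < spec.f_is
        second = np.where(ibd, first, rng_gt.choice(len(freqs), size=n, p=freqs))

        raw_calls: list[tuple[float, float] | None] = []
        for i in range(n):
            a, b = int(first[i]), int(second[i])
            ta = -1 if a == k_null else sizes[a]
            tb = -1 if b == k_null else sizes[b]
            if a == k_null and b == k_null:
                truth.append(GenotypeTruth(ids[i], locus.name, ta, tb, True))
                raw_calls.append(None)
                continue
            if a == k_null or b == k_null:
                vis = tb if a == k_null else ta
                obs = (float(vis), float(vis))  # apparent homozygote
            else:
                obs = (float(ta), float(tb))
            noisy = (
                obs[0] + rng_noise.normal(0.0, spec.size_noise_sd),
                obs[1] + rng_noise.normal(0.0, spec.size_noise_sd),
            )
            missing = bool(rng_miss.random() < spec.missing_rate)
            truth.append(GenotypeTruth(ids[i], locus.name, ta, tb, missing))
            raw_calls.append(None if missing else noisy)

        observed_sizes = [s for call in raw_calls if call for s in call]
        if observed_sizes:
            gap = spec.bin_min_gap if spec.bin_min_gap is not None else locus.repeat_unit / 4.0
            bmap = bin_alleles(observed_sizes, locus.repeat_unit, gap, locus_name=locus.name)
            col = [
                None if call is None else (bmap(call[0]), bmap(call[1]))
                for call in raw_calls
            ]
        else:
            col = [None] * n
        columns[locus.name] = col

    locus_names = [l.name for l in spec.loci]
    calls = [[columns[ln][i] for ln in locus_names] for i in range(n)]
    matrix = GenotypeMatrix(spec.species_label, locus_names, ids, calls)
    return matrix, truth


# ---------------------------------------------------------------------------
# Default study-scale conditions


def default_transcriptome_spec(seed: int = 0, n_transcripts: int = 200) -> TranscriptomeSpec:
    return TranscriptomeSpec(n_transcripts=n_transcripts, seed=seed)


def default_genotype_spec(seed: int = 0) -> list[GenotypeSimSpec]:
    """Three-species panel emulating the study's sampling: 21/20/18
    individuals genotyped at a shared set of dinucleotide markers with a mix
    of polymorphic and monomorphic loci and one null-allele-bearing locus."""
    loci = (
        LocusSimSpec("Syn_mono", 100, 2, (1.0,)),
        LocusSimSpec("Syn_biallelic", 120, 2, (0.7, 0.3)),
        LocusSimSpec("Syn_multi", 180, 2, (0.4, 0.25, 0.2, 0.1, 0.05)),
        LocusSimSpec("Syn_null", 140, 2, (0.55, 0.25, 0.15), null_freq=0.05),
    )
    return [
        GenotypeSimSpec("L_nudifrons_syn", 21, loci, seed=seed),
        GenotypeSimSpec("L_squamifrons_syn", 20, loci, seed=seed + 1),
        GenotypeSimSpec("L_larseni_syn", 18, loci, seed=seed + 2),
    ]
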