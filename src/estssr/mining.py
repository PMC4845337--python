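"""Detection of perfect microsatellites (SSRs) in transcript sequences.

A simple sequence repeat (SSR) is a tandem array of a short motif (here
2-10 bp). The scanner reports every *maximal* run of perfect period-``m``
repetition whose motif is *primitive* (not itself a repetition of a shorter
motif) and whose full-copy count reaches a configurable minimum (default 5
repeat units for every motif class). Each run is reported once, anchored at
its leftmost base, so a dinucleotide array is never double-counted as a
tetranucleotide one and phase-shifted duplicates are suppressed.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Transcript",
    "SSRLocus",
    "MiningConfig",
    "MiningSummary",
    "canonical_motif",
    "is_primitive",
    "find_ssrs",
    "summarize_mining",
    "read_fasta",
]

_ACGT = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class InvalidMotifError(ValueError):
    """Raised for motifs that are empty, non-ACGT, or non-primitive."""


@dataclass(frozen=True)
class Transcript:
    """A single assembled transcript sequence."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class SSRLocus:
    """A maximal perfect tandem repeat found in one transcript.

    ``start``/``end`` are 0-based half-open on the transcript, spanning the
    full copies only: ``end - start == motif_len * repeat_count``. Flank
    lengths are measured to the transcript boundaries.
    """

    transcript_id: str
    motif: str
    canonical_motif: str
    motif_len: int
    repeat_count: int
    start: int
    end: int
    left_flank: int
    right_flank: int


@dataclass(frozen=True)
class MiningConfig:
    """Search parameters for the SSR scanner.

    min_units
        Minimum number of full motif copies (>= 2); the marker-development
        convention used here is 5 for all motif classes.
    motif_len_range
        Inclusive (low, high) primitive motif lengths, within 2..10.
    n_policy
        "break_run": ambiguity characters terminate repeat runs (default);
        "skip_transcript": any non-ACGT base makes the transcript yield
        no loci.
    """

    min_units: int = 5
    motif_len_range: tuple[int, int] = (2, 10)
    n_policy: str = "break_run"

    def __post_init__(self) -> None:
        lo, hi = self.motif_len_range
        if self.min_units < 2:
            raise ValueError("min_units must be >= 2")
        if not (2 <= lo <= hi <= 10):
            raise ValueError("motif lengths must satisfy 2 <= lo <= hi <= 10")
        if self.n_policy not in ("break_run", "skip_transcript"):
            raise ValueError(f"unknown n_policy: {self.n_policy!r}")


@dataclass
class MiningSummary:
    """Panel-level totals for a mining run (per-motif-class breakdown).

    ``transcripts_by_motif_len`` counts a transcript once in every motif
    class it carries, so its values may sum to more than
    ``transcripts_with_ssr``. ``density_kb_per_ssr`` is kilobases of
    transcriptome per SSR locus; it is None when no loci were found.
    """

    transcripts_total: int
    transcripts_with_ssr: int
    ssr_loci_total: int
    transcripts_by_motif_len: dict[int, int]
    loci_by_motif_len: dict[int, int]
    total_bases: int
    density_kb_per_ssr: float | None
    pct_transcripts_with_ssr: float
    pct_loci_dinucleotide: float

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["transcripts_by_motif_len"] = {
            str(k): v for k, v in sorted(self.transcripts_by_motif_len.items())
        }
        d["loci_by_motif_len"] = {
            str(k): v for k, v in sorted(self.loci_by_motif_len.items())
        }
        return d


def is_primitive(motif: str) -> bool:
    """True if ``motif`` is not a whole-number repetition of a shorter string."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Canonical representative of a motif class.

    Two motifs describe the same repeat class if one is a rotation of the
    other or of its reverse complement — (GA)n, (AG)n, (TC)n and (CT)n are
    all one dinucleotide class. The canonical form is the lexicographically
    smallest of all such rotations, so it is invariant under rotation and
    reverse complement, and idempotent.
    """
    if not motif:
        raise InvalidMotifError("empty motif")
    if not _ACGT.issuperset(motif):
        raise InvalidMotifError(f"motif contains non-ACGT characters: {motif!r}")
    if not is_primitive(motif):
        raise InvalidMotifError(f"motif is not primitive: {motif!r}")
    rc = motif.translate(_COMPLEMENT)[::-1]
    candidates = [
        s[i:] + s[:i] for s in (motif, rc) for i in range(len(motif))
    ]
    return min(candidates)


def _segments(seq: str, policy: str) -> Iterator[tuple[int, str]]:
    """Yield (offset, subsequence) runs of pure ACGT sequence."""
    if not seq:
        return
    if policy == "skip_transcript" and not _ACGT.issuperset(seq):
        return
    start = None
    for i, ch in enumerate(seq):
        if ch in _ACGT:
            if start is None:
                start = i
        else:
            if start is not None:
                yield start, seq[start:i]
                start = None
    if start is not None:
        yield start, seq[start:]


def _scan_segment(seg: str, offset: int, cfg: MiningConfig) -> Iterator[tuple[int, int, int]]:
    """Yield (start, motif_len, repeat_count) for maximal primitive runs.

    For each period m, positions j with seg[j] == seg[j+m] are marked; a
    maximal run of marks [a, b) corresponds to a periodic region [a, b+m).
    The locus is anchored at a with floor((b+m-a)/m) full copies.
    """
    lo, hi = cfg.motif_len_range
    L = len(seg)
    if L < lo * cfg.min_units:
        return
    arr = np.frombuffer(seg.encode("ascii"), dtype=np.uint8)
    for m in range(lo, min(hi, L // cfg.min_units) + 1):
        eq = arr[:-m] == arr[m:]
        if not eq.any():
            continue
        # boundaries of runs of True
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)  # exclusive ends of the mark runs
        for a, b in zip(starts, ends):
            count = (b + m - a) // m
            if count < cfg.min_units:
                continue
            motif = seg[a : a + m]
            if not is_primitive(motif):
                continue
            yield offset + int(a), m, int(count)


def find_ssrs(t: Transcript, cfg: MiningConfig | None = None) -> list[SSRLocus]:
    """All maximal perfect SSRs in one transcript, sorted by start.

    Returns an empty list for empty sequences. Lowercase input is accepted.
    """
    cfg = cfg or MiningConfig()
    seq = t.seq.upper()
    length = len(seq)
    found: list[SSRLocus] = []
    for offset, seg in _segments(seq, cfg.n_policy):
        for start, m, count in _scan_segment(seg, offset, cfg):
            end = start + m * count
            motif = seq[start : start + m]
            found.append(
                SSRLocus(
                    transcript_id=t.id,
                    motif=motif,
                    canonical_motif=canonical_motif(motif),
                    motif_len=m,
                    repeat_count=count,
                    start=start,
                    end=end,
                    left_flank=start,
                    right_flank=length - end,
                )
            )
    found.sort(key=lambda loc: (loc.start, loc.motif_len))
    return found


def summarize_mining(
    transcripts: Sequence[Transcript], loci: Iterable[SSRLocus]
) -> MiningSummary:
    """Totals, density and percentages over a mining run.

    A transcript contributes once to ``transcripts_with_ssr`` and once per
    motif-length class it carries. Raises ``KeyError`` if a locus references
    an unknown transcript id.
    """
    ids = {t.id for t in transcripts}
    total_bases = sum(t.length for t in transcripts)
    loci = list(loci)
    with_ssr: set[str] = set()
    by_class: dict[int, set[str]] = defaultdict(set)
    loci_by_len: dict[int, int] = defaultdict(int)
    for loc in loci:
        if loc.transcript_id not in ids:
            raise KeyError(f"locus references unknown transcript {loc.transcript_id!r}")
        with_ssr.add(loc.transcript_id)
        by_class[loc.motif_len].add(loc.transcript_id)
        loci_by_len[loc.motif_len] += 1
    return summarize_counts(
        transcripts_total=len(transcripts),
        transcripts_with_ssr=len(with_ssr),
        transcripts_by_motif_len={m: len(s) for m, s in by_class.items()},
        loci_by_motif_len=dict(loci_by_len),
        total_bases=total_bases,
    )


def summarize_counts(
    *,
    transcripts_total: int,
    transcripts_by_motif_len: dict[int, int],
    loci_by_motif_len: dict[int, int] | None = None,
    transcripts_with_ssr: int | None = None,
    total_bases: int = 0,
) -> MiningSummary:
    """Totalizer: derive panel-level totals and proportions from per-class counts.

    Useful both for fresh mining runs and for recomputing published summary
    tables from their printed per-class rows. When ``loci_by_motif_len`` is
    absent, each SSR-bearing transcript is assumed to carry one locus (the
    one-class-per-transcript convention used in published transcript counts),
    and the per-class transcript counts double as locus counts.
    """
    if loci_by_motif_len is None:
        loci_by_motif_len = dict(transcripts_by_motif_len)
    ssr_loci_total = sum(loci_by_motif_len.values())
    if transcripts_with_ssr is None:
        transcripts_with_ssr = sum(transcripts_by_motif_len.values())
    density = (
        total_bases / ssr_loci_total / 1000.0 if ssr_loci_total and total_bases else None
    )
    pct_with = (
        100.0 * transcripts_with_ssr / transcripts_total if transcripts_total else 0.0
    )
    pct_di = (
        100.0 * loci_by_motif_len.get(2, 0) / ssr_loci_total if ssr_loci_total else 0.0
    )
    return MiningSummary(
        transcripts_total=transcripts_total,
        transcripts_with_ssr=transcripts_with_ssr,
        ssr_loci_total=ssr_loci_total,
        transcripts_by_motif_len=dict(transcripts_by_motif_len),
        loci_by_motif_len=dict(loci_by_motif_len),
        total_bases=total_bases,
        density_kb_per_ssr=density,
        pct_transcripts_with_ssr=pct_with,
        pct_loci_dinucleotide=pct_di,
    )


def read_fasta(path) -> list[Transcript]:
    """Read a multi-record FASTA into Transcript objects (case preserved)."""
    from Bio import SeqIO

    return [Transcript(id=rec.id, seq=str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
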