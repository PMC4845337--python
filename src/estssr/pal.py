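"""Selection of Potentially Amplifiable Loci (PALs).

A mined SSR qualifies as a PAL when both flanking sequences are long enough
to place PCR primers (strictly more than ``min_flank`` bp on each side, i.e.
>= 51 bp at the default 50) and the repeat array is long enough to be
reliably polymorphic (>= 8 repeat units by default, a stricter bar than the
mining threshold of 5). Exact duplicates — same canonical motif and both
flank sequences — are collapsed to a single record, with later copies marked
redundant; similarity-based redundancy clustering is deliberately out of
scope.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .mining import SSRLocus, Transcript

__all__ = ["PALConfig", "PALRecord", "select_pals", "pal_report"]


@dataclass(frozen=True)
class PALConfig:
    min_flank: int = 50
    min_units_pal: int = 8
    dedupe: bool = True

    def __post_init__(self) -> None:
        if self.min_flank < 0:
            raise ValueError("min_flank must be >= 0")
        if self.min_units_pal < 2:
            raise ValueError("min_units_pal must be >= 2")


@dataclass(frozen=True)
class PALRecord:
    locus: SSRLocus
    left_flank_seq: str
    right_flank_seq: str
    redundant_of: str | None = None


def select_pals(
    loci: Iterable[SSRLocus],
    transcripts: Sequence[Transcript] | Mapping[str, Transcript],
    cfg: PALConfig | None = None,
) -> list[PALRecord]:
    """Filter mined loci to PALs; non-redundant records come first in input order.

    Records failing the flank (> min_flank on each side) or repeat-count
    threshold are dropped. With dedupe on, a record whose (canonical motif,
    left flank, right flank) triple repeats an earlier one is kept in the
    output but marked ``redundant_of`` the first record's transcript; callers
    wanting the non-redundant set filter on ``redundant_of is None``.

    Raises ``KeyError`` when a locus references a transcript id that is not
    present.
    """
    cfg = cfg or PALConfig()
    if not isinstance(transcripts, Mapping):
        transcripts = {t.id: t for t in transcripts}
    out: list[PALRecord] = []
    seen: dict[tuple[str, str, str], str] = {}
    for loc in loci:
        if loc.transcript_id not in transcripts:
            raise KeyError(f"locus references unknown transcript {loc.transcript_id!r}")
        if loc.repeat_count < cfg.min_units_pal:
            continue
        if loc.left_flank <= cfg.min_flank or loc.right_flank <= cfg.min_flank:
            continue
        seq = transcripts[loc.transcript_id].seq.upper()
        left = seq[: loc.start]
        right = seq[loc.end :]
        redundant_of = None
        if cfg.dedupe:
            key = (loc.canonical_motif, left, right)
            if key in seen:
                redundant_of = seen[key]
            else:
                seen[key] = loc.transcript_id
        out.append(PALRecord(loc, left, right, redundant_of))
    return out


def pal_report(pals: Iterable[PALRecord]) -> dict:
    """Per-motif-length counts over the non-redundant PAL set, plus the total."""
    counts = Counter(
        p.locus.motif_len for p in pals if p.redundant_of is None
    )
    return {
        "pal_by_motif_len": {m: counts[m] for m in sorted(counts)},
        "pal_total": sum(counts.values()),
    }
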