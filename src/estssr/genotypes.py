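"""Diploid microsatellite genotype matrices: Genepop/CSV I/O and allele binning.

The in-memory container is :class:`GenotypeMatrix`: an individuals x loci
table of unordered diploid allele-size pairs (integer bp), with ``None``
as the missing sentinel (never 0, which Genepop reserves for missing).

The binner replaces proprietary fragment-binning tools with a transparent
single-linkage gap rule: sorted raw sizes are split into bins wherever the
gap between neighbours exceeds ``min_gap`` (default half the repeat unit),
and each bin is labelled by its rounded mean.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "BinningMap",
    "GenepopFormatError",
    "read_genepop",
    "write_genepop",
    "read_csv_long",
    "write_csv_long",
    "bin_alleles",
]

#: Missing-call sentinel (a call is an (int, int) tuple or MISSING).
MISSING = None


class GenepopFormatError(ValueError):
    """Malformed Genepop text; message carries the 1-based line number."""


@dataclass
class GenotypeMatrix:
    """Rectangular diploid genotype matrix for one population/species.

    ``calls[i][j]`` is the unordered allele pair (stored sorted ascending)
    of individual ``individual_ids[i]`` at locus ``locus_names[j]``, or
    ``MISSING``. Allele codes are positive integers <= 999 (the Genepop
    3-digit convention; for microsatellites these are fragment sizes in bp).
    """

    species_label: str
    locus_names: list[str]
    individual_ids: list[str]
    calls: list[list[tuple[int, int] | None]]

    def __post_init__(self) -> None:
        ncol = len(self.locus_names)
        for i, row in enumerate(self.calls):
            if len(row) != ncol:
                raise ValueError(
                    f"ragged matrix: individual {self.individual_ids[i]!r} has "
                    f"{len(row)} calls for {ncol} loci"
                )
        normd = []
        for row in self.calls:
            out_row = []
            for call in row:
                if call is MISSING:
                    out_row.append(MISSING)
                    continue
                a, b = call
                if not (1 <= a <= 999 and 1 <= b <= 999):
                    raise ValueError(f"allele codes must be in 1..999, got {call}")
                out_row.append((min(a, b), max(a, b)))
            normd.append(out_row)
        self.calls = normd

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def locus_index(self, locus: str) -> int:
        try:
            return self.locus_names.index(locus)
        except ValueError:
            raise KeyError(f"locus {locus!r} not in matrix") from None

    def column(self, locus: str) -> list[tuple[int, int] | None]:
        j = self.locus_index(locus)
        return [row[j] for row in self.calls]


@dataclass
class BinningMap:
    """Raw fragment size -> integer allele assignment for one locus."""

    locus_name: str
    repeat_unit: int
    raw_to_binned: dict[float, int]
    bin_centers: list[int]

    def __call__(self, raw: float) -> int:
        """Bin a raw size: exact member lookup, else nearest bin center."""
        if raw in self.raw_to_binned:
            return self.raw_to_binned[raw]
        return min(self.bin_centers, key=lambda c: (abs(c - raw), c))


# ---------------------------------------------------------------------------
# Genepop format


def _parse_call(token: str, width: int, lineno: int) -> tuple[int, int] | None:
    if len(token) != 2 * width or not token.isdigit():
        raise GenepopFormatError(
            f"line {lineno}: bad genotype token {token!r} for {width}-digit coding"
        )
    a, b = int(token[:width]), int(token[width:])
    if a == 0 or b == 0:
        return MISSING
    return (a, b)


def read_genepop(text: str) -> list[GenotypeMatrix]:
    """Parse Genepop text into one matrix per POP block.

    The first line is a title, then locus names (one per line and/or
    comma-separated), then ``POP`` blocks of ``id , g1 g2 ...`` lines with
    2- or 3-digit diploid coding (width auto-detected from the data).
    ``000000``/``0000`` (or any all-zero allele) is the missing sentinel.
    Each block's species label is the last whitespace token of its first
    individual's name. Raises :class:`GenepopFormatError` with a line
    number on malformed input.
    """
    lines = text.splitlines()
    if not lines:
        raise GenepopFormatError("line 1: empty file")
    # locus names until first POP line
    loci: list[str] = []
    i = 1
    npop = 0
    while i < len(lines) and lines[i].strip().upper() != "POP":
        chunk = [s.strip() for s in lines[i].split(",")]
        loci.extend(s for s in chunk if s)
        i += 1
    if i == len(lines):
        raise GenepopFormatError(f"line {len(lines)}: no POP line found")
    if not loci:
        raise GenepopFormatError("line 2: no locus names before first POP")

    blocks: list[tuple[int, list[tuple[int, str, list[str]]]]] = []
    current: list[tuple[int, str, list[str]]] = []
    for lineno0 in range(i, len(lines)):
        line = lines[lineno0]
        if line.strip().upper() == "POP":
            current = []
            blocks.append((lineno0 + 1, current))
            continue
        if not line.strip():
            continue
        if "," not in line:
            raise GenepopFormatError(
                f"line {lineno0 + 1}: expected 'id , genotypes' (no comma found)"
            )
        name, _, geno = line.partition(",")
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise GenepopFormatError(
                f"line {lineno0 + 1}: {len(tokens)} genotypes for {len(loci)} loci"
            )
        current.append((lineno0 + 1, name.strip(), tokens))

    # detect digit width from the first token (4 -> 2-digit, 6 -> 3-digit);
    # _parse_call then flags any token that disagrees, with its line number
    width = 3
    for _, rows in blocks:
        for lineno, _, toks in rows:
            if toks:
                if len(toks[0]) == 4:
                    width = 2
                elif len(toks[0]) != 6:
                    raise GenepopFormatError(
                        f"line {lineno}: bad genotype token {toks[0]!r} "
                        "(expected 4 or 6 digits)"
                    )
                break
        else:
            continue
        break

    matrices = []
    for popno, (_, rows) in enumerate(blocks, 1):
        ids = [name for _, name, _ in rows]
        calls = [
            [_parse_call(tok, width, lineno) for tok in toks]
            for lineno, _, toks in rows
        ]
        label = rows[0][1].split()[-1] if rows else f"pop{popno}"
        matrices.append(GenotypeMatrix(label, list(loci), ids, calls))
    return matrices


def write_genepop(matrices: Sequence[GenotypeMatrix], title: str = "estssr genotypes") -> str:
    """Serialize matrices as 3-digit Genepop text (deterministic, round-trips)."""
    if matrices:
        loci = matrices[0].locus_names
        for m in matrices[1:]:
            if m.locus_names != loci:
                raise ValueError("all matrices must share the same locus list")
    else:
        loci = []
    out = [title]
    out.extend(loci)
    for m in matrices:
        out.append("POP")
        for ind, row in zip(m.individual_ids, m.calls):
            toks = []
            for call in row:
                if call is MISSING:
                    toks.append("000000")
                else:
                    a, b = call
                    if a > 999 or b > 999:
                        raise ValueError(f"allele code out of 3-digit range: {call}")
                    toks.append(f"{a:03d}{b:03d}")
            out.append(f"{ind} ,  " + " ".join(toks))
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# CSV long format: species,individual,locus,allele1,allele2 (empty = missing)


def write_csv_long(matrices: Sequence[GenotypeMatrix]) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["species", "individual", "locus", "allele1", "allele2"])
    for m in matrices:
        for ind, row in zip(m.individual_ids, m.calls):
            for locus, call in zip(m.locus_names, row):
                if call is MISSING:
                    w.writerow([m.species_label, ind, locus, "", ""])
                else:
                    w.writerow([m.species_label, ind, locus, call[0], call[1]])
    return buf.getvalue()


def read_csv_long(text: str) -> list[GenotypeMatrix]:
    rows = list(csv.DictReader(io.StringIO(text)))
    if not rows:
        return []
    species_order: list[str] = []
    per_species: dict[str, dict[str, dict[str, tuple[int, int] | None]]] = {}
    locus_order: list[str] = []
    for r in rows:
        sp, ind, locus = r["species"], r["individual"], r["locus"]
        if sp not in per_species:
            per_species[sp] = {}
            species_order.append(sp)
        if locus not in locus_order:
            locus_order.append(locus)
        a1, a2 = r["allele1"].strip(), r["allele2"].strip()
        call = MISSING if not a1 or not a2 else (int(a1), int(a2))
        per_species[sp].setdefault(ind, {})[locus] = call
    out = []
    for sp in species_order:
        inds = list(per_species[sp])
        calls = [
            [per_species[sp][ind].get(loc, MISSING) for loc in locus_order]
            for ind in inds
        ]
        out.append(GenotypeMatrix(sp, list(locus_order), inds, calls))
    return out


# ---------------------------------------------------------------------------
# Allele binning


def bin_alleles(
    raw_sizes: Sequence[float],
    repeat_unit: int,
    min_gap: float | None = None,
    locus_name: str = "",
) -> BinningMap:
    """Cluster raw fragment sizes into integer allele bins by gap splitting.

    Sizes are sorted; a new bin opens whenever the gap between consecutive
    sorted sizes exceeds ``min_gap`` (default ``repeat_unit / 2``). Each
    bin's allele label is the rounded mean of its members. Permutation
    invariant in the input and idempotent on already-binned integer sizes.
    """
    if len(raw_sizes) == 0:
        raise ValueError("raw_sizes must be non-empty")
    if min_gap is None:
        min_gap = repeat_unit / 2.0
    if min_gap <= 0:
        raise ValueError("min_gap must be positive")
    srt = sorted(float(x) for x in raw_sizes)
    bins: list[list[float]] = [[srt[0]]]
    for prev, cur in zip(srt, srt[1:]):
        if cur - prev > min_gap:
            bins.append([cur])
        else:
            bins[-1].append(cur)
    mapping: dict[float, int] = {}
    centers: list[int] = []
    for members in bins:
        center = int(round(float(np.mean(members))))
        centers.append(center)
        for x in members:
            mapping[x] = center
    return BinningMap(locus_name, repeat_unit, mapping, centers)
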