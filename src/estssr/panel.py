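"""Marker-panel assembly: per-species locus status grids, panel means, and
cross-species transferability.

A locus in a given species is classified P (polymorphic, >= 2 alleles),
M (monomorphic) or F (failed / not genotyped, printed as "-" in status
grids). Panel-level means and standard deviations of Na, Ho and He are
computed over polymorphic loci only, with the n-1 (sample) SD; a marker
developed in a source species counts as *transferable* when it was
successfully genotyped (P or M) in every other species of the panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .popgen import LocusStats

__all__ = ["SpeciesLocusStatus", "PanelSummary", "PanelReport", "classify", "summarize_panel"]


@dataclass(frozen=True)
class SpeciesLocusStatus:
    locus_name: str
    species_label: str
    status: str  # "P" | "M" | "F"


@dataclass(frozen=True)
class PanelSummary:
    """Per-species panel aggregates over polymorphic loci."""

    species_label: str
    n_polymorphic: int
    n_monomorphic: int
    n_failed: int
    mean_Na: float | None
    sd_Na: float | None
    mean_Ho: float | None
    sd_Ho: float | None
    mean_He: float | None
    sd_He: float | None
    na_range: tuple[int, int] | None


@dataclass(frozen=True)
class PanelReport:
    status_grid: list[SpeciesLocusStatus]
    per_species: dict[str, PanelSummary]
    n_transferable: int | None
    source_species: str | None

    def to_dict(self) -> dict:
        return {
            "source_species": self.source_species,
            "n_transferable": self.n_transferable,
            "status_grid": [
                {"locus": s.locus_name, "species": s.species_label, "status": s.status}
                for s in self.status_grid
            ],
            "per_species": {
                sp: {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(s).items()}
                for sp, s in self.per_species.items()
            },
        }


def classify(stats: LocusStats | None) -> str:
    """P/M/F status for one locus in one species (absent or failed -> F)."""
    if stats is None or stats.status == "failed" or stats.n == 0:
        return "F"
    return "M" if stats.Na == 1 else "P"


def _mean_sd(values: Sequence[float]) -> tuple[float | None, float | None]:
    if not values:
        return None, None
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else None
    return mean, sd


def summarize_panel(
    per_species_stats: Mapping[str, Mapping[str, LocusStats | None]],
    locus_names: Sequence[str],
    source_species: str | None = None,
) -> PanelReport:
    """Assemble the status grid and per-species aggregates for a panel.

    ``per_species_stats`` maps species -> locus -> LocusStats (None for a
    locus not genotyped in that species); ``locus_names`` fixes the grid's
    row order and must cover every locus. Means/SDs (n-1) are over
    polymorphic loci only; ``na_range`` is the (min, max) allele number
    among them. With a ``source_species``, ``n_transferable`` counts loci
    with status P or M in every *other* species.
    """
    grid: list[SpeciesLocusStatus] = []
    per_species: dict[str, PanelSummary] = {}
    status_by: dict[tuple[str, str], str] = {}
    for sp, stats_map in per_species_stats.items():
        poly: list[LocusStats] = []
        n_mono = n_fail = 0
        for locus in locus_names:
            st = classify(stats_map.get(locus))
            grid.append(SpeciesLocusStatus(locus, sp, st))
            status_by[(locus, sp)] = st
            if st == "P":
                poly.append(stats_map[locus])
            elif st == "M":
                n_mono += 1
            else:
                n_fail += 1
        mean_na, sd_na = _mean_sd([s.Na for s in poly])
        mean_ho, sd_ho = _mean_sd([s.Ho for s in poly])
        mean_he, sd_he = _mean_sd([s.He for s in poly])
        na_range = (
            (min(s.Na for s in poly), max(s.Na for s in poly)) if poly else None
        )
        per_species[sp] = PanelSummary(
            sp, len(poly), n_mono, n_fail,
            mean_na, sd_na, mean_ho, sd_ho, mean_he, sd_he, na_range,
        )

    n_transferable: int | None = None
    if source_species is not None:
        others = [sp for sp in per_species_stats if sp != source_species]
        n_transferable = sum(
            1
            for locus in locus_names
            if all(status_by[(locus, sp)] != "F" for sp in others)
        )
    return PanelReport(grid, per_species, n_transferable, source_species)
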