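"""Published summary data for the *Lepidonotothen nudifrons* EST-SSR panel.

These are the printed summary tables from the marker-development study of
the Gaudy notothen (*L. nudifrons*) and its congeners *L. squamifrons* and
*L. larseni*: the per-motif-class SSR/PAL counts from mining 112,477 spleen
transcripts (~128 Mb), the 16-locus cross-species status grid, and the
per-locus allele numbers and observed heterozygosities for the source
species. They serve as fixed inputs for consistency checks of the summary
machinery — the underlying transcripts and genotypes are not bundled.
"""

from __future__ import annotations

#: Transcripts screened for SSRs and their total length in bases.
TRANSCRIPTS_TOTAL = 112_477
TOTAL_BASES = 128_000_000

#: Transcripts containing an SSR, by motif length (one class per transcript).
SSR_TRANSCRIPTS_BY_MOTIF_LEN = {
    2: 35_697,
    3: 6_905,
    4: 549,
    5: 32,
    6: 23,
    7: 5,
    8: 15,
    9: 26,
    10: 17,
}

#: Potentially Amplifiable Loci (>= 8 repeat units, > 50 bp flanks), by motif length.
PAL_BY_MOTIF_LEN = {2: 478, 3: 5, 4: 1}

SPECIES = ("L_nudifrons", "L_squamifrons", "L_larseni")
SOURCE_SPECIES = "L_nudifrons"

#: 16-locus status grid: locus -> (Ln, Ls, Ll) with P/M/F (F printed as "-").
STATUS_GRID = {
    "Ln_22268": ("M", "M", "M"),
    "Ln_22517": ("P", "M", "F"),
    "Ln_23194": ("M", "P", "P"),
    "Ln_32298": ("M", "M", "M"),
    "Ln_34878": ("P", "F", "F"),
    "Ln_35217": ("P", "P", "P"),
    "Ln_36100": ("P", "M", "P"),
    "Ln_36156": ("P", "P", "P"),
    "Ln_40551": ("P", "P", "P"),
    "Ln_41246": ("M", "F", "F"),
    "Ln_41281": ("P", "P", "P"),
    "Ln_42016": ("P", "P", "P"),
    "Ln_42233": ("P", "M", "P"),
    "Ln_42701": ("M", "M", "M"),
    "Ln_45257": ("P", "P", "P"),
    "Ln_45589": ("P", "P", "P"),
}

#: Source-species (n = 21) per-locus allele number and observed
#: heterozygosity for the 11 polymorphic loci.
NUDIFRONS_POLYMORPHIC = {
    "Ln_22517": {"Na": 4, "Ho": 0.29},
    "Ln_34878": {"Na": 7, "Ho": 0.86},
    "Ln_35217": {"Na": 3, "Ho": 0.33},
    "Ln_36100": {"Na": 2, "Ho": 0.10},
    "Ln_36156": {"Na": 17, "Ho": 1.00},
    "Ln_40551": {"Na": 6, "Ho": 0.52},
    "Ln_41281": {"Na": 2, "Ho": 0.10},
    "Ln_42016": {"Na": 7, "Ho": 0.62},
    "Ln_42233": {"Na": 2, "Ho": 0.10},
    "Ln_45257": {"Na": 2, "Ho": 0.05},
    "Ln_45589": {"Na": 4, "Ho": 0.76},
}
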