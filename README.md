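# estssr

Development and characterization of EST-linked microsatellite (SSR) markers,
from a transcriptome to a genotyped, statistically characterized marker panel.

Microsatellites mined from transcribed sequence (Type I / EST-linked markers)
are a standard route to polymorphic nuclear markers in non-model organisms:
perfect tandem repeats of 2–10 bp motifs are detected in assembled
transcripts, loci with enough flanking sequence for PCR primers are selected,
and a genotyped panel is characterized with the classical single-population
statistics. `estssr` implements that whole workflow as a tested Python
library and CLI, motivated by marker panels developed for Antarctic
notothenioid fishes (*Lepidonotothen* spp.), where cross-species
transferability of the markers is a key design goal.

## What it computes

* **SSR mining** — all maximal perfect tandem repeats with a primitive motif
  of length 2–10 and ≥ 5 repeat units (configurable), each anchored at the
  leftmost base of its periodicity run; per-motif-class summaries, SSR
  density (kb per SSR) and the proportion of SSR-bearing transcripts.
* **PAL selection** — Potentially Amplifiable Loci: SSRs with > 50 bp of
  flanking sequence on each side and ≥ 8 repeat units, with exact-duplicate
  removal.
* **Genotype I/O and binning** — Genepop (2/3-digit) and long CSV readers
  and writers; a transparent gap-rule binner assigning raw capillary
  fragment sizes to integer alleles.
* **Per-locus statistics** — allele counts `Na`, observed heterozygosity
  `Ho = h/n`, unbiased expected heterozygosity
  `He = (2n/(2n−1)) (1 − Σ pᵢ²)`, the exact Hardy–Weinberg probability test
  on Levene's conditional distribution of genotype tables
  (`P(table) = n! Π aᵢ! 2^h / ((2n)! Π n_ij!)`, p = total probability of
  tables no more probable than the observed; full enumeration or seeded
  conditional Monte Carlo), maximum-likelihood null-allele frequency by EM,
  a permutation G-test of genotypic disequilibrium, and Bonferroni
  correction.
* **Panel reports** — per-species P/M/– status grids, panel means ± SD over
  polymorphic loci, and cross-species transferability counts.
* **Synthetic data** — transcriptomes with planted SSRs and genotype
  matrices with controlled inbreeding (F), null alleles and size noise,
  each with a complete ground-truth table.

## Worked example

```python
import estssr

# simulate a small transcriptome and mine it
spec = estssr.TranscriptomeSpec(n_transcripts=200, seed=1)
transcripts, truth = estssr.simulate_transcriptome(spec)
loci = [l for t in transcripts for l in estssr.find_ssrs(t)]
s = estssr.summarize_mining(transcripts, loci)
print(len(loci), s.transcripts_with_ssr, round(s.density_kb_per_ssr, 2))

# characterize one genotyped locus (21 individuals, two alleles)
sim = estssr.GenotypeSimSpec(
    "demo", 21, (estssr.LocusSimSpec("L1", 120, 2, (0.6, 0.4)),), seed=1)
matrix, _ = estssr.simulate_genotypes(sim)
c = estssr.tally(matrix, "L1")
print(c.num_alleles,
      round(estssr.observed_het(c), 3),
      round(estssr.expected_het(c), 3),
      round(estssr.hwe_exact_test(c), 4))
```

prints

```
81 80 2.74
2 0.333 0.508 0.1847
```

— 81 SSR loci found in 80 of the 200 synthetic transcripts (one SSR per
2.74 kb of sequence), and a biallelic locus with `Na = 2`, `Ho = 0.333`,
`He = 0.508` and an exact HWE p-value of 0.18 (no departure, as simulated).

The same stages are available from the shell:

```bash
estssr simulate transcriptome --seed 1 --out-prefix sim
estssr mine sim.fasta --min-units 5 --out-prefix sim
estssr pal sim.ssr.tsv sim.fasta --min-flank 50 --min-units 8
estssr simulate genotypes --seed 1 --out-prefix panel
estssr stats panel.gen --seed 42
estssr report panel.gen --source-species L_nudifrons_syn
```

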