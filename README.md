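# dietbarcoder

18S rRNA V9 metabarcoding for diet analysis — a tested re-implementation of
the full computation used to characterise the stomach contents of
zooplanktivorous fish (sardine and sprat) from short-amplicon community
sequencing.

Degraded, digested prey DNA can be profiled by amplifying the short
(~120–134 nt) V9 hypervariable region of the eukaryotic 18S rRNA gene and
sequencing it bidirectionally (MiSeq 2×150 bp paired ends, fully
overlapping the amplicon). This package provides every computational stage
of that analysis, for people who want to run it, test it, or study its
failure modes:

- **Reference database** construction and resolution analysis: amplicon
  extraction between universal primers, pairwise identity (semi-global,
  free end gaps: identity = matches/aligned columns), **synonymy groups**
  (species 100% identical over ≥64 nt — the locus's hard resolution limit)
  and **diagnostic positions** for near-identical species.
- **Read processing**: sliding-window quality trimming (Phred ≥ 20),
  quality-arbitrated paired-end merging (ungapped overlap, ≤1 mismatch,
  binomial-tail significance at p ≤ 0.01, higher-Phred base wins), exact
  12-nt tag demultiplexing, and a forward-only mode for
  bidirectional-versus-single-direction comparisons.
- **Taxonomic assignment**: exhaustive closed-reference best-identity
  search at a configurable threshold (97/99/100%), greedy abundance-ordered
  open-reference clustering of unassigned reads, OTU tables with singleton
  and predator-read removal.
- **Character-based classification**: species identification from the
  nucleotides at diagnostic alignment columns (e.g. the four clupeid fishes
  herring/sprat/sardine/anchovy, separated by three positions with tuples
  CGC/CAT/TGC/CGT), with a discrepancy report against clustering-based
  counts: (clustering − character)/clustering × 100.
- **Quantification**: expected mock-community profiles, length–biomass
  power-law conversion, within-taxon and among-taxa Pearson correlations,
  per-OTU Kruskal–Wallis replicate-consistency tests, analytic
  (hypergeometric) rarefaction.
- **Diet comparison**: >0.5% OTU filtering, square-root transformation,
  correspondence analysis by reciprocal averaging with Hill's detrending by
  segments (DCA), per-OTU Mann–Whitney U tests between predator groups.
- **Synthetic data**: a first-class simulator that plants synonymy groups,
  diagnostic-position groups, log-uniform rDNA copy numbers spanning four
  orders of magnitude, and paired reads with cycle-dependent qualities and
  quality-derived substitution errors — so the entire pipeline is testable
  end-to-end with known ground truth, including the packaged 13-species ×
  4-sample mock design (884 individuals).

See `docs/methods.md` for the model details, numerical choices and
limitations.

## Worked example

Simulate the packaged mock design under null conditions (constant rDNA
copy number, zero sequencing error), run the full pipeline — trim, merge,
primer-trim, closed-reference assignment at 99% identity — and compare
recovered read fractions to the known composition:

```python
from dietbarcoder.simulate import (
    mock_from_table1, generate_reference_for_design, simulate_copy_numbers, SimConfig,
)
from dietbarcoder.pipeline import run_mock_design, design_otu_representatives
from dietbarcoder.quantify import expected_profiles, within_taxon_correlation

design = mock_from_table1()
print("individuals:", design.total_individuals(), "| samples:", design.samples)

db = generate_reference_for_design(design, seed=1)
copy_numbers = simulate_copy_numbers(design.species, constant=True)
config = SimConfig(seed=1, reads_per_sample=5000, error_rate=0.0)
table, truth, stats = run_mock_design(design, db, copy_numbers, config, threshold=0.99)

reps = design_otu_representatives(design, db)
expected = expected_profiles(design)
rel = table.relative_abundance()
print(f"{'OTU':<28}{'expected %':>11}{'recovered %':>12}{'r':>7}")
for otu, rep in reps.items():
    j = table.otus.index(rep)
    exp_vec = [expected[s].fractions[otu] for s in table.samples]
    r, _ = within_taxon_correlation(exp_vec, rel[:, j])
    print(f"{otu:<28}{100*expected['MOCK-D'].fractions[otu]:>10.1f}{100*rel[3, j]:>12.1f}{r:>8.3f}")
```

Output:

```
individuals: 884 | samples: ['MOCK-A', 'MOCK-B', 'MOCK-C', 'MOCK-D']
OTU                          expected % recovered %      r
Meganyctiphanes norvegica         89.3        89.1   1.000
Para-Und-Euch group                7.1         7.3   1.000
Pleuromamma robusta                0.9         0.9   1.000
Candacia armata                    0.9         0.9   1.000
Calanus helgolandicus              0.9         1.0   0.997
Tomopteris spp.                    0.9         0.8   0.999
```

The 13 species collapse to 6 OTUs because eight copepod species (the
"Para-Und-Euch group") share one V9 sequence — their reads are
indistinguishable and map to a single OTU. Expected/recovered columns show
the most uneven sample (MOCK-D, 89% of individuals in one euphausiid); `r`
is each OTU's within-taxon Pearson correlation between expected and
recovered fractions across all four samples. Under null conditions
recovery is limited only by multinomial sampling noise; switching
`simulate_copy_numbers(..., orders_of_magnitude=4)` shows how rDNA
copy-number variation degrades among-taxa quantification while the
within-taxon view survives.

A CLI mirrors the library for shell use: `dietbarcoder refdb build`,
`dietbarcoder refdb synonymy`, `dietbarcoder reads process`,
`dietbarcoder assign`, `dietbarcoder chars classify`,
`dietbarcoder diet ordinate|compare`, `dietbarcoder simulate mock`
(see `--help`).

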