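# barcodekit

Distance-based DNA barcoding analysis for species identification —
built for reference libraries of the core plant barcodes (*rbcL*a,
*matK*) and for assigning degraded, processed plant material (for example
samples bought at South African *muthi* traditional-medicine markets) to
species.

## What it does

Given an aligned per-locus reference library with species labels,
`barcodekit`:

1. computes pairwise **Kimura two-parameter (K2P)** distances with
   pairwise deletion of gap/ambiguity columns,

       d = -1/2 ln[(1 - 2P - Q) √(1 - 2Q)]

   where *P* and *Q* are the observed proportions of transitions and
   transversions over the comparable sites of each pair;
2. evaluates the **barcode gap**: the partition of distances into
   intra- vs interspecific sets, a Wilcoxon rank-sum comparison, and the
   per-individual test `min(interspecific) > max(intraspecific)`;
3. **optimises an identification threshold** by grid search, scoring each
   candidate *t* with cumulative error = (records whose furthest
   conspecific lies beyond *t*) + (records whose nearest heterospecific
   lies within *t*);
4. scores three leave-one-out **identification estimators** — near
   neighbour, best close match (Meier-style), and BOLD-style
   threshold identification at a 1% cutoff;
5. matches degraded **query sequences** against the library by
   semi-global percent identity (a local stand-in for a BLAST search) and
   adjudicates each best hit against the species expected from the
   sample's vernacular name;
6. places queries on a **neighbour-joining tree** with column-bootstrap
   support (weak 50–74%, strong 75–100%).

A synthetic-data module generates reference libraries, degraded queries
and vernacular lookups with the statistical structure these analyses
assume (star phylogeny, K2P substitution process with transition /
transversion ratio κ), so the whole pipeline is testable without any
sequence downloads.

## Worked example

```python
import barcodekit as bk

cfg = bk.SyntheticConfig(
    n_species=20, individuals_per_species=3, seq_length=600,
    inter_target=0.10, intra_target=0.003, seed=1,
)
lib, truth = bk.generate_library(cfg)
m = bk.build_distance_matrix(lib)                       # K2P, pairwise deletion
intra, inter = bk.partition_distances(m, lib.species_of())
U, p = bk.wilcoxon_rank_sum(intra, inter)
t, profile = bk.optimize_threshold(m, lib.species_of())
bcm = bk.best_close_match(m, lib.species_of(), threshold=t)

print(f"library: {len(lib)} sequences, {len(set(lib.species_of().values()))} species")
print(f"mean intraspecific K2P: {intra.mean():.4f}")
print(f"mean interspecific K2P: {inter.mean():.4f}")
print(f"Wilcoxon rank-sum p:    {p:.3g}")
print(f"optimized threshold:    {t:.4f} ({100*t:.2f}%)")
print(f"best close match:       {bcm.summary['correct']:.0f}% correct")
```

prints

```
library: 60 sequences, 20 species
mean intraspecific K2P: 0.0033
mean interspecific K2P: 0.0967
Wilcoxon rank-sum p:    1.09e-39
optimized threshold:    0.0067 (0.67%)
best close match:       100% correct
```

The realized divergences sit on the generator's targets (0.3% within,
~10% between species), the rank-sum test confirms the barcode gap, the
optimised threshold falls inside the gap, and with that threshold every
specimen's nearest neighbour identifies it correctly.

The same analysis runs from the shell — `barcodekit run --seed 1 --out
out/` simulates a two-locus study-scale panel (108 species, 552 bp + 915
bp loci) and writes the per-locus distance summary (`table1.tsv`), the
efficacy table for the three estimators (`table2.tsv`), the market-query
report (`table3.tsv`), the per-individual gap table (`gaps.tsv`), and a
bootstrapped query tree (`tree.nwk`).  Subcommands (`simulate`,
`distances`, `gap`, `identify`, `optimize-threshold`, `market-id`,
`tree`) expose each stage on its own.

## Layout

```
src/barcodekit/
  core_io.py         domain types; FASTA/TSV readers and writers
  distances.py       site-pattern counts, K2P and p-distance, Tajima's K
  gap_analysis.py    intra/inter partition, Wilcoxon, per-individual gap
  identification.py  NN / BCM / threshold estimators, threshold optimiser
  query_match.py     semi-global identity, hit ranking, market reports
  tree.py            neighbour joining, column bootstrap, query placement
  synthetic_data.py  library/query/lookup generators
  pipeline.py        end-to-end orchestration
  cli.py             `barcodekit` command-line interface
  data/table3.tsv    packaged market-survey adjudication table
```

See `docs/methods.md` for the models, defaults and design decisions.
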