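# ohnorhythm

Detection of diurnal (24 h cyclic) gene expression in organ RNA-seq
time courses, and classification of how teleost whole-genome-duplication
(TGD) gene duplicates — *ohnologs* — diverged in that rhythmicity.

## Who this is for

Teleost fish genomes went through a whole-genome duplication ~375 Mya.
Each retained duplicate pair shares a single ortholog in the spotted
gar, a ray-finned fish that split off before the duplication, which
makes gar a bridge for tracing duplicate fates. Given gene × sample
read counts from organs sampled around the clock (e.g. 9 organs × 8
zeitgeber times × 2 replicates) and a Biomart-style homology export,
this package answers: which genes cycle over the day, in which organs,
with what peak time and amplitude — and for duplicated genes, whether
the two copies kept the same cyclic pattern (super-functionalization),
split it between phases or organs (sub-functionalization), or only one
copy carries it (neo-/sub-functionalization, depending on the unseen
ancestral state).

## What it computes

1. **Normalization** — cpm = counts / library size × 10⁶; replicate
   averaging per (organ, Zt); relative expression (per-timepoint mean ÷
   daily mean, so an expressed gene averages 1); a gene is *expressed*
   when cpm > 1 at ≥ 2 of the 8 timepoints.
2. **Rhythm detection** — a nonparametric umbrella rank test: for every
   candidate (peak, trough) placement on the circular Zt grid, the
   rising and falling arcs are scored by summing Mann-Whitney U counts
   over all ordered group pairs (Jonckheere–Terpstra style, ties = ½);
   per-hypothesis permutation p-values (exact ≤ 10 observations, seeded
   Monte-Carlo otherwise) are Bonferroni-combined, and a gene is cyclic
   at combined p < 0.01. Peak Zt, peak shape (hours from peak to
   minimum, circular) and amplitude (max − min relative expression)
   describe each hit.
3. **Ohnologs & singletons** — five conjunctive filters reduce paralog
   pairs to 2:1 gar relationships (no "Clupeocephala" ancestor, one
   shared gar ortholog, no gene in two pairs, chromosome-anchored,
   ≥ 5 Mbp apart on the same chromosome); four filters call 1:1
   singletons; a synteny score (fraction of a gene's 2n neighbors with
   orthologs in the candidate's 2n-gene window) resolves ambiguous
   orthology.
4. **Divergence classification** — cyclic pairs are routed to
   intra-organ (ONE_CYCLIC / BOTH_CYCLIC_SAME / BOTH_CYCLIC_DIFFERENT)
   or inter-organ (ONE_CYCLIC_MULTI / SYNCHRONIZED_MULTI /
   DIFFERENT_BY_ORGAN) scopes; multi-organ cyclic singletons are
   SYNCHRONIZED or DIFFERENT.
5. **nCounter normalization** — positive-control scaling with the
   0.3–3 qualification window, housekeeping geometric-mean
   normalization, negative-control background removal.
6. **Synthetic data** — negative-binomial count simulation with planted
   cosine rhythms and a homology-table simulator with planted pairs,
   singletons and one decoy class per filter, so every stage is
   testable with known ground truth and no downloads.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

```python
from ohnorhythm import SimulationConfig, simulate_counts, detect_rhythms

cfg = SimulationConfig(n_genes=200, organs=("eye", "liver"),
                       cyclic_fraction=0.2, amplitude_range=(0.8, 1.0),
                       seed=4)
cm, truth = simulate_counts(cfg)          # counts + planted ground truth
res = detect_rhythms(cm, n_perm=10_000, seed=1)
print(res[res["is_cyclic"]].head(5).to_string(index=False))
```

```
gene_id organ  expressed  statistic  s_max  p_value  peak_zt  peak_shape  amplitude  is_cyclic  degenerate
 G00007   eye       True         95    116 0.005599      3.5          21     0.5214       True       False
 G00010   eye       True         79     84 0.005599     15.5          15      1.585       True       False
 G00013   eye       True         86     96 0.005599     21.5          12      2.442       True       False
 G00015   eye       True         74     80 0.005599     21.5           9      1.918       True       False
 G00019   eye       True         77     84 0.005599     21.5          12      1.782       True       False
```

Reading the first row: in eye, gene G00007's umbrella statistic reached
95 of a possible 116 concordances; no better score occurred often enough
among 10,000 permutations, so the Bonferroni-combined p-value is
56/10,001 ≈ 0.0056 < 0.01 and the gene is called cyclic. It peaks at
Zt 3.5 (3.5 h after lights-on), takes 21 h to reach its minimum, and
swings 0.52 relative-expression units peak-to-trough. In this run 41 of
200 eye genes and 36 of 200 liver genes are called cyclic against 40
planted per organ.

The same pipeline runs from the shell:

```sh
ohnorhythm simulate expression --seed 4 --out sim/
ohnorhythm simulate homology  --seed 4 --out sim/
ohnorhythm report --counts sim/counts.tsv --samples sim/samples.tsv \
    --homology sim/homology.tsv --seed 1 --out results/
ohnorhythm query --counts sim/counts.tsv --samples sim/samples.tsv \
    --gene G00007 --plots plots/
```

`report` writes per-stage TSVs (rhythm results, ohnolog pairs,
singletons, divergence calls) plus `summary.json` with per-organ
expressed/cyclic counts, homology tallies and divergence tables;
`query` prints the per-gene browser view and optionally saves the two
SVG panels (mean cpm per organ; relative expression over the day).

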