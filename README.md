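# cvtree

Whole-genome, alignment-free prokaryotic phylogeny from K-peptide
composition vectors, with a taxonomy-reconciliation layer.

## The problem

Single-gene phylogenies (16S rRNA above all) depend on alignable markers
and struggle with lateral gene transfer, and they cannot place organisms
that lack validly published names. An alternative is to compare *whole
proteomes*: count every length-K amino-acid window (*K-peptide*) in all
protein products of a genome, subtract the part of the spectrum that a
(K−2)-order Markov model predicts from shorter words (the neutral
background), and keep the selection-shaped residual as a sparse
*composition vector*

```
a(s) = (f_K(s) − f0(s)) / f0(s),
f0(s) = f_{K−1}(a1…a_{K−1}) · f_{K−1}(a2…aK) / f_{K−2}(a2…a_{K−1})
```

Genomes are compared by the cosine `C` of their vectors, turned into a
dissimilarity `D = (1 − C)/2 ∈ [0, 1]`, and the matrix feeds Saitou–Nei
neighbor joining. Because there are no alignment columns, statistical
support comes from resampling whole protein products per genome
(bootstrap over the proteome as a sampling pool).

The second half of the package reconciles trees with a rank-labeled
taxonomy (`<D><P><C><O><F><G><S>` lineages): monophyly tests, collapsing
branches to rank-labeled leaves with `{m}`, `{m+n}` (m complete + n
incompletely classified genomes) and `{k/m}` (split taxon) bookkeeping,
per-K "convergence statistics" reports, and trial lineage-modification
rules. A synthetic proteome evolver makes the whole pipeline testable
against a known truth tree — no downloads needed.

This package is for people who build or study alignment-free phylogenies
and for teaching/benchmarking: it is a faithful, tested reimplementation
of the method at library scale, not a web service.

## Worked example

Simulate six genomes down a random tree, then run the pipeline at
K = 5 and 6:

```
$ cvtree simulate --leaves 6 --seed 7 --out demo --proteins 80
$ cvtree run --manifest demo/manifest.tsv --lineages demo/lineages.tsv \
             -K 5 -K 6 --out out --seed 7
```

`out/` now holds per-K PHYLIP matrices, Newick trees, collapsed trees per
rank, and the convergence report. The report begins:

```
<D>SimDomain{6} K5 K6
<P>Pclade1{3} K5 K6
<P>Pclade6{3} K5 K6
<C>Cclade3{2} K5 K6
```

Each row is one taxon: `<P>Pclade1{3}` is a phylum with 3 members, and
the `K5 K6` slots say its members form a single branch in both trees (a
non-monophyletic taxon would show `-` in that slot). The K = 6 tree

```
(g4:0.138,(g3:0.155,(g1:0.125,g5:0.119):0.061):0.084,(g2:0.136,g6:0.137):0.039);
```

recovers the simulated truth topology exactly. The collapsed phylum view

```
(<P>Pclade1{1/3}:0.138,<P>Pclade6{3}:0.084,<P>Pclade1{2/3}:0.039);
```

shows the `{k/m}` convention: `Pclade1` straddles the arbitrary storage
root of the unrooted tree, so the *display* splits it into parts of 1 and
2 of its 3 members even though the convergence report (which tests
unrooted bipartitions) correctly calls it monophyletic. Rooting with
`--outgroup` removes the artifact.

Stage-by-stage subcommands (`count`, `cv`, `dist`, `nj`, `collapse`,
`report`, `modify`) expose every intermediate; `cvtree run` is their
composition. Library use mirrors the CLI:

```python
from cvtree import simulate_dataset, build_tree, rf_distance
proteomes, truth, lineages = simulate_dataset(12, seed=1)
tree = build_tree(list(proteomes.values()), K=6)
assert rf_distance(tree, truth) == 0
```

See `docs/methods.md` for the model, parameter defaults, the frozen
simulation regime, and known limitations.

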