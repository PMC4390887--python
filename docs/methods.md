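# Methods

## The model

`cvtree` compares whole proteomes without alignment. A genome is reduced
to the multiset of its length-K amino-acid windows (*K-peptides*),
counted over every protein product independently (windows never span
protein boundaries, and windows containing a non-standard letter are
dropped from both counts and totals). With `f_K(s) = n(s)/T_K` the
observed frequency of peptide `s = a1…aK` and `T_K` the number of counted
windows of length K, the expected frequency under a (K−2)-order Markov
model is

```
f0(s) = f_{K-1}(a1…a_{K-1}) · f_{K-1}(a2…aK) / f_{K-2}(a2…a_{K-1})
```

and the stored component is the relative deviation

```
a(s) = (f_K(s) − f0(s)) / f0(s)        (a(s) = 0 where f0(s) = 0)
```

Subtracting the Markov background removes the part of the K-peptide
spectrum predictable from shorter words — the shared signature of neutral
mutation pressure — and leaves the selection-shaped residual. Two genomes
A, B are compared by the cosine of their composition vectors,

```
C(A,B) = Σ_s a_A(s) a_B(s) / (‖a_A‖ ‖a_B‖),     D(A,B) = (1 − C)/2 ∈ [0,1],
```

and the pairwise `D` matrix feeds Saitou–Nei neighbor joining.

Assumptions worth stating plainly: the dissimilarity is *not* an
evolutionary distance — it saturates with divergence, so branch lengths
are reported but not interpreted as time, and tree topology is the object
of interest. Monophyly of a taxon is evaluated on the *unrooted* tree as
the existence of an edge whose bipartition isolates exactly the taxon's
members; with an outgroup supplied the tree can be rooted first, but no
rooting is required for the reconciliation layer.

## Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| `K` | peptide length (residues) | 6 | K = 5–6 is the resolution sweet spot for prokaryotic proteomes; supported range 3–9 |
| `extended` | store unobserved-but-predicted peptides (`a = −1`) | off | the cosine is dominated by shared observed peptides; the flag exists for sensitivity checks |
| `B` | bootstrap replicates | 0 (off) | resampling whole protein products; there are no alignment columns to resample |
| `seed` | RNG seed | 0 | replicate RNGs are derived from `(seed, replicate, genome index)` so runs are reproducible and parallelizable |

Neighbor joining breaks Q-criterion ties by the smallest (row, column)
index pair, making the output deterministic for any input. Negative
branch-length estimates (possible for non-additive input) are kept
internally and clamped to zero only in written artifacts, with the
clamped total recorded in the run log.

## Taxonomy reconciliation

Lineages are one line per genome, `<D>…<P>…<C>…<O>…<F>…<G>…<S>…`, with
`Unclassified` marking missing ranks; a lineage is *complete* when all of
D..S are proper names. Only complete lineages define taxa: genomes with
incomplete lineages never make or break monophyly, but they surface in
collapsed labels through the `{m+n}` convention (m complete + n
incomplete members of a branch). Collapsing replaces every maximal branch
whose classified members share one taxon at the chosen rank by a single
leaf `<R>Name{m}`; a taxon scattered over several branches yields leaves
`<R>Name{k/m}` with the parts k summing to the taxon size m; a branch
with no classified member at the rank is labeled at the deepest higher
rank its members share (`<P>Name{0+n}`). The convergence report prints
one row per (rank, taxon) with one slot per configured K — `K5` when the
taxon is monophyletic in the K=5 tree, `-` otherwise — over a default
range of K = 3..7. Lineage-modification rules `old_fragment new_fragment`
rewrite exactly the ranks they name, on every genome matching all pairs
of the old fragment; zero matches is an error rather than a no-op.

## The synthetic data generator

The simulator exists to make every stage testable against a known truth.
It draws a root proteome i.i.d. uniform over the 20 amino acids (protein
lengths Normal(500, 100), truncated at 30) and evolves it down a binary
tree: per branch of length t each site substitutes with probability
1 − exp(−t) to a uniformly chosen different residue; optional whole-protein
loss and duplication model gene-content variation (defaults 0). Lineages
are read off the truth tree's clades, so every taxon is monophyletic by
construction, and an injection helper blanks ranks below a random cut to
emulate incompletely classified genomes.

What the generator does **not** emulate: amino-acid exchange biases,
among-site and among-lineage rate variation, indels, domain shuffling,
lateral transfer, or compositional (GC-translation) skew. Passing the
recovery tests therefore demonstrates correctness of the pipeline
machinery and the internal consistency of the method under its own
assumptions — not performance on real genomes.

### The frozen recovery regime

The end-to-end studies use 12-leaf random trees with branch lengths drawn
uniformly from [0.03, 0.045] at substitution rate 1.0, and 400 proteins
per genome (roughly 2 × 10⁵ residues). This band was calibrated once and
then frozen. Both ends matter: because D saturates with divergence, deep
trees distort additivity and neighbor joining starts mis-resolving; and
internal edges much shorter than ≈ 0.03 expected substitutions per site
fall below the resolution of the substitution-realization noise at this
proteome size. Within the band, topology recovery at K = 5 and K = 6 was
100/100 and 100/100 on one 100-seed window and 100/100 and 99/100 on a
second, disjoint window, and protein-bootstrap supports on true
bipartitions are ≈ 1.0 at B = 100.

## Numerical choices

* Peptides are base-20 integer codes in sorted arrays; counting,
  subtraction and sparse dot products are vectorized, and the
  string-keyed dictionaries in the API are materialized views.
* The cosine's dot product runs over the intersection of stored keys,
  which is exact because absent components are zero by construction;
  norms are per-vector over the full stored set. `D` is clipped to
  [0, 1] against floating-point excursions; no other tolerance is applied
  to the matrix.
* An observed K-peptide always has observed prefix, suffix and middle
  words, so `f0 > 0` for every stored observed component — the code
  asserts this instead of special-casing it.
* Degenerate inputs fail loudly: a proteome with no countable window, a
  zero-norm vector, or a bootstrap replicate that loses every window
  raises a typed error (the replicate case is redrawn and counted).
* PHYLIP matrices are written with 10 significant digits, which is what
  makes write→read a floating-point round-trip.

## Known limitations

* The dissimilarity is not additive; no distance correction is applied,
  by design. Very divergent or very compositionally biased genome sets
  may mis-resolve short deep branches.
* Monophyly is bipartition existence on the unrooted tree; rooted-clade
  semantics require supplying an outgroup.
* Collapsing operates on the tree as displayed (arbitrarily rooted for
  storage), so a taxon that straddles the storage root appears as
  `{k/m}` parts even when the convergence report correctly calls it
  monophyletic on the unrooted tree. Rooting by outgroup before
  collapsing removes the artifact.
* The jackknife variant subsamples a fixed fraction of proteins without
  replacement behind the bootstrap interface; no separate jackknife
  statistics are computed.
* Tiny proteomes (tens of proteins) produce noisy vectors at K ≥ 6; the
  counting itself remains exact.
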