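"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's vectorized code paths:
counting is naive substring enumeration, the composition vector is direct
dictionary arithmetic, cosines are computed densely over the union key
set, and tree bipartitions come from flood-filling an explicit adjacency
graph. They are slow and transparent on purpose.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np
import pytest

from cvtree import Lineage, Proteome, SimParams, simulate_dataset
from cvtree.composition import AMINO_ACIDS

# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def naive_count(proteins: list[str], K: int) -> tuple[dict[str, int], int]:
    """Substring-enumeration K-peptide counting oracle."""
    counts: Counter[str] = Counter()
    for p in proteins:
        for i in range(len(p) - K + 1):
            w = p[i : i + K]
            if all(c in AMINO_ACIDS for c in w):
                counts[w] += 1
    return dict(counts), sum(counts.values())


def naive_cv(proteins: list[str], K: int, extended: bool = False) -> dict[str, float]:
    """Dense dictionary-arithmetic composition-vector oracle."""
    cK, tK = naive_count(proteins, K)
    c1, t1 = naive_count(proteins, K - 1)
    c2, t2 = naive_count(proteins, K - 2)
    f1 = {s: c / t1 for s, c in c1.items()}
    f2 = {s: c / t2 for s, c in c2.items()}

    def f0(s: str) -> float:
        mid = f2.get(s[1:-1], 0.0)
        if mid == 0.0:
            return 0.0
        return f1.get(s[:-1], 0.0) * f1.get(s[1:], 0.0) / mid

    out: dict[str, float] = {}
    for s, c in cK.items():
        b = f0(s)
        out[s] = (c / tK - b) / b
    if extended:
        for p, q in itertools.product(c1, repeat=2):
            if p[1:] == q[:-1]:
                s = p + q[-1]
                if s not in out and f0(s) > 0:
                    out[s] = -1.0
    return out


def dense_cosine(u: dict[str, float], v: dict[str, float]) -> float:
    """Cosine over the union key set with absent entries as zero."""
    keys = set(u) | set(v)
    dot = math.fsum(u.get(k, 0.0) * v.get(k, 0.0) for k in keys)
    nu = math.sqrt(math.fsum(x * x for x in u.values()))
    nv = math.sqrt(math.fsum(x * x for x in v.values()))
    return dot / (nu * nv)


def adjacency_bipartitions(tree) -> set[frozenset[str]]:
    """Edge-enumeration bipartition oracle via explicit flood fill."""
    nodes = list(tree.traverse(include_self=True))
    idx = {id(n): i for i, n in enumerate(nodes)}
    edges = []
    adj: dict[int, set[int]] = {i: set() for i in range(len(nodes))}
    for n in nodes:
        for c in n.children:
            i, j = idx[id(n)], idx[id(c)]
            adj[i].add(j)
            adj[j].add(i)
            edges.append((i, j))
    leaves = {idx[id(t)]: t.name for t in tree.tips()}
    all_leaves = frozenset(leaves.values())
    ref = min(all_leaves)
    out = set()
    for i, j in edges:
        # flood from j with edge (i, j) removed
        seen = {j}
        stack = [j]
        while stack:
            k = stack.pop()
            for m in adj[k]:
                if (k, m) in ((i, j), (j, i)) or m in seen:
                    continue
                seen.add(m)
                stack.append(m)
        side = frozenset(leaves[k] for k in seen if k in leaves)
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(side if ref not in side else all_leaves - side)
    return out


def random_proteome(
    rng: np.random.Generator, genome_id: str = "g", n_proteins: int = 10,
    length: int = 60,
) -> Proteome:
    proteins = [
        "".join(rng.choice(list(AMINO_ACIDS), size=max(3, int(L))))
        for L in rng.normal(length, length / 4, n_proteins)
    ]
    return Proteome(genome_id=genome_id, proteins=proteins)


def make_lineage(**names: str) -> Lineage:
    """Complete lineage with given ranks overridden (lowercase kwargs)."""
    defaults = dict(
        D="Archaea", P="Phy", C="Cls", O="Ord", F="Fam", G="Gen", S="Sp"
    )
    defaults.update({k.upper(): v for k, v in names.items()})
    return Lineage.from_pairs([(c, defaults[c]) for c in "DPCOFGS"])


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


#: small, fast simulation settings for unit tests (the acceptance tests
#: use the frozen study-condition defaults instead)
SMALL_SIM = SimParams(n_proteins=60, length_mean=150, length_sd=30)


@pytest.fixture(scope="session")
def small_dataset():
    """8-leaf simulated dataset shared by unit tests (read-only)."""
    return simulate_dataset(8, seed=11, params=SMALL_SIM)
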