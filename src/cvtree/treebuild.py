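"""Tree construction: neighbor joining, bootstrap supports, rooting.

The tree-building step is Saitou–Nei neighbor joining with the
Studier–Keppler O(N^3) update. NJ is exactly consistent on additive
(tree-metric) matrices, which is what the test suite exploits. Ties in the
Q-criterion are broken by the smallest (row, column) index pair so the
output is deterministic.

Because composition vectors are not site-based, there are no alignment
columns to resample: bootstrap replicates instead resample each genome's
*protein products* with replacement (to the original proteome size,
independently per genome) and rerun the whole vector → distance → NJ
pipeline. Supports on the point-estimate tree are the fraction of
replicates whose tree contains each internal bipartition. A jackknife
variant (subsampling proteins without replacement) is available behind the
same interface.

Negative NJ branch-length estimates are retained internally and clamped to
zero only for output, with the clamped amount reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from skbio import TreeNode

from .composition import proteome_to_cv
from .dissimilarity import distance_matrix
from .errors import DegenerateDataError, UsageError
from .io import DistMatrix, Proteome

__all__ = [
    "neighbor_joining",
    "clamp_negative_branch_lengths",
    "bipartitions",
    "rf_distance",
    "patristic_matrix",
    "bootstrap_support",
    "BootstrapResult",
    "root_by_outgroup",
    "build_tree",
]


def neighbor_joining(matrix: DistMatrix) -> TreeNode:
    """Build an unrooted NJ tree from a distance matrix.

    The result has N leaves and N-2 internal nodes (the storage root is
    the final trifurcation). Raw branch-length estimates are kept, so
    additive input matrices are reproduced exactly; negative estimates are
    only clamped by :func:`clamp_negative_branch_lengths`.
    """
    n = len(matrix.labels)
    if n < 3:
        raise UsageError(f"neighbor joining needs >= 3 taxa, got {n}")
    if np.any(matrix.values < 0):
        raise UsageError("distance matrix has negative entries")
    d = matrix.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in matrix.labels]

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        # Q(i,j) = (m-2) d_ij - r_i - r_j ; first strict minimum in
        # row-major (i<j) order wins, which fixes the tie-break
        best = (math.inf, -1, -1)
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best[0]:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.extend([nodes[i], nodes[j]])
        # Studier–Keppler distance update to the new node
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.empty((m - 1, m - 1))
        d_new[: m - 2, : m - 2] = d[np.ix_(keep, keep)]
        d_new[: m - 2, m - 2] = dk[keep]
        d_new[m - 2, : m - 2] = dk[keep]
        d_new[m - 2, m - 2] = 0.0
        d = d_new
        nodes = [nodes[k] for k in keep] + [parent]

    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = 0.5 * (dab + dac - dbc)
    b.length = 0.5 * (dab + dbc - dac)
    c.length = 0.5 * (dac + dbc - dab)
    root = TreeNode()
    root.extend([a, b, c])
    return root


def clamp_negative_branch_lengths(tree: TreeNode) -> tuple[TreeNode, float, int]:
    """Copy the tree with negative branch lengths set to 0.

    Returns ``(copy, total_amount_clamped, n_branches_clamped)``.
    """
    out = tree.copy()
    total, count = 0.0, 0
    for node in out.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            total += -node.length
            count += 1
            node.length = 0.0
    return out, total, count


# ---------------------------------------------------------------------------
# Bipartitions / Robinson-Foulds
# ---------------------------------------------------------------------------


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree.

    Each internal edge is represented by its canonical side: the side NOT
    containing the lexicographically smallest leaf. Trivial splits (single
    leaf / full set) are excluded.
    """
    leaves = frozenset(t.name for t in tree.tips())
    ref = min(leaves)
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) <= 1 or len(side) >= len(leaves) - 1:
            continue
        if ref in side:
            side = leaves - side
        out.add(side)
    return out


def rf_distance(t1: TreeNode, t2: TreeNode) -> int:
    """Robinson–Foulds distance (symmetric difference of bipartitions)."""
    l1 = {t.name for t in t1.tips()}
    l2 = {t.name for t in t2.tips()}
    if l1 != l2:
        raise UsageError("trees have different leaf sets")
    return len(bipartitions(t1) ^ bipartitions(t2))


def patristic_matrix(tree: TreeNode) -> DistMatrix:
    """Leaf-to-leaf path-length (additive) distance matrix of a tree."""
    labels = sorted(t.name for t in tree.tips())
    tipmap = {t.name: t for t in tree.tips()}
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist = tipmap[labels[i]].distance(tipmap[labels[j]])
            values[i, j] = values[j, i] = dist
    return DistMatrix(labels=labels, values=values)


# ---------------------------------------------------------------------------
# Pipeline helpers
# ---------------------------------------------------------------------------


def build_tree(
    proteomes: Sequence[Proteome], K: int, *, extended: bool = False
) -> TreeNode:
    """Composition vectors → dissimilarity matrix → NJ tree."""
    vectors = [proteome_to_cv(p, K, extended=extended) for p in proteomes]
    return neighbor_joining(distance_matrix(vectors))


# ---------------------------------------------------------------------------
# Bootstrap / jackknife over whole protein products
# ---------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    """Point-estimate tree with per-bipartition supports attached."""

    tree: TreeNode
    supports: dict[frozenset[str], float]
    n_replicates: int
    n_redrawn: int = 0

    def min_support(self) -> float:
        return min(self.supports.values()) if self.supports else 1.0


def _resample_proteins(
    proteome: Proteome, rng: np.random.Generator, method: str, fraction: float
) -> Proteome:
    n = proteome.n_proteins
    if method == "bootstrap":
        idx = rng.integers(0, n, size=n)
    elif method == "jackknife":
        k = max(1, int(round(fraction * n)))
        idx = rng.choice(n, size=k, replace=False)
    else:
        raise UsageError(f"unknown resampling method {method!r}")
    return Proteome(
        genome_id=proteome.genome_id,
        proteins=[proteome.proteins[i] for i in idx],
        source=proteome.source,
    )


def bootstrap_support(
    proteomes: Sequence[Proteome],
    K: int,
    B: int,
    seed: int,
    *,
    extended: bool = False,
    method: str = "bootstrap",
    jackknife_fraction: float = 0.5,
    resample_hook: Callable[[Proteome, np.random.Generator], Proteome] | None = None,
) -> BootstrapResult:
    """Attach resampling supports to the point-estimate NJ tree.

    Each replicate resamples every genome's protein list with replacement
    to its original size, with an RNG seeded deterministically from
    ``(seed, replicate, genome_index)``, then reruns the full pipeline.
    Replicates in which some genome loses every countable window are
    rejected and redrawn (the redraw count is reported).

    ``resample_hook`` replaces the per-genome resampler (test hook, e.g.
    identity resampling).
    """
    if B < 1:
        raise UsageError(f"B must be >= 1, got {B}")
    point = build_tree(proteomes, K, extended=extended)
    target = bipartitions(point)
    hits: dict[frozenset[str], int] = {bp: 0 for bp in target}
    n_redrawn = 0
    for rep in range(B):
        for attempt in range(100):
            try:
                rep_proteomes = []
                for gi, p in enumerate(proteomes):
                    rng = np.random.default_rng([seed, rep, gi, attempt])
                    if resample_hook is not None:
                        rep_proteomes.append(resample_hook(p, rng))
                    else:
                        rep_proteomes.append(
                            _resample_proteins(p, rng, method, jackknife_fraction)
                        )
                rep_tree = build_tree(rep_proteomes, K, extended=extended)
            except DegenerateDataError:
                n_redrawn += 1
                continue
            break
        else:
            raise DegenerateDataError(
                f"bootstrap replicate {rep} degenerate after 100 redraws"
            )
        rep_bps = bipartitions(rep_tree)
        for bp in target:
            if bp in rep_bps:
                hits[bp] += 1

    supports = {bp: hits[bp] / B for bp in target}
    leaves = frozenset(t.name for t in point.tips())
    ref = min(leaves)
    for node in point.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = leaves - side
        if side in supports:
            node.support = supports[side]
            node.name = f"{supports[side]:.3f}"
    return BootstrapResult(
        tree=point, supports=supports, n_replicates=B, n_redrawn=n_redrawn
    )


# ---------------------------------------------------------------------------
# Rooting
# ---------------------------------------------------------------------------


def root_by_outgroup(tree: TreeNode, outgroup_labels: set[str]) -> TreeNode:
    """Root the tree on the edge separating the outgroup from the rest.

    The outgroup must be a proper nonempty subset of the leaves and must
    form one side of a bipartition of the unrooted tree.
    """
    leaves = {t.name for t in tree.tips()}
    outgroup = set(outgroup_labels)
    unknown = outgroup - leaves
    if unknown:
        raise UsageError(f"outgroup leaves not in tree: {sorted(unknown)}")
    if not outgroup or outgroup == leaves:
        raise UsageError("outgroup must be a proper nonempty subset of leaves")
    # the outgroup is a bipartition side iff it or its complement appears
    # as some node's tip set on the (arbitrarily rooted) storage tree
    sides = set()
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            sides.add(frozenset([node.name]))
        else:
            sides.add(frozenset(t.name for t in node.tips()))
    og = frozenset(outgroup)
    if og not in sides and (frozenset(leaves) - og) not in sides:
        violating = sorted(outgroup)
        raise UsageError(
            f"outgroup does not form a bipartition side: {violating}"
        )
    return tree.root_by_outgroup(sorted(outgroup), branch_attrs=[])
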