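"""Synthetic proteome evolution along a known tree.

The generator exists so the whole pipeline — counting, subtraction,
distances, NJ, bootstrap, collapsing, reporting — can be exercised and
validated against a known truth without downloading genomes. The model is
intentionally simple and analyzable:

* the root proteome is drawn i.i.d. uniform over the 20 amino acids, with
  protein lengths ~ Normal(length_mean, length_sd) truncated below;
* along each branch of length t, each site substitutes independently with
  probability 1 - exp(-rate * t), to a uniformly chosen *different*
  residue (a Jukes–Cantor-style uniform exchange, no rate matrix);
* optionally, whole proteins are lost or duplicated per branch with fixed
  probabilities, emulating gene-content variation; a leaf is guaranteed
  at least one surviving protein.

Everything is deterministic given the seed. A pluggable substitution
model hook is defined (``mutate_fn``), but only the uniform model ships.

No claim of realism is made: there are no indels, no domain shuffling, no
among-site rate variation, and no lateral transfer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Mapping

import numpy as np
from skbio import TreeNode

from .composition import AMINO_ACIDS
from .errors import UsageError
from .io import LINEAGE_RANKS, UNCLASSIFIED, Lineage, Proteome

__all__ = [
    "SimParams",
    "EASY_REGIME",
    "random_tree",
    "simulate",
    "simulate_dataset",
    "lineages_from_tree",
    "inject_unclassified",
]

_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)


@dataclass(frozen=True)
class SimParams:
    """Generator settings.

    substitution_rate is the expected number of substitutions per site per
    unit branch length; loss_prob / dup_prob are per-protein, per-branch
    whole-protein event probabilities.
    """

    n_proteins: int = 400
    length_mean: float = 500.0
    length_sd: float = 100.0
    substitution_rate: float = 1.0
    loss_prob: float = 0.0
    dup_prob: float = 0.0
    seed: int = 0
    min_length: int = 30

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise UsageError("n_proteins must be >= 1")
        for name in ("loss_prob", "dup_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise UsageError(f"{name} must be in [0, 1], got {v}")
        if self.substitution_rate < 0:
            raise UsageError("substitution_rate must be >= 0")
        if self.length_mean <= 0 or self.length_sd < 0:
            raise UsageError("bad protein-length parameters")


#: Divergence regime used by the end-to-end recovery studies: branch
#: lengths drawn uniformly from this narrow band at substitution rate 1
#: give per-branch site-change probabilities of about 3-4.4%. The band is
#: deliberately narrow and shallow: the cosine dissimilarity saturates
#: with divergence, so deep trees distort additivity, while internal
#: edges much shorter than ~0.03 fall below the resolution of the
#: substitution-realization noise at this proteome size.
EASY_REGIME = {"blen_min": 0.03, "blen_max": 0.045}


def random_tree(
    n_leaves: int,
    seed: int | np.random.Generator,
    blen_min: float = EASY_REGIME["blen_min"],
    blen_max: float = EASY_REGIME["blen_max"],
    prefix: str = "g",
) -> TreeNode:
    """Random binary tree with uniform branch lengths, leaves g1..gN."""
    if n_leaves < 3:
        raise UsageError("need >= 3 leaves")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    nodes = [TreeNode(name=f"{prefix}{i + 1}") for i in range(n_leaves)]
    for node in nodes:
        node.length = float(rng.uniform(blen_min, blen_max))
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=float(rng.uniform(blen_min, blen_max)))
        parent.extend([nodes[i], nodes[j]])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(parent)
    root = TreeNode()
    root.extend(nodes)
    return root


def _mutate_uniform(
    seqs: list[np.ndarray], t: float, rate: float, rng: np.random.Generator
) -> list[np.ndarray]:
    p = 1.0 - np.exp(-rate * t)
    out = []
    for s in seqs:
        s = s.copy()
        mask = rng.random(s.shape[0]) < p
        k = int(mask.sum())
        if k:
            # uniform over the 19 other residues: add 1..19 mod 20
            s[mask] = (s[mask] + rng.integers(1, 20, size=k)) % 20
        out.append(s)
    return out


def simulate(
    tree: TreeNode,
    params: SimParams,
    mutate_fn: Callable[
        [list[np.ndarray], float, float, np.random.Generator], list[np.ndarray]
    ] = _mutate_uniform,
) -> tuple[dict[str, Proteome], TreeNode]:
    """Evolve proteomes down a tree; returns (leaf proteomes, truth tree).

    Fully deterministic given ``params.seed`` (the RNG is consumed in a
    fixed preorder traversal).
    """
    for node in tree.traverse(include_self=False):
        if node.length is None or node.length <= 0:
            raise UsageError("tree must have positive branch lengths")
    rng = np.random.default_rng(params.seed)
    lengths = np.maximum(
        params.min_length,
        np.rint(
            rng.normal(params.length_mean, params.length_sd, params.n_proteins)
        ).astype(int),
    )
    root_seqs = [rng.integers(0, 20, size=int(L)).astype(np.int64) for L in lengths]

    proteomes: dict[str, Proteome] = {}

    def descend(node: TreeNode, seqs: list[np.ndarray]) -> None:
        for child in node.children:
            cs = mutate_fn(seqs, child.length, params.substitution_rate, rng)
            if params.loss_prob > 0 or params.dup_prob > 0:
                survived: list[np.ndarray] = []
                for s in cs:
                    if rng.random() < params.loss_prob:
                        continue
                    survived.append(s)
                    if rng.random() < params.dup_prob:
                        survived.append(s.copy())
                if not survived:
                    warnings.warn(
                        "all proteins lost on a branch; keeping one at random"
                    )
                    survived = [cs[int(rng.integers(0, len(cs)))]]
                cs = survived
            if child.is_tip():
                proteomes[child.name] = Proteome(
                    genome_id=child.name,
                    proteins=[bytes(_AA[s]).decode("ascii") for s in cs],
                    source="synthetic",
                )
            else:
                descend(child, cs)

    descend(tree, root_seqs)
    return proteomes, tree.copy()


# ---------------------------------------------------------------------------
# Lineages for synthetic data
# ---------------------------------------------------------------------------


def lineages_from_tree(tree: TreeNode, domain: str = "SimDomain") -> dict[str, Lineage]:
    """Assign complete rank-labeled lineages from the truth tree's clades.

    Rank P is defined by the ancestor clade at depth 1, C at depth 2, and
    so on down to G; leaves shallower than a depth simply keep their own
    clade. Species names are unique per leaf, so every lineage is
    complete and every rank's taxa are by construction monophyletic on
    the truth tree.
    """
    # enumerate internal nodes in preorder for stable clade naming
    clade_id: dict[int, int] = {}
    for i, node in enumerate(tree.traverse(include_self=True)):
        clade_id[id(node)] = i
    out: dict[str, Lineage] = {}
    for tip in tree.tips():
        ancestry = [tip] + list(tip.ancestors())  # tip ... root
        path = ancestry[::-1]  # root ... tip
        pairs = [("D", domain)]
        for depth, rank in enumerate(("P", "C", "O", "F", "G"), start=1):
            node = path[depth] if depth < len(path) else tip
            pairs.append((rank, f"{rank}clade{clade_id[id(node)]}"))
        pairs.append(("S", f"Sp_{tip.name}"))
        out[tip.name] = Lineage.from_pairs(pairs)
    return out


def inject_unclassified(
    lineages: Mapping[str, Lineage], fraction: float, seed: int
) -> dict[str, Lineage]:
    """Blank ranks below a random cut for a seeded subset of genomes.

    Each genome is hit independently with probability ``fraction``; a hit
    genome gets a cut rank drawn uniformly from P..S and that rank and
    everything below it replaced by ``Unclassified``.
    """
    if not 0.0 <= fraction <= 1.0:
        raise UsageError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out: dict[str, Lineage] = {}
    for gid in lineages:  # preserve insertion order; rng order is fixed
        lin = lineages[gid]
        if fraction > 0 and rng.random() < fraction:
            cut = int(rng.integers(1, len(LINEAGE_RANKS)))  # P..S
            repl = {c: UNCLASSIFIED for c in LINEAGE_RANKS[cut:]}
            out[gid] = lin.with_names(repl)
        else:
            out[gid] = lin
    return out


def simulate_dataset(
    n_leaves: int,
    seed: int,
    params: SimParams | None = None,
    unclassified_fraction: float = 0.0,
) -> tuple[dict[str, Proteome], TreeNode, dict[str, Lineage]]:
    """One-call fixture: (proteomes, truth tree, lineages).

    The tree topology/lengths use ``seed``; evolution uses ``seed + 1``
    (kept below 2**31); optional unclassified injection uses ``seed + 2``.
    """
    base = SimParams() if params is None else params
    params = replace(base, seed=(seed + 1) % (2**31))
    tree = random_tree(n_leaves, seed)
    proteomes, truth = simulate(tree, params)
    lineages = lineages_from_tree(truth)
    if unclassified_fraction > 0:
        lineages = inject_unclassified(
            lineages, unclassified_fraction, (seed + 2) % (2**31)
        )
    return proteomes, truth, lineages
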