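"""Reconciling a tree with a rank-labeled taxonomy.

This layer answers, for a tree whose leaves are genome ids and a table of
rank-labeled lineages:

* *monophyly* — does a taxon's full membership occupy exactly one side of
  some edge of the unrooted tree? (Singletons and the full leaf set are
  trivially monophyletic.)
* *collapsing* — replace every maximal branch whose classified members all
  belong to one taxon at a chosen rank by a single labeled leaf
  ``<R>Name{m}``. Genomes with an incomplete lineage (one or more
  Unclassified ranks) never define or break a taxon; when they sit inside
  such a branch they are absorbed and surfaced via the ``{m+n}``
  convention. A taxon scattered over several maximal branches yields
  leaves labeled ``{k/m}`` with the parts summing to the taxon size.
* *convergence statistics* — a per-taxon, per-K report of monophyly
  across trees built at different peptide lengths, e.g.
  ``<D>Archaea{165} - - K5 K6 K7`` (monophyletic at K=5,6,7 but not 3,4).
* *lineage modification* — a rewrite rule ``old_fragment new_fragment``
  applied to every lineage matching the old fragment, for testing trial
  reclassifications before re-collapsing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from skbio import TreeNode

from .errors import InputError, UsageError
from .io import LINEAGE_RANKS, UNCLASSIFIED, Lineage

__all__ = [
    "CollapsedLeaf",
    "ConvergenceReport",
    "ModificationRule",
    "is_monophyletic",
    "collapse",
    "convergence_report",
    "apply_modification",
]

#: Ranks covered by collapse labels and the convergence report.
REPORT_RANKS = ("D", "P", "C", "O", "F", "G")


def is_monophyletic(tree: TreeNode, leafset: set[str]) -> bool:
    """True iff some edge bipartitions the leaves into (leafset, rest).

    Singletons — and the full leaf set — are trivially monophyletic.
    """
    leaves = frozenset(t.name for t in tree.tips())
    target = frozenset(leafset)
    if not target:
        raise UsageError("leafset must be nonempty")
    unknown = target - leaves
    if unknown:
        raise UsageError(f"leaves not in tree: {sorted(unknown)}")
    if len(target) == 1 or target == leaves:
        return True
    for node in tree.traverse(include_self=False):
        side = (
            frozenset([node.name])
            if node.is_tip()
            else frozenset(t.name for t in node.tips())
        )
        if side == target or leaves - side == target:
            return True
    return False


# ---------------------------------------------------------------------------
# Collapsing
# ---------------------------------------------------------------------------


@dataclass
class CollapsedLeaf:
    """One leaf of a collapsed tree.

    ``m`` counts members with complete lineages, ``n`` absorbed genomes
    with one or more Unclassified ranks. When the taxon is split over
    several branches, ``k`` is this branch's part of the taxon's total
    ``m`` and the label renders as ``{k/m}``.
    """

    rank_code: str
    taxon_name: str
    m: int
    n: int
    k: int | None = None
    members: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.m + self.n < 1:
            raise UsageError("collapsed leaf must represent >= 1 genome")

    def label(self) -> str:
        if self.k is not None:
            counts = f"{{{self.k}/{self.m}}}"
        elif self.n > 0:
            counts = f"{{{self.m}+{self.n}}}"
        else:
            counts = f"{{{self.m}}}"
        return f"<{self.rank_code}>{self.taxon_name}{counts}"


def _branch_label(
    leaf_ids: Sequence[str], lineages: Mapping[str, Lineage], rank: str
) -> tuple[str, str]:
    """(rank_code, name) for a collapsed branch.

    Branches with classified members are named by the shared taxon at the
    requested rank. An all-unclassified branch falls back to the deepest
    rank at or above the requested one where every member still carries
    one shared proper name (mirroring labels like ``<P>Euryarchaeota{0+3}``
    for a cluster unclassified at the class rank).
    """
    classified = [g for g in leaf_ids if lineages[g].complete]
    if classified:
        return rank, lineages[classified[0]].name_at(rank)
    idx = LINEAGE_RANKS.index(rank)
    for r in reversed(LINEAGE_RANKS[: idx + 1]):
        names = {lineages[g].name_at(r) for g in leaf_ids}
        if len(names) == 1 and UNCLASSIFIED not in names:
            return r, names.pop()
    return rank, UNCLASSIFIED


def collapse(
    tree: TreeNode, lineages: Mapping[str, Lineage], rank: str
) -> tuple[TreeNode, list[CollapsedLeaf]]:
    """Collapse maximal single-taxon branches at a rank to labeled leaves.

    Returns the collapsed tree (topology among surviving nodes unchanged)
    and the list of :class:`CollapsedLeaf` records in tip order. Leaf
    accounting is conserved: the branch sizes (split part ``k`` where set,
    else ``m``, plus ``n``) sum to the original leaf count.
    """
    if rank not in LINEAGE_RANKS:
        raise UsageError(f"unknown rank code {rank!r}")
    tips = [t.name for t in tree.tips()]
    missing = [t for t in tips if t not in lineages]
    if missing:
        raise InputError(f"leaves without lineage: {missing}")

    def taxa_below(node: TreeNode) -> set[str]:
        return {
            lineages[t.name].name_at(rank)
            for t in node.tips(include_self=True)
            if lineages[t.name].complete
        }

    records: list[CollapsedLeaf] = []
    placeholder_of: dict[int, CollapsedLeaf] = {}

    def build(node: TreeNode) -> TreeNode:
        if node.is_tip() or len(taxa_below(node)) <= 1:
            leaf_ids = [t.name for t in node.tips(include_self=True)]
            rank_code, name = _branch_label(leaf_ids, lineages, rank)
            m = sum(1 for g in leaf_ids if lineages[g].complete)
            rec = CollapsedLeaf(
                rank_code=rank_code,
                taxon_name=name,
                m=m,
                n=len(leaf_ids) - m,
                members=tuple(leaf_ids),
            )
            records.append(rec)
            new = TreeNode(length=node.length)
            placeholder_of[id(new)] = rec
            return new
        new = TreeNode(length=node.length)
        new.extend([build(c) for c in node.children])
        return new

    out = build(tree)

    # taxa split over several maximal branches get {k/m} labels
    totals: dict[tuple[str, str], int] = {}
    parts: dict[tuple[str, str], int] = {}
    for rec in records:
        if rec.m > 0:
            key = (rec.rank_code, rec.taxon_name)
            totals[key] = totals.get(key, 0) + rec.m
            parts[key] = parts.get(key, 0) + 1
    for rec in records:
        key = (rec.rank_code, rec.taxon_name)
        if rec.m > 0 and parts[key] > 1:
            rec.k = rec.m
            rec.m = totals[key]
    for tip in out.tips(include_self=True):
        tip.name = placeholder_of[id(tip)].label()
    return out, records


# ---------------------------------------------------------------------------
# Convergence statistics
# ---------------------------------------------------------------------------


@dataclass
class ReportRow:
    rank_code: str
    taxon_name: str
    size: int
    flags: dict[int, bool]  # K -> monophyletic in tree_K

    def render(self) -> str:
        slots = " ".join(
            f"K{K}" if self.flags[K] else "-" for K in sorted(self.flags)
        )
        return f"<{self.rank_code}>{self.taxon_name}{{{self.size}}} {slots}"


@dataclass
class ConvergenceReport:
    """Per-taxon, per-K monophyly flags across trees built at several K."""

    rows: list[ReportRow]
    k_values: list[int]

    def render(self) -> str:
        return "\n".join(r.render() for r in self.rows) + "\n"

    def to_tsv(self) -> str:
        header = "rank\ttaxon\tsize\t" + "\t".join(f"K{K}" for K in self.k_values)
        lines = [header]
        for r in self.rows:
            flags = "\t".join(
                "1" if r.flags[K] else "0" for K in self.k_values
            )
            lines.append(f"{r.rank_code}\t{r.taxon_name}\t{r.size}\t{flags}")
        return "\n".join(lines) + "\n"

    def row(self, rank: str, taxon: str) -> ReportRow:
        for r in self.rows:
            if (r.rank_code, r.taxon_name) == (rank, taxon):
                return r
        raise KeyError((rank, taxon))


def convergence_report(
    trees_by_K: Mapping[int, TreeNode],
    lineages: Mapping[str, Lineage],
    ranks: Sequence[str] = REPORT_RANKS,
) -> ConvergenceReport:
    """Monophyly of every taxon at every rank, across all K trees.

    Only genomes with complete lineage information define taxa or count
    toward sizes; incompletely classified genomes cannot break monophyly.
    """
    k_values = sorted(trees_by_K)
    if not k_values:
        raise UsageError("need at least one tree")
    leafsets = {
        K: frozenset(t.name for t in tree.tips())
        for K, tree in trees_by_K.items()
    }
    ref = leafsets[k_values[0]]
    for K, ls in leafsets.items():
        if ls != ref:
            raise UsageError(f"tree at K={K} has a different leaf set")

    rows: list[ReportRow] = []
    for rank in ranks:
        members: dict[str, set[str]] = {}
        for gid in sorted(ref):
            lin = lineages.get(gid)
            if lin is None or not lin.complete:
                continue
            members.setdefault(lin.name_at(rank), set()).add(gid)
        for taxon in sorted(members, key=lambda t: (-len(members[t]), t)):
            flags = {
                K: is_monophyletic(trees_by_K[K], members[taxon])
                for K in k_values
            }
            rows.append(
                ReportRow(
                    rank_code=rank,
                    taxon_name=taxon,
                    size=len(members[taxon]),
                    flags=flags,
                )
            )
    return ConvergenceReport(rows=rows, k_values=k_values)


# ---------------------------------------------------------------------------
# Lineage modification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModificationRule:
    """Rewrite rule ``old_fragment new_fragment`` over partial lineages."""

    old_fragment: tuple[tuple[str, str], ...]
    new_fragment: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        for frag in (self.old_fragment, self.new_fragment):
            if not frag:
                raise UsageError("rule fragments must be non-empty")
            codes = [c for c, _ in frag]
            expect = [c for c in LINEAGE_RANKS if c in set(codes)]
            if codes != expect:
                raise UsageError(f"fragment ranks out of order: {codes}")
        if {c for c, _ in self.old_fragment} != {c for c, _ in self.new_fragment}:
            raise UsageError("old and new fragments must name the same ranks")

    @classmethod
    def parse(cls, text: str) -> "ModificationRule":
        parts = text.split()
        if len(parts) != 2:
            raise UsageError(
                "rule must be two whitespace-separated fragments "
                "'old_lineage new_lineage'"
            )
        return cls(_parse_fragment(parts[0]), _parse_fragment(parts[1]))

    def inverse(self) -> "ModificationRule":
        return ModificationRule(self.new_fragment, self.old_fragment)


def _parse_fragment(text: str) -> tuple[tuple[str, str], ...]:
    import re

    parts = re.split(r"<([A-Za-z])>", text)
    if parts[0].strip():
        raise UsageError(f"fragment must start with a rank label: {text!r}")
    pairs = []
    for code, name in zip(parts[1::2], parts[2::2]):
        if code not in LINEAGE_RANKS:
            raise UsageError(f"unknown rank code <{code}> in fragment")
        if not name:
            raise UsageError(f"empty name for rank <{code}> in fragment")
        pairs.append((code, name))
    if not pairs:
        raise UsageError(f"no rank labels in fragment {text!r}")
    return tuple(pairs)


def apply_modification(
    lineages: Mapping[str, Lineage], rule: ModificationRule
) -> tuple[dict[str, Lineage], int]:
    """Apply a lineage-modification rule; returns (new map, #changed).

    A genome matches iff its lineage agrees with every (rank, name) pair
    of the old fragment; matching genomes have exactly the ranks named in
    the new fragment rewritten. Zero matches is an error (the fragment is
    not recognizable in this dataset).
    """
    old = dict(rule.old_fragment)
    new = dict(rule.new_fragment)
    out: dict[str, Lineage] = {}
    changed = 0
    for gid, lin in lineages.items():
        if all(lin.name_at(c) == n for c, n in old.items()):
            out[gid] = lin.with_names(new)
            changed += 1
        else:
            out[gid] = lin
    if changed == 0:
        raise InputError("lineage fragment not recognizable: no genome matches")
    return out, changed
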