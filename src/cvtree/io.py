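"""Input/output for every external format the pipeline touches.

Formats
-------
* amino-acid multi-FASTA, one file per genome, one record per protein
  product (read via Biopython);
* rank-labeled lineage tables, TSV ``genome_id<TAB><D>Name<P>Name...``;
* Newick trees with branch lengths and optional internal labels
  (via scikit-bio ``TreeNode``);
* square PHYLIP distance matrices.

The container for a genome is :class:`Proteome`; a taxonomic assignment is
a :class:`Lineage` over the fixed rank ladder domain, phylum, class, order,
family, genus, species (plus the strain code ``T`` that may appear on tree
leaves but never in lineage tables).
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from skbio import TreeNode

from .errors import InputError, ParseError, UsageError

__all__ = [
    "RANK_CODES",
    "LINEAGE_RANKS",
    "UNCLASSIFIED",
    "Proteome",
    "Lineage",
    "DistMatrix",
    "read_proteome",
    "write_proteome",
    "parse_lineage_line",
    "read_lineages",
    "write_lineages",
    "read_distmatrix",
    "write_distmatrix",
    "read_newick",
    "write_newick",
]

#: Rank codes in their fixed order; ``T`` (strain) is display-only.
RANK_CODES = ("D", "P", "C", "O", "F", "G", "S", "T")
#: Ranks that may legitimately appear in a lineage table.
LINEAGE_RANKS = RANK_CODES[:-1]
#: Sentinel name for a missing rank.
UNCLASSIFIED = "Unclassified"

_VALID_SEQ = re.compile(r"^[A-Z]+$")


@dataclass
class Proteome:
    """All protein products encoded in one genome.

    Sequences are uppercase; terminal/internal ``*`` stop characters are
    stripped at load time. The genome id is assigned by the caller (from a
    manifest or the file stem) — never taken from per-protein FASTA
    headers.
    """

    genome_id: str
    proteins: list[str]
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise UsageError("genome_id must be non-empty")
        if not self.proteins:
            raise InputError(f"proteome {self.genome_id!r} has no proteins")
        for i, p in enumerate(self.proteins):
            if not p or not _VALID_SEQ.match(p):
                raise InputError(
                    f"proteome {self.genome_id!r}: protein {i} is empty or "
                    "contains non-uppercase-letter characters"
                )

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_residues(self) -> int:
        return sum(len(p) for p in self.proteins)


def _clean_seq(raw: str) -> str:
    return raw.upper().replace("*", "").strip()


def read_proteome(path: str | Path, genome_id: str | None = None) -> Proteome:
    """Read one genome's proteome from an amino-acid multi-FASTA file.

    Parameters
    ----------
    path
        FASTA file with one record per protein product.
    genome_id
        Identifier for the genome; defaults to the file stem.
    """
    path = Path(path)
    if genome_id is None:
        genome_id = path.stem
    if not path.exists():
        raise InputError(f"proteome file not found: {path}")
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        first = text.lstrip().splitlines()[0]
        raise ParseError(f"{path}: not FASTA — first line {first!r} lacks '>'")
    proteins = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _clean_seq(str(rec.seq))
        if seq:
            proteins.append(seq)
    if not proteins:
        raise InputError(f"{path}: no FASTA records with sequence")
    return Proteome(genome_id=genome_id, proteins=proteins, source=str(path))


def write_proteome(proteome: Proteome, path: str | Path) -> Path:
    """Write a proteome as multi-FASTA, one record per protein."""
    path = Path(path)
    with path.open("w") as fh:
        for i, seq in enumerate(proteome.proteins):
            fh.write(f">{proteome.genome_id}|p{i + 1}\n")
            for j in range(0, len(seq), 70):
                fh.write(seq[j : j + 70] + "\n")
    return path


# ---------------------------------------------------------------------------
# Lineages
# ---------------------------------------------------------------------------

_RANK_TOKEN = re.compile(r"<([A-Za-z])>")


@dataclass(frozen=True)
class Lineage:
    """Ordered rank → name assignment, domain down to species.

    ``names`` maps rank codes (a subset of D,P,C,O,F,G,S in that order) to
    taxon names; a missing rank is represented by the name
    ``"Unclassified"``. The domain is always present.
    """

    names: tuple[tuple[str, str], ...]  # ((rank_code, name), ...)

    def __post_init__(self) -> None:
        codes = [c for c, _ in self.names]
        if codes != [c for c in LINEAGE_RANKS if c in set(codes)]:
            raise ParseError(f"ranks out of order or duplicated: {codes}")
        if "D" not in codes:
            raise ParseError("lineage must assign the domain rank <D>")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "Lineage":
        full = dict(pairs)
        return cls(tuple((c, full.get(c, UNCLASSIFIED)) for c in LINEAGE_RANKS))

    def name_at(self, rank: str) -> str:
        for c, n in self.names:
            if c == rank:
                return n
        return UNCLASSIFIED

    @property
    def complete(self) -> bool:
        """True iff none of the ranks D..S is Unclassified."""
        return all(self.name_at(c) != UNCLASSIFIED for c in LINEAGE_RANKS)

    def classified_through(self, rank: str) -> bool:
        """True iff every rank from D down to `rank` has a proper name."""
        for c in LINEAGE_RANKS:
            if self.name_at(c) == UNCLASSIFIED:
                return False
            if c == rank:
                return True
        raise UsageError(f"unknown rank code {rank!r}")

    def with_names(self, replacements: Mapping[str, str]) -> "Lineage":
        """Copy with the named ranks rewritten."""
        unknown = set(replacements) - set(LINEAGE_RANKS)
        if unknown:
            raise UsageError(f"unknown rank codes {sorted(unknown)}")
        return Lineage(
            tuple((c, replacements.get(c, n)) for c, n in self.names)
        )

    def render(self) -> str:
        return "".join(f"<{c}>{n}" for c, n in self.names)


def _parse_lineage_string(text: str, where: str = "") -> Lineage:
    parts = _RANK_TOKEN.split(text)
    if parts[0].strip():
        raise ParseError(f"{where}lineage must start with a rank label, got {parts[0]!r}")
    pairs: list[tuple[str, str]] = []
    seen: set[str] = set()
    order = {c: i for i, c in enumerate(LINEAGE_RANKS)}
    last = -1
    for code, name in zip(parts[1::2], parts[2::2]):
        if code not in order:
            raise ParseError(f"{where}unknown rank code <{code}>")
        if code in seen:
            raise ParseError(f"{where}duplicate rank code <{code}>")
        if order[code] < last:
            raise ParseError(f"{where}rank <{code}> out of order")
        name = name.strip()
        if not name:
            raise ParseError(f"{where}empty name for rank <{code}>")
        seen.add(code)
        last = order[code]
        pairs.append((code, name))
    if not pairs:
        raise ParseError(f"{where}no rank labels found in {text!r}")
    return Lineage.from_pairs(pairs)


def parse_lineage_line(text: str) -> tuple[str, Lineage]:
    """Parse one ``genome_id<TAB><D>Name<P>Name...`` lineage line.

    Omitted trailing ranks are filled as Unclassified; duplicate, unknown
    or out-of-order rank codes are rejected.
    """
    if "\t" not in text:
        raise ParseError(f"lineage line lacks a TAB separator: {text!r}")
    genome_id, lineage_text = text.rstrip("\n").split("\t", 1)
    genome_id = genome_id.strip()
    if not genome_id:
        raise ParseError(f"empty genome id in lineage line: {text!r}")
    return genome_id, _parse_lineage_string(lineage_text.strip(), where=f"{genome_id}: ")


def read_lineages(path: str | Path) -> dict[str, Lineage]:
    """Read a lineage TSV (``#`` comment lines and blank lines skipped)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"lineage file not found: {path}")
    out: dict[str, Lineage] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        try:
            gid, lin = parse_lineage_line(line)
        except ParseError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if gid in out:
            raise ParseError(f"{path}:{lineno}: duplicate genome id {gid!r}")
        out[gid] = lin
    if not out:
        raise InputError(f"{path}: no lineage entries")
    return out


def write_lineages(lineages: Mapping[str, Lineage], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for gid, lin in lineages.items():
            fh.write(f"{gid}\t{lin.render()}\n")
    return path


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------


@dataclass
class DistMatrix:
    """Symmetric pairwise dissimilarity matrix with genome-id labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise UsageError("duplicate labels in distance matrix")
        if self.values.shape != (n, n):
            raise UsageError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise UsageError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise UsageError("distance matrix diagonal must be zero")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])


def write_distmatrix(matrix: DistMatrix, path: str | Path) -> Path:
    """Write a square PHYLIP distance matrix (count line, then rows).

    Taxon names have internal whitespace replaced by ``_``; a collision
    after sanitization is an error. Values are written with 10 significant
    digits so a read round-trip reproduces them.
    """
    path = Path(path)
    safe = [re.sub(r"\s+", "_", lab) for lab in matrix.labels]
    if len(set(safe)) != len(safe):
        raise UsageError("label collision after whitespace sanitization")
    with path.open("w") as fh:
        fh.write(f"{len(safe)}\n")
        for name, row in zip(safe, matrix.values):
            cells = "  ".join(f"{v:.10g}" for v in row)
            fh.write(f"{name}  {cells}\n")
    return path


def read_distmatrix(path: str | Path) -> DistMatrix:
    """Read a square PHYLIP distance matrix."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty distance matrix file")
    try:
        n = int(lines[0].split()[0])
    except ValueError as exc:
        raise ParseError(f"{path}: bad taxon count line {lines[0]!r}") from exc
    if len(lines) - 1 != n:
        raise ParseError(f"{path}: expected {n} rows, found {len(lines) - 1}")
    labels, rows = [], []
    for ln in lines[1:]:
        fields = ln.split()
        if len(fields) != n + 1:
            raise ParseError(f"{path}: row {fields[0]!r} has {len(fields) - 1} values, expected {n}")
        labels.append(fields[0])
        rows.append([float(x) for x in fields[1:]])
    return DistMatrix(labels=labels, values=np.array(rows))


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------


def read_newick(path: str | Path) -> TreeNode:
    """Read a Newick tree; duplicate leaf labels are rejected."""
    path = Path(path)
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises its own parse errors
        raise ParseError(f"{path}: {exc}") from exc
    tips = [t.name for t in tree.tips()]
    if len(set(tips)) != len(tips):
        dups = sorted({t for t in tips if tips.count(t) > 1})
        raise ParseError(f"{path}: duplicate leaf labels {dups}")
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> Path:
    """Write a tree as Newick with branch lengths and internal labels."""
    path = Path(path)
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    path.write_text(buf.getvalue())
    return path


def newick_string(tree: TreeNode) -> str:
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue()
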