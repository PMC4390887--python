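"""K-peptide counting and background-subtracted composition vectors.

A genome is represented by the counts ``n(s)`` of every length-K window
(*K-peptide*) over the 20 standard amino acids, pooled over all its protein
products; windows never span protein boundaries, and windows containing a
non-standard letter are discarded from both counts and totals. With
``f_K(s) = n(s) / T_K`` (``T_K`` the number of counted windows of length
K), the expected frequency of ``s = a1..aK`` under a (K-2)-order Markov
model is

    f0(s) = f_{K-1}(a1..a_{K-1}) * f_{K-1}(a2..aK) / f_{K-2}(a2..a_{K-1})

and the composition-vector component is the relative deviation

    a(s) = (f_K(s) - f0(s)) / f0(s),   a(s) = 0 where f0(s) = 0.

Subtracting the Markov background suppresses the shared signal of neutral
mutations and highlights selection, which is what makes the cosine of two
such vectors phylogenetically informative.

Internally peptides are base-20 integer codes in sorted numpy arrays, so
counting, subtraction and (in the next module) sparse dot products are
vectorized; the string-keyed ``counts`` / ``components`` dictionaries the
API documents are materialized on demand.

By default only observed K-peptides (``n(s) > 0``) are stored; the
``extended`` flag additionally stores unobserved-but-predicted peptides
(``n(s) = 0`` with ``f0(s) > 0``), whose components equal −1 exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import DegenerateDataError, UsageError
from .io import Proteome

__all__ = [
    "AMINO_ACIDS",
    "KmerTable",
    "CompositionVector",
    "count_kmers",
    "composition_vector",
    "proteome_to_cv",
    "dump_cv_table",
]

#: The 20 standard amino acids, in the fixed encoding order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_LUT = np.full(256, -1, dtype=np.int64)
for _i, _aa in enumerate(AMINO_ACIDS):
    _LUT[ord(_aa)] = _i


def _encode_codes(proteins: list[str], K: int) -> np.ndarray:
    """Base-20 codes of every valid length-K window (big-endian digits)."""
    # joining on a non-standard letter invalidates cross-protein windows
    blob = np.frombuffer("X".join(proteins).encode("ascii"), dtype=np.uint8)
    idx = _LUT[blob]
    if idx.shape[0] < K:
        return np.empty(0, dtype=np.int64)
    windows = sliding_window_view(idx, K)
    valid = (windows >= 0).all(axis=1)
    powers = 20 ** np.arange(K - 1, -1, -1, dtype=np.int64)
    return windows[valid] @ powers


def decode_peptide(code: int, K: int) -> str:
    """Inverse of the base-20 encoding: code → K-peptide string."""
    out = []
    for _ in range(K):
        code, r = divmod(code, 20)
        out.append(AMINO_ACIDS[r])
    return "".join(reversed(out))


@dataclass
class KmerTable:
    """Counts of every valid length-K window in a proteome.

    ``codes`` are the distinct observed peptides as sorted base-20 codes
    with parallel ``code_counts``; the ``counts`` property materializes
    the string-keyed dictionary view.
    """

    K: int
    codes: np.ndarray
    code_counts: np.ndarray
    total: int

    @classmethod
    def from_counts(cls, K: int, counts: dict[str, int]) -> "KmerTable":
        """Build from a string-keyed counts dictionary."""
        powers = 20 ** np.arange(K - 1, -1, -1, dtype=np.int64)
        codes, vals = [], []
        for s, c in counts.items():
            if len(s) != K:
                raise UsageError(f"peptide {s!r} is not length {K}")
            digits = _LUT[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
            if (digits < 0).any():
                raise UsageError(f"peptide {s!r} has non-standard letters")
            codes.append(int(digits @ powers))
            vals.append(int(c))
        order = np.argsort(codes)
        return cls(
            K=K,
            codes=np.asarray(codes, dtype=np.int64)[order],
            code_counts=np.asarray(vals, dtype=np.int64)[order],
            total=int(sum(vals)),
        )

    @property
    def counts(self) -> dict[str, int]:
        return {
            decode_peptide(int(c), self.K): int(n)
            for c, n in zip(self.codes, self.code_counts)
        }

    def frequency(self, s: str) -> float:
        if self.total == 0:
            raise DegenerateDataError("K-mer table has zero total")
        return self.counts.get(s, 0) / self.total


def count_kmers(proteome: Proteome, K: int) -> KmerTable:
    """Count K-peptides in all protein products of a genome.

    Each protein is scanned independently (windows never cross protein
    boundaries). Windows containing any letter outside the 20 standard
    amino acids are discarded and do not contribute to the total.
    """
    if K < 1:
        raise UsageError(f"K must be >= 1, got {K}")
    all_codes = _encode_codes(proteome.proteins, K)
    if all_codes.size == 0:
        raise DegenerateDataError(
            f"proteome {proteome.genome_id!r}: no valid length-{K} window"
        )
    codes, counts = np.unique(all_codes, return_counts=True)
    return KmerTable(
        K=K, codes=codes, code_counts=counts, total=int(counts.sum())
    )


@dataclass
class CompositionVector:
    """Sparse background-subtracted composition vector of one genome.

    ``codes`` / ``values`` are the stored peptides (sorted base-20 codes)
    and their a(s); ``norm`` is the Euclidean norm over all stored
    components. ``components`` materializes the string-keyed view.
    """

    K: int
    codes: np.ndarray
    values: np.ndarray
    norm: float = 0.0
    genome_id: str = ""

    def __post_init__(self) -> None:
        if self.K < 3:
            raise UsageError(f"composition vectors require K >= 3, got K={self.K}")
        if not self.norm:
            self.norm = float(np.sqrt(np.dot(self.values, self.values)))

    @classmethod
    def from_components(
        cls, K: int, components: dict[str, float], genome_id: str = ""
    ) -> "CompositionVector":
        powers = 20 ** np.arange(K - 1, -1, -1, dtype=np.int64)
        codes, vals = [], []
        for s, a in components.items():
            digits = _LUT[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
            if len(s) != K or (digits < 0).any():
                raise UsageError(f"bad K-peptide key {s!r}")
            codes.append(int(digits @ powers))
            vals.append(float(a))
        order = np.argsort(codes)
        return cls(
            K=K,
            codes=np.asarray(codes, dtype=np.int64)[order],
            values=np.asarray(vals, dtype=float)[order],
            genome_id=genome_id,
        )

    @property
    def components(self) -> dict[str, float]:
        return {
            decode_peptide(int(c), self.K): float(v)
            for c, v in zip(self.codes, self.values)
        }

    def __len__(self) -> int:
        return int(self.codes.size)


def _lookup_freq(table: KmerTable, codes: np.ndarray) -> np.ndarray:
    """Frequencies of `codes` in `table`; zero where unobserved."""
    pos = np.searchsorted(table.codes, codes)
    pos_c = np.clip(pos, 0, table.codes.size - 1)
    hit = table.codes[pos_c] == codes
    out = np.zeros(codes.shape[0])
    out[hit] = table.code_counts[pos_c[hit]] / table.total
    return out


def composition_vector(
    tK: KmerTable,
    tK1: KmerTable,
    tK2: KmerTable,
    *,
    extended: bool = False,
    genome_id: str = "",
) -> CompositionVector:
    """Build the subtracted composition vector from K, K-1 and K-2 tables.

    The three tables must come from the same proteome. With
    ``extended=True``, peptides that are unobserved but predicted by the
    Markov background (f0 > 0) are stored too; their components are
    exactly −1.
    """
    K = tK.K
    if K < 3:
        raise UsageError(f"K must be >= 3, got {K}")
    if (tK1.K, tK2.K) != (K - 1, K - 2):
        raise UsageError(
            f"table lengths must be K, K-1, K-2; got {tK.K}, {tK1.K}, {tK2.K}"
        )
    for t in (tK, tK1, tK2):
        if t.total == 0:
            raise DegenerateDataError(f"length-{t.K} table has zero total")

    codes = tK.codes
    f = tK.code_counts / tK.total
    p1 = 20 ** (K - 1)
    p2 = 20 ** (K - 2)
    prefix = codes // 20
    suffix = codes % p1
    middle = prefix % p2
    f_pre = _lookup_freq(tK1, prefix)
    f_suf = _lookup_freq(tK1, suffix)
    f_mid = _lookup_freq(tK2, middle)
    # an observed K-peptide always has observed prefix/suffix/middle, so
    # its background prediction cannot vanish
    if not ((f_pre > 0) & (f_suf > 0) & (f_mid > 0)).all():
        raise UsageError(
            "K, K-1, K-2 tables are inconsistent (not from one proteome)"
        )
    f0 = f_pre * f_suf / f_mid
    values = (f - f0) / f0

    if extended:
        # candidates with f0 > 0 are overlapping pairs (p, q) of observed
        # (K-1)-mers whose shared (K-2)-mer is observed: s = p·last(q)
        c1 = tK1.codes
        p1_pref = c1 // 20  # leading K-2 digits of each (K-1)-mer
        order = np.argsort(p1_pref, kind="stable")
        sorted_pref = p1_pref[order]
        p_suffix2 = c1 % p2  # trailing K-2 digits
        lo = np.searchsorted(sorted_pref, p_suffix2, side="left")
        hi = np.searchsorted(sorted_pref, p_suffix2, side="right")
        reps = hi - lo
        base = np.repeat(c1 * 20, reps)
        take = np.concatenate(
            [order[a:b] for a, b in zip(lo, hi)]
        ) if reps.sum() else np.empty(0, dtype=np.int64)
        cand = base + (c1[take] % 20)
        cand = np.setdiff1d(cand, codes)  # unique & not already stored
        if cand.size:
            codes = np.concatenate([codes, cand])
            values = np.concatenate([values, np.full(cand.size, -1.0)])
            order2 = np.argsort(codes)
            codes, values = codes[order2], values[order2]
    return CompositionVector(
        K=K, codes=codes, values=values, genome_id=genome_id
    )


def proteome_to_cv(
    proteome: Proteome, K: int, *, extended: bool = False
) -> CompositionVector:
    """Count K, K-1, K-2 peptides and build the composition vector."""
    return composition_vector(
        count_kmers(proteome, K),
        count_kmers(proteome, K - 1),
        count_kmers(proteome, K - 2),
        extended=extended,
        genome_id=proteome.genome_id,
    )


def dump_cv_table(
    proteome: Proteome, K: int, path: str | Path, *, extended: bool = False
) -> Path:
    """Write a debug TSV (peptide, count, f, f0, a), lexicographic order."""
    tK = count_kmers(proteome, K)
    tK1 = count_kmers(proteome, K - 1)
    tK2 = count_kmers(proteome, K - 2)
    cv = composition_vector(tK, tK1, tK2, extended=extended, genome_id=proteome.genome_id)
    countsK = tK.counts
    fK1 = {s: c / tK1.total for s, c in tK1.counts.items()}
    fK2 = {s: c / tK2.total for s, c in tK2.counts.items()}
    path = Path(path)
    with path.open("w") as fh:
        fh.write("peptide\tcount\tf\tf0\ta\n")
        comp = cv.components
        for s in sorted(comp):
            n = countsK.get(s, 0)
            f = n / tK.total
            mid = fK2.get(s[1:-1], 0.0)
            b = 0.0 if mid == 0.0 else fK1.get(s[:-1], 0.0) * fK1.get(s[1:], 0.0) / mid
            fh.write(f"{s}\t{n}\t{f:.10g}\t{b:.10g}\t{comp[s]:.10g}\n")
    return path
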