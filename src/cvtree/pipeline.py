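"""End-to-end pipeline: FASTA in → trees, matrices and reports out.

The contract is deliberately parameter-free in the spirit of the method:
given the input files, every artifact is a deterministic function of the
K list, the seed and the two flags (extended vector storage, rooted
monophyly display). Running twice with the same configuration produces
byte-identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .composition import proteome_to_cv
from .dissimilarity import distance_matrix
from .errors import InputError, UsageError
from .io import (
    DistMatrix,
    Proteome,
    read_lineages,
    read_proteome,
    write_distmatrix,
    write_newick,
)
from .taxonomy import REPORT_RANKS, collapse, convergence_report
from .treebuild import (
    bootstrap_support,
    clamp_negative_branch_lengths,
    neighbor_joining,
    root_by_outgroup,
)

__all__ = ["RunConfig", "run_pipeline", "read_manifest"]


def read_manifest(path: str | Path) -> dict[str, Path]:
    """Read a genome manifest TSV: ``genome_id<TAB>fasta_path`` per line."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"manifest not found: {path}")
    out: dict[str, Path] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise InputError(f"{path}:{lineno}: expected 'id<TAB>path'")
        gid, fasta = fields[0].strip(), Path(fields[1].strip())
        if gid in out:
            raise InputError(f"{path}:{lineno}: duplicate genome id {gid!r}")
        if not fasta.is_absolute():
            fasta = path.parent / fasta
        out[gid] = fasta
    if not out:
        raise InputError(f"{path}: empty manifest")
    return out


@dataclass
class RunConfig:
    """Everything a run depends on; validated before any computation."""

    manifest: dict[str, Path]
    out_dir: Path
    k_values: list[int] = field(default_factory=lambda: [5, 6])
    lineage_path: Path | None = None
    bootstrap: int = 0
    seed: int = 0
    outgroup: list[str] = field(default_factory=list)
    extended: bool = False
    collapse_ranks: tuple[str, ...] = REPORT_RANKS

    def validate(self) -> None:
        if not self.manifest:
            raise UsageError("empty manifest")
        for K in self.k_values:
            if K < 3:
                raise UsageError(f"K must be >= 3, got {K}")
        missing = [str(p) for p in self.manifest.values() if not Path(p).exists()]
        if missing:
            raise InputError(f"manifest references missing files: {missing}")
        if self.lineage_path is not None and not Path(self.lineage_path).exists():
            raise InputError(f"lineage file not found: {self.lineage_path}")
        unknown_og = set(self.outgroup) - set(self.manifest)
        if unknown_og:
            raise UsageError(f"outgroup ids not in manifest: {sorted(unknown_og)}")


def run_pipeline(
    config: RunConfig, proteomes: dict[str, Proteome] | None = None
) -> dict[str, Path]:
    """Run the whole pipeline; returns a name → path map of artifacts.

    ``proteomes`` may be passed directly (e.g. from the simulator) to skip
    FASTA reading; the manifest then only provides ids.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [
        f"cvtree {__version__}",
        f"seed={config.seed} K={config.k_values} bootstrap={config.bootstrap} "
        f"extended={config.extended}",
        f"genomes={list(config.manifest)}",
    ]
    artifacts: dict[str, Path] = {}

    if proteomes is None:
        proteomes = {
            gid: read_proteome(path, genome_id=gid)
            for gid, path in config.manifest.items()
        }
    order = list(config.manifest)
    plist = [proteomes[g] for g in order]

    lineages = None
    if config.lineage_path is not None:
        lineages = read_lineages(config.lineage_path)
        missing = [g for g in order if g not in lineages]
        if missing:
            raise InputError(f"genomes without lineage entry: {missing}")

    trees_by_K = {}
    for K in config.k_values:
        vectors = [proteome_to_cv(p, K, extended=config.extended) for p in plist]
        dm = distance_matrix(vectors, labels=order)
        p = out_dir / f"dist_K{K}.phylip"
        write_distmatrix(dm, p)
        artifacts[f"dist_K{K}"] = p

        if config.bootstrap > 0:
            res = bootstrap_support(
                plist, K, config.bootstrap, config.seed, extended=config.extended
            )
            tree = res.tree
            log_lines.append(
                f"K={K}: bootstrap B={res.n_replicates}, "
                f"min support={res.min_support():.3f}, redrawn={res.n_redrawn}"
            )
        else:
            tree = neighbor_joining(dm)
        tree, clamped, n_clamped = clamp_negative_branch_lengths(tree)
        if n_clamped:
            log_lines.append(
                f"K={K}: clamped {n_clamped} negative branch lengths "
                f"(total {clamped:.6g})"
            )
        if config.outgroup:
            tree = root_by_outgroup(tree, set(config.outgroup))
        trees_by_K[K] = tree
        p = out_dir / f"tree_K{K}.newick"
        write_newick(tree, p)
        artifacts[f"tree_K{K}"] = p

        if lineages is not None:
            for rank in config.collapse_ranks:
                ctree, records = collapse(tree, lineages, rank)
                p = out_dir / f"collapsed_K{K}_{rank}.newick"
                write_newick(ctree, p)
                artifacts[f"collapsed_K{K}_{rank}"] = p

    if lineages is not None:
        report = convergence_report(trees_by_K, lineages)
        p = out_dir / "convergence_report.txt"
        p.write_text(report.render())
        artifacts["report_txt"] = p
        p = out_dir / "convergence_report.tsv"
        p.write_text(report.to_tsv())
        artifacts["report_tsv"] = p

    log = out_dir / "run.log"
    log.write_text("\n".join(log_lines) + "\n")
    artifacts["log"] = log
    return artifacts
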