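"""End-to-end analysis of one structure/mutation pair, and batch driving.

Stages: read and filter mutations → extract and reconcile the Cα trace →
remap to 1D by MDS (optional) → order-statistic cluster test → map
clusters back to canonical numbering.  ``run_single`` ties the stages to
files on disk and writes reports; ``analyze_structure`` is the in-memory
core reused by simulations and the 1D-vs-3D comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.sequence.io.fasta as biofasta

from ._version import __version__
from .config import RunConfig
from .embedding import Embedding1D, embed_1d, linearize, pairwise_distances
from .mutations import (
    MutationTable,
    collapse_to_counts,
    deduplicate,
    drop_out_of_range,
    filter_mutations,
    read_mutation_records,
)
from .nmc import (
    ClusterSet,
    OrderStatistics,
    PairTest,
    compute_order_statistics,
    find_clusters,
    test_all_pairs,
)
from .structure import (
    CaStructure,
    ReconciliationError,
    StructureError,
    align_to_canonical,
    build_ca_structure,
    parse_ca,
    restrict_mutations,
)


class PipelineError(RuntimeError):
    """A stage failure with a machine-readable error class."""

    def __init__(self, stage: str, error_class: str, message: str):
        super().__init__(f"[{stage}/{error_class}] {message}")
        self.stage = stage
        self.error_class = error_class
        self.message = message


@dataclass
class StructureAnalysis:
    """Full per-structure result of the clustering pipeline."""

    structure: CaStructure
    table: MutationTable  # restricted to residues with coordinates
    order_stats: OrderStatistics
    tests: list[PairTest]
    clusters: ClusterSet
    embedding: Embedding1D | None  # None for a linear-only run
    linear_to_canonical: dict[int, int]

    @property
    def num_clusters(self) -> int:
        return len(self.clusters)


def analyze_structure(
    structure: CaStructure, table: MutationTable, config: RunConfig | None = None
) -> StructureAnalysis:
    """Run the cluster test for one structure and mutation table.

    Mutations at residues without coordinates are dropped first.  With
    ``config.linear_only`` the test runs on the residues' sequence order
    (missing residues removed); otherwise residues are remapped to 1D by
    MDS and tested on their rank positions.
    """
    config = config or RunConfig()
    restricted = restrict_mutations(table, structure)
    if restricted.n < 2:
        raise PipelineError(
            "nmc",
            "insufficient mutations",
            f"{restricted.n} mutation(s) fall on residues with coordinates; "
            "at least 2 required",
        )
    N = structure.N
    canon = [int(p) for p in structure.positions]
    if config.linear_only:
        embedding = None
        to_linear = np.arange(1, N + 1)
    else:
        delta = pairwise_distances(structure)
        embedding = embed_1d(
            delta, restarts=config.mds_restarts, seed=config.seed
        )
        to_linear, _ = linearize(embedding)
    lin_of_canon = {c: int(l) for c, l in zip(canon, to_linear)}
    linear_to_canonical = {l: c for c, l in lin_of_canon.items()}
    counts_linear = {
        lin_of_canon[pos]: cnt for pos, cnt in restricted.counts.items()
    }
    order_stats = compute_order_statistics(counts_linear, N)
    tests = test_all_pairs(
        order_stats,
        alpha=config.alpha,
        method=config.adjust,
        c_convention=config.c_convention,
    )
    clusters = find_clusters(
        tests, order_stats, linear_to_canonical, restricted.counts, config.alpha
    )
    return StructureAnalysis(
        structure=structure,
        table=restricted,
        order_stats=order_stats,
        tests=tests,
        clusters=clusters,
        embedding=embedding,
        linear_to_canonical=linear_to_canonical,
    )


@dataclass
class SingleResult:
    analysis: StructureAnalysis
    manifest: dict


def _read_single_fasta(path: str | Path) -> str:
    fasta = biofasta.FastaFile.read(str(path))
    seqs = list(fasta.values())
    if not seqs:
        raise PipelineError("io", "empty fasta", f"{path}: no sequences")
    return str(seqs[0])


def run_single(
    structure_path: str | Path,
    mutation_path: str | Path,
    fasta_path: str | Path,
    config: RunConfig | None = None,
    chain: str | None = None,
    out_dir: str | Path | None = None,
) -> SingleResult:
    """Run the full pipeline on one structure, mutation table and sequence.

    Optionally writes a cluster TSV, per-residue embedding diagnostics
    and a JSON run manifest to ``out_dir``.  Stage failures raise
    :class:`PipelineError` carrying the stage name and an error class.
    """
    config = config or RunConfig()
    try:
        records = read_mutation_records(mutation_path)
        canonical_seq = _read_single_fasta(fasta_path)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("io", "unreadable input", str(exc)) from exc

    records = filter_mutations(records, config.accepted_statuses)
    records = deduplicate(records)
    records = drop_out_of_range(records, len(canonical_seq))
    table = collapse_to_counts(records)

    try:
        raw = parse_ca(
            structure_path,
            chain=chain,
            canonical_seq=canonical_seq,
            min_identity=config.min_identity,
        )
        mapping = align_to_canonical(
            raw.sequence,
            canonical_seq,
            min_identity=config.min_identity,
            gap_open=config.gap_open,
            gap_extend=config.gap_extend,
        )
        structure = build_ca_structure(raw, mapping)
    except ReconciliationError as exc:
        raise PipelineError("reconciliation", "reconciliation", str(exc)) from exc
    except StructureError as exc:
        raise PipelineError("structure", "unusable structure", str(exc)) from exc

    analysis = analyze_structure(structure, table, config)
    manifest = {
        "tool": "mutclust3d",
        "version": __version__,
        "structure": str(structure_path),
        "mutations": str(mutation_path),
        "fasta": str(fasta_path),
        "chain": structure.chain_id,
        "config": config.to_dict(),
        "N": structure.N,
        "n": analysis.table.n,
        "m": analysis.table.m,
        "pairs_tested": len(analysis.tests),
        "stress1": (
            analysis.embedding.stress1 if analysis.embedding is not None else None
        ),
        "num_clusters": analysis.num_clusters,
    }
    if out_dir is not None:
        _write_reports(Path(out_dir), analysis, manifest)
    return SingleResult(analysis=analysis, manifest=manifest)


def clusters_frame(clusters: ClusterSet) -> pd.DataFrame:
    """Cluster report as a table: cluster_id/start/end/mutations/p-values."""
    rows = [
        {
            "cluster_id": idx + 1,
            "start": c.start,
            "end": c.end,
            "num_mutations": c.num_mutations,
            "p_value": c.p_value,
            "p_adjusted": c.p_adjusted,
        }
        for idx, c in enumerate(clusters.clusters)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "start",
            "end",
            "num_mutations",
            "p_value",
            "p_adjusted",
        ],
    )


def _write_reports(
    out_dir: Path, analysis: StructureAnalysis, manifest: dict
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    clusters_frame(analysis.clusters).to_csv(
        out_dir / "clusters.tsv", sep="\t", index=False
    )
    diag_rows = []
    for idx, pos in enumerate(analysis.structure.positions):
        diag_rows.append(
            {
                "residue": analysis.structure.sequence[idx],
                "canonical_position": int(pos),
                "coord_1d": (
                    float(analysis.embedding.coords[idx])
                    if analysis.embedding is not None
                    else float("nan")
                ),
                "linear_position": (
                    int(analysis.embedding.linear_order[idx])
                    if analysis.embedding is not None
                    else idx + 1
                ),
            }
        )
    pd.DataFrame(diag_rows).to_csv(
        out_dir / "diagnostics.tsv", sep="\t", index=False
    )
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def run_batch(entries, config: RunConfig | None = None, out_dir=None):
    """Per-structure runs plus cross-structure aggregation.

    Thin wrapper around :func:`mutclust3d.multi.run_study`; see there.
    """
    from .multi import run_study

    return run_study(entries, config=config, out_dir=out_dir)
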