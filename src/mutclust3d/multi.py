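"""Aggregation of cluster results across structures.

Bonferroni within a structure is complemented by a screen across the
``k`` structures of a study: each cluster's p-value is restored to the
raw (pre-Bonferroni) scale as P*, and compared against a rough FDR
threshold rFDR = α(k+1)/(2k), which approximates FDR control for a
large number of positively correlated or independent tests.  A second
Bonferroni across structures would be too conservative because multiple
structures of one protein give near-identical results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._version import __version__
from .config import RunConfig
from .mutations import MutationTable
from .nmc import Cluster, ClusterSet
from .pipeline import PipelineError, StructureAnalysis, analyze_structure, run_single
from .structure import CaStructure


def compute_pstar(p_adjusted: float, n: int) -> float:
    """Invert the within-structure Bonferroni adjustment of a cluster.

    With ``n`` mutations the adjustment multiplies the raw pair p-value
    by the ``n(n-1)/2`` tested pairs, so on the adjusted value the
    inversion is the identity: P* = raw p × n(n-1)/2 = p_adjusted.  The
    mutation count is still required (and validated) because P* is only
    meaningful for a tested pair.
    """
    if n < 2:
        raise ValueError("P* requires at least two mutations")
    return float(p_adjusted)


def rfdr_threshold(alpha: float, k: int) -> float:
    """Rough-FDR significance threshold α(k+1)/(2k) over k structures.

    Decreases monotonically from α at k = 1 toward α/2 as the number of
    structures grows.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return alpha * (k + 1) / (2 * k)


@dataclass
class StructureResult:
    """Per-structure entry of a study summary."""

    structure_id: str
    protein_id: str
    clusters: ClusterSet | None
    n_mutations: int = 0
    num_clusters_3d: int = 0
    num_clusters_linear: int = 0
    category: str = ""  # more / fewer / same (3D vs linear cluster count)
    error: str | None = None

    @property
    def best_p_adjusted(self) -> float | None:
        if not self.clusters or not self.clusters.clusters:
            return None
        return min(c.p_adjusted for c in self.clusters.clusters)

    @property
    def best_pstar(self) -> float | None:
        best = self.best_p_adjusted
        if best is None:
            return None
        return compute_pstar(best, self.n_mutations)


@dataclass
class StudySummary:
    """Cross-structure aggregation of a batch run."""

    results: list[StructureResult]
    alpha: float
    k_structures: int
    rfdr: float

    def significant(self) -> list[tuple[str, Cluster, float]]:
        """(structure_id, cluster, P*) for clusters passing the rFDR screen."""
        return decide_significance(self, self.alpha)


def decide_significance(
    summary: StudySummary, alpha: float
) -> list[tuple[str, Cluster, float]]:
    """Flag every cluster whose P* is at or below the rFDR threshold.

    The screen is applied to all clusters of all structures; with a
    single structure (k = 1) it reduces to the per-structure α rule.
    """
    threshold = rfdr_threshold(alpha, summary.k_structures)
    flagged = []
    for res in summary.results:
        if res.clusters is None:
            continue
        for cluster in res.clusters.clusters:
            pstar = compute_pstar(cluster.p_adjusted, res.n_mutations)
            if pstar <= threshold:
                flagged.append((res.structure_id, cluster, pstar))
    return flagged


def compare_with_linear(
    structure: CaStructure,
    table: MutationTable,
    alpha: float = 0.05,
    config: RunConfig | None = None,
) -> tuple[int, int, str]:
    """Cluster counts with and without the 3D remapping.

    Runs the pipeline twice on identical inputs — once on the MDS rank
    positions and once on plain sequence order over the same residue
    set — and bins the structure by whether the 3D-aware run finds
    ``more``, ``fewer`` or the ``same`` number of clusters.
    """
    from dataclasses import replace

    config = config or RunConfig(alpha=alpha)
    cfg3d = replace(config, alpha=alpha, linear_only=False)
    cfg1d = replace(config, alpha=alpha, linear_only=True)
    n3d = analyze_structure(structure, table, cfg3d).num_clusters
    n1d = analyze_structure(structure, table, cfg1d).num_clusters
    category = "more" if n3d > n1d else "fewer" if n3d < n1d else "same"
    return n3d, n1d, category


def run_study(
    entries,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> StudySummary:
    """Run the pipeline over a batch of structures and aggregate.

    ``entries`` is a sequence of mappings with keys ``structure``,
    ``mutations``, ``fasta`` and optional ``chain``.  Per-entry failures
    are recorded in the summary and do not abort the batch.  ``k`` for
    the rFDR threshold counts the structures that were successfully
    analyzed in this run.
    """
    config = config or RunConfig()
    results: list[StructureResult] = []
    for entry in entries:
        sid = Path(str(entry["structure"])).stem
        try:
            single = run_single(
                entry["structure"],
                entry["mutations"],
                entry["fasta"],
                config=config,
                chain=entry.get("chain"),
            )
            analysis = single.analysis
            n3d, n1d, category = compare_with_linear(
                analysis.structure, analysis.table, config.alpha, config
            )
            results.append(
                StructureResult(
                    structure_id=analysis.structure.structure_id,
                    protein_id=analysis.table.protein_id,
                    clusters=analysis.clusters,
                    n_mutations=analysis.table.n,
                    num_clusters_3d=n3d,
                    num_clusters_linear=n1d,
                    category=category,
                )
            )
        except (PipelineError, OSError) as exc:
            results.append(
                StructureResult(
                    structure_id=sid,
                    protein_id="",
                    clusters=None,
                    error=str(exc),
                )
            )
    k = sum(1 for r in results if r.error is None)
    threshold = rfdr_threshold(config.alpha, max(k, 1))
    summary = StudySummary(
        results=results, alpha=config.alpha, k_structures=max(k, 1), rfdr=threshold
    )
    if out_dir is not None:
        write_study_reports(Path(out_dir), summary, config)
    return summary


def summary_frame(summary: StudySummary) -> pd.DataFrame:
    rows = []
    for r in summary.results:
        rows.append(
            {
                "structure_id": r.structure_id,
                "protein_id": r.protein_id,
                "best_p_adjusted": r.best_p_adjusted,
                "p_star": r.best_pstar,
                "significant_rfdr": (
                    r.best_pstar is not None and r.best_pstar <= summary.rfdr
                ),
                "num_clusters_3d": r.num_clusters_3d,
                "num_clusters_linear": r.num_clusters_linear,
                "category": r.category,
                "error": r.error or "",
            }
        )
    return pd.DataFrame(rows)


def write_study_reports(
    out_dir: Path, summary: StudySummary, config: RunConfig
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    summary_frame(summary).to_csv(out_dir / "summary.tsv", sep="\t", index=False)
    run_info = {
        "tool": "mutclust3d",
        "version": __version__,
        "alpha": summary.alpha,
        "k_structures": summary.k_structures,
        "rfdr_threshold": summary.rfdr,
        "config": config.to_dict(),
    }
    with open(out_dir / "study.json", "w") as fh:
        json.dump(run_info, fh, indent=2, sort_keys=True)
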