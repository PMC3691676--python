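"""Run configuration shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class RunConfig:
    """Parameters controlling a clustering run.

    Defaults follow the method's published choices where stated: the
    cluster test uses an alpha level of 0.05 with the Bonferroni
    adjustment; the Beta approximation is evaluated at ``(span + 1) / N``
    so that same-residue clusters (span 0) receive finite p-values.

    Attributes
    ----------
    alpha
        Per-structure significance level for adjusted pair p-values.
    adjust
        Multiple-comparison adjustment over mutation pairs:
        ``"bonferroni"`` (default) or ``"bh"`` (Benjamini-Hochberg).
    mds_restarts
        Number of random initializations for the 1D stress majorization,
        in addition to the classical-scaling start.
    seed
        Seed feeding every source of randomness in a run.
    c_convention
        Evaluation point of the Beta CDF for a pair with span ``s``:
        ``"span_plus_one"`` uses ``(s + 1) / N`` (default, finite at
        span 0), ``"span"`` uses ``s / N``.
    min_identity
        Minimum alignment identity (over aligned columns) for accepting a
        structure-to-canonical-sequence reconciliation.
    gap_open, gap_extend
        Affine gap penalties (score units, negative) for the global
        end-gap-free pairwise alignment with BLOSUM62 scoring.
    accepted_statuses
        Somatic-status strings retained by the mutation filter; ``None``
        means the module defaults.
    linear_only
        Skip the MDS remapping and run the clustering test on canonical
        sequence positions (for 1D-vs-3D comparison).
    """

    alpha: float = 0.05
    adjust: str = "bonferroni"
    mds_restarts: int = 10
    seed: int = 0
    c_convention: str = "span_plus_one"
    min_identity: float = 0.6
    gap_open: float = -10.0
    gap_extend: float = -0.5
    accepted_statuses: tuple[str, ...] | None = None
    linear_only: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.adjust not in ("bonferroni", "bh"):
            raise ValueError(f"unknown adjustment {self.adjust!r}")
        if self.c_convention not in ("span_plus_one", "span"):
            raise ValueError(f"unknown c convention {self.c_convention!r}")
        if self.mds_restarts < 0:
            raise ValueError("mds_restarts must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["accepted_statuses"] is not None:
            d["accepted_statuses"] = list(d["accepted_statuses"])
        return d
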