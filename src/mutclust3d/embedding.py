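"""One-dimensional metric MDS of the Cα distance matrix.

The clustering test needs positions along a line, so the 3D backbone is
remapped to 1D scalars ``x1..xN`` such that ``|xi - xj|`` approximates
the Euclidean Cα distance ``δij`` as closely as possible.  Badness of
fit is measured by Stress-1,

    σ1 = sqrt( Σ_{i<j} (δij − |xi−xj|)² / Σ_{i<j} |xi−xj|² ),

which, unlike raw stress, is not distorted by the measurement units.
Optimization uses SMACOF majorization started from classical (Torgerson)
scaling plus random restarts — 1D stress surfaces are highly multimodal —
followed by the analytically optimal dilation of each candidate.
Residues are then linearized by the rank order of their 1D coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import smacof

from .structure import CaStructure


@dataclass
class Embedding1D:
    """Result of the 1D embedding.

    ``coords`` holds one scalar per residue; ``stress1`` is Kruskal's
    normalized badness of fit (0 = all pairwise distances preserved) and
    ``raw_stress`` its unnormalized numerator in Å².  ``linear_order``
    assigns each residue a rank 1..N by its coordinate, ties broken by
    the earlier residue.
    """

    coords: np.ndarray
    stress1: float
    raw_stress: float
    linear_order: np.ndarray  # (N,) int, a permutation of 1..N
    converged: bool = True

    @property
    def N(self) -> int:
        return len(self.coords)


def pairwise_distances(structure: CaStructure) -> np.ndarray:
    """Euclidean Cα distance matrix in Å (symmetric, zero diagonal)."""
    if structure.N < 2:
        raise ValueError("need at least 2 residues for a distance matrix")
    delta = squareform(pdist(structure.coords))
    off_diag_zero = (delta + np.eye(structure.N)) == 0
    if np.any(off_diag_zero):
        warnings.warn(
            "duplicate Cα coordinates: zero off-diagonal distances present",
            stacklevel=2,
        )
    return delta


def _pair_sums(coords: np.ndarray, delta: np.ndarray):
    x = np.asarray(coords, dtype=float).ravel()
    d = np.abs(x[:, None] - x[None, :])
    iu = np.triu_indices(len(x), k=1)
    return delta[iu], d[iu]


def stress1(coords: np.ndarray, delta: np.ndarray) -> float:
    """Stress-1 of a 1D configuration against a dissimilarity matrix.

    Sums run over unordered pairs; the value is invariant to translation
    and reflection of ``coords``.  Raises if all coordinates coincide
    (the normalization is undefined).
    """
    dl, d = _pair_sums(coords, delta)
    denom = float(np.sum(d**2))
    if denom == 0.0:
        raise ValueError("all coordinates identical: Stress-1 undefined")
    return float(np.sqrt(np.sum((dl - d) ** 2) / denom))


def raw_stress(coords: np.ndarray, delta: np.ndarray) -> float:
    """Unnormalized stress Σ_{i<j} (δij − |xi−xj|)² in squared Å."""
    dl, d = _pair_sums(coords, delta)
    return float(np.sum((dl - d) ** 2))


def classical_scaling_1d(delta: np.ndarray) -> np.ndarray:
    """Torgerson classical scaling to one dimension.

    Double-centers the squared dissimilarities and projects onto the
    leading eigenvector.  Exact when the dissimilarities come from truly
    collinear points.
    """
    n = delta.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (delta**2) @ j
    evals, evecs = np.linalg.eigh(b)
    lead = np.argmax(evals)
    lam = max(evals[lead], 0.0)
    return evecs[:, lead] * np.sqrt(lam)


def _optimal_dilation(coords: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """Rescale a configuration to minimize Stress-1 at fixed shape.

    With Stress-1 normalized by the configuration distances, the optimal
    dilation is t* = Σδ² / Σδd; applying it gives
    σ1² = 1 − (Σδd)² / (Σd² Σδ²).
    """
    dl, d = _pair_sums(coords, delta)
    a = float(np.sum(dl * d))
    if a <= 0:
        return coords
    t = float(np.sum(dl**2)) / a
    return coords * t


def embed_1d(
    delta: np.ndarray,
    restarts: int = 10,
    seed: int = 0,
    max_iter: int = 300,
    eps: float = 1e-9,
) -> Embedding1D:
    """Embed a dissimilarity matrix into 1D by minimizing Stress-1.

    Runs SMACOF majorization from the classical-scaling configuration
    and from ``restarts - 1`` random configurations, applies the optimal
    dilation to every candidate (including the unoptimized classical
    start), and keeps the candidate with the lowest Stress-1 — the
    result is therefore never worse than classical scaling alone.
    Deterministic for a fixed seed.

    Non-convergence within ``max_iter`` majorization steps is reported
    through ``converged=False`` on the best iterate, not an exception.
    """
    delta = np.asarray(delta, dtype=float)
    n = delta.shape[0]
    if n < 2:
        raise ValueError("need at least 2 residues to embed")
    rng = np.random.RandomState(seed % (2**32))

    classical = classical_scaling_1d(delta)
    scale = max(delta.max(), 1.0)
    inits = [classical]
    for _ in range(max(restarts - 1, 0)):
        inits.append(rng.uniform(-scale, scale, size=n))

    candidates: list[tuple[float, np.ndarray, bool]] = []
    # the raw classical configuration is itself a candidate
    cl = _optimal_dilation(classical, delta)
    candidates.append((stress1(cl, delta), cl, True))
    for init in inits:
        coords, _, n_iter = smacof(
            delta,
            metric=True,
            n_components=1,
            init=init[:, None],
            n_init=1,
            max_iter=max_iter,
            eps=eps,
            random_state=rng,
            normalized_stress=False,
            return_n_iter=True,
        )
        x = _optimal_dilation(coords.ravel(), delta)
        try:
            s1 = stress1(x, delta)
        except ValueError:
            continue  # degenerate collapse of all points
        candidates.append((s1, x, n_iter < max_iter))

    s1, best, converged = min(candidates, key=lambda c: c[0])
    if not converged:
        warnings.warn(
            "SMACOF did not converge within max_iter; returning best iterate",
            stacklevel=2,
        )
    order = _rank_order(best)
    return Embedding1D(
        coords=best,
        stress1=s1,
        raw_stress=raw_stress(best, delta),
        linear_order=order,
        converged=bool(converged),
    )


def _rank_order(coords: np.ndarray) -> np.ndarray:
    """Ranks 1..N of the coordinates; ties go to the earlier residue."""
    n = len(coords)
    order = np.lexsort((np.arange(n), coords))
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    return ranks


def linearize(embedding: Embedding1D) -> tuple[np.ndarray, np.ndarray]:
    """Linear positions of residues and the inverse map.

    Returns ``(to_linear, from_linear)``: ``to_linear[i]`` is the 1-based
    linear position of residue ``i`` (in structure order), and
    ``from_linear[r - 1]`` is the residue index occupying linear
    position ``r`` — used to map clusters back to canonical numbering.
    """
    to_linear = embedding.linear_order
    from_linear = np.empty(embedding.N, dtype=int)
    from_linear[to_linear - 1] = np.arange(embedding.N)
    return to_linear, from_linear
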