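"""Synthetic backbones and mutation samplers for testing and calibration.

Generates toy Cα backbones with known geometry (collinear, ideal
α-helix, β-hairpin, self-avoiding random coil) and per-sample mutation
tables drawn either from the uniform null the cluster test assumes or
from a spatially concentrated hotspot alternative.  Writers emit the
same PDB/TSV/FASTA dialects the pipeline reads, so synthetic fixtures
exercise the real parsers end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as biostruct
import biotite.structure.io.pdb as biopdb
import biotite.sequence as bioseq

from .mutations import (
    DEFAULT_ACCEPTED_STATUSES,
    MutationRecord,
    MutationTable,
    collapse_to_counts,
)
from .nmc import min_adjusted_pvalues
from .structure import CaStructure

GEOMETRIES = ("collinear", "helix", "hairpin", "random-coil")

#: Standard Cα–Cα virtual bond length, Å.
CA_CA_DISTANCE = 3.8
#: Ideal α-helix parameters: rise per residue (Å), twist per residue
#: (degrees), helix radius (Å).
HELIX_RISE = 1.5
HELIX_TWIST_DEG = 100.0
HELIX_RADIUS = 2.3
#: Cross-strand Cα separation of the hairpin, Å.
HAIRPIN_STRAND_SEP = 5.0

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic structure/mutation-table pair.

    ``mutation_model`` is ``"uniform"`` (each of the N residues equally
    likely) or ``"hotspot"``; for the latter, ``hotspots`` maps residue
    positions to extra probability mass (summing to at most 1), with the
    remaining mass spread uniformly over all residues.  ``n`` mutations
    are distributed round-robin over ``m`` samples.  A fixed seed makes
    structures and tables bit-reproducible.
    """

    N: int
    geometry: str = "collinear"
    mutation_model: str = "uniform"
    hotspots: dict[int, float] | None = None
    n: int = 0
    m: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.geometry not in GEOMETRIES:
            raise ValueError(
                f"unknown geometry {self.geometry!r}; choose from {GEOMETRIES}"
            )
        if self.mutation_model not in ("uniform", "hotspot"):
            raise ValueError(f"unknown mutation model {self.mutation_model!r}")
        if self.mutation_model == "hotspot":
            if not self.hotspots:
                raise ValueError("hotspot model requires hotspot weights")
            total = sum(self.hotspots.values())
            if not 0.0 < total <= 1.0 + 1e-9:
                raise ValueError(
                    f"hotspot weights must sum to (0, 1], got {total}"
                )
            if any(not 1 <= p <= self.N for p in self.hotspots):
                raise ValueError("hotspot positions must lie in 1..N")
        if self.n < 0 or self.m < 1:
            raise ValueError("need n >= 0 and m >= 1")

    def position_probabilities(self) -> np.ndarray:
        """Per-residue mutation probabilities implied by the model."""
        probs = np.full(self.N, 1.0 / self.N)
        if self.mutation_model == "hotspot":
            total = sum(self.hotspots.values())
            probs = np.full(self.N, (1.0 - total) / self.N)
            for pos, w in self.hotspots.items():
                probs[pos - 1] += w
        return probs


def _structure_rng(spec: SyntheticSpec) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))


def _mutation_rng(spec: SyntheticSpec) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))


def _collinear(n: int) -> np.ndarray:
    coords = np.zeros((n, 3))
    coords[:, 0] = CA_CA_DISTANCE * np.arange(n)
    return coords


def _helix(n: int) -> np.ndarray:
    t = np.deg2rad(HELIX_TWIST_DEG) * np.arange(n)
    return np.column_stack(
        [
            HELIX_RADIUS * np.cos(t),
            HELIX_RADIUS * np.sin(t),
            HELIX_RISE * np.arange(n),
        ]
    )


def _hairpin(n: int) -> np.ndarray:
    """Two antiparallel strands joined by a turn.

    Residue i on the first strand faces residue N - i + 1 on the second
    at the cross-strand separation, so sequence-distant ends are
    spatially adjacent.
    """
    half = n // 2
    coords = np.zeros((n, 3))
    coords[:half, 0] = CA_CA_DISTANCE * np.arange(half)
    if n % 2:  # turn residue at the far end, between the strands
        coords[half] = [
            CA_CA_DISTANCE * (half - 1) + HAIRPIN_STRAND_SEP / 2,
            HAIRPIN_STRAND_SEP / 2,
            0.0,
        ]
    back = np.arange(n - half - (n % 2))
    coords[half + (n % 2):, 0] = CA_CA_DISTANCE * (half - 1 - back)
    coords[half + (n % 2):, 1] = HAIRPIN_STRAND_SEP
    return coords


def _random_coil(n: int, rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding random walk with fixed Cα–Cα steps."""
    min_sep = 3.5  # Å, clash distance for non-consecutive residues
    for _ in range(200):  # walk restarts
        coords = [np.zeros(3)]
        ok = True
        for _ in range(n - 1):
            placed = False
            for _ in range(100):  # direction attempts per step
                step = rng.normal(size=3)
                step *= CA_CA_DISTANCE / np.linalg.norm(step)
                cand = coords[-1] + step
                prev = np.asarray(coords[:-1])
                if len(prev) and np.min(
                    np.linalg.norm(prev - cand, axis=1)
                ) < min_sep:
                    continue
                coords.append(cand)
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return np.asarray(coords)
    raise RuntimeError("self-avoiding walk failed to place all residues")


def make_structure(spec: SyntheticSpec) -> CaStructure:
    """Build a toy Cα backbone with the requested geometry.

    Canonical positions are 1..N and the amino-acid sequence is drawn
    deterministically from the spec's seed.
    """
    rng = _structure_rng(spec)
    sequence = "".join(rng.choice(list(_AA), size=spec.N))
    if spec.geometry == "collinear":
        coords = _collinear(spec.N)
    elif spec.geometry == "helix":
        coords = _helix(spec.N)
    elif spec.geometry == "hairpin":
        coords = _hairpin(spec.N)
    else:
        coords = _random_coil(spec.N, rng)
    return CaStructure(
        structure_id=f"synth-{spec.geometry}-{spec.N}",
        chain_id="A",
        positions=np.arange(1, spec.N + 1),
        sequence=sequence,
        coords=coords,
    )


def sample_positions(
    spec: SyntheticSpec, size: tuple[int, ...], rng: np.random.Generator
) -> np.ndarray:
    """Draw mutation positions (1-based) under the spec's model."""
    return rng.choice(
        np.arange(1, spec.N + 1), size=size, p=spec.position_probabilities()
    )


def sample_records(
    spec: SyntheticSpec, protein_id: str = "SYNTH"
) -> list[MutationRecord]:
    """Sample per-sample missense records; sample ids round-robin over m."""
    rng = _mutation_rng(spec)
    positions = sample_positions(spec, (spec.n,), rng)
    records = []
    for idx, pos in enumerate(positions):
        ref = rng.choice(list(_AA))
        alt = rng.choice([a for a in _AA if a != ref])
        records.append(
            MutationRecord(
                protein_id=protein_id,
                sample_id=f"S{idx % spec.m + 1}",
                position=int(pos),
                ref_aa=str(ref),
                alt_aa=str(alt),
                mut_class="missense",
                somatic_status=DEFAULT_ACCEPTED_STATUSES[0],
            )
        )
    return records


def sample_mutations(spec: SyntheticSpec, protein_id: str = "SYNTH") -> MutationTable:
    """Sampled records collapsed to per-residue counts."""
    records = sample_records(spec, protein_id)
    if not records:
        return MutationTable(protein_id=protein_id, counts={}, m=0)
    return collapse_to_counts(records)


def run_simulation(
    spec: SyntheticSpec,
    replicates: int,
    alpha: float = 0.05,
    c_convention: str = "span_plus_one",
) -> tuple[float, float]:
    """Monte-Carlo rejection rate of the cluster test under the spec's model.

    Draws ``replicates`` independent mutation tables, runs the
    Bonferroni-adjusted all-pairs test on linear positions 1..N, and
    returns the fraction of replicates with at least one significant
    cluster together with its binomial standard error.  Under the
    uniform model this estimates the family-wise error rate; under a
    hotspot model, power.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if spec.n < 2:
        raise ValueError("at least two mutations per replicate required")
    rng = _mutation_rng(spec)
    positions = sample_positions(spec, (replicates, spec.n), rng)
    min_adj = min_adjusted_pvalues(positions, spec.N, c_convention)
    rate = float(np.mean(min_adj <= alpha))
    se = float(np.sqrt(rate * (1.0 - rate) / replicates))
    return rate, se


def write_pdb(structure: CaStructure, path: str | Path) -> None:
    """Write a Cα-only PDB file readable by :func:`mutclust3d.parse_ca`."""
    n = structure.N
    atoms = biostruct.AtomArray(n)
    atoms.coord = structure.coords.astype(np.float32)
    atoms.chain_id = np.full(n, structure.chain_id)
    atoms.res_id = structure.positions
    atoms.ins_code = np.full(n, "")
    atoms.res_name = np.array(
        [
            bioseq.ProteinSequence.convert_letter_1to3(aa)
            for aa in structure.sequence
        ]
    )
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    atoms.hetero = np.zeros(n, dtype=bool)
    pdb_file = biopdb.PDBFile()
    pdb_file.set_structure(atoms)
    pdb_file.write(str(path))


def write_mutation_tsv(records: list[MutationRecord], path: str | Path) -> None:
    """Write records in the delimited dialect the mutation reader expects."""
    pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "sample_id": r.sample_id,
                "position": r.position,
                "ref_aa": r.ref_aa,
                "alt_aa": r.alt_aa,
                "class": r.mut_class,
                "status": r.somatic_status,
            }
            for r in records
        ],
        columns=[
            "protein_id",
            "sample_id",
            "position",
            "ref_aa",
            "alt_aa",
            "class",
            "status",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_fasta(sequence: str, path: str | Path, header: str = "SYNTH") -> None:
    with open(path, "w") as fh:
        fh.write(f">{header}\n")
        for i in range(0, len(sequence), 60):
            fh.write(sequence[i : i + 60] + "\n")
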