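"""Cα backbone extraction from PDB files and canonical-numbering reconciliation.

PDB structures and mutation databases number residues differently, so the
two coordinate systems must be reconciled before any positional test.
The extraction keeps one Cα per residue of a single chain (first-listed
alternate location; first model), and a global pairwise alignment maps
structure residue numbering onto the protein's canonical sequence.
Residues without coordinates are removed from the analysis, as are
mutations at residues without coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.sequence as bioseq
import biotite.sequence.align as bioalign
import biotite.structure.io.pdb as biopdb

from .mutations import MutationTable


class StructureError(ValueError):
    """Unusable structure input (no ATOM records, absent chain, ...)."""


class ReconciliationError(ValueError):
    """Structure and canonical sequence could not be reconciled."""


#: Common non-standard residues translated to their parent amino acid.
NONSTANDARD_3TO1 = {
    "MSE": "M",  # selenomethionine
    "CSO": "C",  # S-hydroxycysteine
    "SEC": "C",  # selenocysteine
    "SEP": "S",  # phosphoserine
    "TPO": "T",  # phosphothreonine
    "PTR": "Y",  # phosphotyrosine
    "HYP": "P",  # hydroxyproline
    "MLY": "K",  # N-dimethyl-lysine
    "PCA": "E",  # pyroglutamate
    "PYL": "K",  # pyrrolysine
}


@dataclass
class RawChain:
    """Cα trace of one chain as it appears in the file.

    Residues are in file order; ``res_numbers`` are the author-assigned
    residue sequence numbers (insertion-coded residues keep file order
    and share a number).  ``index`` into these lists is the internal
    residue key used by :class:`ResidueMapping`.
    """

    structure_id: str
    chain_id: str
    res_numbers: list[int]
    ins_codes: list[str]
    sequence: str
    coords: np.ndarray  # (n_residues, 3), Å

    def __len__(self) -> int:
        return len(self.res_numbers)


@dataclass
class ResidueMapping:
    """Injective, order-preserving map from chain residues to canonical positions.

    ``pairs`` is keyed by the residue's index within the chain (0-based,
    file order) and valued by the 1-based canonical sequence position;
    only aligned, non-gap columns are included.  ``coverage`` is the
    fraction of canonical positions mapped; ``identity`` the fraction of
    aligned columns whose residues agree.
    """

    pairs: dict[int, int]
    coverage: float
    identity: float

    def __post_init__(self) -> None:
        items = sorted(self.pairs.items())
        canon = [c for _, c in items]
        if any(b <= a for a, b in zip(canon, canon[1:])):
            raise ValueError("mapping is not strictly order-preserving")


@dataclass
class CaStructure:
    """Ordered Cα trace with residues renumbered to canonical positions.

    ``positions`` are strictly increasing 1-based canonical residue
    indices; ``coords`` are the matching Cα coordinates in Å.
    """

    structure_id: str
    chain_id: str
    positions: np.ndarray  # (N,) int, strictly increasing
    sequence: str
    coords: np.ndarray  # (N, 3), Å

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("canonical positions must be strictly increasing")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if len(self.positions) != len(self.coords):
            raise ValueError("positions/coords length mismatch")

    @property
    def N(self) -> int:
        return len(self.positions)


def _three_to_one(res_name: str) -> str | None:
    if res_name in NONSTANDARD_3TO1:
        return NONSTANDARD_3TO1[res_name]
    try:
        one = bioseq.ProteinSequence.convert_letter_3to1(res_name)
    except KeyError:
        return None
    return one


def parse_ca(
    path: str | Path,
    chain: str | None = None,
    canonical_seq: str | None = None,
    min_identity: float = 0.6,
) -> RawChain:
    """Extract the Cα trace of one chain from a PDB file.

    The first model is used; for alternate side-chain locations only the
    first-listed conformer is kept.  When ``chain`` is given, that chain
    is extracted.  Otherwise, if ``canonical_seq`` is supplied, the first
    chain in file order whose sequence aligns to it with at least
    ``min_identity`` identity is chosen; with neither, the first chain in
    file order is used.

    Residues with an unrecognizable name or without a Cα atom are
    dropped (with a warning for unknown names).
    """
    path = Path(path)
    pdb_file = biopdb.PDBFile.read(str(path))
    try:
        atoms = pdb_file.get_structure(model=1, altloc="first")
    except Exception as exc:
        raise StructureError(f"{path}: cannot read coordinates: {exc}") from exc
    if atoms.array_length() == 0:
        raise StructureError(f"{path}: no ATOM records")

    ca = atoms[atoms.atom_name == "CA"]
    if ca.array_length() == 0:
        raise StructureError(f"{path}: no Cα atoms")

    # chains in file order
    chain_order = list(dict.fromkeys(ca.chain_id))
    if chain is not None:
        if chain not in chain_order:
            raise StructureError(
                f"{path}: chain {chain!r} not found; available: "
                f"{', '.join(chain_order)}"
            )
        candidates = [chain]
    else:
        candidates = chain_order

    chosen: RawChain | None = None
    any_usable = False
    for cid in candidates:
        raw = _extract_chain(path.stem, ca, cid)
        if raw is None:
            continue
        any_usable = True
        if chain is None and canonical_seq is not None:
            try:
                align_to_canonical(
                    raw.sequence, canonical_seq, min_identity=min_identity
                )
            except ReconciliationError:
                continue
        chosen = raw
        break
    if chosen is None:
        if any_usable and canonical_seq is not None:
            raise ReconciliationError(
                f"{path}: no chain matches the canonical sequence "
                f"(tried: {', '.join(candidates)})"
            )
        raise StructureError(f"{path}: no chain with usable Cα residues")
    return chosen


def _extract_chain(structure_id: str, ca, chain_id: str) -> RawChain | None:
    sel = ca[ca.chain_id == chain_id]
    res_numbers: list[int] = []
    ins_codes: list[str] = []
    letters: list[str] = []
    coords: list[np.ndarray] = []
    seen: set[tuple[int, str]] = set()
    for i in range(sel.array_length()):
        key = (int(sel.res_id[i]), str(sel.ins_code[i]))
        if key in seen:
            # duplicate Cα for one residue (e.g. leftover altloc): first wins
            continue
        one = _three_to_one(str(sel.res_name[i]))
        if one is None:
            warnings.warn(
                f"{structure_id} chain {chain_id}: dropping unrecognized "
                f"residue {sel.res_name[i]} at {sel.res_id[i]}",
                stacklevel=2,
            )
            continue
        seen.add(key)
        res_numbers.append(int(sel.res_id[i]))
        ins_codes.append(str(sel.ins_code[i]))
        letters.append(one)
        coords.append(np.asarray(sel.coord[i], dtype=float))
    if not res_numbers:
        return None
    return RawChain(
        structure_id=structure_id,
        chain_id=chain_id,
        res_numbers=res_numbers,
        ins_codes=ins_codes,
        sequence="".join(letters),
        coords=np.vstack(coords),
    )


def align_to_canonical(
    structure_seq: str,
    canonical_seq: str,
    min_identity: float = 0.6,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> ResidueMapping:
    """Globally align the structure sequence to the canonical sequence.

    Uses BLOSUM62 scoring with affine gaps and free end gaps, so a
    structure covering a fragment of the protein aligns without terminal
    penalties.  Mismatched aligned residues are retained in the mapping
    (point substitutions between database sequences are tolerated), but
    an overall identity below ``min_identity`` raises
    :class:`ReconciliationError` to catch wrong-protein inputs.
    """
    if not structure_seq or not canonical_seq:
        raise ReconciliationError("empty sequence")
    matrix = bioalign.SubstitutionMatrix.std_protein_matrix()
    s1 = bioseq.ProteinSequence(structure_seq)
    s2 = bioseq.ProteinSequence(canonical_seq)
    aln = bioalign.align_optimal(
        s1,
        s2,
        matrix,
        gap_penalty=(gap_open, gap_extend),
        terminal_penalty=False,
        max_number=1,
    )[0]
    pairs: dict[int, int] = {}
    matches = 0
    for i1, i2 in aln.trace:
        if i1 == -1 or i2 == -1:
            continue
        pairs[int(i1)] = int(i2) + 1  # canonical positions are 1-based
        if structure_seq[i1] == canonical_seq[i2]:
            matches += 1
    if not pairs:
        raise ReconciliationError("alignment produced no aligned columns")
    # identity over the shorter sequence, not over aligned columns only:
    # a short gappy overlap between unrelated proteins must not pass
    identity = matches / min(len(structure_seq), len(canonical_seq))
    if identity < min_identity:
        raise ReconciliationError(
            f"alignment identity {identity:.2f} below threshold "
            f"{min_identity:.2f}; structure may not match this protein"
        )
    coverage = len(pairs) / len(canonical_seq)
    return ResidueMapping(pairs=pairs, coverage=coverage, identity=identity)


def build_ca_structure(raw: RawChain, mapping: ResidueMapping) -> CaStructure:
    """Renumber a raw Cα trace to canonical positions.

    Only mapped residues are kept; the result's ``N`` therefore excludes
    residues absent from the alignment, and downstream tests run on
    exactly the residues with coordinates.
    """
    if not mapping.pairs:
        raise ReconciliationError("empty residue mapping")
    idx = sorted(mapping.pairs)
    positions = np.array([mapping.pairs[i] for i in idx], dtype=int)
    coords = raw.coords[idx]
    sequence = "".join(raw.sequence[i] for i in idx)
    return CaStructure(
        structure_id=raw.structure_id,
        chain_id=raw.chain_id,
        positions=positions,
        sequence=sequence,
        coords=coords,
    )


def restrict_mutations(table: MutationTable, structure: CaStructure) -> MutationTable:
    """Drop mutation counts at residues lacking structural coordinates.

    Mutational data at residues without positional data cannot be placed
    in 3D and are not used; ``n`` is recomputed accordingly.
    """
    present = set(int(p) for p in structure.positions)
    counts = {p: c for p, c in table.counts.items() if p in present}
    return MutationTable(protein_id=table.protein_id, counts=counts, m=table.m)
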