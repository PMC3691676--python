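"""Reading, filtering and collapsing per-sample somatic mutation records.

The clustering test consumes per-residue mutation counts for a single
protein.  This module turns a delimited per-sample mutation table into
those counts: only missense mutations with an accepted somatic status are
kept, redundant reports of the same event are removed, and the surviving
records are collapsed across samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

#: Somatic-status categories retained by default.  Mutations whose status
#: is anything else (e.g. "Variant of unknown origin") are excluded, as
#: are all non-missense classes.
DEFAULT_ACCEPTED_STATUSES: tuple[str, ...] = (
    "Confirmed somatic variant",
    "Reported in another cancer sample as somatic",
)

REQUIRED_COLUMNS = (
    "protein_id",
    "sample_id",
    "position",
    "ref_aa",
    "alt_aa",
    "class",
    "status",
)

MUTATION_CLASSES = ("missense", "nonsense", "synonymous", "other")


class MutationTableError(ValueError):
    """Malformed mutation input (missing columns, bad positions, ...)."""


@dataclass(frozen=True)
class MutationRecord:
    """A single reported amino-acid substitution in one sample.

    ``position`` is the 1-based residue index in the protein's canonical
    sequence.  ``mut_class`` is one of ``missense``, ``nonsense``,
    ``synonymous`` or ``other``; only missense records are ever tested.
    """

    protein_id: str
    sample_id: str
    position: int
    ref_aa: str
    alt_aa: str
    mut_class: str
    somatic_status: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.mut_class not in MUTATION_CLASSES:
            raise ValueError(f"unknown mutation class {self.mut_class!r}")
        if self.mut_class == "missense" and self.ref_aa == self.alt_aa:
            raise ValueError(
                f"missense record at position {self.position} has "
                f"ref_aa == alt_aa == {self.ref_aa!r}"
            )


@dataclass
class MutationTable:
    """Per-residue mutation counts for one protein.

    ``counts`` maps canonical residue position to a positive mutation
    count; positions without mutations are absent.  ``n`` is the total
    number of mutations and ``m`` the number of distinct samples they
    came from.
    """

    protein_id: str
    counts: dict[int, int] = field(default_factory=dict)
    m: int = 0

    def __post_init__(self) -> None:
        for pos, c in self.counts.items():
            if pos < 1:
                raise ValueError(f"counted position {pos} < 1")
            if c <= 0:
                raise ValueError(f"non-positive count {c} at position {pos}")

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def positions(self) -> list[int]:
        return sorted(self.counts)


def read_mutation_records(
    path: str | Path, delimiter: str = "\t"
) -> list[MutationRecord]:
    """Read per-sample mutation records from a delimited text file.

    The file must carry a header with the columns ``protein_id``,
    ``sample_id``, ``position``, ``ref_aa``, ``alt_aa``, ``class`` and
    ``status``.  Extra columns are ignored.

    Raises
    ------
    MutationTableError
        If a required column is missing, or a position fails to parse as
        a positive integer (the error names the offending line).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise MutationTableError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    records: list[MutationRecord] = []
    for row_idx, row in enumerate(df.itertuples(index=False)):
        # +2: header line plus 1-based numbering
        line_no = row_idx + 2
        raw_pos = getattr(row, "position")
        try:
            position = int(raw_pos)
        except (TypeError, ValueError):
            raise MutationTableError(
                f"{path}, line {line_no}: unparseable position {raw_pos!r}"
            ) from None
        try:
            records.append(
                MutationRecord(
                    protein_id=getattr(row, "protein_id"),
                    sample_id=getattr(row, "sample_id"),
                    position=position,
                    ref_aa=getattr(row, "ref_aa"),
                    alt_aa=getattr(row, "alt_aa"),
                    mut_class=getattr(row, "_5"),  # "class" is a keyword
                    somatic_status=getattr(row, "status"),
                )
            )
        except ValueError as exc:
            raise MutationTableError(f"{path}, line {line_no}: {exc}") from None
    return records


def filter_mutations(
    records: list[MutationRecord],
    accepted_statuses: tuple[str, ...] | set[str] | None = None,
) -> list[MutationRecord]:
    """Keep only missense mutations with an accepted somatic status.

    Nonsense, synonymous and other classes are excluded, as are missense
    records whose status is not in ``accepted_statuses`` (defaults to
    :data:`DEFAULT_ACCEPTED_STATUSES`).
    """
    accepted = (
        set(DEFAULT_ACCEPTED_STATUSES)
        if accepted_statuses is None
        else set(accepted_statuses)
    )
    return [
        r
        for r in records
        if r.mut_class == "missense" and r.somatic_status in accepted
    ]


def deduplicate(records: list[MutationRecord]) -> list[MutationRecord]:
    """Remove redundant reports of the same mutation event.

    Multiple studies can report the same event from the same sample or
    cell line; to avoid double counting, at most one record is kept per
    ``(sample_id, position, alt_aa)`` triple.  The first occurrence wins;
    input order is otherwise preserved.
    """
    seen: set[tuple[str, int, str]] = set()
    out: list[MutationRecord] = []
    for r in records:
        key = (r.sample_id, r.position, r.alt_aa)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def drop_out_of_range(
    records: list[MutationRecord], seq_length: int
) -> list[MutationRecord]:
    """Drop records whose position exceeds the canonical sequence length.

    Emits a warning per dropped record rather than failing: positions
    beyond the sequence usually indicate isoform-numbering mismatches and
    are excluded from analysis like any other unmatchable data.
    """
    kept: list[MutationRecord] = []
    for r in records:
        if r.position > seq_length:
            warnings.warn(
                f"dropping mutation at position {r.position} beyond "
                f"canonical sequence length {seq_length}",
                stacklevel=2,
            )
        else:
            kept.append(r)
    return kept


def collapse_to_counts(records: list[MutationRecord]) -> MutationTable:
    """Collapse per-sample records into per-residue counts.

    All records must share one ``protein_id``.  The result's ``n`` equals
    the number of records and ``m`` the number of distinct samples.
    """
    protein_ids = {r.protein_id for r in records}
    if len(protein_ids) > 1:
        raise MutationTableError(
            f"records span multiple proteins: {sorted(protein_ids)}"
        )
    protein_id = protein_ids.pop() if protein_ids else ""
    counts: dict[int, int] = {}
    for r in records:
        counts[r.position] = counts.get(r.position, 0) + 1
    m = len({r.sample_id for r in records})
    return MutationTable(protein_id=protein_id, counts=counts, m=m)
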