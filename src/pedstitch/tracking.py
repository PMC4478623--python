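"""Field-level provenance: the source of every attribute of every individual.

The table maps each (individual id, field name) pair of a companion
pedigree to a source label — typically the base name of the pedigree file
the value came from, or ``"manual"`` for hand edits.  The domain is total:
every role field (name, father, mother, sex) and every attribute column of
every member has exactly one label, no gaps.  Only the current source is
stored, not a history: the goal is tracing a value back to its origin.

On disk the table is a metadata file: a TSV mirroring the pedigree file's
geometry (same rows, same columns) plus a leading id column, so row i /
column j holds the source label of member i's j-th field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import GeometryError, ProvenanceError
from .model import Pedigree

ID_HEADER = "ID"


@dataclass
class ProvenanceTable:
    """Immutable-by-convention mapping (id, field) -> source label."""

    labels: dict[tuple[str, str], str] = field(default_factory=dict)
    default_source: str = ""

    def copy(self) -> "ProvenanceTable":
        return ProvenanceTable(dict(self.labels), self.default_source)

    def domain(self) -> set[tuple[str, str]]:
        return set(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ProvenanceTable):
            return NotImplemented
        return self.labels == other.labels


def default_provenance(ped: Pedigree, pedigree_file_name: str) -> ProvenanceTable:
    """Label every (id, field) pair with the pedigree file's name."""
    labels = {
        (member.id, f): pedigree_file_name
        for member in ped.members
        for f in ped.fields()
    }
    return ProvenanceTable(labels, pedigree_file_name)


def trace(table: ProvenanceTable, individual_id: str, field_name: str) -> str:
    """Source label of one field of one individual; pure query."""
    try:
        return table.labels[(individual_id, field_name)]
    except KeyError:
        raise ProvenanceError(
            f"no provenance entry for ({individual_id!r}, {field_name!r})"
        ) from None


def record_change(
    table: ProvenanceTable, individual_id: str, field_name: str, new_source: str
) -> ProvenanceTable:
    """Return a new table with one entry relabeled; the input is unchanged."""
    if (individual_id, field_name) not in table.labels:
        raise ProvenanceError(
            f"no provenance entry for ({individual_id!r}, {field_name!r})"
        )
    if not new_source:
        raise ProvenanceError("source label must be non-empty")
    new = table.copy()
    new.labels[(individual_id, field_name)] = new_source
    return new


def add_rows(
    table: ProvenanceTable, ped: Pedigree, individual_id: str, source: str
) -> ProvenanceTable:
    """Create the full field set for a newly added individual."""
    new = table.copy()
    for f in ped.fields():
        new.labels[(individual_id, f)] = source
    return new


def drop_rows(table: ProvenanceTable, individual_id: str) -> ProvenanceTable:
    """Remove every entry of one individual (after removal from the pedigree)."""
    new = table.copy()
    new.labels = {
        key: label for key, label in new.labels.items() if key[0] != individual_id
    }
    return new


def is_total(table: ProvenanceTable, ped: Pedigree) -> bool:
    """True iff the table's domain is exactly the pedigree's (id, field) set."""
    expected = {(m.id, f) for m in ped.members for f in ped.fields()}
    return table.domain() == expected


def write_metadata(table: ProvenanceTable, ped: Pedigree, path) -> None:
    """Serialize the table as a TSV parallel to the pedigree file.

    Each row corresponds to a row in the pedigree file; the first column
    repeats the individual id for self-description.
    """
    if not is_total(table, ped):
        raise ProvenanceError(
            "provenance table does not cover the pedigree's (id, field) domain"
        )
    fields = ped.fields()
    lines = ["\t".join((ID_HEADER,) + fields)]
    for member in ped.members:
        lines.append(
            "\t".join([member.id] + [table.labels[(member.id, f)] for f in fields])
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_metadata(path, ped: Pedigree) -> ProvenanceTable:
    """Read a metadata file, checking its geometry against the pedigree."""
    path = Path(path)
    with open(path, encoding="utf-8", newline="") as handle:
        lines = [line.rstrip("\r\n") for line in handle if line.rstrip("\r\n")]
    fields = ped.fields()
    expected_cols = 1 + len(fields)
    if not lines:
        raise GeometryError(f"{path}: empty metadata file")
    rows = [line.split("\t") for line in lines[1:]]
    if len(rows) != len(ped.members):
        raise GeometryError(
            f"{path}: expected {len(ped.members)} rows, found {len(rows)}"
        )
    labels: dict[tuple[str, str], str] = {}
    for lineno, (member, row) in enumerate(zip(ped.members, rows), start=2):
        if len(row) != expected_cols:
            raise GeometryError(
                f"{path}:{lineno}: expected {expected_cols} columns, "
                f"found {len(row)}"
            )
        if row[0] != member.id:
            raise GeometryError(
                f"{path}:{lineno}: row id {row[0]!r} does not correspond to "
                f"pedigree row id {member.id!r}"
            )
        for f, label in zip(fields, row[1:]):
            if not label:
                raise GeometryError(
                    f"{path}:{lineno}: empty source label for field {f!r}"
                )
            labels[(member.id, f)] = label
    default = ped.name
    return ProvenanceTable(labels, default)
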