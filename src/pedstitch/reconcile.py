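"""Cross-pedigree comparison, discordance reconciliation, and editing.

Two informants rarely report identical information about the same person.
:func:`compare_individual` lines up one individual's fields across two
pedigrees; :func:`reconcile_individual` applies the user's per-field
choices before a merge, so that destination precedence never silently
discards information the user would have preferred to keep.

All operations are copy-on-write: inputs are never modified, and every
change is recorded in the companion provenance table.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import EditError, NoSuchIndividualError
from .model import MISSING, Individual, Pedigree, ROLE_FIELDS
from .tracking import (
    ProvenanceTable,
    add_rows,
    default_provenance,
    drop_rows,
    record_change,
)

MANUAL_SOURCE = "manual"

EQUAL = "equal"
DISCORDANT = "discordant"
ONLY_A = "only-A"
ONLY_B = "only-B"


@dataclass(frozen=True)
class DiffRow:
    field: str
    value_a: str | None
    value_b: str | None
    status: str


@dataclass
class FieldDiff:
    """Field-by-field comparison of one individual across two pedigrees."""

    id: str
    rows: list[DiffRow]

    def discordant_fields(self) -> list[str]:
        return [r.field for r in self.rows if r.status == DISCORDANT]

    def to_tsv(self) -> str:
        lines = ["field\tA\tB\tstatus"]
        for r in self.rows:
            lines.append(
                f"{r.field}\t{'' if r.value_a is None else r.value_a}\t"
                f"{'' if r.value_b is None else r.value_b}\t{r.status}"
            )
        return "\n".join(lines) + "\n"

    def to_text(self) -> str:
        """Aligned-column report, the batch analog of a side-by-side view."""
        header = ("field", "A", "B", "status")
        table = [header] + [
            (
                r.field,
                "-" if r.value_a is None else r.value_a,
                "-" if r.value_b is None else r.value_b,
                r.status,
            )
            for r in self.rows
        ]
        widths = [max(len(row[i]) for row in table) for i in range(4)]
        lines = ["  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip()
                 for row in table]
        return "\n".join(lines) + "\n"


def compare_individual(
    a: Pedigree, b: Pedigree, individual_id: str
) -> FieldDiff:
    """One row per field of the union of both schemas.

    Field order is deterministic: role fields first, then A's attribute
    columns in A's order, then B-only columns.  A field is *present* on one
    side iff the individual exists there and the field is in that
    pedigree's schema; ``equal`` means present on both sides and identical.
    """
    in_a, in_b = individual_id in a, individual_id in b
    if not in_a and not in_b:
        raise NoSuchIndividualError(individual_id, f"{a.name!r} or {b.name!r}")
    ma = a.get(individual_id) if in_a else None
    mb = b.get(individual_id) if in_b else None
    fields = list(ROLE_FIELDS) + list(a.columns) + [
        c for c in b.columns if c not in a.columns
    ]
    rows: list[DiffRow] = []
    for f in fields:
        has_a = ma is not None and (f in ROLE_FIELDS or f in a.columns)
        has_b = mb is not None and (f in ROLE_FIELDS or f in b.columns)
        va = ma.field_value(f) if has_a else None
        vb = mb.field_value(f) if has_b else None
        if has_a and has_b:
            status = EQUAL if va == vb else DISCORDANT
        elif has_a:
            status = ONLY_A
        else:
            status = ONLY_B
        rows.append(DiffRow(f, va, vb, status))
    return FieldDiff(individual_id, rows)


def _ensure_table(ped: Pedigree, table: ProvenanceTable | None) -> ProvenanceTable:
    return table if table is not None else default_provenance(ped, ped.name)


def reconcile_individual(
    a: Pedigree,
    b: Pedigree,
    individual_id: str,
    choices: dict[str, str | tuple[str, str]],
    target: str = "A",
    table: ProvenanceTable | None = None,
) -> tuple[Pedigree, ProvenanceTable]:
    """Apply per-field choices to the target pedigree.

    ``choices`` maps a field name to ``"A"`` or ``"B"`` (take that
    pedigree's value) or ``("value", v)`` for an explicit manual value.
    Every discordant field must be covered — unresolved discordances are an
    error, forcing explicit review rather than a silent default.  The
    provenance of each changed field is the donor pedigree's name, or
    ``"manual"`` for explicit values.
    """
    diff = compare_individual(a, b, individual_id)
    unresolved = [f for f in diff.discordant_fields() if f not in choices]
    if unresolved:
        raise EditError(
            "unresolved discordant fields: " + ", ".join(unresolved)
        )
    if target not in ("A", "B"):
        raise EditError(f"target must be 'A' or 'B', not {target!r}")
    target_ped = a if target == "A" else b
    by_field = {r.field: r for r in diff.rows}
    ped = target_ped.copy()
    prov = _ensure_table(target_ped, table)
    for field_name, choice in choices.items():
        if field_name not in by_field:
            raise EditError(f"unknown field {field_name!r} for {individual_id!r}")
        row = by_field[field_name]
        if choice == "A":
            value, label = row.value_a, a.name
        elif choice == "B":
            value, label = row.value_b, b.name
        elif isinstance(choice, tuple) and len(choice) == 2 and choice[0] == "value":
            value, label = choice[1], MANUAL_SOURCE
        else:
            raise EditError(
                f"choice for {field_name!r} must be 'A', 'B' or ('value', v)"
            )
        if value is None:
            raise EditError(
                f"field {field_name!r} has no value in pedigree {choice}"
            )
        ped, prov = edit_individual(
            ped, individual_id, field_name, value, label, prov
        )
    return ped, prov


def add_individual(
    ped: Pedigree,
    individual: Individual,
    provenance_label: str = MANUAL_SOURCE,
    table: ProvenanceTable | None = None,
) -> tuple[Pedigree, ProvenanceTable]:
    """Append one individual; its id must be new and its parents resolvable."""
    if individual.id in ped:
        raise EditError(f"duplicate id {individual.id!r}")
    for role, parent in (
        ("father", individual.father_id),
        ("mother", individual.mother_id),
    ):
        if parent != MISSING and parent not in ped:
            raise EditError(
                f"{role} {parent!r} of new individual {individual.id!r} "
                "is not in the pedigree"
            )
    table = _ensure_table(ped, table)
    new_ped = ped.copy()
    member = individual.copy()
    for column in ped.columns:
        member.attributes.setdefault(column, MISSING)
    unknown = [c for c in member.attributes if c not in ped.columns]
    if unknown:
        raise EditError(f"attributes outside the pedigree schema: {unknown}")
    new_ped.members.append(member)
    new_ped._index[member.id] = len(new_ped.members) - 1
    return new_ped, add_rows(table, new_ped, member.id, provenance_label)


def remove_individual(
    ped: Pedigree,
    individual_id: str,
    cascade: str = "forbid",
    table: ProvenanceTable | None = None,
) -> tuple[Pedigree, ProvenanceTable]:
    """Remove one individual.

    ``cascade="forbid"`` (default, safest) refuses if anyone references the
    individual as a parent; ``cascade="detach-children"`` blanks the
    matching parent reference of each child instead, recording the change.
    """
    ped.get(individual_id)
    children = ped.children_of(individual_id)
    if cascade == "forbid":
        if children:
            raise EditError(
                f"cannot remove {individual_id!r}: referenced as parent by "
                + ", ".join(c.id for c in children)
            )
    elif cascade != "detach-children":
        raise EditError(f"unknown cascade policy {cascade!r}")
    table = _ensure_table(ped, table)
    members = []
    for member in ped.members:
        if member.id == individual_id:
            continue
        copy = member.copy()
        if copy.father_id == individual_id:
            copy.father_id = MISSING
            table = record_change(table, copy.id, "father", MANUAL_SOURCE)
        if copy.mother_id == individual_id:
            copy.mother_id = MISSING
            table = record_change(table, copy.id, "mother", MANUAL_SOURCE)
        members.append(copy)
    return Pedigree(ped.name, ped.columns, members), drop_rows(table, individual_id)


def edit_individual(
    ped: Pedigree,
    individual_id: str,
    field_name: str,
    value: str,
    provenance_label: str = MANUAL_SOURCE,
    table: ProvenanceTable | None = None,
) -> tuple[Pedigree, ProvenanceTable]:
    """Single-field update, copy-on-write.

    Parent-field edits must name a member or the missing sentinel.  An edit
    to the current value still updates the provenance label: confirming a
    value from a second source is itself information.
    """
    member = ped.get(individual_id)
    if field_name not in ped.fields():
        raise EditError(f"unknown field {field_name!r}")
    if field_name == "name":
        raise EditError("renaming individuals is not supported via edit")
    if field_name in ("father", "mother"):
        if value != MISSING and value not in ped:
            raise EditError(f"{field_name} {value!r} is not in the pedigree")
        if value == individual_id:
            raise EditError(f"{individual_id!r} cannot be its own parent")
    table = _ensure_table(ped, table)
    new_ped = ped.copy()
    position = new_ped.position(individual_id)
    new_ped.members[position] = member.with_field(field_name, value)
    return new_ped, record_change(table, individual_id, field_name, provenance_label)
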