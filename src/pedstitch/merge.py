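"""The three pedigree merge algorithms with duplicate resolution.

A merge has a direction (source into destination) and a scope: the
sublineage of a chosen root in the source pedigree — the root, all of its
descendants without generation limit, and the married-in partners needed
to keep parental pairs intact.

* **replace** — the destination anchor's branch (anchor + descendants) is
  removed and the source sublineage takes its place; the source root
  inherits the anchor's parent references.
* **combine** — the source sublineage is folded into the destination;
  individuals present in both are represented once.  Iterating combines on
  the result is supported.
* **add** — the source sublineage is appended with the source root becoming
  a new sibling of the destination anchor (it takes the anchor's parents).

In every mode duplicated individuals are represented by only one person in
the result.  Where a duplicated pair disagrees on a value, destination
precedence applies: the destination value is kept and the discordance is
recorded as a conflict row.  Where the destination value is missing and the
source value is not, the source value fills the gap; gap-fills are listed
separately in the report and their provenance is the source label.

All inputs are left unmodified; each operation returns a fresh pedigree,
a provenance table over it, and a report of what happened.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import AmbiguousMatchError, IdCollisionError, MergeError
from .model import (
    MISSING,
    Individual,
    Pedigree,
    Sex,
    Sublineage,
    error_findings,
    extract_sublineage,
    descendants,
    validate,
)
from .tracking import ProvenanceTable, default_provenance

MANUAL_SOURCE = "manual"


@dataclass
class MergePlan:
    """A merge direction, mode, anchors, and matching policy.

    ``dest_anchor_id`` is, per mode: the root of the replaced branch
    (replace), the destination sublineage root (combine), or the individual
    whose sibling the source root becomes (add).  ``match_key`` names the
    field(s) used to equate individuals across the two pedigrees; the
    default is the id/name field.
    """

    mode: str  # "replace" | "combine" | "add"
    source: Pedigree
    dest: Pedigree
    source_root_id: str
    dest_anchor_id: str
    match_key: str | tuple[str, ...] = "name"
    source_label: str | None = None
    dest_label: str | None = None
    source_provenance: ProvenanceTable | None = None
    dest_provenance: ProvenanceTable | None = None
    rename_collisions: bool = False


@dataclass
class Conflict:
    """A discordant field of a duplicated individual; destination wins."""

    id: str
    field: str
    source_value: str
    dest_value: str
    kept_value: str


@dataclass
class GapFill:
    """A destination-missing field filled from the source."""

    id: str
    field: str
    value: str


@dataclass
class MergeReport:
    added_ids: list[str] = field(default_factory=list)
    removed_ids: list[str] = field(default_factory=list)
    duplicate_pairs: list[tuple[str, str]] = field(default_factory=list)
    conflicts: list[Conflict] = field(default_factory=list)
    gap_fills: list[GapFill] = field(default_factory=list)
    renamed_ids: dict[str, str] = field(default_factory=dict)

    def to_tsv(self) -> str:
        lines = ["#section\tcolumns..."]
        for added in self.added_ids:
            lines.append(f"added\t{added}")
        for removed in self.removed_ids:
            lines.append(f"removed\t{removed}")
        for src, dst in self.duplicate_pairs:
            lines.append(f"duplicate\t{src}\t{dst}")
        for c in self.conflicts:
            lines.append(
                f"conflict\t{c.id}\t{c.field}\t{c.source_value}\t"
                f"{c.dest_value}\t{c.kept_value}"
            )
        for g in self.gap_fills:
            lines.append(f"gap_fill\t{g.id}\t{g.field}\t{g.value}")
        for old, new in self.renamed_ids.items():
            lines.append(f"renamed\t{old}\t{new}")
        return "\n".join(lines) + "\n"

    def summary(self) -> str:
        return (
            f"added {len(self.added_ids)}, removed {len(self.removed_ids)}, "
            f"{len(self.duplicate_pairs)} duplicate pair(s), "
            f"{len(self.conflicts)} conflict(s) (destination kept), "
            f"{len(self.gap_fills)} gap-fill(s), "
            f"{len(self.renamed_ids)} renamed"
        )


def _match_value(ped: Pedigree, individual: Individual, match_key):
    keys = (match_key,) if isinstance(match_key, str) else tuple(match_key)
    return tuple(individual.field_value(k) for k in keys)


def find_duplicates(
    sub: Sublineage,
    source: Pedigree,
    dest: Pedigree,
    match_key: str | tuple[str, ...] = "name",
    dest_ids: set[str] | None = None,
) -> list[tuple[str, str]]:
    """Pair source sublineage members with equal-keyed destination members.

    The pairing is injective both ways; any source individual matching two
    or more destination candidates (or two sources claiming one
    destination) is an ambiguity error, never a guess.  ``dest_ids``
    optionally restricts the destination side (used by replace, which
    matches only against surviving members).
    """
    candidates: dict[tuple, list[str]] = {}
    for member in dest.members:
        if dest_ids is not None and member.id not in dest_ids:
            continue
        candidates.setdefault(_match_value(dest, member, match_key), []).append(
            member.id
        )
    pairs: list[tuple[str, str]] = []
    claimed: dict[str, str] = {}
    for source_id in sub.member_order:
        key = _match_value(source, source.get(source_id), match_key)
        found = candidates.get(key, [])
        if len(found) > 1:
            raise AmbiguousMatchError(source_id, found)
        if found:
            dest_id = found[0]
            if dest_id in claimed:
                raise AmbiguousMatchError(dest_id, [claimed[dest_id], source_id])
            claimed[dest_id] = source_id
            pairs.append((source_id, dest_id))
    return pairs


def resolve_duplicate(
    source_ind: Individual, dest_ind: Individual
) -> tuple[Individual, list[Conflict], list[GapFill]]:
    """Resolve one duplicated pair under destination precedence.

    For every field where both values are non-missing and differ, the
    destination value is kept and a conflict row records both.  Where the
    destination value is the missing sentinel and the source value is not,
    the source value fills the gap (returned separately).  Parent
    references and sex follow the same rule.  Gap-filled parent references
    still name *source* individuals; callers remap them into the result.
    """
    merged = dest_ind.copy()
    conflicts: list[Conflict] = []
    fills: list[GapFill] = []

    def _resolve(field_name: str, source_value: str, dest_value: str) -> str:
        if source_value == dest_value:
            return dest_value
        if dest_value != MISSING:
            if source_value != MISSING:
                conflicts.append(
                    Conflict(dest_ind.id, field_name, source_value, dest_value, dest_value)
                )
            return dest_value
        if source_value != MISSING:
            fills.append(GapFill(dest_ind.id, field_name, source_value))
            return source_value
        return dest_value

    merged.father_id = _resolve("father", source_ind.father_id, dest_ind.father_id)
    merged.mother_id = _resolve("mother", source_ind.mother_id, dest_ind.mother_id)
    merged.sex = Sex.from_code(
        _resolve("sex", source_ind.sex.code, dest_ind.sex.code)
    )
    for attr in list(dest_ind.attributes) + [
        a for a in source_ind.attributes if a not in dest_ind.attributes
    ]:
        merged.attributes[attr] = _resolve(
            attr,
            source_ind.attributes.get(attr, MISSING),
            dest_ind.attributes.get(attr, MISSING),
        )
    return merged, conflicts, fills


def _check_inputs(plan: MergePlan) -> None:
    for which, ped in (("source", plan.source), ("destination", plan.dest)):
        errors = error_findings(validate(ped))
        if errors:
            raise MergeError(
                f"{which} pedigree {ped.name!r} fails validation: "
                + "; ".join(f.message for f in errors)
            )
    plan.source.get(plan.source_root_id)
    plan.dest.get(plan.dest_anchor_id)


def _labels(plan: MergePlan) -> tuple[str, str]:
    return (
        plan.source_label or plan.source.name,
        plan.dest_label or plan.dest.name,
    )


def _assemble(
    plan: MergePlan,
    survivors: list[Individual],
    sub: Sublineage,
    removed_ids: list[str],
    reparent_root_to: Individual | None,
) -> tuple[Pedigree, ProvenanceTable, MergeReport]:
    """Shared back half of all three modes.

    ``survivors`` are the retained destination members in file order;
    ``reparent_root_to`` (replace/add) donates its parent references to the
    source root when the root is actually appended.
    """
    source, dest = plan.source, plan.dest
    source_label, dest_label = _labels(plan)
    report = MergeReport(removed_ids=list(removed_ids))

    survivor_ids = {m.id for m in survivors}
    pairs = find_duplicates(sub, source, dest, plan.match_key, dest_ids=survivor_ids)
    pair_map = dict(pairs)  # source id -> dest id
    report.duplicate_pairs = pairs

    added_order = [sid for sid in sub.member_order if sid not in pair_map]
    rename: dict[str, str] = {}
    if plan.match_key != "name":
        for sid in added_order:
            if sid in survivor_ids:
                if not plan.rename_collisions:
                    raise IdCollisionError(
                        f"source id {sid!r} collides with an unmatched "
                        "destination id (use rename_collisions)"
                    )
                new_id = f"{sid}@{source_label}"
                while new_id in survivor_ids:
                    new_id += "+"
                rename[sid] = new_id
        report.renamed_ids = dict(rename)

    added_ids = {rename.get(sid, sid) for sid in added_order}
    result_ids = survivor_ids | added_ids

    def _remap_parent(value: str) -> str:
        """Parent reference of an imported member, expressed in result ids."""
        if value == MISSING:
            return MISSING
        if value in pair_map:
            return pair_map[value]
        value = rename.get(value, value)
        return value if value in result_ids else MISSING

    # provenance base: retained destination entries keep their labels
    dest_prov = plan.dest_provenance or default_provenance(dest, dest_label)
    labels: dict[tuple[str, str], str] = {}

    members: list[Individual] = []
    matched_dest = {did: sid for sid, did in pairs}
    for member in survivors:
        if member.id in matched_dest:
            source_ind = source.get(matched_dest[member.id])
            merged, conflicts, fills = resolve_duplicate(source_ind, member)
            for f in fills:
                if f.field in ("father", "mother"):
                    remapped = _remap_parent(f.value)
                    merged = merged.with_field(f.field, remapped)
                    f.value = remapped
            report.conflicts.extend(conflicts)
            report.gap_fills.extend(f for f in fills if f.value != MISSING)
            members.append(merged)
        else:
            members.append(member.copy())
    filled = {(g.id, g.field) for g in report.gap_fills}

    root_result_id = rename.get(sub.root_id, sub.root_id)
    for sid in added_order:
        member = source.get(sid).copy()
        member.id = rename.get(sid, sid)
        if sid == sub.root_id and reparent_root_to is not None:
            member.father_id = reparent_root_to.father_id
            member.mother_id = reparent_root_to.mother_id
        else:
            member.father_id = _remap_parent(member.father_id)
            member.mother_id = _remap_parent(member.mother_id)
        members.append(member)
        report.added_ids.append(member.id)

    columns = list(dest.columns) + [c for c in source.columns if c not in dest.columns]
    result = Pedigree(dest.name, columns, members)

    all_fields = result.fields()
    for member in result.members:
        original_dest = member.id in survivor_ids
        for f in all_fields:
            if original_dest:
                if (member.id, f) in filled:
                    labels[(member.id, f)] = source_label
                else:
                    labels[(member.id, f)] = dest_prov.labels.get(
                        (member.id, f), dest_label
                    )
            else:
                src_id = next(
                    (s for s, new in rename.items() if new == member.id), member.id
                )
                if plan.source_provenance is not None:
                    labels[(member.id, f)] = plan.source_provenance.labels.get(
                        (src_id, f), source_label
                    )
                else:
                    labels[(member.id, f)] = source_label
                if (
                    f in ("father", "mother")
                    and member.id == root_result_id
                    and reparent_root_to is not None
                ):
                    # parent values donated by the destination anchor
                    labels[(member.id, f)] = dest_label
    provenance = ProvenanceTable(labels, dest_label)

    # contradictory plans (e.g. replacing a branch with one of its own
    # ancestors) would yield an ancestor cycle; reject rather than emit
    errors = error_findings(validate(result))
    if errors:
        raise MergeError(
            "merge produced an invalid pedigree: "
            + "; ".join(f.message for f in errors)
        )
    return result, provenance, report


def merge_replace(plan: MergePlan) -> tuple[Pedigree, ProvenanceTable, MergeReport]:
    """Replace the destination anchor's branch with the source sublineage.

    The anchor and all of its descendants are removed; their married-in
    partners are removed only if left isolated (no remaining children and
    no parents of their own in the result).  The source root inherits the
    anchor's parent references, occupying the vacated position.
    """
    if plan.mode != "replace":
        raise MergeError(f"plan mode is {plan.mode!r}, expected 'replace'")
    _check_inputs(plan)
    dest = plan.dest
    anchor = dest.get(plan.dest_anchor_id)
    removed_descent = {plan.dest_anchor_id} | set(
        descendants(dest, plan.dest_anchor_id)
    )
    dest_sub = extract_sublineage(dest, plan.dest_anchor_id)
    partners = set(dest_sub.member_ids) - set(dest_sub.descent_ids)

    surviving = {m.id for m in dest.members} - removed_descent
    pruned: set[str] = set()
    for partner_id in partners:
        partner = dest.get(partner_id)
        keeps_children = any(
            c.id in surviving and c.id not in pruned
            for c in dest.children_of(partner_id)
        )
        has_parents = any(
            p != MISSING and p in surviving for p in (partner.father_id, partner.mother_id)
        )
        if not keeps_children and not has_parents:
            pruned.add(partner_id)
    removed = removed_descent | pruned

    survivors = []
    for member in dest.members:
        if member.id in removed:
            continue
        copy = member.copy()
        # surviving members may reference a removed partner as a parent
        if copy.father_id in removed:
            copy.father_id = MISSING
        if copy.mother_id in removed:
            copy.mother_id = MISSING
        survivors.append(copy)

    sub = extract_sublineage(plan.source, plan.source_root_id)
    removed_order = [m.id for m in dest.members if m.id in removed]
    return _assemble(plan, survivors, sub, removed_order, reparent_root_to=anchor)


def merge_combine(plan: MergePlan) -> tuple[Pedigree, ProvenanceTable, MergeReport]:
    """Fold the source sublineage into the destination, deduplicating.

    Individuals present in both pedigrees are represented once, with
    destination precedence on discordant values; everyone else from the
    source sublineage is appended with parent references remapped through
    the duplicate pairing.  The output can serve as the destination of a
    further combine iteration.
    """
    if plan.mode != "combine":
        raise MergeError(f"plan mode is {plan.mode!r}, expected 'combine'")
    _check_inputs(plan)
    sub = extract_sublineage(plan.source, plan.source_root_id)
    survivors = [m.copy() for m in plan.dest.members]
    return _assemble(plan, survivors, sub, removed_ids=[], reparent_root_to=None)


def merge_add(plan: MergePlan) -> tuple[Pedigree, ProvenanceTable, MergeReport]:
    """Append the source sublineage, the root becoming the anchor's sibling.

    The source root's parent references are set to the anchor's, so the
    anchor must not be a founder.  No destination members are removed.
    """
    if plan.mode != "add":
        raise MergeError(f"plan mode is {plan.mode!r}, expected 'add'")
    _check_inputs(plan)
    anchor = plan.dest.get(plan.dest_anchor_id)
    if anchor.father_id == MISSING and anchor.mother_id == MISSING:
        raise MergeError(
            f"cannot attach as sibling of a founder: {plan.dest_anchor_id!r} "
            "has no specified parents"
        )
    sub = extract_sublineage(plan.source, plan.source_root_id)
    survivors = [m.copy() for m in plan.dest.members]
    return _assemble(plan, survivors, sub, removed_ids=[], reparent_root_to=anchor)


def run_merge(plan: MergePlan) -> tuple[Pedigree, ProvenanceTable, MergeReport]:
    """Dispatch on plan.mode."""
    dispatch = {"replace": merge_replace, "combine": merge_combine, "add": merge_add}
    try:
        op = dispatch[plan.mode]
    except KeyError:
        raise MergeError(f"unknown merge mode {plan.mode!r}") from None
    return op(plan)
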