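"""In-memory pedigree representation, traversal, and structural validation.

A :class:`Pedigree` is an ordered collection of :class:`Individual` rows,
one per person, linked by parent references.  The parent relation must be
acyclic, but marriage loops (consanguinity, inbreeding) are legal: a
pedigree may contain multiple descent trees, multiple spouses per person,
and marriages between relatives.

The missing-parent sentinel is the literal ``"0"`` and sex is encoded
``1``/``2``/``0`` on file (male/female/unknown), following the LINKAGE/PED
convention so that exported files interoperate with standard linkage
analysis programs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator

import networkx as nx

from .errors import NoSuchIndividualError

#: Missing-value sentinel used for parent references and attribute values.
MISSING = "0"

#: Canonical names of the four role fields every pedigree carries.
ROLE_FIELDS = ("name", "father", "mother", "sex")


class Sex(Enum):
    """Biological sex with LINKAGE file codes."""

    MALE = "1"
    FEMALE = "2"
    UNKNOWN = "0"

    @classmethod
    def from_code(cls, code: str) -> "Sex":
        code = code.strip()
        for member in cls:
            if member.value == code:
                return member
        return cls.UNKNOWN

    @property
    def code(self) -> str:
        return self.value


@dataclass
class Individual:
    """One pedigree row: identifier, parent references, sex, attributes.

    ``attributes`` is an ordered mapping from attribute column name to a
    text value; it covers affection status, phenotype and genotype columns.
    The missing sentinel ``"0"`` marks an unknown value.
    """

    id: str
    father_id: str = MISSING
    mother_id: str = MISSING
    sex: Sex = Sex.UNKNOWN
    attributes: dict[str, str] = field(default_factory=dict)

    def copy(self) -> "Individual":
        return Individual(
            self.id, self.father_id, self.mother_id, self.sex, dict(self.attributes)
        )

    def field_value(self, name: str) -> str:
        """Value of a role field or attribute, as file text."""
        if name == "name":
            return self.id
        if name == "father":
            return self.father_id
        if name == "mother":
            return self.mother_id
        if name == "sex":
            return self.sex.code
        if name in self.attributes:
            return self.attributes[name]
        raise KeyError(name)

    def with_field(self, name: str, value: str) -> "Individual":
        """Copy with one field replaced (role fields accept file codes)."""
        new = self.copy()
        if name == "name":
            new.id = value
        elif name == "father":
            new.father_id = value
        elif name == "mother":
            new.mother_id = value
        elif name == "sex":
            new.sex = value if isinstance(value, Sex) else Sex.from_code(value)
        else:
            new.attributes[name] = value
        return new


class Pedigree:
    """Ordered collection of individuals with an id index.

    Construction tolerates structurally broken input (duplicate ids,
    dangling parents, cycles); :func:`validate` reports such problems as
    findings so that files can be loaded, inspected and repaired.
    """

    def __init__(self, name: str, columns, members):
        self.name = name
        self.columns: list[str] = list(columns)
        self.members: list[Individual] = list(members)
        self._index: dict[str, int] = {}
        for pos, member in enumerate(self.members):
            self._index.setdefault(member.id, pos)

    # -- basic container protocol ------------------------------------

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self.members)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._index

    def ids(self) -> list[str]:
        return [m.id for m in self.members]

    def fields(self) -> tuple[str, ...]:
        """Role fields followed by attribute columns, in schema order."""
        return ROLE_FIELDS + tuple(self.columns)

    def get(self, individual_id: str) -> Individual:
        try:
            return self.members[self._index[individual_id]]
        except KeyError:
            raise NoSuchIndividualError(individual_id, self.name) from None

    def position(self, individual_id: str) -> int:
        """File-order position of an id (first occurrence)."""
        try:
            return self._index[individual_id]
        except KeyError:
            raise NoSuchIndividualError(individual_id, self.name) from None

    def children_of(self, individual_id: str) -> list[Individual]:
        """Children of an individual, in file order."""
        return [
            m
            for m in self.members
            if m.father_id == individual_id or m.mother_id == individual_id
        ]

    def copy(self) -> "Pedigree":
        return Pedigree(self.name, self.columns, [m.copy() for m in self.members])


@dataclass(frozen=True)
class Sublineage:
    """A root individual, its descendants, and their married-in partners.

    ``descent_ids`` is the root plus everyone reachable via child links;
    ``member_ids`` additionally contains each non-sentinel parent of every
    descent member other than the root itself, so that every parental pair
    inside the sublineage is complete and no copied child dangles.
    ``member_order`` fixes a deterministic traversal order: the descent in
    generation-major order, then married-in partners in source file order.
    """

    root_id: str
    member_ids: frozenset[str]
    descent_ids: frozenset[str]
    member_order: tuple[str, ...]


@dataclass(frozen=True)
class Finding:
    """One structural validation finding."""

    code: str
    level: str  # "error" | "warning"
    ids: tuple[str, ...]
    message: str


def ancestors(ped: Pedigree, individual_id: str) -> set[str]:
    """All ancestors of an individual (excluding itself)."""
    ped.get(individual_id)
    seen: set[str] = set()
    stack = [individual_id]
    while stack:
        current = stack.pop()
        for parent in (ped.get(current).father_id, ped.get(current).mother_id):
            if parent != MISSING and parent in ped and parent not in seen:
                # guard against parent cycles during traversal
                if parent == individual_id:
                    seen.add(parent)
                    continue
                seen.add(parent)
                stack.append(parent)
    return seen


def descendants(ped: Pedigree, individual_id: str) -> list[str]:
    """All descendants of an individual, excluding itself.

    Order is deterministic: breadth-first by generation, ties broken by
    file order within each generation.
    """
    ped.get(individual_id)
    result: list[str] = []
    seen: set[str] = {individual_id}
    frontier = [individual_id]
    while frontier:
        next_level: list[str] = []
        for pid in frontier:
            for child in ped.children_of(pid):
                if child.id not in seen:
                    seen.add(child.id)
                    next_level.append(child.id)
        next_level.sort(key=ped.position)
        result.extend(next_level)
        frontier = next_level
    return result


def extract_sublineage(ped: Pedigree, root_id: str) -> Sublineage:
    """The scope of a merge: the root, its descendants, and the married-in
    partners needed to keep every parental pair inside the set intact.

    The root's own parents are *not* included; there is no limit on the
    number of generations a sublineage can span.
    """
    descent = [root_id] + descendants(ped, root_id)
    descent_set = set(descent)
    partners: list[str] = []
    partner_set: set[str] = set()
    for member_id in descent:
        if member_id == root_id:
            continue
        member = ped.get(member_id)
        for parent in (member.father_id, member.mother_id):
            if (
                parent != MISSING
                and parent in ped
                and parent not in descent_set
                and parent not in partner_set
            ):
                partner_set.add(parent)
                partners.append(parent)
    partners.sort(key=ped.position)
    return Sublineage(
        root_id=root_id,
        member_ids=frozenset(descent_set | partner_set),
        descent_ids=frozenset(descent_set),
        member_order=tuple(descent + partners),
    )


def validate(ped: Pedigree) -> list[Finding]:
    """Structural validation: returns findings, never raises.

    Codes: DUPLICATE_ID, DANGLING_PARENT, PARENT_SEX_CONFLICT,
    ANCESTOR_CYCLE (all error-level) and HALF_SPECIFIED_PARENTS (warning).
    An empty list means every structural invariant holds.  Marriage loops
    between relatives are deliberately not findings.
    """
    findings: list[Finding] = []

    counts = Counter(m.id for m in ped.members)
    for dup_id, n in sorted(counts.items()):
        if n > 1:
            findings.append(
                Finding(
                    "DUPLICATE_ID",
                    "error",
                    (dup_id,),
                    f"id {dup_id!r} appears {n} times",
                )
            )

    fathers: dict[str, str] = {}
    mothers: dict[str, str] = {}
    for member in ped.members:
        for role, parent in (("father", member.father_id), ("mother", member.mother_id)):
            if parent == MISSING:
                continue
            if parent not in ped:
                findings.append(
                    Finding(
                        "DANGLING_PARENT",
                        "error",
                        (member.id, parent),
                        f"{member.id!r} lists {role} {parent!r}, "
                        "absent from the pedigree",
                    )
                )
            elif role == "father":
                fathers.setdefault(parent, member.id)
            else:
                mothers.setdefault(parent, member.id)
        specified = (member.father_id != MISSING) + (member.mother_id != MISSING)
        if specified == 1:
            findings.append(
                Finding(
                    "HALF_SPECIFIED_PARENTS",
                    "warning",
                    (member.id,),
                    f"{member.id!r} has exactly one specified parent",
                )
            )

    for parent, child in sorted(fathers.items()):
        if ped.get(parent).sex is Sex.FEMALE:
            findings.append(
                Finding(
                    "PARENT_SEX_CONFLICT",
                    "error",
                    (parent, child),
                    f"{parent!r} is referenced as father of {child!r} "
                    "but has female sex",
                )
            )
    for parent, child in sorted(mothers.items()):
        if ped.get(parent).sex is Sex.MALE:
            findings.append(
                Finding(
                    "PARENT_SEX_CONFLICT",
                    "error",
                    (parent, child),
                    f"{parent!r} is referenced as mother of {child!r} "
                    "but has male sex",
                )
            )

    graph = nx.DiGraph()
    graph.add_nodes_from(ped.ids())
    for member in ped.members:
        for parent in (member.father_id, member.mother_id):
            if parent != MISSING and parent in ped:
                graph.add_edge(parent, member.id)
    for component in nx.strongly_connected_components(graph):
        in_cycle = len(component) > 1 or any(
            graph.has_edge(node, node) for node in component
        )
        if in_cycle:
            cycle_ids = tuple(sorted(component))
            findings.append(
                Finding(
                    "ANCESTOR_CYCLE",
                    "error",
                    cycle_ids,
                    "ancestor cycle among: " + ", ".join(cycle_ids),
                )
            )

    return findings


def error_findings(findings: list[Finding]) -> list[Finding]:
    return [f for f in findings if f.level == "error"]


def isomorphic(a: Pedigree, b: Pedigree) -> tuple[bool, str | None]:
    """Id-anchored structural equality, with a witness on mismatch.

    True iff both pedigrees have the same id set and, per id, the same
    parent references, sex, and attribute values.  Member order and column
    order are not compared.  This is deliberately id-preserving matching,
    not general graph isomorphism.
    """
    ids_a, ids_b = set(a.ids()), set(b.ids())
    if ids_a != ids_b:
        only_a = sorted(ids_a - ids_b)
        only_b = sorted(ids_b - ids_a)
        return False, f"id sets differ (only in A: {only_a}, only in B: {only_b})"
    for member_id in sorted(ids_a):
        ma, mb = a.get(member_id), b.get(member_id)
        if ma.father_id != mb.father_id:
            return False, f"{member_id}: father {ma.father_id!r} != {mb.father_id!r}"
        if ma.mother_id != mb.mother_id:
            return False, f"{member_id}: mother {ma.mother_id!r} != {mb.mother_id!r}"
        if ma.sex is not mb.sex:
            return False, f"{member_id}: sex {ma.sex.code} != {mb.sex.code}"
        if ma.attributes != mb.attributes:
            diff = sorted(
                k
                for k in set(ma.attributes) | set(mb.attributes)
                if ma.attributes.get(k) != mb.attributes.get(k)
            )
            return False, f"{member_id}: attributes differ in {diff}"
    return True, None
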