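"""Shared fixtures: two-informant example families and brute-force oracles.

The example families mirror the canonical three merge scenarios: replacing
branch B.5 with branch A.4, combining the two reports of AB.2's
descendants, and appending A.2 as a new sibling of B.3.  The oracles are
deliberately naive (exhaustive path enumeration, set algebra) and
independent of the library's traversal code.
"""

import pytest

from pedstitch import Individual, Pedigree, Sex
from pedstitch.model import MISSING

COLUMNS = ["AFF", "BY"]


def _ind(pid, father, mother, sex, aff=MISSING, by=MISSING):
    return Individual(
        id=pid,
        father_id=father,
        mother_id=mother,
        sex=sex,
        attributes={"AFF": aff, "BY": by},
    )


def build_ped_b():
    """Destination family B: founder couple, two children, one grandchild."""
    return Pedigree(
        "B",
        COLUMNS,
        [
            _ind("B.1", "0", "0", Sex.MALE, "1", "1930"),
            _ind("B.2", "0", "0", Sex.FEMALE, "1", "1932"),
            _ind("B.3", "B.1", "B.2", Sex.FEMALE, "2", "1955"),
            _ind("B.5", "B.1", "B.2", Sex.MALE, "1", "1957"),
            _ind("B.4", "0", "0", Sex.FEMALE, "1", "1958"),
            _ind("B.6", "B.5", "B.4", Sex.MALE, "2", "1980"),
        ],
    )


def build_ped_a():
    """Source family A: two branches under a founder couple."""
    return Pedigree(
        "A",
        COLUMNS,
        [
            _ind("A.1", "0", "0", Sex.MALE, "1", "1928"),
            _ind("A.3", "0", "0", Sex.FEMALE, "2", "1931"),
            _ind("A.2", "A.1", "A.3", Sex.FEMALE, "2", "1954"),
            _ind("A.4", "A.1", "A.3", Sex.MALE, "1", "1956"),
            _ind("A.5", "0", "0", Sex.FEMALE, "1", "1959"),
            _ind("A.6", "A.4", "A.5", Sex.FEMALE, "2", "1983"),
            _ind("A.7", "0", "0", Sex.MALE, "1", "1952"),
            _ind("A.8", "A.7", "A.2", Sex.MALE, "1", "1979"),
        ],
    )


def build_combo_source():
    """Informant A's report of AB.2's family (source of the combine)."""
    return Pedigree(
        "CA",
        COLUMNS,
        [
            _ind("AB.1", "0", "0", Sex.MALE, "1", "1929"),
            _ind("AB.2", "0", "0", Sex.FEMALE, "2", "1931"),
            _ind("AB.3", "AB.1", "AB.2", Sex.FEMALE, "1", "1956"),
            _ind("AB.4", "AB.1", "AB.2", Sex.MALE, "2", "1958"),
            _ind("A.9", "0", "0", Sex.FEMALE, "1", "1960"),
            _ind("A.10", "AB.4", "A.9", Sex.MALE, "1", "1985"),
        ],
    )


def build_combo_dest():
    """Informant B's report of the same family (destination of the combine).

    Discordances with the source: AB.3's affection (2 here, 1 there) and
    AB.2's birth year missing here but reported there (a gap to fill).
    """
    return Pedigree(
        "CB",
        COLUMNS,
        [
            _ind("AB.1", "0", "0", Sex.MALE, "1", "1929"),
            _ind("AB.2", "0", "0", Sex.FEMALE, "2", MISSING),
            _ind("AB.3", "AB.1", "AB.2", Sex.FEMALE, "2", "1956"),
            _ind("AB.5", "AB.1", "AB.2", Sex.MALE, "1", "1961"),
            _ind("B.9", "0", "0", Sex.FEMALE, "2", "1963"),
            _ind("B.10", "AB.5", "B.9", Sex.FEMALE, "1", "1988"),
        ],
    )


@pytest.fixture
def ped_b():
    return build_ped_b()


@pytest.fixture
def ped_a():
    return build_ped_a()


@pytest.fixture
def combo_source():
    return build_combo_source()


@pytest.fixture
def combo_dest():
    return build_combo_dest()


# ---------------------------------------------------------------- oracles


def oracle_is_ancestor(ped, candidate, individual, _seen=None):
    """Exhaustive path enumeration up the parent links."""
    if _seen is None:
        _seen = set()
    if individual in _seen:
        return False
    _seen.add(individual)
    member = ped.get(individual)
    for parent in (member.father_id, member.mother_id):
        if parent == MISSING or parent not in ped:
            continue
        if parent == candidate or oracle_is_ancestor(ped, candidate, parent, _seen):
            return True
    return False


def oracle_descendants(ped, individual_id):
    """Every member of which ``individual_id`` is an ancestor."""
    return {
        m.id
        for m in ped.members
        if m.id != individual_id and oracle_is_ancestor(ped, individual_id, m.id)
    }


def oracle_sublineage_members(ped, root_id):
    """Root, descendants, and parents of descendants other than the root."""
    descent = {root_id} | oracle_descendants(ped, root_id)
    partners = set()
    for member_id in descent - {root_id}:
        member = ped.get(member_id)
        for parent in (member.father_id, member.mother_id):
            if parent != MISSING and parent in ped:
                partners.add(parent)
    return descent | partners


def oracle_has_cycle(ped):
    """Reflexive pair in the transitive closure of the parent relation."""
    edges = set()
    for member in ped.members:
        for parent in (member.father_id, member.mother_id):
            if parent != MISSING and parent in ped:
                edges.add((parent, member.id))
    closure = set(edges)
    changed = True
    while changed:
        changed = False
        for (a, b) in list(closure):
            for (c, d) in list(closure):
                if b == c and (a, d) not in closure:
                    closure.add((a, d))
                    changed = True
    return any(a == b for a, b in closure)
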