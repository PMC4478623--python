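"""Synthetic pedigrees and multi-informant views with controlled discordance.

The generator emulates the data-collection setting this package targets: a
single large family whose structure is reported piecewise by several
informants.  :func:`generate_pedigree` grows a multi-generation ground
truth from a founder couple; :func:`make_informant_views` splits it into
overlapping sub-pedigrees with controlled omissions (peripheral relatives
the informant does not know) and attribute discordances (values the
informant mis-reports).  Every view ships with a manifest listing each
deviation from the truth, so tests can predict comparison and merge
outcomes exactly.

Everything is reproducible from the seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field as dc_field
from pathlib import Path

from .errors import PedstitchError
from .model import (
    MISSING,
    Individual,
    Pedigree,
    Sex,
    ancestors,
    extract_sublineage,
)
from . import io as pedio
from .tracking import default_provenance, write_metadata

#: Default attribute schema: an affection status (1 unaffected / 2 affected)
#: and a coarse measured phenotype, each with a realistic missing rate.
DEFAULT_SCHEMA = (
    ("AFF", ("1", "2"), 0.05),
    ("HT", tuple(str(h) for h in range(150, 200, 5)), 0.15),
)


@dataclass
class SimSpec:
    """Ground-truth pedigree shape.

    ``generations`` counts child generations below the founder couple;
    ``mean_children`` is the Poisson mean family size; ``partner_prob`` is
    the probability a reproducing member's co-parent is drawn from inside
    the pedigree (creating a consanguinity loop) rather than married in.
    """

    generations: int = 3
    mean_children: float = 2.2
    partner_prob: float = 0.1
    attribute_schema: tuple = DEFAULT_SCHEMA
    family_name: str = "FAM"
    seed: int = 0

    def __post_init__(self):
        if self.generations < 1:
            raise PedstitchError("generations must be >= 1")
        if not 0.0 <= self.partner_prob <= 1.0:
            raise PedstitchError("partner_prob must be in [0, 1]")
        if self.mean_children <= 0:
            raise PedstitchError("mean_children must be positive")


@dataclass
class ViewSpec:
    """How informant views are carved out of the truth."""

    n_views: int = 2
    anchor_policy: str = "top-siblings"  # or "random"
    omission_rate: float = 0.1
    discordance_rate: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_views < 2:
            raise PedstitchError("n_views must be >= 2")
        for rate in (self.omission_rate, self.discordance_rate):
            if not 0.0 <= rate <= 1.0:
                raise PedstitchError("rates must be in [0, 1]")


@dataclass
class Perturbation:
    id: str
    field: str
    true_value: str
    view_value: str


@dataclass
class Detachment:
    """A parent reference blanked because the parent is absent from the view."""

    id: str
    role: str  # "father" | "mother"
    true_parent: str


@dataclass
class ViewManifest:
    """Exact record of how one informant view deviates from the truth."""

    view_name: str
    anchor_id: str
    member_ids: set[str] = dc_field(default_factory=set)
    omitted_ids: set[str] = dc_field(default_factory=set)
    perturbations: list[Perturbation] = dc_field(default_factory=list)
    detachments: list[Detachment] = dc_field(default_factory=list)


def _poisson(rng: random.Random, mean: float) -> int:
    # Knuth's method; means here are tiny
    limit = pow(2.718281828459045, -mean)
    k, product = 0, rng.random()
    while product > limit:
        k += 1
        product *= rng.random()
    return k


def generate_pedigree(spec: SimSpec) -> Pedigree:
    """Grow a ground-truth pedigree from a founder couple.

    Every child has two parents: co-parents are either synthesized
    married-in founders or, with ``partner_prob``, existing same-generation
    members (never an ancestor or descendant, so the parent relation stays
    acyclic).  Ids are ``<family>.<n>`` in creation order; attributes are
    sampled independently from the schema's value domains.
    """
    rng = random.Random(spec.seed)
    columns = [name for name, _, _ in spec.attribute_schema]
    members: list[Individual] = []
    generation_of: dict[str, int] = {}

    def sample_attrs() -> dict[str, str]:
        out = {}
        for name, domain, missing_rate in spec.attribute_schema:
            out[name] = (
                MISSING if rng.random() < missing_rate else rng.choice(domain)
            )
        return out

    counter = [0]

    def new_member(father: str, mother: str, sex: Sex, generation: int) -> Individual:
        counter[0] += 1
        ind = Individual(
            id=f"{spec.family_name}.{counter[0]}",
            father_id=father,
            mother_id=mother,
            sex=sex,
            attributes=sample_attrs(),
        )
        members.append(ind)
        generation_of[ind.id] = generation
        return ind

    father0 = new_member(MISSING, MISSING, Sex.MALE, 0)
    mother0 = new_member(MISSING, MISSING, Sex.FEMALE, 0)
    couples = [(father0.id, mother0.id)]

    ped_so_far = lambda: Pedigree(spec.family_name, columns, members)

    for generation in range(1, spec.generations + 1):
        next_couples: list[tuple[str, str]] = []
        children_this_gen: list[Individual] = []
        for father, mother in couples:
            n_children = _poisson(rng, spec.mean_children)
            if generation == 1 and (father, mother) == couples[0]:
                n_children = max(2, n_children)  # truth is a non-trivial family
            for _ in range(n_children):
                sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
                children_this_gen.append(new_member(father, mother, sex, generation))
        if generation == spec.generations:
            break
        for child in children_this_gen:
            if rng.random() < 0.25:  # some lineage members stay childless
                continue
            partner_id = None
            if rng.random() < spec.partner_prob:
                ped = ped_so_far()
                siblings = {
                    m.id
                    for m in members
                    if (m.father_id, m.mother_id) == (child.father_id, child.mother_id)
                }
                forbidden = (
                    {child.id}
                    | siblings
                    | ancestors(ped, child.id)
                    | {d for d in ped.ids() if child.id in ancestors(ped, d)}
                )
                # cousin marriages model consanguinity; full siblings never pair
                candidates = [
                    m.id
                    for m in members
                    if generation_of[m.id] == generation_of[child.id]
                    and m.id not in forbidden
                    and m.sex is not child.sex
                ]
                if candidates:
                    partner_id = rng.choice(candidates)
            if partner_id is None:
                partner_sex = Sex.FEMALE if child.sex is Sex.MALE else Sex.MALE
                partner_id = new_member(
                    MISSING, MISSING, partner_sex, generation_of[child.id]
                ).id
            partner_sex = next(m.sex for m in members if m.id == partner_id)
            if child.sex is Sex.MALE or partner_sex is Sex.FEMALE:
                next_couples.append((child.id, partner_id))
            else:
                next_couples.append((partner_id, child.id))
        couples = next_couples
        if not couples:
            break
    return ped_so_far()


def _view_base(ped: Pedigree, anchor_id: str) -> set[str]:
    """What an informant anchored at ``anchor_id`` knows before omissions:
    their own sublineage plus their ancestor chain (closed upward)."""
    sub = extract_sublineage(ped, anchor_id)
    return set(sub.member_ids) | ancestors(ped, anchor_id)


def make_informant_views(
    ped: Pedigree, spec: ViewSpec
) -> list[tuple[Pedigree, ViewManifest]]:
    """Split a ground-truth pedigree into overlapping informant views.

    Anchors are, by default, the children of the founder couple assigned
    round-robin to views ("top-siblings": each informant knows one major
    branch plus the shared ancestors, so views overlap at the top).
    Omission drops peripheral members — only ever members with no retained
    children, so every view stays a valid pedigree without detaching
    anyone.  Discordance perturbs non-role attribute values.  Both are
    recorded exhaustively in the manifest.
    """
    rng = random.Random(spec.seed)
    founders_children = [
        m.id for m in ped.members if m.father_id != MISSING or m.mother_id != MISSING
    ]
    top_children = [
        m.id
        for m in ped.members
        if (m.father_id, m.mother_id) == (ped.members[0].id, ped.members[1].id)
    ] if len(ped.members) >= 2 else []
    if spec.anchor_policy == "top-siblings" and top_children:
        anchors = [
            top_children[i % len(top_children)] for i in range(spec.n_views)
        ]
    elif spec.anchor_policy == "random" and founders_children:
        anchors = [rng.choice(founders_children) for _ in range(spec.n_views)]
    else:
        raise PedstitchError(
            f"cannot choose anchors (policy {spec.anchor_policy!r}, "
            f"{len(ped.members)} members)"
        )

    domains: dict[str, list[str]] = {}
    for column in ped.columns:
        values = sorted({m.attributes.get(column, MISSING) for m in ped.members})
        domains[column] = [v for v in values if v != MISSING]

    views: list[tuple[Pedigree, ViewManifest]] = []
    for view_index, anchor_id in enumerate(anchors, start=1):
        view_name = f"{ped.name}.view{view_index}"
        manifest = ViewManifest(view_name=view_name, anchor_id=anchor_id)
        base = _view_base(ped, anchor_id)
        protected = {anchor_id} | ancestors(ped, anchor_id)
        retained = set(base)
        # peripheral decay: one omission coin per member, children considered
        # before parents so a dropped branch can cascade upward one step
        for member_id in sorted(
            retained - protected, key=ped.position, reverse=True
        ):
            has_retained_child = any(
                c.id in retained for c in ped.children_of(member_id)
            )
            if not has_retained_child and rng.random() < spec.omission_rate:
                retained.discard(member_id)
        # a spouse whose children were all omitted is disconnected from the
        # anchor's tree: informants mention spouses only along a family line
        for member_id in sorted(retained - protected, key=ped.position):
            member = ped.get(member_id)
            has_child = any(c.id in retained for c in ped.children_of(member_id))
            has_parent = any(
                p != MISSING and p in retained
                for p in (member.father_id, member.mother_id)
            )
            if not has_child and not has_parent:
                retained.discard(member_id)
        if not retained:
            raise PedstitchError(f"view {view_name} would be empty")
        manifest.member_ids = set(retained)
        manifest.omitted_ids = base - retained

        members = []
        for member in ped.members:
            if member.id not in retained:
                continue
            copy = member.copy()
            # a parent outside the view (e.g. a cousin-spouse's parents when
            # the informant does not know that side) must not dangle
            for role in ("father", "mother"):
                parent = copy.field_value(role)
                if parent != MISSING and parent not in retained:
                    manifest.detachments.append(Detachment(copy.id, role, parent))
                    copy = copy.with_field(role, MISSING)
            for column in ped.columns:
                true_value = copy.attributes.get(column, MISSING)
                if rng.random() < spec.discordance_rate:
                    alternatives = [v for v in domains[column] if v != true_value]
                    if not alternatives:
                        continue
                    new_value = rng.choice(alternatives)
                    copy.attributes[column] = new_value
                    manifest.perturbations.append(
                        Perturbation(copy.id, column, true_value, new_value)
                    )
            members.append(copy)
        views.append((Pedigree(view_name, ped.columns, members), manifest))
    return views


def write_fixture_trio(
    ped: Pedigree, directory, config: pedio.PedConfig | None = None
) -> pedio.PedConfig:
    """Write a config/pedigree/metadata trio for a pedigree into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ped_file = directory / f"{ped.name}.ped"
    meta_file = directory / f"{ped.name}.meta"
    conf_file = directory / f"{ped.name}.conf"
    if config is None:
        config = pedio.PedConfig(
            pedigree_path=ped_file,
            pedigree_name=ped.name,
            column_roles={
                "name": "NAME",
                "father": "FATHER",
                "mother": "MOTHER",
                "sex": "SEX",
            },
            attribute_columns=list(ped.columns),
            metadata_path=meta_file,
        )
    pedio.write_pedigree(ped, config, ped_file)
    write_metadata(default_provenance(ped, ped_file.name), ped, meta_file)
    pedio.write_config(config, conf_file)
    return config
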