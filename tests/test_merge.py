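"""The three merge algorithms: scenario fixtures, count identities, precedence."""

import random

import pytest

from pedstitch import (
    MergePlan,
    descendants,
    extract_sublineage,
    find_duplicates,
    isomorphic,
    merge_add,
    merge_combine,
    merge_replace,
    resolve_duplicate,
    run_merge,
    trace,
    validate,
)
from pedstitch.errors import AmbiguousMatchError, MergeError
from pedstitch.model import MISSING, error_findings
from pedstitch.synthetic import SimSpec, ViewSpec, generate_pedigree, make_informant_views
from pedstitch.tracking import is_total

from conftest import build_combo_dest, build_combo_source, build_ped_a, build_ped_b


class TestReplaceScenario:
    """Replace B.5 and B.5's descendants with A.4 and A.4's descendants."""

    def plan(self, ped_a, ped_b):
        return MergePlan(
            mode="replace",
            source=ped_a,
            dest=ped_b,
            source_root_id="A.4",
            dest_anchor_id="B.5",
        )

    def test_branch_substituted(self, ped_a, ped_b):
        result, table, report = merge_replace(self.plan(ped_a, ped_b))
        # B.5's branch (B.5, B.6) and the isolated spouse B.4 are gone
        assert set(report.removed_ids) == {"B.5", "B.6", "B.4"}
        assert set(report.added_ids) == {"A.4", "A.6", "A.5"}
        assert set(result.ids()) == {"B.1", "B.2", "B.3", "A.4", "A.5", "A.6"}
        # the replacement root occupies the vacated position in the family
        a4 = result.get("A.4")
        assert (a4.father_id, a4.mother_id) == ("B.1", "B.2")
        assert report.duplicate_pairs == []
        assert error_findings(validate(result)) == []

    def test_count_identity(self, ped_a, ped_b):
        result, _, report = merge_replace(self.plan(ped_a, ped_b))
        sub = extract_sublineage(ped_a, "A.4")
        assert len(result) == len(ped_b) - len(report.removed_ids) + len(
            sub.member_ids
        )

    def test_imported_fields_carry_source_label(self, ped_a, ped_b):
        _, table, _ = merge_replace(self.plan(ped_a, ped_b))
        assert trace(table, "A.6", "AFF") == "A"
        assert trace(table, "B.3", "AFF") == "B"
        # the re-parented root's parent references came from the destination
        assert trace(table, "A.4", "father") == "B"

    def test_replace_leaf_with_childless_individual(self, ped_a, ped_b):
        plan = MergePlan(
            mode="replace",
            source=ped_a,
            dest=ped_b,
            source_root_id="A.8",
            dest_anchor_id="B.6",
        )
        result, _, report = merge_replace(plan)
        assert set(result.ids()) == (set(ped_b.ids()) - {"B.6"}) | {"A.8"}
        assert result.get("A.8").father_id == "B.5"
        assert result.get("A.8").mother_id == "B.4"


class TestCombineScenario:
    """Combine the two informants' reports of AB.2's descendants."""

    def plan(self, source, dest):
        return MergePlan(
            mode="combine",
            source=source,
            dest=dest,
            source_root_id="AB.2",
            dest_anchor_id="AB.2",
        )

    def test_duplicates_once_and_destination_attributes_retained(
        self, combo_source, combo_dest
    ):
        result, table, report = merge_combine(self.plan(combo_source, combo_dest))
        assert set(p[0] for p in report.duplicate_pairs) == {"AB.1", "AB.2", "AB.3"}
        assert len(result) == len(combo_dest) + 3  # AB.4, A.9, A.10 appended
        assert result.ids().count("AB.2") == 1
        # discordant affection of AB.3: destination value 2 kept
        conflict = next(c for c in report.conflicts if c.id == "AB.3")
        assert (conflict.source_value, conflict.dest_value) == ("1", "2")
        assert conflict.kept_value == "2"
        assert result.get("AB.3").attributes["AFF"] == "2"

    def test_count_identity(self, combo_source, combo_dest):
        result, _, report = merge_combine(self.plan(combo_source, combo_dest))
        sub = extract_sublineage(combo_source, "AB.2")
        dup = len(set(sub.member_ids) & set(combo_dest.ids()))
        assert len(result) == len(combo_dest) + len(sub.member_ids) - dup

    def test_gap_fill_from_source_with_source_provenance(
        self, combo_source, combo_dest
    ):
        result, table, report = merge_combine(self.plan(combo_source, combo_dest))
        fills = {(g.id, g.field): g.value for g in report.gap_fills}
        assert fills[("AB.2", "BY")] == "1931"
        assert result.get("AB.2").attributes["BY"] == "1931"
        assert trace(table, "AB.2", "BY") == "CA"
        assert trace(table, "AB.2", "AFF") == "CB"

    def test_self_merge_is_identity_up_to_isomorphism(self, combo_dest):
        twin = combo_dest.copy()
        twin.name = "CB2"
        plan = MergePlan(
            mode="combine",
            source=twin,
            dest=combo_dest,
            source_root_id="AB.2",
            dest_anchor_id="AB.2",
        )
        result, _, report = merge_combine(plan)
        assert report.added_ids == []
        assert isomorphic(result, combo_dest)[0]

    def test_iterated_combine_reaches_full_composite(self, combo_source, combo_dest):
        once, _, _ = merge_combine(self.plan(combo_source, combo_dest))
        plan2 = MergePlan(
            mode="combine",
            source=combo_source,
            dest=once,
            source_root_id="AB.2",
            dest_anchor_id="AB.2",
        )
        twice, _, report2 = merge_combine(plan2)
        assert report2.added_ids == []
        assert isomorphic(once, twice)[0]


class TestAddScenario:
    """Append A.2 and A.2's descendants with A.2 as a sibling of B.3."""

    def plan(self, ped_a, ped_b):
        return MergePlan(
            mode="add",
            source=ped_a,
            dest=ped_b,
            source_root_id="A.2",
            dest_anchor_id="B.3",
        )

    def test_appended_root_shares_anchor_parents(self, ped_a, ped_b):
        result, _, report = merge_add(self.plan(ped_a, ped_b))
        assert set(result.ids()) == set(ped_b.ids()) | {"A.2", "A.8", "A.7"}
        a2 = result.get("A.2")
        b3 = ped_b.get("B.3")
        assert (a2.father_id, a2.mother_id) == (b3.father_id, b3.mother_id)
        assert report.removed_ids == []
        assert error_findings(validate(result)) == []

    def test_single_childless_sibling(self, ped_a, ped_b):
        plan = MergePlan(
            mode="add",
            source=ped_a,
            dest=ped_b,
            source_root_id="A.6",
            dest_anchor_id="B.6",
        )
        result, _, _ = merge_add(plan)
        assert len(result) == len(ped_b) + 1
        a6 = result.get("A.6")
        assert (a6.father_id, a6.mother_id) == ("B.5", "B.4")

    def test_anchor_must_not_be_a_founder(self, ped_a, ped_b):
        plan = MergePlan(
            mode="add",
            source=ped_a,
            dest=ped_b,
            source_root_id="A.2",
            dest_anchor_id="B.1",
        )
        with pytest.raises(MergeError, match="founder"):
            merge_add(plan)

    def test_edges_unchanged_except_new_sibling(self, ped_a, ped_b):
        before = {
            (m.id, m.father_id, m.mother_id) for m in ped_b.members
        }
        result, _, _ = merge_add(self.plan(ped_a, ped_b))
        after = {(m.id, m.father_id, m.mother_id) for m in result.members}
        assert before <= after
        new = after - before
        assert {t[0] for t in new} == {"A.2", "A.8", "A.7"}


class TestFindDuplicates:
    def test_disjoint_id_sets_give_no_pairs(self, ped_a, ped_b):
        sub = extract_sublineage(ped_a, "A.2")
        assert find_duplicates(sub, ped_a, ped_b) == []

    def test_pairs_equal_id_intersection(self, combo_source, combo_dest):
        sub = extract_sublineage(combo_source, "AB.2")
        pairs = find_duplicates(sub, combo_source, combo_dest)
        assert set(pairs) == {
            (x, x) for x in set(sub.member_ids) & set(combo_dest.ids())
        }

    def test_composite_key_ambiguity_is_an_error(self, combo_source, combo_dest):
        sub = extract_sublineage(combo_source, "AB.2")
        # birth year 1956 appears once in source, but sex=2 appears thrice
        with pytest.raises(AmbiguousMatchError):
            find_duplicates(sub, combo_source, combo_dest, match_key="sex")


class TestResolveDuplicate:
    def test_destination_precedence(self, combo_source, combo_dest):
        merged, conflicts, fills = resolve_duplicate(
            combo_source.get("AB.3"), combo_dest.get("AB.3")
        )
        assert merged.attributes["AFF"] == "2"
        assert [c.field for c in conflicts] == ["AFF"]
        assert all(c.kept_value == c.dest_value for c in conflicts)

    def test_identical_pair_yields_no_conflicts(self, combo_source):
        ind = combo_source.get("AB.1")
        merged, conflicts, fills = resolve_duplicate(ind, ind.copy())
        assert conflicts == [] and fills == []

    def test_gap_fill_is_direction_independent(self, combo_source, combo_dest):
        source_ind = combo_source.get("AB.2")  # BY = 1931
        dest_ind = combo_dest.get("AB.2")  # BY missing
        kept_one, _, fills_one = resolve_duplicate(source_ind, dest_ind)
        kept_two, _, fills_two = resolve_duplicate(dest_ind, source_ind)
        assert kept_one.attributes["BY"] == kept_two.attributes["BY"] == "1931"
        assert [f.field for f in fills_one] == ["BY"]
        assert fills_two == []  # with roles swapped the value is already there


def truth_ancestors(truth, individual_id):
    from pedstitch import ancestors

    return ancestors(truth, individual_id) if individual_id in truth else set()


def random_plans(n_cases, seed):
    """Randomized merge plans over pairs of informant views of one truth."""
    rng = random.Random(seed)
    produced = 0
    attempt = 0
    while produced < n_cases:
        attempt += 1
        truth = generate_pedigree(
            SimSpec(
                generations=2 + attempt % 2,
                mean_children=2.0,
                seed=seed * 100003 + attempt,
            )
        )
        views = make_informant_views(
            truth,
            ViewSpec(
                n_views=2,
                omission_rate=0.2,
                discordance_rate=0.2,
                seed=attempt,
            ),
        )
        (view_a, _), (view_b, _) = views
        for mode in ("replace", "combine", "add"):
            source_root = rng.choice(view_a.ids())
            if mode == "add":
                candidates = [
                    m.id for m in view_b.members if m.father_id != MISSING
                ]
                if not candidates:
                    continue
                anchor = rng.choice(candidates)
            else:
                anchor = rng.choice(view_b.ids())
            if mode in ("replace", "add") and source_root in truth_ancestors(
                truth, anchor
            ):
                # re-parenting one's own ancestor to the anchor's parents is
                # contradictory input; the engine rejects it
                continue
            yield MergePlan(
                mode=mode,
                source=view_a,
                dest=view_b,
                source_root_id=source_root,
                dest_anchor_id=anchor,
            )
            produced += 1
            if produced >= n_cases:
                return


def oracle_result_ids(plan):
    """Set-algebra prediction of the merged id set, computed independently."""
    source, dest = plan.source, plan.dest
    sub_ids = set(extract_sublineage(source, plan.source_root_id).member_ids)
    dest_ids = set(dest.ids())
    if plan.mode == "replace":
        removed = {plan.dest_anchor_id} | set(
            descendants(dest, plan.dest_anchor_id)
        )
        partners = set()
        for member in dest.members:
            # the anchor's own parents are not married-in partners of the
            # removed branch (and keep the replacement root as a child)
            if member.id in removed and member.id != plan.dest_anchor_id:
                for parent in (member.father_id, member.mother_id):
                    if parent != MISSING and parent not in removed and parent in dest:
                        partners.add(parent)
        surviving = dest_ids - removed
        for partner in sorted(partners):
            member = dest.get(partner)
            has_child = any(
                c.id in surviving for c in dest.children_of(partner)
            )
            has_parent = any(
                p != MISSING and p in surviving
                for p in (member.father_id, member.mother_id)
            )
            if not has_child and not has_parent:
                surviving.discard(partner)
        return surviving | sub_ids
    return dest_ids | sub_ids


class TestRandomizedProperties:
    N_PLANS = 520

    def test_count_identities_match_set_algebra_oracle(self):
        checked = 0
        for plan in random_plans(self.N_PLANS, seed=2026):
            expected = oracle_result_ids(plan)
            result, table, report = run_merge(plan)
            assert set(result.ids()) == expected, plan.mode
            # mode-specific count identity
            sub = extract_sublineage(plan.source, plan.source_root_id)
            dup = len(report.duplicate_pairs)
            if plan.mode == "replace":
                assert len(result) == len(plan.dest) - len(
                    report.removed_ids
                ) + len(sub.member_ids) - dup
            else:
                assert len(result) == len(plan.dest) + len(sub.member_ids) - dup
            checked += 1
        assert checked >= 500

    def test_non_destructiveness_and_validity_and_provenance_totality(self):
        for plan in random_plans(150, seed=7):
            source_before = plan.source.copy()
            dest_before = plan.dest.copy()
            result, table, report = run_merge(plan)
            assert isomorphic(plan.source, source_before)[0]
            assert isomorphic(plan.dest, dest_before)[0]
            assert error_findings(validate(result)) == []
            assert is_total(table, result)

    def test_destination_precedence_in_every_conflict(self):
        conflicts_seen = 0
        for plan in random_plans(150, seed=99):
            result, _, report = run_merge(plan)
            for conflict in report.conflicts:
                assert conflict.kept_value == conflict.dest_value
                assert (
                    result.get(conflict.id).field_value(conflict.field)
                    == conflict.dest_value
                )
                conflicts_seen += 1
        assert conflicts_seen > 0

    def test_inputs_failing_validation_are_rejected(self, ped_b):
        broken = build_ped_a()
        broken.members[5].father_id = "A.99"
        plan = MergePlan(
            mode="add",
            source=broken,
            dest=ped_b,
            source_root_id="A.2",
            dest_anchor_id="B.3",
        )
        with pytest.raises(MergeError, match="validation"):
            merge_add(plan)
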