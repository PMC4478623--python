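# pedstitch

Compare, edit, and merge pedigrees collected from multiple informants into
one unified pedigree, with field-level provenance tracking.

## The problem

Family-based genetic studies assemble large pedigrees from reports given
independently by several family members.  Each informant knows one part of
the family well and the rest vaguely: the reports overlap, omit people,
and disagree on disease status, phenotypes, or even who someone's parents
are.  Building the best composite pedigree by hand is laborious and
error-prone, and downstream linkage/association software needs a single
consistent file.

`pedstitch` is a scriptable toolkit for this reconciliation step.  It
models a pedigree as an ordered table of individuals (id, father, mother,
sex, plus attribute columns; `0` is the missing sentinel, sex is coded
`1`/`2`/`0` per the LINKAGE convention) and provides:

- **Sublineage extraction** — the scope of every merge is a chosen root
  individual *r*, its full descendant closure
  D(r) = {r} ∪ {x : r is an ancestor of x}, and the married-in partners
  needed so no copied child has a dangling parent reference.
- **Three merge algorithms** over a source pedigree S and destination D:
  - *replace*: D ∖ branch(anchor) ∪ sublineage(S, root), the root taking
    the anchor's parents;
  - *combine*: D ∪ sublineage(S, root) with duplicated individuals
    represented once (iterable to a fixpoint);
  - *add*: D ∪ sublineage(S, root), the root appended as a new sibling of
    the anchor.
- **Destination precedence**: for a duplicated individual with discordant
  values, the destination pedigree's value is kept and the conflict is
  reported; a destination-missing/source-present value fills the gap and
  is flagged.
- **Field-level provenance**: every (individual, field) pair carries the
  label of the file or edit that produced its current value, stored in a
  metadata file parallel to the pedigree file.
- **Reconciliation and editing**: per-field cross-pedigree diffs, explicit
  per-field choices, add/remove/edit of single individuals — all
  copy-on-write, never touching input files without `--in-place`.
- **A synthetic multi-informant generator** that produces a ground-truth
  family and per-informant views with controlled omission and discordance,
  plus a manifest of every deviation.
- Export to LINKAGE PED (with optional integer re-coding) and Graphviz DOT.

## Worked example

Two informants describe the same family around person AB.2.  Informant A
reports AB.2's branch through son AB.4; informant B reports the branch
through son AB.5, disagrees about daughter AB.3's affection status, and
does not know AB.2's birth year.

```sh
pedstitch simulate --out demo --seed 21 --views 2   # or bring your own trio
pedstitch diff A/CA.conf B/CB.conf
```

```
AB.2    BY      1931    0       discordant
AB.3    AFF     1       2       discordant
```

Combining A's report into B's (B is the destination, so B's values win):

```sh
pedstitch merge A/CA.conf B/CB.conf --mode combine \
    --source-root AB.2 --dest-anchor AB.2 --out unified --name U
```

```
added 3, removed 0, 3 duplicate pair(s), 1 conflict(s) (destination kept), 1 gap-fill(s), 0 renamed
```

The unified pedigree has 9 members: B's six, plus AB.4, his wife A.9 and
son A.10 from A.  AB.1, AB.2 and AB.3 were present in both reports and
appear once.  AB.3 keeps the destination's affection status `2`; AB.2's
missing birth year is gap-filled with `1931` from A.  Provenance records
exactly that:

```sh
pedstitch trace unified/U.conf --id AB.2
```

```
AB.2    name    CB.ped
AB.2    father  CB.ped
AB.2    mother  CB.ped
AB.2    sex     CB.ped
AB.2    AFF     CB.ped
AB.2    BY      CA.ped
```

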