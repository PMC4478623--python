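# Methods

## Data model

A pedigree is an ordered list of individuals, each a row with a unique
text id, father and mother references, sex, and an ordered set of named
attribute values (affection status, phenotypes, genotypes).  The missing
sentinel is the literal `0` for parents and attribute values, and sex is
coded `1` male / `2` female / `0` unknown — the LINKAGE/PED convention,
chosen so exports interoperate with standard linkage-analysis programs.

The parent relation must be acyclic (no individual is its own ancestor);
everything else the field throws at pedigrees is admitted: multiple
descent trees in one file, multiple spouses per person, and marriage loops
from consanguinity or inbreeding.  `validate` reports structural problems
as findings rather than exceptions — `DANGLING_PARENT`,
`PARENT_SEX_CONFLICT`, `ANCESTOR_CYCLE`, `DUPLICATE_ID` at error level and
`HALF_SPECIFIED_PARENTS` as a warning — so that broken files can be
loaded, inspected, and repaired.  Cycle detection uses strongly connected
components of the parent→child digraph (networkx).

### Sublineage semantics

The scope of every merge is a *sublineage*: a root, its complete
descendant closure (no generation limit), and the married-in partners of
descent members.  Partners are included so that a copied child never has a
dangling parent reference; they are, however, excluded from the *descent*
set, so all count identities are stated over descent plus required
partners.  The root's own parents are never part of its sublineage.
Whether spouses of descendants belong to a sublineage at all was a
genuinely open design point; including them (as members, not descent) is
the only choice that keeps every merge result structurally valid.

Descendant traversal order is generation-major breadth-first with ties
broken by file order, which makes every output deterministic and
diff-friendly.

## Merge algorithms

All three modes are scoped by the source sublineage and share a common
back half: duplicate detection, destination-ordered assembly, provenance
relabeling, and validation of the result.  Inputs are never modified;
results list retained destination members in destination file order,
followed by appended source members in sublineage traversal order.

- **replace** removes the destination anchor and its descendants, then
  appends the source sublineage with the source root taking the anchor's
  parent references (the branch "occupies" the vacated position).
  Married-in partners of removed members are pruned only when left
  isolated — no remaining children and no parents of their own in the
  result; a spouse with other ties survives.
- **combine** appends only the source members not matched as duplicates;
  matched pairs are resolved in place.  The output is a valid destination
  for further combine iterations, and combining a pedigree with a copy of
  itself is the identity up to id-anchored isomorphism.
- **add** appends the whole source sublineage with the root re-parented to
  the anchor's parents (a new sibling).  Attaching as a sibling of a
  founder is rejected, since there are no parents to share.

Duplicate matching defaults to exact equality of the id/name field;
a composite key over other fields is supported, in which case a source id
colliding with an *unmatched* destination id is an error unless renaming
is requested.  Any one-to-many match is an error, never a guess.
Duplicates are eliminated in all three modes, not just combine.

Conflict policy: for every field where a duplicated pair disagrees and
both values are non-missing, the destination value is kept and a conflict
row records both (destination precedence).  When the destination value is
missing and the source value is not, the source value fills the gap; gap
fills are reported in their own section — keeping the invariant that every
*conflict* row's kept value equals the destination value exactly — and
their provenance is the source's label.  Gap-filled parent references are
remapped into the result's id space; a reference that cannot be resolved
becomes the missing sentinel.  If a replace/add plan's source root is
itself matched as a duplicate of a surviving destination member,
destination precedence extends to its parents: the survivor keeps its own
parent references and no re-parenting occurs.

Degenerate plans — e.g. replacing a branch with one of its own ancestors,
which would make someone their own forebear — are detected by validating
the assembled result and rejected with an error rather than emitted.

## Provenance

Provenance is total and field-level: after any public-API operation,
every (individual, field) pair — the four role fields plus each attribute
column — has exactly one source label.  Only the *current* source is
stored, not an event history: the goal is tracing a value to its origin,
and a last-writer-wins table is the minimal faithful model of that.  On
disk the table is a TSV with the same row and column geometry as its
pedigree file plus a leading id column; geometry or id mismatches are
errors.  Default labels are the pedigree file's base name; manual edits
and explicit reconcile choices are labeled `manual`.  In merges, retained
destination values keep their prior labels, imported and gap-filled values
take the source's label, and a re-parented root's parent fields take the
destination's label (the values came from the anchor).

## File formats

The configuration file is line-oriented `KEY value` text with
case-sensitive keys and `#` comments; required keys name the pedigree file
and the four role columns.  Unrecognized keys are treated as appearance
options: preserved verbatim and re-emitted byte-identically, never
interpreted — rendering concerns are out of scope (structure is exported
to Graphviz DOT instead, with one point node per parental pair).  The
pedigree file is tab-delimited with a header row by default (self-
describing files survive column drift; a headerless mode takes column
order from the configuration).  Short rows are padded with the missing
sentinel; long rows are line-numbered parse errors.  Writes are UTF-8
with LF newlines, CRLF accepted on read, and serialization is a byte-level
fixed point (`write ∘ read ∘ write = write`).

Non-destructiveness is enforced at the I/O layer: any path registered as
an input of the current session is refused as an output unless the caller
passes the explicit in-place flag.

## Synthetic data

`generate_pedigree` grows a ground truth from a founder couple: family
sizes are Poisson with mean 2.2 children (a realistic large-family mean
that yields ~15–50 members over the default 3 child generations), roughly
three quarters of lineage members in non-final generations reproduce, and
each co-parent is a new married-in founder except with probability 0.1 a
same-generation non-sibling relative (a cousin marriage, producing the
consanguinity loops real extended pedigrees contain; full-sibling pairings
are never generated).  Attributes default to an affection status
(missing 5%) and a coarse quantitative phenotype (missing 15%).

`make_informant_views` emulates informants: each view is anchored at a
child of the founder couple (round-robin), and the informant knows their
own sublineage plus their ancestor chain — so views overlap at the top of
the family.  Omission then drops peripheral members with one coin flip per
member at the configured rate, children considered before parents so a
dropped branch can cascade; only members without retained children are
ever dropped, so views are always valid pedigrees.  Spouses left without
any retained children or parents are disconnected from the anchor's tree
and are omitted as well.  Attribute discordance perturbs non-role values
within the column's observed domain.  Every omission, perturbation, and
(when a known relative's parent falls outside the view) parent detachment
is recorded in the manifest, so tests can predict diff and merge outcomes
exactly.

What the generator does *not* emulate: Mendelian transmission of
genotypes, realistic demography or generation overlap, misremembered
*structure* (wrong parent assignments), and name variation between
informants (views agree on ids, so duplicate matching by name is exact).
Passing tests therefore demonstrate the algorithms' correctness on
structurally consistent reports, not robustness to record-linkage noise.

## Problem sizes and verification

The test suite and the acceptance script run the canonical three-scenario
fixtures (6–8 members each, constructed to match the textbook replace /
combine / add descriptions), ≥500 randomized merge plans over pairs of
informant views checked against independent set-algebra oracles, ≥1000
traversal cases (pedigrees ≤ 30 members) checked against brute-force path
enumeration, and 3–5 reconstruction scenarios in which 3 discordance-free
views are combined iteratively and compared to the union-covered portion
of the truth.  Reconstruction scenarios use `partner_prob = 0`: without
cross-branch marriage loops each informant's knowledge is exactly
parent-closed, which is the setting in which "overlap-covered ground
truth" is well defined.  All randomized tests are seeded and
deterministic.

## Known limitations

- Duplicate matching has no fuzzy mode; reconciling informants who use
  different names for the same person requires renaming beforehand.
- Provenance stores no history, timestamps, or user identity.
- The LINKAGE export is the pre-makeped dialect only.
- There is no undo; the non-destructive file contract (inputs are never
  overwritten without the in-place flag) is the recovery mechanism.
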