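# Methods

This note records the scientific and numerical choices behind
`chemogenlib`: the model each stage implements, the defaults and why,
what the synthetic generator does and does not emulate, and the known
limitations.

## Activity filtering

A molecule–protein pair is *bioactive* when at least one record passes
all five predicates: measure ∈ {Ki, IC50}, assay type B (binding),
curation confidence 9, species ∈ {human, rat, mouse}, and value
strictly below the potency threshold (default 1000 nM). The inequality
is strict: a record at exactly 1000 nM is excluded. EC50 and other
functional readouts never qualify, however potent, because they are not
comparable to binding affinities across assays. Multiple qualifying
records for a pair collapse to the minimum value — the pair carries one
edge in the network and the most potent evidence is the least likely to
be a false negative.

Species-specific targets are collapsed onto species-agnostic protein
entries (*UI*) before pairing and before any counting (promiscuity,
coverage, enrichment). Orthologs are pharmacologically interchangeable
at this resolution; counting them separately would double-weight
well-studied receptors.

Input tables are flat CSV/TSV with a user *dialect* map from semantic
fields to column names. Values must already be unit-normalised to nM;
rows in other units are rejected, not converted — silent unit
conversion is a classic source of 1000-fold errors.

## Scaffold trees

The framework (level 1) is the Murcko scaffold: ring systems plus
linkers after removing terminal side chains, retaining double bonds
whose attachment atom is in a ring (computed with RDKit).
Stereochemistry is stripped first: scaffold identity here is 2-D
chemotype identity. Ring count is the cyclomatic number (the size of a
smallest set of smallest rings), which stays well-defined on bridged
systems where symmetrised ring perception overcounts.

One ring is pruned per level until a single ring remains. Candidate
rings are those whose exclusive atoms can be deleted leaving one
connected scaffold with exactly one ring fewer; deletion is attempted
with aromatic flags intact first (so pruning one ring of naphthalene
leaves benzene aromatic) and kekulised as a fallback. Among candidates
the cascade deletes, in order of preference: hetero-poor rings before
heteroatom-rich ones, larger rings before smaller, linker-attached
before fused, with the lexicographically smallest resulting canonical
SMILES as the final tie-break. This is a deliberately compact
adaptation of published scaffold-tree pruning priorities: it preserves
their intent (keep the characteristic heteroatom-bearing core) while
being short enough to verify exhaustively, and the terminal tie-break
makes every chain byte-reproducible across platforms. Chains therefore
satisfy: length = framework ring count, ring counts R, R−1, …, 1, and
each level is a substructure of the previous one.

Limitation: in fully fused cage systems (e.g. bicyclo[2.2.2]octane) no
single ring can be deleted and the chain terminates early; such
frameworks are rare in medicinal-chemistry series and absent from the
synthetic generator's templates.

Molecules whose framework has a single ring have no level-2 scaffold;
they are excluded from the scaffold-based selection path but remain
candidates for coverage completion.

## Promiscuity pruning

Scaffolds linked to more than `max_targets_per_scaffold` protein
entries (default 6) are removed. Promiscuity is counted in UI space so
species replicates do not inflate it. The threshold is inclusive:
exactly 6 targets survives.

## Clustering and representatives

The scaffold×protein binary matrix has a row per surviving scaffold and
a 1 where some retained molecule carrying that scaffold hits that
protein. Distances are Jaccard: d = (b+c)/(a+b+c) over the 1-positions,
ignoring shared zeros — shared inactivity carries no information in
sparse bioactivity profiles. Clustering is agglomerative with average
linkage (UPGMA), the conventional choice for binary fingerprint
profiles; complete and Ward linkage are configurable. The dendrogram is
cut to exactly k clusters (when tied merge heights make the standard
cut coarser than k, the last merges are undone explicitly).

One representative per cluster, by cascade: (1) the medoid — minimal
summed Jaccard distance to co-members ("lowest distance" is read as
distance within the cluster, and the medoid is the only reference-free
reading); (2) most protein entries hit; (3) most molecules; (4)
smallest canonical SMILES. Rule 4 makes the pick invariant to member
order where the first three rules tie.

## Pareto selection

Candidate pool: every bioactive molecule whose level-2 scaffold is a
selected representative. Individuals are fixed-size molecule subsets;
three maximisation objectives:

- **O1** — distinct protein entries covered. Coverage, not per-molecule
  target sums: a library that hits 100 proteins once each is worth more
  for screening than one that hits 50 proteins twice.
- **O2** — distinct representative scaffolds present (chemical
  diversity).
- **O3** — mean hits per covered protein (Σ hits / O1), rewarding
  redundancy of evidence separately from breadth.

The evolutionary scheme is elitist non-dominated sorting with crowding
distance (NSGA-II): binary tournaments on (rank, crowding), survival of
the best `ga_population` among parents plus offspring. Crossover keeps
the parents' intersection and repairs the child to size from the
symmetric difference; the repair is *coverage-greedy* — shuffled
candidates that add an uncovered protein are admitted first, the
remainder fill randomly. Greedy repair is the standard recombination
for set-covering encodings and is what lets a small evolution budget
(population 40, 60 generations at desk scale) reliably reach full
coverage; plain random repair stalls far from the optimum on the same
budget. Mutation swaps an included molecule for an excluded one,
Poisson-distributed with mean `ga_mutation_rate` (default 0.1) swaps
per individual per generation. Everything is driven by one seeded
generator, so runs are bit-reproducible.

Full-scale defaults are population 1000, subset 5000, 600 generations;
the desk-scale sizes used by the synthetic workflow and tests
(population 40, subset 50, 60 generations, 40 clusters) keep the whole
suite in seconds while exercising the identical code path.

The final library is the first-front subset lexicographically maximal
in (O1, O2, O3), ties to the lowest creation index. Completion then
appends, for each protein with bioactive candidates but no library
molecule, the candidate whose scaffold is carried by the most pool
molecules (ties: more targets, then smallest InChIKey). Completion
never removes molecules and never decreases O1; proteins with no
bioactive candidate anywhere are reported as uncoverable rather than
failing the run.

## Protein-class restriction

Only protein entries attached to a level-1 class node (the most
specific level of the 7-level family classification) stay on the main
selection path; entries the schema leaves unclassified are routed to
the completion pool. This mirrors how a class-driven selection misses
exactly the proteins the classification never reached, and completion
is what restores them.

## Enrichment

Per compound and namespace (GO / KEGG / DO), each term sharing at least
`min_term_overlap` (default 2) proteins with the compound's target set
is tested with the hypergeometric upper tail P(X ≥ k) (SciPy's survival
function; an exhaustive enumeration oracle checks it in the tests).
The universe defaults to all proteins annotated in the namespace, the
annotated-universe convention of standard over-representation tools.
Bonferroni multiplies by the number of *tested* terms for that compound
and namespace; significance is adjusted p < 0.1.

Calibration caveat: because the overlap-≥2 condition is itself a
selection, the family-wise error is guaranteed conservative only when
most terms reach the test condition (dense annotation). In sparse
regimes — few annotated proteins per term — the effective family is
smaller than the candidate collection and the realised error rate can
exceed the nominal cutoff. The null-calibration check therefore runs
under dense annotation; users testing sparse custom annotation sets
should widen the family or tighten the cutoff accordingly.

## Morphology

Replicates (1–8 per compound) are averaged per feature, missing values
ignored. Within each compartment (cell, cytoplasm, nucleus)
independently: zero-variance features are dropped (correlation is
undefined for constants, so this must precede the correlation filter),
then features are scanned in input column order and kept iff their
absolute Pearson correlation with every already-kept feature is below
0.95. Greedy keep-first is order-dependent by construction — the input
column order is the canonical order and is what the survivors are
defined against; the result is invariant to compound (row) order.
Profile–network matching uses the full 27-character InChIKey
(stereochemistry-sensitive); first-block matching is available by
configuration.

## Synthetic data

The generator emulates the *structure* of the real inputs, not their
marginal statistics:

- **Compounds**: 60 families (default) built by decorating distinct
  3-ring templates (central ring, two flanking ring systems, varied
  linkers) with saturated side chains, so level-1 and level-2 scaffold
  identities are known a priori and distinct across families.
- **Activities**: log-normal potencies around per-family means (median
  100 nM, σ = 1 log); each record is clean or carries exactly one
  planted violation (10% of records) of one filter predicate; two
  boundary records (exactly 1000 nM, and 999 nM on an otherwise
  untouched pair) pin the strict threshold. The truth record holds the
  exactly-expected retained pair set.
- **Targets**: 80 protein entries with randomised species variants, a
  7-family class tree with level-1 leaves, and 10% of entries left
  unclassified to exercise the completion path. Three families are
  planted promiscuous (8 targets) to exercise pruning.
- **Annotations**: random terms of 2–6 members per namespace plus
  planted terms containing exactly two targets of a chosen compound.
- **Morphology**: per compartment, 10 independent Gaussian features, 2
  exact constants, and 3 noisy copies of a latent vector (pairwise
  r > 0.99 within the group, independent of the rest); replicate counts
  uniform on 1–8 with small replicate noise.

What passing on this data shows: the pipeline's logic — predicates,
bookkeeping, optimisation, determinism — is correct against known
ground truth. What it does not show: behaviour under real ChEMBL-scale
skew (hugely uneven family sizes, correlated assay noise, redundant
near-duplicate series) or real image-feature covariance; conclusions
about those require the full-scale inputs.

A separate abstract benchmark (`planted_optimum_pool`) builds a
300-molecule pool in which 50 profile classes cover 100 proteins and
any class-transversal of size 50 is the unique optimum, used to verify
the genetic algorithm recovers a known optimum at the desk-scale
budget.

## Numerical and degenerate-input choices

- Jaccard distance for two all-zero profiles is an error, not 0 or 1;
  all-zero matrix rows are impossible by construction and rejected
  defensively.
- Hypergeometric bounds are validated; k = 0 returns exactly 1.
- The GA with pool size equal to subset size returns the single
  possible subset without evolving; a pool smaller than the subset is a
  configuration error, as is cutting more clusters than scaffolds.
- Empty subsets evaluate to the zero objective triple with O3 = 0.
- Manifest count identities (pruned + retained = generated;
  subset + additions = library) are asserted before any manifest is
  written.

## Known limitations

- The ring-pruning cascade is an adaptation, not a re-implementation,
  of the full published scaffold-tree rule set; chains can differ from
  Scaffold Hunter's on molecules where the finer rules disagree with
  the compact cascade.
- Exact reproduction of full-scale published counts depends on database
  releases and unstated orderings (e.g. the elimination order of the
  correlation filter); the package fixes and documents its own
  orderings instead.
- The GA is a heuristic: it finds the planted optimum on the benchmark
  but carries no optimality guarantee on arbitrary pools.
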