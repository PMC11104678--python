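# Methods

## Model

`cytodisc` tests whether cytonuclear discordance is explainable by
incomplete lineage sorting (ILS) under the neutral multispecies coalescent
(MSC). The organellar genome is treated as one non-recombining, haploid,
uniparentally inherited locus whose genealogy is a single draw from the
contained (censored) coalescent inside the nuclear species tree.

**Contained coalescent.** The guide tree's internal branch lengths are in
coalescent units (CU = generations / effective population size). One gene
lineage is sampled per species tip. Traversing the species tree from the
tips toward the root, a branch of CU length `L` entered by `k` lineages
experiences coalescent events at Exponential(`k(k−1)/2`) waiting times, each
merging a uniformly chosen pair; events that do not fit within `L` are
censored and the survivors enter the parent branch. The root branch is
infinite, so every draw yields a binary, rooted gene tree on the full tip
set. A polytomy passes all its children's surviving lineages jointly into
the parent branch (the coalescent semantics of a hard, unresolved
radiation).

**Inheritance scalar.** With haploidy and uniparental inheritance the
organellar effective population size is Ne/2 in hermaphroditic and Ne/4 in
dioecious taxa, i.e. the organellar coalescence rate is 2× or 4× the
nuclear rate. Multiplying all CU branch lengths by the scalar before
simulation is exactly equivalent; no conversion to generations or
population sizes is ever attempted, and both scalars are run by default so
the user sees the hermaphroditic and dioecious bounds.

**Concordance and decision rule.** Concordance is computed on unrooted,
canonical bipartitions over the full shared taxon set; the rooting of
simulated and observed trees is ignored. For each nontrivial split of the
observed organellar tree the report gives the fraction of the `n`
(default 1000) simulated trees containing it. A branch is an
*introgression candidate* when its frequency is ≤ the threshold (default
1%, compared with exact ≤ — ties at the boundary are candidates) under
**every** evaluated scalar; this conservative aggregation mirrors arguing
for capture only when ILS is rare under both inheritance assumptions.
Per-scalar verdicts are available via `per_scalar_verdicts`. Each row also
records whether the branch conflicts with the guide tree, so
discordance-flagging is mechanical rather than visual.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_trees` | 1000 | simulated gene trees per scalar; the frequency resolution is 1/n |
| `scalars` | 2, 4 | organellar inheritance scalars (hermaphroditic / dioecious) |
| `threshold` | 0.01 | ILS-rejection frequency (fraction, compared with ≤) |
| `missing_internal_length` | `"error"` | refuse to simulate, or substitute a CU value (0 = ILS-maximising, conservative) |
| `terminal_length` | 0 CU | immaterial with one lineage per species: no coalescence can occur in a terminal branch |

Missing branch lengths are never silently coerced: summary-coalescent
species trees lack terminal CU lengths and may lack some internal ones, so
absence is stored as absence and policy is explicit.

## Randomness and reproducibility

A master seed spawns one counter-derived stream per simulated tree
(`numpy` `SeedSequence.spawn`), so runs are bit-reproducible and tree `i`
does not depend on how many trees are drawn. The pipeline derives one
sub-seed per scalar from the run seed. Report tables are written with fixed
formatting and deterministic row order (sorted by smaller-side size, then
label string); two runs with identical inputs and seed are byte-identical.
The run manifest records tool version, input SHA-256 digests and the full
parameter set.

## Synthetic data: what it emulates, what it does not

The generator stands in for study-specific inputs:

* **Guide trees** — random-join topologies with i.i.d. internal CU lengths
  (exponential with configurable mean, default 1.0, or a fixed value) and
  absent terminal lengths. Lengths are drawn independently of topology
  depth: the harness needs controllable ILS levels, not a realistic
  diversification process. Tip labels are `T0001…`.
* **Observed trees** — `pure_ils`: one contained-coalescent draw (default
  at scalar 2.0, an organellar locus in hermaphroditic taxa; the spec of
  the scenario is otherwise agnostic about the draw's scalar);
  `capture`: the guide topology with the recipient clade pruned and
  regrafted as sister to the donor clade. Capture is modelled as a
  topology-level SPR, not as a mixture of gene histories, because the
  decision rule consumes only the observed topology.
* **Alignments** — Jukes–Cantor evolution along a caller-supplied
  substitution-scale tree, with gap/N blocks injected at recorded
  coordinates so masking expectations are exact. Richer substitution
  models would add nothing to what the alignment operators test.

A green end-to-end test therefore establishes that the simulator obeys the
MSC's distributional laws and that the decision rule recovers planted
captures in this idealised world; it does not establish robustness to gene
tree estimation error, branch-length misestimation in the guide tree, or
realistic diversification histories.

## Alignment operators

* **Masking**: every `N` is converted to `-` (optional), then columns whose
  gap fraction is *strictly greater* than the threshold (default 0.99) are
  removed — the verbatim "more than 99%" rule, so a 100-row column with
  exactly 99 gaps is kept. At the default threshold the removed columns are
  exactly the autapomorphic-insertion columns (present in ≤ 1% of rows).
  The comparison uses exact rational arithmetic (`Fraction`), never
  floating-point, so boundary columns are stable for any row count.
* **RY recoding**: A,G→R; C,T→Y; gaps and existing R/Y are fixed points
  (the map is idempotent); every other IUPAC code collapses to `N`, the
  information-conservative choice since codes such as W={A,T} span both
  categories. Output alphabet ⊆ {R,Y,N,−}.
* **Statistics**: degapped length counts characters that are neither `-`
  nor `N`. A column is parsimony-informative iff at least two of the
  unambiguous bases A,C,G,T each occur in at least two sequences; gaps,
  `N` and ambiguity codes are never states. Consequently an RY-recoded
  matrix has zero parsimony-informative sites by construction — a
  deliberate limitation: counting R/Y as states in two-state matrices
  would make "PIS never increases under recoding" false (e.g. a column
  A,G,C,C is uninformative as DNA but would be informative as RY).

## Numerical and design choices

* Bipartitions are canonicalized to the side not containing the
  lexicographically smallest taxon label; internally they are integer
  bitmasks, which makes tabulating 10³–10⁵ trees on >100 taxa cheap.
* Newick output uses 6 significant digits — beyond any biological signal,
  and round-trip stable. Internal node labels are always annotations
  (support values, simulated frequencies), never taxa.
* Gene-tree node times are bookkeeping on a max-based species-node height;
  on non-time-consistent species trees (absent terminal lengths) only the
  topology distribution is contractual, and it depends solely on per-edge
  CU lengths and lineage counts.
* Rescaling composes exactly for power-of-two factors; in general floating
  multiplication is associative only to the last ulp.
* The root edge of the guide tree is treated as infinite regardless of any
  stated root length.
* Annotated trees label every internal non-root node whose split has a
  report row with the per-scalar percentages at one decimal (`"7.4/2.6"`);
  with a binary root, both root-adjacent nodes carry the same (shared)
  split label.

## Known limitations

* One allele per species; no migration, recombination or time-calibrated
  output branch lengths.
* The test is one-sided: a frequency above the threshold shows ILS is
  *sufficient*, not that introgression is absent; a frequency below it
  makes ILS unlikely under the stated guide tree and scalars but inherits
  any error in the guide tree's CU lengths (gene-tree estimation error
  biases CU lengths downward, making the test conservative).
* In worlds where all internal branches are long (≥ ~2 CU), any
  ILS-generated discordant branch is itself a rare event whose specific
  minor split has expected frequency (1/3)e^(−sT) ≤ 1% — the rule then
  flags it. The false-positive rate of the 1% rule is only controlled
  where discordance arises at short branches, its intended regime.
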