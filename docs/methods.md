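# Methods

## Model

A mixture profile is a set of difference operations against a linear
reference sequence (1-based EMPOP/rCRS coordinates): substitutions with
IUPAC allele sets, insertions (`p.iS`), and deletions (`p del` / `p-`),
each with a `reference_retained` flag recording whether the reference
state was also observed.  For substitutions the flag is implied by the
allele set (reference base ∈ alleles); for indels a single difference
string cannot express it, so tokens default to "reference state present
in some contributor" and an explicit `!` suffix marks an indel as fixed
in all contributors.  This keeps plain EMPOP strings valid input while
letting the graph drop the reference state when it was truly absent.

The graph is built from the reference backbone — source and sink
sentinels, one base node per position, and an epsilon node between every
pair of adjacent positions plus terminals — by applying substitutions,
then insertions, then deletions, each in coordinate order:

* a substitution removes the reference base node and adds one node per
  observed allele between the flanking epsilons (the reference base is
  re-added like any allele when observed);
* an insertion after p splices a chain `e_p → i_1 … i_k → e_new`, with
  `e_new` taking over `e_p`'s former outgoing edges; a skip edge
  `e_p → e_new` exists only for non-fixed insertions, and is a
  first-class coverable element — exactly what makes a doubly-inserted
  contributor pair fail to explain an optional insertion;
* a deletion of span s..e adds a bypass edge from the epsilon directly
  preceding base s to the backbone epsilon `e_e`; a fixed deletion
  additionally removes the spanned base nodes (and any interior
  epsilons left dangling), making the bypass the only route.

The bypass is taken from the epsilon *currently* preceding base s: the
backbone epsilon in the ordinary case, or the insertion epsilon when an
insertion is anchored at s−1.  The alternative (always the backbone
epsilon) would strand a fixed insertion chain abutting a fixed deletion;
with the chosen rule both indel semantics stay correct, at the price
that an optional insertion and an abutting optional deletion may appear
on one path.  Nothing in the matching semantics depends on resolving
that ambiguity, and the simulator rejects abutting indel pairs anyway.

Because all variation hangs off the reference backbone, equivalent
encodings (a deletion placed anywhere in a homopolymer run, per-position
versus multi-base insertion forms) compile to graphs with identical
generated string sets — the property the whole design exists for, and
one of the property-tested invariants.

## Matching

Consistency of a haplotype h is decided by forward dynamic programming
over states (node, number of characters of h consumed), processed in
topological order; base nodes consume one matching character, epsilon
nodes none.  Accepting paths are enumerated by a DFS pruned with the
corresponding backward table, so every branch taken ends in an accepting
path and enumeration is linear in its output; successor order is
lexicographic in node id, making path lists deterministic.

The explanation test takes one accepting path per haplotype
(duplicated haplotypes may take different paths) and asks whether some
choice covers every node and edge.  The search is exhaustive over path
combinations with memoization on (haplotype index, uncovered-element
set) and a suffix-coverability prune.  Caps — 1,000 accepting paths per
haplotype, 10^6 assignments explored — exist only as safety valves for
adversarial graphs; hitting one flags the verdict `approximate` (a
lower bound on explainability).  Real mixtures sit far below the caps
because only a handful of haplotypes are ever consistent.

`feasible_pairs` enumerates the generated set and tests every unordered
pair through the same cover logic; for k biallelic substitution sites
the count is 2^(k−1) (1 for k = 0, where the only pair is the single
haplotype twice), which the closed-form route (`feasible_pair_count`)
computes from allele-node counts and the tests cross-check against
enumeration up to k = 12.

## Statistics

* **Clopper–Pearson upper bound**: the (1 − α/2) quantile of
  Beta(s + 1, n − s), 1.0 when s = n; confidence defaults to 0.95
  (two-sided).  Tests verify the zero-success closed form
  1 − (α/2)^(1/n) to 1e−10 and general cases against an independent
  binomial-tail bisection.
* **RMNE**: proportion of database records (within the selected
  population, after any masking) whose decoded sequence is consistent
  with the graph, plus the upper bound.
* **Likelihoods**: haplotype frequencies are relative frequencies
  (count/n) in the population slice — the minimal estimator consistent
  with a database framing.  The total likelihood sums
  |U|!·∏Pr(Hⱼ) over distinct u-sets of unique database haplotypes that
  (with the knowns) explain the graph; an empty sum is reported as 0
  with an `empty_t` flag.  The GBC likelihood counts u-combinations of
  database *records* (so duplicate sequences weight naturally) whose
  sequences explain the mixture, over C(n, u); knowns are conditioned
  on, not drawn, and do not enter the denominator.  A
  `with_replacement` switch (denominator C(n+u−1, u)) covers the
  alternative reading of unknown sampling; the default follows the
  C(n, u) combinatorics.
* **Pre-filter**: combination scans only consider haplotypes that pass
  the consistency test, which cannot change any count (every member of
  an explaining set is consistent); soundness is asserted against
  unrestricted scans on small databases.

A second, purely engineering pre-filter accelerates database scans: a
haplotype is discarded before the graph DP only if (a) its decoded
length is not among the lengths the graph can generate, or (b) one of
its substitution calls (or one of the mixture's fixed substitution
sites) mismatches outside a ±30 bp window around any indel footprint of
either the mixture or the record.  Outside such windows substitutions
cannot be re-aligned, so the screen is conservative; a property test
checks it never rejects a DP-consistent haplotype, and `prescreen=False`
disables it.

## Masking

Masking removes every call whose reference footprint (substitution
position, insertion anchor, deletion span) intersects a 1-based interval
set (BED input is converted from 0-based half-open).  It is applied
identically to the mixture and to database haplotypes, is idempotent,
and commutes with interval union.  It is only trustworthy away from
ambiguously placed indels, which is why the screen windows above are
generous.

## Synthetic data

The simulator stands in for a curated population database.  Haplotypes
are generated by independent per-site mutation on a random reference:
substitutions at rate 0.025/site and indels at 0.0005/site (half
insertions, half deletions; lengths geometric, mean ≈ 1.4, capped at 4),
with indels kept non-overlapping and non-abutting within a haplotype.
On the default 600 bp reference this yields ≈ 30 mean pairwise
differences and ≈ 0.3 indels per haplotype — European-like mitochondrial
diversity compressed onto a short backbone, so per-mixture behaviour
(tens of variant sites, occasional indel conflicts) matches the real
regime while each graph stays small.

What the generator does *not* emulate: phylogeny and linkage (sites are
independent, so shared variants between two random haplotypes are rare
and nearly every mixture site is ambiguous), recurrent-mutation
hotspots, and realistic indel placement inside homopolymer tracts.
Consequently the study's statistics probe the algorithm's correctness
and scaling, not population-genetic effect sizes: passing tests show
the graph machinery and the estimators behave as specified, not that
real-database RMNE values will match.

Two-person mixtures merge the contributors' call sets: substitution
allele sets are unioned (the reference allele kept when either
contributor carries it, also when a position sits inside the other
contributor's deletion), identical shared indels become fixed, private
indels stay optional.  Pairs are rejected — a typed outcome, not an
exception — when the haplotypes are identical or when indels partially
overlap *or abut* (abutting indels are as ambiguous to merge as
overlapping ones).  The study runner samples record pairs with
replacement, redraws on rejection up to a bounded attempt count
(50 × requested mixtures; a shortfall is reported rather than raised
unless nothing at all could be formed), and tabulates per mixture: the
number of distinct explaining haplotype pairs, the number of distinct
non-excluded haplotypes, p(RMNE) with its bound, and the u = 1 GBC
likelihood treating the first-sampled contributor as the known.

## Problem sizes and numerical choices

The end-to-end study runs 2,000 mixtures against a 2,000-haplotype
database on a 600 bp reference (seeds 2021 for the database, 1 for the
study), which completes in about a minute; the encoding-invariance check
covers 1,000 random homopolymer-deletion encodings on 60 bp references.
Enumeration caps: 100,000 generated spellings (oracle use only — never
on 2^31-path graphs, whose counts come from the linear-time DP instead).
Node identifiers are deterministic strings derived from anchors
(`b:154:T`, `e:154`, `bi:4.1:T`), so identical profiles give equal
graphs and stable fixtures.  Degenerate inputs: an empty variant string
is the pure-reference profile; an empty mask is the identity; a
zero-diversity database makes the study raise after its attempt bound.

## Known limitations

* Binary semantics only: no read counts, no genotyping-error model, no
  fuzzy matching.
* Single-source database haplotypes must be unambiguous (no point
  heteroplasmy codes).
* The reference is linear; mitochondrial circularity is ignored.
* No theta/population-substructure correction of likelihoods.
* The explanation search is exponential in the worst case; the caps
  above make it safe, at the cost of an `approximate` flag on
  pathological inputs.
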