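# mtmixgraph

Quantitation-free interpretation of mitochondrial DNA mixtures with
epsilon-node variation graphs.

## The problem

Forensic mtDNA profiles are reported as sequence *differences* against a
reference (the rCRS), in EMPOP style: `73G` (substitution), `4.1T`
(insertion after position 4), `5 del` (deletion).  Different alignment
parameters and variant-calling conventions can encode the *same*
haplotype in different ways — `4 del` and `5 del` inside a homopolymer
are different call sets but identical sequences — so call sets cannot be
compared directly.  For single-source profiles the fix is to decode calls
into strings and compare strings.  `mtmixgraph` provides the analogous
machinery for **mixtures**: the mixture's calls (with IUPAC ambiguity
codes such as `154W` = A or T observed) are compiled into a directed
acyclic *variation graph* whose source-to-sink paths spell exactly the
haplotypes compatible with the mixture.  All comparisons then happen at
the string-versus-graph level and are invariant to the calling and
alignment conventions used.

Sequence-free "epsilon" nodes are placed between every pair of adjacent
reference positions.  They bottleneck paths between variable sites so
that every node *and every edge* of the graph is certainly present in
the mixture — no uncertain phase edges are ever added.  That licenses
two binary tests for a candidate haplotype set:

* **consistency** — a haplotype is not excluded if it traces some
  source→sink path (decided by dynamic programming over
  (node, prefix-length) states);
* **explanation** — a set of haplotypes explains the mixture if each is
  consistent and some choice of one accepting path per haplotype
  covers every node and edge of the graph.

From these, two match statistics are computed over a population database
of single-source haplotypes (sample id, population, variant string):

* **p(RMNE)** — the proportion of database haplotypes consistent with
  the graph, with the exact Clopper–Pearson 95% (two-sided) upper bound
  correcting for finite database size;
* **likelihoods** — the naive likelihood of a set *U* of unknowns,
  `|U|! · ∏ⱼ Pr(Hⱼ)`, summed over all explaining sets (total
  likelihood), and the **GBC likelihood**: the proportion of the
  C(n, u) u-combinations of database haplotypes (knowns appended) that
  explain the mixture, again with a Clopper–Pearson upper bound so an
  unexplainable mixture yields a usable bound instead of zero.

For a two-person mixture with k ambiguous sites there are 2^(k−1)
feasible haplotype pairs, so explicit pair enumeration is hopeless at
realistic diversity (~30–55 pairwise differences); the graph makes the
statistics computable by testing database haplotypes directly and only
combining the (few) non-excluded ones.

It is a *binary* method: allele calls are assumed error-free and read
counts are deliberately ignored.  Heteroplasmy within single-source
database haplotypes, fuzzy matching and theta-corrected likelihoods are
out of scope.

## Worked example

With `ref.fasta` a 200 bp reference carrying A at positions 73/154/178
and `db.tsv` a five-entry database

```text
#sample_id  population  variants
S1          EU          73G 154T 178A
S2          EU          73G 154A 178C
S3          EU          73G 154T 178C
S4          EU          9A 73G
S5          EU          151C
```

the mixture `73G 154W 178M` (both contributors G at 73; A/T observed at
154, A/C at 178) gives:

```sh
$ mtmixgraph rmne ref.fasta db.tsv "73G 154W 178M"
{
 "n_consistent": 3,
 "n": 5,
 "p_rmne": 0.6,
 "p_rmne_upper": 0.9472550494736831,
 "population": null,
 "consistent_ids": ["S1", "S2", "S3"]
}
```

S1–S3 carry one of the observed alleles at every site, so they cannot be
excluded; S4 and S5 carry private variants absent from the mixture and
are excluded.  p(RMNE) = 3/5, with its exact-binomial upper bound.

```sh
$ mtmixgraph likelihood ref.fasta db.tsv "73G 154W 178M" -u 2
{
 "mode": "gbc",
 "n_explaining": 1,
 "denominator": 10,
 "proportion": 0.1,
 "upper_bound": 0.4450161170281954,
 "u": 2,
 "approximate": false
}
```

Of the C(5,2) = 10 database pairs only (S1, S2) explains the mixture —
they are complementary at both ambiguous sites, so their paths jointly
cover every node and edge.  (S1, S3) share 154T and leave the 154A node
uncovered.  Conditioning on a known contributor works the same way
(`-u 1 --known "73G 154A 178A"` scans single unknowns against the
known); a likelihood ratio is the ratio of two such runs under different
known/unknown configurations.

Other subcommands: `build-graph` (export a mixture's graph as JSON/DOT),
`explain` (test a specific haplotype set), `simulate` (generate a
synthetic database and an in silico two-person mixture study; see
`docs/methods.md`).  Everything is also available as a library:

```python
import mtmixgraph as mg
ref = mg.ReferenceSequence.from_fasta("ref.fasta")
vg  = mg.build_mixture_graph(mg.parse_variant_string("73G 154W 178M", ref))
mg.enumerate_generated(vg).count      # 4 compatible haplotypes
len(mg.feasible_pairs(vg).pairs)      # 2 explaining pairs
```

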