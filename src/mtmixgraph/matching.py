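"""String-to-graph matching and the explanation (cover) test.

A haplotype is *consistent* with (not excluded by) a mixture when it
spells some source-to-sink path of the variation graph; epsilon nodes
consume no characters.  A set of haplotypes *explains* the mixture when
each is consistent and some choice of one accepting path per haplotype
collectively covers every node and every edge of the graph -- the binary
analogue of "these contributors, and nothing unaccounted for, produced
the mixture".

Consistency is decided by dynamic programming over (node, consumed-prefix
length) states in topological order; accepting paths are enumerated by a
backward-table-pruned DFS, so enumeration is linear in its output.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

from .errors import MtMixError
from .graph import KIND_BASE, GeneratedSet, VariantGraph, enumerate_generated

DEFAULT_PATH_CAP = 1_000
DEFAULT_ASSIGNMENT_CAP = 1_000_000


def _forward_table(vg: VariantGraph, hap: str):
    """f[v] = set of prefix lengths consumed on some source->v path,
    v's own label included.  Empty dict values are dropped."""
    L = len(hap)
    f = {vg.source: frozenset({0})}
    for v in vg.topological_order():
        sv = f.get(v)
        if not sv:
            continue
        for w in vg.g.successors(v):
            if vg.kind(w) == KIND_BASE:
                lab = vg.label(w)
                nxt = frozenset(i + 1 for i in sv if i < L and hap[i] == lab)
                if not nxt:
                    continue
            else:
                nxt = sv
            cur = f.get(w)
            f[w] = nxt if cur is None else cur | nxt
    return f


def _backward_table(vg: VariantGraph, hap: str):
    """g[v] = set of consumed counts at v from which the sink is reachable
    consuming exactly the rest of the haplotype."""
    L = len(hap)
    g = {vg.sink: frozenset({L})}
    for v in reversed(vg.topological_order()):
        if v == vg.sink:
            continue
        acc = set()
        for w in vg.g.successors(v):
            gw = g.get(w)
            if not gw:
                continue
            if vg.kind(w) == KIND_BASE:
                lab = vg.label(w)
                acc.update(j for j in (i - 1 for i in gw) if 0 <= j and hap[j] == lab)
            else:
                acc.update(gw)
        if acc:
            g[v] = frozenset(acc)
    return g


def is_consistent(vg: VariantGraph, haplotype: str) -> bool:
    """True iff some source->sink path spells the haplotype."""
    f = _forward_table(vg, haplotype)
    return len(haplotype) in f.get(vg.sink, ())


@dataclass(frozen=True)
class AcceptingPathSet:
    """All (up to ``truncated``) distinct source->sink node paths spelling
    one haplotype."""

    haplotype: str
    paths: tuple
    truncated: bool = False

    def cover_sets(self):
        """One frozenset of covered nodes+edges per accepting path
        (duplicates removed, order preserved)."""
        seen, out = set(), []
        for p in self.paths:
            c = frozenset(p) | frozenset(zip(p, p[1:]))
            if c not in seen:
                seen.add(c)
                out.append(c)
        return out


def accepting_paths(
    vg: VariantGraph, haplotype: str, cap: int = DEFAULT_PATH_CAP
) -> AcceptingPathSet:
    """Enumerate distinct accepting paths for one haplotype, deterministic
    (lexicographic by node id), pruned by the backward DP table so every
    DFS branch ends in an accepting path."""
    L = len(haplotype)
    g = _backward_table(vg, haplotype)
    if 0 not in g.get(vg.source, ()):
        return AcceptingPathSet(haplotype, ())
    paths = []
    truncated = False
    path = [vg.source]
    counts = [0]
    stack = [iter(vg.successors_sorted(vg.source))]
    while stack:
        it = stack[-1]
        w = next(it, None)
        if w is None:
            stack.pop()
            path.pop()
            counts.pop()
            continue
        i = counts[-1]
        if vg.kind(w) == KIND_BASE:
            if i >= L or haplotype[i] != vg.label(w):
                continue
            j = i + 1
        else:
            j = i
        if j not in g.get(w, ()):
            continue
        if w == vg.sink:
            paths.append(tuple(path) + (w,))
            if len(paths) >= cap:
                truncated = True
                break
            continue
        path.append(w)
        counts.append(j)
        stack.append(iter(vg.successors_sorted(w)))
    return AcceptingPathSet(haplotype, tuple(paths), truncated)


def graph_universe(vg: VariantGraph) -> frozenset:
    """All coverable elements: every node and every (ordered) edge."""
    return frozenset(vg.g.nodes) | frozenset(vg.g.edges())


@dataclass(frozen=True)
class ExplanationResult:
    """Outcome of the node+edge cover test for a haplotype multiset."""

    explained: bool
    uncovered_nodes: frozenset
    uncovered_edges: frozenset
    witness: tuple = None
    approximate: bool = False


class PathCache:
    """Per-graph memo of accepting path sets, shared across many explain
    queries against the same mixture."""

    def __init__(self, vg: VariantGraph, cap: int = DEFAULT_PATH_CAP):
        self.vg = vg
        self.cap = cap
        self._memo = {}

    def get(self, hap: str) -> AcceptingPathSet:
        aps = self._memo.get(hap)
        if aps is None:
            aps = accepting_paths(self.vg, hap, self.cap)
            self._memo[hap] = aps
        return aps


def _split_uncovered(vg: VariantGraph, uncovered: frozenset):
    nodes = frozenset(x for x in uncovered if not isinstance(x, tuple))
    edges = frozenset(x for x in uncovered if isinstance(x, tuple))
    return nodes, edges


def explains(
    vg: VariantGraph,
    haplotypes,
    cap_paths: int = DEFAULT_PATH_CAP,
    cap_assignments: int = DEFAULT_ASSIGNMENT_CAP,
    path_cache: PathCache = None,
) -> ExplanationResult:
    """Decide whether a multiset of haplotypes explains the mixture graph.

    Each haplotype must be individually consistent, and there must exist
    one accepting path per haplotype whose union covers every node and
    edge (duplicated haplotypes may take different paths).  The search
    over path choices is exhaustive with memoized pruning; hitting a cap
    flags the verdict as approximate (a lower bound on explainability).
    """
    haps = list(haplotypes)
    if not haps:
        raise ValueError("explains requires at least one haplotype")
    if path_cache is None:
        path_cache = PathCache(vg, cap_paths)
    universe = graph_universe(vg)
    approximate = False
    cover_lists = []
    default_assignment = []
    for h in haps:
        aps = path_cache.get(h)
        if aps.truncated:
            approximate = True
        covers = aps.cover_sets()
        cover_lists.append(covers)
        default_assignment.append(aps.paths[0] if aps.paths else None)

    if any(not covers for covers in cover_lists):
        covered = frozenset().union(
            *(c[0] for c in cover_lists if c), frozenset()
        )
        un, ue = _split_uncovered(vg, universe - covered)
        return ExplanationResult(False, un, ue, None, approximate)

    # suffix unions for pruning: elements only coverable by haps >= i
    n = len(haps)
    suffix = [frozenset()] * (n + 1)
    for i in range(n - 1, -1, -1):
        suffix[i] = suffix[i + 1] | frozenset().union(*cover_lists[i])

    visited = set()
    budget = [cap_assignments]
    witness = [None]

    def dfs(i, uncovered, chosen):
        if witness[0] is not None or budget[0] <= 0:
            return
        if not uncovered:
            witness[0] = tuple(chosen) + tuple(default_assignment[i:])
            return
        if i == n or not uncovered <= suffix[i]:
            return
        key = (i, uncovered)
        if key in visited:
            return
        visited.add(key)
        aps = path_cache.get(haps[i])
        seen_covers = set()
        for path in aps.paths:
            cover = frozenset(path) | frozenset(zip(path, path[1:]))
            if cover in seen_covers:
                continue
            seen_covers.add(cover)
            budget[0] -= 1
            if budget[0] <= 0:
                break
            dfs(i + 1, uncovered - cover, chosen + [path])
            if witness[0] is not None:
                return

    dfs(0, universe, [])
    if budget[0] <= 0:
        approximate = True
    if witness[0] is not None:
        return ExplanationResult(True, frozenset(), frozenset(), witness[0], approximate)
    # report uncovered elements for the default (first-path) assignment
    covered = frozenset()
    for p in default_assignment:
        covered |= frozenset(p) | frozenset(zip(p, p[1:]))
    un, ue = _split_uncovered(vg, universe - covered)
    return ExplanationResult(
        False, un, ue, tuple(default_assignment), approximate
    )


def pair_cover_explains(covers_a, covers_b, universe: frozenset) -> bool:
    """True when some pair of accepting-path cover sets jointly covers the
    whole graph.  Shared fast path for pair statistics."""
    missing_a = [universe - ca for ca in covers_a]
    for ma, ca in zip(missing_a, covers_a):
        for cb in covers_b:
            if ma <= cb and (universe - cb) <= ca:
                return True
    return False


@dataclass(frozen=True)
class FeasiblePairSet:
    """All unordered generated-haplotype pairs passing the explanation
    test (the 2^(k-1) combinatorics object)."""

    pairs: frozenset
    truncated: bool = False


def feasible_pairs(vg: VariantGraph, cap: int = 100_000) -> FeasiblePairSet:
    """Enumerate the generated set and return every unordered pair (identical
    pairs included) that explains the graph.

    Small-scale oracle: for a mixture of k biallelic substitution sites the
    result has exactly 2^(k-1) pairs (1 for k = 0).
    """
    gen = enumerate_generated(vg, cap)
    universe = graph_universe(vg)
    seqs = sorted(gen.sequences)
    covers = {}
    truncated = gen.truncated
    for s in seqs:
        aps = accepting_paths(vg, s)
        truncated = truncated or aps.truncated
        covers[s] = aps.cover_sets()
    pairs = set()
    for i, a in enumerate(seqs):
        for b in seqs[i:]:
            if pair_cover_explains(covers[a], covers[b], universe):
                pairs.add((a, b))
    return FeasiblePairSet(frozenset(pairs), truncated)


def ambiguous_substitution_sites(vg: VariantGraph) -> int:
    """Number of backbone positions carrying more than one allele node."""
    counts = {}
    for n, d in vg.g.nodes(data=True):
        if d["kind"] == KIND_BASE and d["anchor"].startswith("pos:"):
            p = int(d["anchor"].split(":")[1])
            counts[p] = counts.get(p, 0) + 1
    return sum(1 for c in counts.values() if c > 1)


def feasible_pair_count(vg: VariantGraph) -> int:
    """Closed-form unordered explaining-pair count 2^(k-1) for mixtures of
    k biallelic substitution sites and no indels (1 when k = 0).

    Raises when the closed form does not apply (indels present, or a site
    with more than two alleles).
    """
    has_indel = any(":" in n and n.split(":")[0] in ("bi", "ei") for n in vg.g.nodes)
    if has_indel or vg._deletion_spans or vg._insertion_anchors:
        raise MtMixError("closed-form pair count requires a substitution-only graph")
    counts = {}
    for n, d in vg.g.nodes(data=True):
        if d["kind"] == KIND_BASE:
            p = int(d["anchor"].split(":")[1])
            counts[p] = counts.get(p, 0) + 1
    if any(c > 2 for c in counts.values()):
        raise MtMixError(
            "closed-form pair count requires biallelic sites only"
        )
    k = sum(1 for c in counts.values() if c == 2)
    return 1 if k == 0 else 2 ** (k - 1)
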