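"""Epsilon-node variation graphs for mixtures.

The graph is built by treating the reference as a template and applying
each difference operation in turn.  An epsilon (sequence-free) node sits
between every pair of adjacent reference positions, plus terminal epsilons
and source/sink sentinels:

    source -> e0 -> b1 -> e1 -> b2 -> ... -> bL -> eL -> sink

Epsilon nodes bottleneck paths between variable positions so that every
node *and every edge* in the graph is asserted present in the mixture --
the construction never adds uncertain edges.  Source-to-sink paths spell
exactly the haplotypes compatible with the mixture, which makes the graph
a haplotype generator and the basis for the matching tests.

Conventions (one per operation):

* substitution: the reference base node is removed and one node per
  observed allele is added in its place (the reference base is re-added
  like any other allele when it was observed);
* insertion after position p: a chain ``e_p -> i1 .. ik -> e_new`` takes
  over ``e_p``'s former outgoing edges; a skip edge ``e_p -> e_new`` is
  added only when some contributor lacks the insertion;
* deletion of span s..e: a bypass edge from the epsilon directly before
  base s to the backbone epsilon ``e_e``; when the deletion is fixed in
  all contributors the spanned base nodes are removed instead of merely
  bypassed.

Node identifiers are deterministic functions of their anchors, so graphs
built from identical profiles compare equal.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx

from .errors import GraphConstructionError
from .variants import (
    DELETION,
    INSERTION,
    SUBSTITUTION,
    MixtureProfile,
    ReferenceSequence,
    format_variant_string,
    parse_variant_string,
)

SOURCE = "source"
SINK = "sink"

KIND_BASE = "base"
KIND_EPSILON = "epsilon"
KIND_SOURCE = "source"
KIND_SINK = "sink"


def eps_id(p: int) -> str:
    """Backbone epsilon after reference position p (e:0 precedes base 1)."""
    return f"e:{p}"


def base_id(p: int, b: str) -> str:
    return f"b:{p}:{b}"


def ins_base_id(anchor: int, i: int, b: str) -> str:
    return f"bi:{anchor}.{i}:{b}"


def ins_eps_id(anchor: int) -> str:
    return f"ei:{anchor}"


@dataclass(eq=False)
class VariantGraph:
    """A directed acyclic variation graph with base and epsilon nodes.

    Equality compares nodes (with attributes), edges and the reference;
    bookkeeping fields are excluded.
    """

    g: nx.DiGraph
    reference: ReferenceSequence
    profile: MixtureProfile = None
    source: str = SOURCE
    sink: str = SINK
    _modified_subs: set = field(default_factory=set)
    _insertion_anchors: set = field(default_factory=set)
    _deletion_spans: list = field(default_factory=list)
    _topo: list = None

    # -- introspection -------------------------------------------------

    def kind(self, node) -> str:
        return self.g.nodes[node]["kind"]

    def label(self, node) -> str:
        return self.g.nodes[node]["label"]

    def topological_order(self):
        if self._topo is None:
            self._topo = list(nx.topological_sort(self.g))
        return self._topo

    def successors_sorted(self, node):
        return sorted(self.g.successors(node))

    def copy(self) -> "VariantGraph":
        return VariantGraph(
            self.g.copy(),
            self.reference,
            self.profile,
            self.source,
            self.sink,
            set(self._modified_subs),
            set(self._insertion_anchors),
            list(self._deletion_spans),
        )

    def __eq__(self, other):
        if not isinstance(other, VariantGraph):
            return NotImplemented
        return (
            self.reference == other.reference
            and dict(self.g.nodes(data=True)) == dict(other.g.nodes(data=True))
            and set(self.g.edges()) == set(other.g.edges())
        )

    # -- export --------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "reference": {"name": self.reference.name, "bases": self.reference.bases},
            "profile": format_variant_string(self.profile)
            if self.profile is not None
            else None,
            "nodes": [
                {"id": n, "kind": d["kind"], "label": d["label"], "anchor": d["anchor"]}
                for n, d in sorted(self.g.nodes(data=True))
            ],
            "edges": sorted(self.g.edges()),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "VariantGraph":
        payload = json.loads(text)
        ref = ReferenceSequence(**payload["reference"])
        g = nx.DiGraph()
        for n in payload["nodes"]:
            g.add_node(n["id"], kind=n["kind"], label=n["label"], anchor=n["anchor"])
        g.add_edges_from(tuple(e) for e in payload["edges"])
        profile = (
            parse_variant_string(payload["profile"], ref)
            if payload.get("profile") is not None
            else None
        )
        return cls(g, ref, profile)

    def to_dot(self) -> str:
        lines = ["digraph variant_graph {", "  rankdir=LR;"]
        for n, d in sorted(self.g.nodes(data=True)):
            if d["kind"] == KIND_BASE:
                lines.append(f'  "{n}" [label="{d["label"]}", shape=circle];')
            elif d["kind"] == KIND_EPSILON:
                lines.append(
                    f'  "{n}" [label="", shape=point, width=0.12];'
                )
            else:
                lines.append(f'  "{n}" [label="{d["kind"]}", shape=plaintext];')
        for u, v in sorted(self.g.edges()):
            lines.append(f'  "{u}" -> "{v}";')
        lines.append("}")
        return "\n".join(lines)


# --------------------------------------------------------------------------
# Construction
# --------------------------------------------------------------------------

def build_reference_graph(reference: ReferenceSequence) -> VariantGraph:
    """Linear backbone: L base nodes interleaved with L+1 epsilons (terminal
    epsilons included) between source and sink sentinels."""
    g = nx.DiGraph()
    g.add_node(SOURCE, kind=KIND_SOURCE, label="", anchor="source")
    g.add_node(SINK, kind=KIND_SINK, label="", anchor="sink")
    g.add_node(eps_id(0), kind=KIND_EPSILON, label="", anchor="after:0")
    g.add_edge(SOURCE, eps_id(0))
    for p in range(1, reference.length + 1):
        b = reference.bases[p - 1]
        g.add_node(base_id(p, b), kind=KIND_BASE, label=b, anchor=f"pos:{p}")
        g.add_node(eps_id(p), kind=KIND_EPSILON, label="", anchor=f"after:{p}")
        g.add_edge(eps_id(p - 1), base_id(p, b))
        g.add_edge(base_id(p, b), eps_id(p))
    g.add_edge(eps_id(reference.length), SINK)
    return VariantGraph(g, reference)


def _base_nodes_at(vg: VariantGraph, p: int):
    prefix = f"b:{p}:"
    return [n for n in vg.g.nodes if n.startswith(prefix)]


def _apply_substitution(vg: VariantGraph, call) -> None:
    p = call.position
    if p in vg._modified_subs:
        raise GraphConstructionError(f"position {p} already substituted")
    ref_base = vg.reference.base_at(p)
    ref_node = base_id(p, ref_base)
    if ref_node not in vg.g:
        raise GraphConstructionError(
            f"position {p} has no intact reference node (already modified)"
        )
    vg.g.remove_node(ref_node)
    for allele in sorted(call.alleles):
        n = base_id(p, allele)
        vg.g.add_node(n, kind=KIND_BASE, label=allele, anchor=f"pos:{p}")
        vg.g.add_edge(eps_id(p - 1), n)
        vg.g.add_edge(n, eps_id(p))
    vg._modified_subs.add(p)
    vg._topo = None


def _apply_insertion(vg: VariantGraph, call) -> None:
    p = call.position
    if p in vg._insertion_anchors:
        raise GraphConstructionError(f"conflicting insertion at anchor {p}")
    attach = eps_id(p)
    if attach not in vg.g:
        raise GraphConstructionError(
            f"insertion anchor {p} has no epsilon node (deleted region?)"
        )
    new_eps = ins_eps_id(p)
    old_succ = list(vg.g.successors(attach))
    for w in old_succ:
        vg.g.remove_edge(attach, w)
    vg.g.add_node(new_eps, kind=KIND_EPSILON, label="", anchor=f"after-ins:{p}")
    prev = attach
    for i, b in enumerate(call.inserted, start=1):
        n = ins_base_id(p, i, b)
        vg.g.add_node(n, kind=KIND_BASE, label=b, anchor=f"ins:{p}.{i}")
        vg.g.add_edge(prev, n)
        prev = n
    vg.g.add_edge(prev, new_eps)
    for w in old_succ:
        vg.g.add_edge(new_eps, w)
    if call.reference_retained:
        vg.g.add_edge(attach, new_eps)
    vg._insertion_anchors.add(p)
    vg._topo = None


def _prune_dangling(vg: VariantGraph) -> None:
    changed = True
    while changed:
        changed = False
        for n in list(vg.g.nodes):
            if n in (vg.source, vg.sink):
                continue
            if vg.g.in_degree(n) == 0 or vg.g.out_degree(n) == 0:
                vg.g.remove_node(n)
                changed = True


def _apply_deletion(vg: VariantGraph, call) -> None:
    s, e = call.position, call.end_position
    for s0, e0 in vg._deletion_spans:
        if s <= e0 and s0 <= e:
            raise GraphConstructionError(
                f"deletion {s}..{e} overlaps existing deletion {s0}..{e0}"
            )
    start_nodes = _base_nodes_at(vg, s)
    if not start_nodes:
        raise GraphConstructionError(f"no base nodes at deletion start {s}")
    # the epsilon directly preceding base s: the backbone epsilon e_{s-1},
    # or the insertion epsilon ei_{s-1} when an insertion was applied there
    preds = {
        w
        for n in start_nodes
        for w in vg.g.predecessors(n)
        if vg.kind(w) == KIND_EPSILON
    }
    if len(preds) != 1:
        raise GraphConstructionError(
            f"ambiguous predecessor epsilon for deletion start {s}: {sorted(preds)}"
        )
    eps_before = preds.pop()
    target = eps_id(e)
    if target not in vg.g:
        raise GraphConstructionError(f"no epsilon after deletion end {e}")
    vg.g.add_edge(eps_before, target)
    if not call.reference_retained:
        for p in range(s, e + 1):
            for n in _base_nodes_at(vg, p):
                vg.g.remove_node(n)
        for p in range(s, e):
            if eps_id(p) in vg.g:
                vg.g.remove_node(eps_id(p))
        _prune_dangling(vg)
    vg._deletion_spans.append((s, e))
    vg._topo = None


def apply_substitution(vg: VariantGraph, call) -> VariantGraph:
    """Pure wrapper: return a new graph with the substitution applied."""
    out = vg.copy()
    _apply_substitution(out, call)
    return out


def apply_insertion(vg: VariantGraph, call) -> VariantGraph:
    out = vg.copy()
    _apply_insertion(out, call)
    return out


def apply_deletion(vg: VariantGraph, call) -> VariantGraph:
    out = vg.copy()
    _apply_deletion(out, call)
    return out


def build_mixture_graph(profile: MixtureProfile) -> VariantGraph:
    """Build the full mixture graph: substitutions, then insertions, then
    deletions, each in coordinate order (deterministic node ids)."""
    vg = build_reference_graph(profile.reference)
    for c in sorted(profile.substitutions, key=lambda c: c.position):
        _apply_substitution(vg, c)
    for c in sorted(profile.insertions, key=lambda c: c.position):
        _apply_insertion(vg, c)
    for c in sorted(profile.deletions, key=lambda c: c.position):
        _apply_deletion(vg, c)
    vg.profile = profile
    return vg


# --------------------------------------------------------------------------
# Generator operations
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratedSet:
    """Distinct source-to-sink spellings of a graph (the haplotypes it
    generates); ``truncated`` flags a hit enumeration cap."""

    sequences: frozenset
    count: int
    truncated: bool = False


def enumerate_generated(vg: VariantGraph, cap: int = 100_000) -> GeneratedSet:
    """Exhaustively enumerate distinct source->sink spellings (up to ``cap``
    paths explored).  This is the small-scale oracle for the matching
    module; it is never intended for graphs with astronomically many paths.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    seqs = set()
    truncated = False
    chars = []
    stack = [(vg.source, iter(vg.successors_sorted(vg.source)))]
    explored = 0
    while stack:
        node, it = stack[-1]
        w = next(it, None)
        if w is None:
            stack.pop()
            if vg.kind(node) == KIND_BASE:
                chars.pop()
            continue
        if w == vg.sink:
            seqs.add("".join(chars))
            explored += 1
            if explored >= cap:
                truncated = True
                break
            continue
        if vg.kind(w) == KIND_BASE:
            chars.append(vg.label(w))
        stack.append((w, iter(vg.successors_sorted(w))))
    return GeneratedSet(frozenset(seqs), len(seqs), truncated)


def count_generated(vg: VariantGraph) -> int:
    """Exact number of distinct source->sink *paths* by dynamic programming
    over the topological order (linear in the number of edges).

    Equals the number of distinct spellings when no indel creates
    sequence-identical alternative paths.
    """
    ways = {n: 0 for n in vg.g.nodes}
    ways[vg.source] = 1
    for v in vg.topological_order():
        wv = ways[v]
        if wv:
            for w in vg.g.successors(v):
                ways[w] += wv
    return ways[vg.sink]
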