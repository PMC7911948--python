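"""Synthetic haplotype databases and in silico two-person mixtures.

The generator stands in for a curated population database: haplotypes are
drawn by independent per-site mutation on a random (or supplied) linear
reference -- substitutions at a per-site rate plus occasional short
indels.  There is no phylogeny or linkage; the match statistics under
test do not require realistic LD, and diversity is tuned through the
substitution rate (the default targets roughly 30 mean pairwise
differences on a 600 bp reference, i.e. European-like mitochondrial
nucleotide diversity at reduced scale).

Two-person mixtures are built by merging the contributors' call sets:
substitution allele sets are unioned (ambiguity codes appear where the
contributors differ), indels carried by only one contributor keep the
reference state available, and indels shared identically are fixed.
Pairs are rejected -- a typed outcome, not an exception -- when the two
haplotypes are identical or when their indels partially overlap or abut.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SimulationError
from .graph import build_mixture_graph
from .matching import PathCache, graph_universe, pair_cover_explains
from .stats import (
    HaplotypeDatabase,
    HaplotypeRecord,
    clopper_pearson_upper,
    consistent_records,
)
from .variants import (
    DELETION,
    INSERTION,
    SUBSTITUTION,
    MixtureProfile,
    ReferenceSequence,
    VariantCall,
    decode_haplotype,
    format_variant_string,
)

_ALPHABET = np.array(list("ACGT"))


@dataclass(frozen=True)
class PopulationModel:
    """Parameters of the synthetic population generator.

    ``substitution_rate`` is the per-site probability that a haplotype
    carries a non-reference base (0.025 on a 600 bp reference gives ~30
    mean pairwise differences); ``indel_rate`` is the per-site probability
    of starting an indel (insertions and deletions equally likely, lengths
    geometric with mean ~1/``indel_length_p`` capped at ``max_indel``).
    """

    reference_length: int = 600
    substitution_rate: float = 0.025
    indel_rate: float = 0.0005
    indel_length_p: float = 0.7
    max_indel: int = 4
    n_haplotypes: int = 1000
    population: str = "POP"
    seed: int = 0

    def __post_init__(self):
        for name in ("substitution_rate", "indel_rate", "indel_length_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.reference_length < 1:
            raise SimulationError("reference length must be positive")


def simulate_reference(length: int, seed: int, name: str = "synthref") -> ReferenceSequence:
    """A uniform-random A/C/G/T reference (synthetic stand-in for the rCRS)."""
    if length < 1:
        raise SimulationError("reference length must be positive")
    rng = np.random.default_rng(seed)
    return ReferenceSequence(name, "".join(rng.choice(_ALPHABET, size=length)))


def _simulate_calls(rng, reference: ReferenceSequence, model: PopulationModel):
    L = reference.length
    sub_pos = np.flatnonzero(rng.random(L) < model.substitution_rate) + 1
    indel_pos = np.flatnonzero(rng.random(L) < model.indel_rate) + 1
    calls = []
    indel_spans = []  # inclusive footprints, used to keep indels apart

    def clear_of_indels(lo, hi):
        # require a >=1 base gap so indels never overlap or abut
        return all(hi < s - 1 or lo > e + 1 for s, e in indel_spans)

    for p in indel_pos:
        p = int(p)
        length = min(int(rng.geometric(model.indel_length_p)), model.max_indel)
        if rng.random() < 0.5:  # deletion
            end = min(p + length - 1, L)
            if clear_of_indels(p, end):
                calls.append(VariantCall.deletion(p, end, reference_retained=False))
                indel_spans.append((p, end))
        else:  # insertion after p
            if clear_of_indels(p, p):
                seq = "".join(rng.choice(_ALPHABET, size=length))
                calls.append(
                    VariantCall.insertion(p, seq, reference_retained=False)
                )
                indel_spans.append((p, p))

    deleted = {
        q for c in calls if c.kind == DELETION for q in range(c.position, c.end_position + 1)
    }
    for p in sub_pos:
        p = int(p)
        if p in deleted:
            continue
        ref_base = reference.bases[p - 1]
        alts = [b for b in "ACGT" if b != ref_base]
        alt = alts[int(rng.integers(3))]
        calls.append(
            VariantCall.substitution(p, {alt}, reference_retained=False)
        )
    return tuple(sorted(calls, key=lambda c: c.sort_key))


def simulate_database(
    model: PopulationModel, reference: ReferenceSequence = None
) -> HaplotypeDatabase:
    """Generate a deterministic (seeded) synthetic haplotype database."""
    rng = np.random.default_rng(model.seed)
    if reference is None:
        reference = ReferenceSequence(
            "synthref", "".join(rng.choice(_ALPHABET, size=model.reference_length))
        )
    records = []
    for i in range(model.n_haplotypes):
        calls = _simulate_calls(rng, reference, model)
        records.append(
            HaplotypeRecord(
                f"{model.population}-{i:05d}",
                model.population,
                calls,
                decode_haplotype(reference, calls),
            )
        )
    return HaplotypeDatabase(reference, records)


# --------------------------------------------------------------------------
# Mixture construction
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureRejection:
    """A sampled haplotype pair that cannot form a well-defined mixture."""

    reason: str  # "identical_haplotype" | "indel_overlap"


def _indel_key(c: VariantCall):
    if c.kind == INSERTION:
        return (INSERTION, c.position, c.inserted)
    return (DELETION, c.position, c.end_position)


def _indels_conflict(a: VariantCall, b: VariantCall) -> bool:
    """Partially overlapping or abutting indels from different contributors
    cannot be merged into single graph events."""
    if a.kind == DELETION and b.kind == DELETION:
        return b.position <= a.end_position + 1 and a.position <= b.end_position + 1
    if a.kind == INSERTION and b.kind == INSERTION:
        return a.position == b.position
    ins, dele = (a, b) if a.kind == INSERTION else (b, a)
    return dele.position - 1 <= ins.position <= dele.end_position


def make_mixture(h1: HaplotypeRecord, h2: HaplotypeRecord, reference: ReferenceSequence):
    """Merge two single-source call sets into a mixture profile, or return a
    :class:`MixtureRejection`.

    Substitution allele sets are unioned with the reference state kept
    whenever either contributor carries it; identical shared indels become
    fixed; indels private to one contributor keep the reference state
    available.  Identical haplotypes and partially overlapping (or
    abutting) non-identical indels are rejected.
    """
    if h1.sequence == h2.sequence:
        return MixtureRejection("identical_haplotype")
    ind1 = [c for c in h1.calls if c.kind != SUBSTITUTION]
    ind2 = [c for c in h2.calls if c.kind != SUBSTITUTION]
    keys1 = {_indel_key(c) for c in ind1}
    keys2 = {_indel_key(c) for c in ind2}
    for a in ind1:
        for b in ind2:
            if _indel_key(a) == _indel_key(b):
                continue
            if _indels_conflict(a, b):
                return MixtureRejection("indel_overlap")
    calls = []
    for c in ind1:
        shared = _indel_key(c) in keys2
        calls.append(
            VariantCall(
                c.kind,
                c.position,
                c.alleles,
                insert_index=c.insert_index,
                end_position=c.end_position,
                reference_retained=not shared,
            )
        )
    for c in ind2:
        if _indel_key(c) not in keys1:
            calls.append(
                VariantCall(
                    c.kind,
                    c.position,
                    c.alleles,
                    insert_index=c.insert_index,
                    end_position=c.end_position,
                    reference_retained=True,
                )
            )

    def sub_map(calls_):
        return {
            c.position: next(iter(c.alleles))
            for c in calls_
            if c.kind == SUBSTITUTION
        }

    def del_spans(ind):
        return [
            (c.position, c.end_position) for c in ind if c.kind == DELETION
        ]

    subs1, subs2 = sub_map(h1.calls), sub_map(h2.calls)
    spans1, spans2 = del_spans(ind1), del_spans(ind2)

    def deleted_in(p, spans):
        return any(s <= p <= e for s, e in spans)

    for p in sorted(set(subs1) | set(subs2)):
        ref_base = reference.base_at(p)
        alleles = set()
        if p in subs1:
            alleles.add(subs1[p])
        elif not deleted_in(p, spans1):
            alleles.add(ref_base)
        if p in subs2:
            alleles.add(subs2[p])
        elif not deleted_in(p, spans2):
            alleles.add(ref_base)
        if alleles and alleles != {ref_base}:
            calls.append(
                VariantCall(
                    SUBSTITUTION,
                    p,
                    frozenset(alleles),
                    reference_retained=ref_base in alleles,
                )
            )
    return MixtureProfile.from_calls(reference, calls)


# --------------------------------------------------------------------------
# Study runner
# --------------------------------------------------------------------------

@dataclass
class StudyResult:
    """Per-mixture statistics table plus rejection accounting."""

    table: pd.DataFrame
    n_rejected_identical: int
    n_rejected_indel: int
    attempts: int
    shortfall: int = 0


def _mixture_statistics(db, recs, h1, h2, profile, confidence=0.95):
    """All per-mixture quantities: explaining pairs, non-excluded count,
    RMNE and the u=1 GBC likelihood with the first contributor known."""
    vg = build_mixture_graph(profile)
    hits = consistent_records(vg, db)
    n = len(recs)
    n_consistent_records = len(hits)
    unique = sorted({r.sequence for r in hits})
    counts = {}
    for r in hits:
        counts[r.sequence] = counts.get(r.sequence, 0) + 1
    universe = graph_universe(vg)
    cache = PathCache(vg)
    covers = {s: cache.get(s).cover_sets() for s in unique}

    pair_verdict = {}
    n_pairs = 0
    for i, a in enumerate(unique):
        for b in unique[i:]:
            ok = pair_cover_explains(covers[a], covers[b], universe)
            pair_verdict[(a, b)] = ok
            if ok:
                n_pairs += 1
    gen_pair = tuple(sorted((h1.sequence, h2.sequence)))
    generating_ok = pair_verdict.get(gen_pair, False)

    p_rmne = n_consistent_records / n
    p_rmne_upper = clopper_pearson_upper(n_consistent_records, n, confidence)

    # GBC likelihood, u = 1, first contributor known
    known = h1.sequence
    numerator = 0
    for s in unique:
        key = tuple(sorted((known, s)))
        if pair_verdict.get(key, False):
            numerator += counts[s]
    gbc_prop = numerator / n
    gbc_upper = clopper_pearson_upper(numerator, n, confidence)
    return {
        "n_explaining_pairs": n_pairs,
        "n_consistent_haplotypes": len(unique),
        "n_consistent_records": n_consistent_records,
        "generating_pair_explains": generating_ok,
        "p_rmne": p_rmne,
        "p_rmne_upper": p_rmne_upper,
        "log10_p_rmne": float(np.log10(p_rmne)) if p_rmne > 0 else float("-inf"),
        "gbc_u1_proportion": gbc_prop,
        "gbc_u1_upper": gbc_upper,
        "log10_gbc_u1": float(np.log10(gbc_prop)) if gbc_prop > 0 else float("-inf"),
    }


def run_study(
    db: HaplotypeDatabase,
    n_mixtures: int,
    seed: int,
    population=None,
    confidence: float = 0.95,
    max_attempts: int = None,
) -> StudyResult:
    """Sample contributor pairs with replacement, build mixtures under the
    rejection rules, and tabulate the per-mixture match statistics.

    The first-sampled contributor is the known for the u=1 GBC likelihood.
    Fully reproducible under ``seed``; if the attempt bound is exhausted
    the table is returned short (with the shortfall recorded) unless no
    mixture at all could be formed, which raises.
    """
    recs = db.population_records(population)
    if len({r.sequence for r in recs}) < 2:
        raise SimulationError("database needs >= 2 distinct haplotypes")
    if max_attempts is None:
        max_attempts = 50 * n_mixtures
    rng = np.random.default_rng(seed)
    rows = []
    rej_same = rej_indel = attempts = 0
    while len(rows) < n_mixtures and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(0, len(recs), size=2)
        h1, h2 = recs[int(i)], recs[int(j)]
        merged = make_mixture(h1, h2, db.reference)
        if isinstance(merged, MixtureRejection):
            if merged.reason == "identical_haplotype":
                rej_same += 1
            else:
                rej_indel += 1
            continue
        stats = _mixture_statistics(db, recs, h1, h2, merged, confidence)
        row = {
            "mixture_index": len(rows),
            "id1": h1.sample_id,
            "id2": h2.sample_id,
            "profile": format_variant_string(merged),
        }
        row.update(stats)
        rows.append(row)
    if not rows:
        raise SimulationError(
            f"no mixture could be formed in {attempts} attempts "
            f"({rej_same} identical, {rej_indel} indel conflicts)"
        )
    table = pd.DataFrame(rows)
    return StudyResult(
        table=table,
        n_rejected_identical=rej_same,
        n_rejected_indel=rej_indel,
        attempts=attempts,
        shortfall=n_mixtures - len(rows),
    )
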