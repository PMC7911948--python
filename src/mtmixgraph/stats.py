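"""Match statistics over a single-source haplotype database.

Two statistics are computed against a mixture's variation graph:

* **RMNE** -- the random-man-not-excluded probability: the proportion of
  database haplotypes that trace some path in the graph, with an exact
  Clopper-Pearson 95% (two-sided) upper bound correcting for the finite
  database size.
* **Likelihoods** -- the naive likelihood of a set U of unknown
  contributors, ``|U|! * prod_j Pr(H_j)``, summed over every set that
  explains the mixture (the total likelihood), and the GBC likelihood:
  the proportion of u-combinations of database haplotypes (any known
  contributors appended) that explain the mixture, again with a
  Clopper-Pearson upper bound so that "no combination explains" yields a
  usable bound rather than zero.

Haplotype frequencies Pr(H_j) are relative frequencies (count / n) within
the selected population.  Unknown draws default to combinations without
replacement of database records, matching the C(n, u) denominator; a
``with_replacement`` switch covers the alternative reading.

A conservative variant-level prescreen (sequence-length feasibility plus
substitution checks away from indel-affected windows) cheaply discards
haplotypes that certainly cannot trace a path, before the exact graph DP
runs on the survivors; the prescreen never rejects a consistent haplotype.
"""
from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass

from scipy.stats import beta as _beta

from .errors import MtMixError
from .graph import VariantGraph
from .matching import PathCache, explains, is_consistent
from .variants import (
    DELETION,
    INSERTION,
    SUBSTITUTION,
    MaskIntervalSet,
    MixtureProfile,
    ReferenceSequence,
    decode_haplotype,
    format_variant_string,
    mask_profile,
    parse_variant_string,
)

#: padding (bases) around indel footprints inside which the variant-level
#: prescreen makes no claim; generous relative to realistic indel lengths
#: and homopolymer runs, so placement ambiguity cannot leak past it.
SCREEN_PAD = 30


def clopper_pearson_upper(successes: int, trials: int, confidence: float = 0.95) -> float:
    """Upper limit of the exact two-sided Clopper-Pearson binomial interval
    (the (1 - alpha/2) quantile of Beta(successes + 1, trials - successes)).

    For zero successes this equals ``1 - (alpha/2)**(1/trials)``; for all
    successes it is 1.
    """
    if trials < 1:
        raise ValueError("Clopper-Pearson bound undefined for zero trials")
    if not 0 <= successes <= trials:
        raise ValueError(f"need 0 <= successes <= trials, got {successes}/{trials}")
    if successes >= trials:
        return 1.0
    alpha = 1.0 - confidence
    return float(_beta.ppf(1.0 - alpha / 2.0, successes + 1, trials - successes))


# --------------------------------------------------------------------------
# Database
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HaplotypeRecord:
    """One single-source database entry: its variant calls and the decoded
    haplotype string."""

    sample_id: str
    population: str
    calls: tuple
    sequence: str


class HaplotypeDatabase:
    """Population-labeled single-source haplotypes against one reference."""

    def __init__(self, reference: ReferenceSequence, records):
        self.reference = reference
        self.records = list(records)
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids in database: {dup[:5]}")
        self._screen_info = {}

    def __len__(self):
        return len(self.records)

    @classmethod
    def build(cls, reference, entries) -> "HaplotypeDatabase":
        """Build from (sample_id, population, variant_string) triples."""
        records = []
        for sample_id, population, variants in entries:
            profile = parse_variant_string(variants, reference, single_source=True)
            records.append(
                HaplotypeRecord(
                    str(sample_id),
                    str(population),
                    profile.calls,
                    decode_haplotype(reference, profile.calls),
                )
            )
        return cls(reference, records)

    @classmethod
    def from_tsv(cls, path, reference) -> "HaplotypeDatabase":
        """Read a ``sample_id <TAB> population <TAB> variants`` TSV
        (``#`` lines are comments; the variants column may be empty for a
        pure-reference haplotype)."""
        entries = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(f"malformed database row: {line!r}")
                sample_id, population = fields[0], fields[1]
                variants = fields[2] if len(fields) > 2 else ""
                entries.append((sample_id, population, variants))
        return cls.build(reference, entries)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#sample_id\tpopulation\tvariants\n")
            for r in self.records:
                prof = MixtureProfile(self.reference, r.calls)
                fh.write(f"{r.sample_id}\t{r.population}\t{format_variant_string(prof)}\n")

    def populations(self):
        return sorted({r.population for r in self.records})

    def population_records(self, population=None):
        if population is None:
            return self.records
        recs = [r for r in self.records if r.population == population]
        if not recs:
            raise MtMixError(
                f"no records for population {population!r}; available: "
                f"{self.populations()}"
            )
        return recs

    def masked(self, mask: MaskIntervalSet) -> "HaplotypeDatabase":
        """A copy with masked variation removed and sequences re-decoded."""
        out = []
        for r in self.records:
            calls = mask_profile(r.calls, mask)
            out.append(
                HaplotypeRecord(
                    r.sample_id,
                    r.population,
                    calls,
                    decode_haplotype(self.reference, calls),
                )
            )
        return HaplotypeDatabase(self.reference, out)

    # -- prescreen support --------------------------------------------

    def _record_screen(self, record: HaplotypeRecord):
        info = self._screen_info.get(record.sample_id)
        if info is None:
            subs = {}
            zones = []
            for c in record.calls:
                if c.kind == SUBSTITUTION:
                    subs[c.position] = next(iter(c.alleles))
                else:
                    lo, hi = c.footprint()
                    zones.append((lo - SCREEN_PAD, hi + SCREEN_PAD))
            info = (subs, tuple(zones), len(record.sequence))
            self._screen_info[record.sample_id] = info
        return info


class MixtureScreen:
    """Per-mixture context for the conservative consistency prescreen."""

    def __init__(self, profile: MixtureProfile, pad: int = SCREEN_PAD):
        ref = profile.reference
        self.ref = ref
        self.allowed = {}
        self.fixed_subs = {}
        zones = []
        mandatory_delta = 0
        optional_deltas = []
        for c in profile.calls:
            if c.kind == SUBSTITUTION:
                self.allowed[c.position] = c.alleles
                if not c.reference_retained:
                    self.fixed_subs[c.position] = c.alleles
                continue
            lo, hi = c.footprint()
            zones.append((lo - pad, hi + pad))
            delta = (
                len(c.inserted)
                if c.kind == INSERTION
                else -(c.end_position - c.position + 1)
            )
            if c.reference_retained:
                optional_deltas.append(delta)
            else:
                mandatory_delta += delta
        self.zones = tuple(zones)
        if len(optional_deltas) <= 16:
            lengths = {ref.length + mandatory_delta}
            for d in optional_deltas:
                lengths |= {x + d for x in lengths}
            self.lengths = frozenset(lengths)
        else:
            self.lengths = None

    @staticmethod
    def _in_zones(p, zones):
        return any(lo <= p <= hi for lo, hi in zones)

    def maybe_consistent(self, rec_subs, rec_zones, rec_len) -> bool:
        """False only when the haplotype certainly cannot trace a path."""
        if self.lengths is not None and rec_len not in self.lengths:
            return False
        zones = self.zones + rec_zones
        bases = self.ref.bases
        for p, a in rec_subs.items():
            allowed = self.allowed.get(p)
            if allowed is None:
                if self._in_zones(p, zones):
                    continue
                return False
            if a not in allowed and not self._in_zones(p, zones):
                return False
        for p, alleles in self.fixed_subs.items():
            ra = rec_subs.get(p)
            if (ra is None or ra not in alleles) and not self._in_zones(p, zones):
                return False
        return True


def consistent_records(
    vg: VariantGraph, db: HaplotypeDatabase, population=None, prescreen: bool = True
):
    """Database records tracing some path in the graph (prescreen + exact
    DP; a per-sequence memo collapses duplicate haplotypes)."""
    recs = db.population_records(population)
    screen = None
    if prescreen and vg.profile is not None:
        screen = MixtureScreen(vg.profile)
    verdicts = {}
    out = []
    for r in recs:
        if screen is not None:
            subs, zones, rlen = db._record_screen(r)
            if not screen.maybe_consistent(subs, zones, rlen):
                continue
        v = verdicts.get(r.sequence)
        if v is None:
            v = is_consistent(vg, r.sequence)
            verdicts[r.sequence] = v
        if v:
            out.append(r)
    return out


# --------------------------------------------------------------------------
# RMNE
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RMNEResult:
    n_consistent: int
    n: int
    p_rmne: float
    p_rmne_upper: float
    population: str = None
    consistent_ids: tuple = ()


def rmne(
    vg: VariantGraph,
    db: HaplotypeDatabase,
    population=None,
    confidence: float = 0.95,
    mask: MaskIntervalSet = None,
    prescreen: bool = True,
) -> RMNEResult:
    """Random-man-not-excluded: the proportion of database haplotypes
    consistent with the mixture graph, with its Clopper-Pearson upper
    bound.  When a mask is given it is applied to the database calls (the
    caller builds the graph from the equally-masked mixture)."""
    if mask is not None:
        db = db.masked(mask)
    recs = db.population_records(population)
    hits = consistent_records(vg, db, population, prescreen=prescreen)
    n, k = len(recs), len(hits)
    return RMNEResult(
        n_consistent=k,
        n=n,
        p_rmne=k / n,
        p_rmne_upper=clopper_pearson_upper(k, n, confidence),
        population=population,
        consistent_ids=tuple(r.sample_id for r in hits),
    )


# --------------------------------------------------------------------------
# Likelihoods
# --------------------------------------------------------------------------

def naive_likelihood(frequencies) -> float:
    """``|U|! * prod_j Pr(H_j)`` for one set of unknown haplotypes."""
    freqs = list(frequencies)
    if not freqs:
        raise ValueError("need at least one frequency")
    if any(not 0.0 <= f <= 1.0 for f in freqs):
        raise ValueError("frequencies must lie in [0, 1]")
    return math.factorial(len(freqs)) * math.prod(freqs)


@dataclass(frozen=True)
class TotalLikelihoodResult:
    likelihood: float
    n_explaining_sets: int
    empty_t: bool
    approximate: bool = False


def total_likelihood(
    vg: VariantGraph,
    db: HaplotypeDatabase,
    u: int,
    knowns=(),
    population=None,
    prescreen: bool = True,
) -> TotalLikelihoodResult:
    """Sum the naive likelihood over every distinct u-set of database
    haplotypes that (with the knowns) explains the mixture.

    Candidate unknowns are drawn only from the non-excluded haplotypes
    (the consistency pre-filter, which provably cannot change the sum).
    An empty total is reported with the ``empty_t`` flag: no combination
    of database haplotypes explains the mixture.
    """
    if u < 1:
        raise ValueError("u must be >= 1")
    recs = db.population_records(population)
    n = len(recs)
    freq = Counter(r.sequence for r in recs)
    candidates = sorted({r.sequence for r in consistent_records(vg, db, population, prescreen)})
    knowns = list(knowns)
    cache = PathCache(vg)
    total = 0.0
    terms = 0
    approximate = False
    for combo in itertools.combinations(candidates, u):
        res = explains(vg, knowns + list(combo), path_cache=cache)
        approximate = approximate or res.approximate
        if res.explained:
            total += naive_likelihood(freq[s] / n for s in combo)
            terms += 1
    return TotalLikelihoodResult(total, terms, terms == 0, approximate)


@dataclass(frozen=True)
class GBCResult:
    n_explaining: int
    denominator: int
    proportion: float
    upper_bound: float
    u: int
    approximate: bool = False


def gbc_likelihood(
    vg: VariantGraph,
    db: HaplotypeDatabase,
    u: int,
    knowns=(),
    population=None,
    confidence: float = 0.95,
    with_replacement: bool = False,
    prescreen: bool = True,
) -> GBCResult:
    """GBC likelihood: the proportion of u-combinations of database
    haplotypes that (with the knowns appended) explain the mixture, out of
    C(n, u) possible combinations, with a Clopper-Pearson upper bound.

    ``with_replacement=True`` draws unknowns as multisets of records
    (denominator C(n + u - 1, u)) instead of the default without-
    replacement combinations.
    """
    if u < 1:
        raise ValueError("u must be >= 1")
    recs = db.population_records(population)
    n = len(recs)
    if n < u and not with_replacement:
        raise ValueError(f"u={u} exceeds database size n={n}")
    denominator = (
        math.comb(n + u - 1, u) if with_replacement else math.comb(n, u)
    )
    counts = Counter(r.sequence for r in consistent_records(vg, db, population, prescreen))
    unique = sorted(counts)
    knowns = list(knowns)
    cache = PathCache(vg)
    numerator = 0
    approximate = False
    for multiset in itertools.combinations_with_replacement(unique, u):
        mult = Counter(multiset)
        if not with_replacement and any(m > counts[s] for s, m in mult.items()):
            continue
        res = explains(vg, knowns + list(multiset), path_cache=cache)
        approximate = approximate or res.approximate
        if res.explained:
            if with_replacement:
                ways = math.prod(
                    math.comb(counts[s] + m - 1, m) for s, m in mult.items()
                )
            else:
                ways = math.prod(math.comb(counts[s], m) for s, m in mult.items())
            numerator += ways
    return GBCResult(
        n_explaining=numerator,
        denominator=denominator,
        proportion=numerator / denominator,
        upper_bound=clopper_pearson_upper(numerator, denominator, confidence),
        u=u,
        approximate=approximate,
    )
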