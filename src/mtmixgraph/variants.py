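"""EMPOP-style variant calls against a linear DNA reference.

A mitochondrial haplotype or mixture is described as a set of difference
operations (substitution, insertion, deletion) relative to a reference
sequence -- in practice the rCRS, but any linear A/C/G/T string works.
Substitutions may carry IUPAC ambiguity codes: in a mixture profile an
ambiguous call such as ``154W`` means both A and T were observed at
position 154.

Coordinates are 1-based throughout the API, matching the EMPOP/rCRS
convention.  BED mask files on disk are 0-based half-open and converted
on read.

Because a single difference string cannot say whether an indel is carried
by *all* contributors of a mixture or only some, indel tokens default to
"reference state also present" (some contributor lacks the indel); an
explicit ``!`` suffix (``4.1T!``, ``5 del!``) marks the indel as fixed in
every contributor.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable

from Bio import SeqIO

from .errors import (
    PositionBoundsError,
    ProfileConsistencyError,
    VariantParseError,
)

DNA_BASES = frozenset("ACGT")

#: IUPAC nucleotide ambiguity codes -> the base sets they denote.
IUPAC_TO_BASES = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

BASES_TO_IUPAC = {bases: code for code, bases in IUPAC_TO_BASES.items()}

SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"


def expand_iupac(code: str) -> frozenset:
    """Expand a single IUPAC letter into its base set (``W`` -> ``{A, T}``)."""
    try:
        return IUPAC_TO_BASES[code.upper()]
    except KeyError:
        raise VariantParseError(f"not an IUPAC nucleotide code: {code!r}") from None


def iupac_for(bases: Iterable[str]) -> str:
    """Inverse of :func:`expand_iupac`: the IUPAC letter for a base set."""
    key = frozenset(b.upper() for b in bases)
    try:
        return BASES_TO_IUPAC[key]
    except KeyError:
        raise VariantParseError(f"no IUPAC code for base set {sorted(key)}") from None


@dataclass(frozen=True)
class ReferenceSequence:
    """A named linear reference sequence over A/C/G/T, 1-based positions."""

    name: str
    bases: str

    def __post_init__(self):
        object.__setattr__(self, "bases", self.bases.upper())
        if not self.bases:
            raise ValueError("reference sequence must be non-empty")
        bad = set(self.bases) - DNA_BASES
        if bad:
            raise ValueError(f"reference contains non-ACGT characters: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.bases)

    def base_at(self, position: int) -> str:
        """Reference base at a 1-based position."""
        if not 1 <= position <= self.length:
            raise PositionBoundsError(
                f"position {position} outside reference 1..{self.length}"
            )
        return self.bases[position - 1]

    @classmethod
    def from_fasta(cls, path) -> "ReferenceSequence":
        """Read the first record of a FASTA file (extra records are ignored
        with a warning)."""
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise VariantParseError(f"no FASTA records in {path}")
        if len(records) > 1:
            warnings.warn(
                f"{path}: {len(records)} FASTA records found; using the first "
                f"({records[0].id}) as the reference",
                stacklevel=2,
            )
        return cls(name=records[0].id, bases=str(records[0].seq))

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.name}\n")
            for i in range(0, len(self.bases), 70):
                fh.write(self.bases[i : i + 70] + "\n")


_KIND_ORDER = {SUBSTITUTION: 0, INSERTION: 1, DELETION: 2}


@dataclass(frozen=True)
class VariantCall:
    """One difference operation against the reference.

    ``alleles`` holds the observed bases for a substitution (after IUPAC
    expansion) or the single inserted string for an insertion; it is empty
    for a deletion.  ``reference_retained`` records whether the reference
    state (the reference base, absence of the insertion, presence of the
    deleted bases) is *also* observed in the mixture.
    """

    kind: str
    position: int
    alleles: frozenset = frozenset()
    insert_index: int = None
    end_position: int = None
    reference_retained: bool = True

    def __post_init__(self):
        if self.kind not in _KIND_ORDER:
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.position < 1:
            raise PositionBoundsError(f"position {self.position} < 1")
        if self.kind == SUBSTITUTION:
            if not self.alleles or not self.alleles <= DNA_BASES:
                raise ValueError(
                    f"substitution alleles must be a non-empty subset of ACGT, "
                    f"got {sorted(self.alleles)}"
                )
        elif self.kind == INSERTION:
            if len(self.alleles) != 1:
                raise ValueError("insertion must carry exactly one inserted string")
            ins = next(iter(self.alleles))
            if not ins or not set(ins) <= DNA_BASES:
                raise ValueError(f"invalid inserted sequence {ins!r}")
            if self.insert_index is None:
                object.__setattr__(self, "insert_index", 1)
            if self.insert_index < 1:
                raise ValueError("insert_index must be >= 1")
        elif self.kind == DELETION:
            if self.end_position is None:
                object.__setattr__(self, "end_position", self.position)
            if self.end_position < self.position:
                raise ValueError(
                    f"deletion end {self.end_position} < start {self.position}"
                )

    # -- constructors -------------------------------------------------

    @classmethod
    def substitution(cls, position, alleles, reference=None, reference_retained=None):
        alleles = frozenset(a.upper() for a in alleles)
        if reference is not None:
            reference_retained = reference.base_at(position) in alleles
        elif reference_retained is None:
            raise ValueError("need reference or explicit reference_retained")
        return cls(SUBSTITUTION, position, alleles, reference_retained=reference_retained)

    @classmethod
    def insertion(cls, position, sequence, reference_retained=True, insert_index=1):
        return cls(
            INSERTION,
            position,
            frozenset({sequence.upper()}),
            insert_index=insert_index,
            reference_retained=reference_retained,
        )

    @classmethod
    def deletion(cls, position, end_position=None, reference_retained=True):
        return cls(
            DELETION,
            position,
            end_position=end_position if end_position is not None else position,
            reference_retained=reference_retained,
        )

    # -- accessors ----------------------------------------------------

    @property
    def inserted(self) -> str:
        if self.kind != INSERTION:
            raise ValueError("not an insertion")
        return next(iter(self.alleles))

    def footprint(self) -> tuple:
        """Inclusive reference-coordinate span touched by this call.

        An insertion's footprint is its anchor base (the insertion sits in
        the gap after it)."""
        if self.kind == DELETION:
            return (self.position, self.end_position)
        return (self.position, self.position)

    @property
    def sort_key(self):
        return (self.position, _KIND_ORDER[self.kind], self.insert_index or 0)


def _indel_gap_inside_deletion(ins: VariantCall, dele: VariantCall) -> bool:
    """True when an insertion's gap (p, p+1) lies strictly inside a deletion
    span [s, e] -- i.e. the inserted material would sit between deleted bases."""
    return dele.position <= ins.position <= dele.end_position - 1


def _normalize_calls(reference: ReferenceSequence, calls) -> tuple:
    """Validate and canonicalize a collection of calls into the profile form:
    one substitution per position, per-index insertions merged, adjacent
    deletions merged, partial indel overlaps rejected."""
    subs, inss, dels = {}, {}, []
    for c in calls:
        lo, hi = c.footprint()
        if not (1 <= lo and hi <= reference.length):
            raise PositionBoundsError(
                f"variant at {lo}..{hi} outside reference 1..{reference.length}"
            )
        if c.kind == SUBSTITUTION:
            subs.setdefault(c.position, []).append(c)
        elif c.kind == INSERTION:
            inss.setdefault(c.position, []).append(c)
        else:
            dels.append(c)

    out = []

    for pos, group in subs.items():
        alleles = frozenset().union(*(c.alleles for c in group))
        ref_base = reference.base_at(pos)
        if alleles == frozenset({ref_base}):
            continue  # no-op call: reference-only observation
        out.append(
            VariantCall(
                SUBSTITUTION, pos, alleles, reference_retained=ref_base in alleles
            )
        )

    merged_ins = []
    for pos, group in inss.items():
        group = sorted(group, key=lambda c: c.insert_index)
        idx = [c.insert_index for c in group]
        if len(set(idx)) != len(idx):
            strings = {(c.insert_index, c.inserted) for c in group}
            if len(strings) != len(set(i for i, _ in strings)):
                raise ProfileConsistencyError(
                    f"conflicting insertions at anchor {pos}: partially "
                    f"overlapping non-identical insertion calls"
                )
            # exact duplicates: dedupe
            seen = {}
            for c in group:
                seen[c.insert_index] = c
            group = [seen[i] for i in sorted(seen)]
            idx = [c.insert_index for c in group]
        if idx != list(range(idx[0], idx[0] + len(idx))) or idx[0] != 1:
            raise ProfileConsistencyError(
                f"insertion indices at anchor {pos} must be consecutive from .1, "
                f"got {idx}"
            )
        flags = {c.reference_retained for c in group}
        if len(flags) != 1:
            raise ProfileConsistencyError(
                f"insertions at anchor {pos} disagree on the fixed/! flag"
            )
        merged_ins.append(
            VariantCall.insertion(
                pos,
                "".join(c.inserted for c in group),
                reference_retained=flags.pop(),
            )
        )

    merged_dels = []
    for d in sorted(dels, key=lambda c: (c.position, c.end_position)):
        if merged_dels:
            last = merged_dels[-1]
            if d.position <= last.end_position + 1:  # identical, nested, overlapping or adjacent
                identical = (d.position, d.end_position) == (
                    last.position,
                    last.end_position,
                )
                adjacent = d.position == last.end_position + 1
                if d.reference_retained != last.reference_retained:
                    raise ProfileConsistencyError(
                        f"deletions {last.position}..{last.end_position} and "
                        f"{d.position}..{d.end_position} disagree on the fixed/! flag"
                    )
                if identical:
                    continue
                if not adjacent:
                    raise ProfileConsistencyError(
                        f"partially overlapping deletions "
                        f"{last.position}..{last.end_position} and "
                        f"{d.position}..{d.end_position}"
                    )
                merged_dels[-1] = VariantCall.deletion(
                    last.position, d.end_position, last.reference_retained
                )
                continue
        merged_dels.append(d)

    for ins in merged_ins:
        for d in merged_dels:
            if _indel_gap_inside_deletion(ins, d):
                raise ProfileConsistencyError(
                    f"insertion after {ins.position} lies inside deletion "
                    f"{d.position}..{d.end_position}"
                )

    out.extend(merged_ins)
    out.extend(merged_dels)
    return tuple(sorted(out, key=lambda c: c.sort_key))


@dataclass(frozen=True)
class MixtureProfile:
    """A normalized set of variant calls describing a mixture (or a
    single-source haplotype) against a reference: the recipe for the
    variation graph."""

    reference: ReferenceSequence
    calls: tuple

    @classmethod
    def from_calls(cls, reference, calls) -> "MixtureProfile":
        return cls(reference, _normalize_calls(reference, calls))

    @property
    def substitutions(self):
        return tuple(c for c in self.calls if c.kind == SUBSTITUTION)

    @property
    def insertions(self):
        return tuple(c for c in self.calls if c.kind == INSERTION)

    @property
    def deletions(self):
        return tuple(c for c in self.calls if c.kind == DELETION)

    @property
    def indels(self):
        return tuple(c for c in self.calls if c.kind != SUBSTITUTION)


# --------------------------------------------------------------------------
# Parsing / formatting
# --------------------------------------------------------------------------

_SUB_RE = re.compile(r"^(\d+)([A-Z])$")
_INS_RE = re.compile(r"^(\d+)\.(\d+)([A-Z]+)(!?)$")
_DEL_RE = re.compile(r"^(\d+)(?:DEL|-)(!?)$")


def _join_del_tokens(tokens):
    """Fuse EMPOP two-token deletions (``5 del`` -> ``5del``)."""
    out, i = [], 0
    while i < len(tokens):
        t = tokens[i]
        if (
            i + 1 < len(tokens)
            and t.isdigit()
            and tokens[i + 1].upper() in ("DEL", "DEL!")
        ):
            out.append(t + tokens[i + 1])
            i += 2
        else:
            out.append(t)
            i += 1
    return out


def parse_variant_string(
    text: str, reference: ReferenceSequence, single_source: bool = False
) -> MixtureProfile:
    """Parse a whitespace-separated EMPOP-style variant string into a
    normalized :class:`MixtureProfile`.

    Grammar per token: ``<pos><IUPAC>`` substitution, ``<pos>.<idx><bases>``
    insertion, ``<pos> del`` / ``<pos>del`` / ``<pos>-`` deletion.  Indels
    take an optional ``!`` suffix marking them fixed in all contributors.
    Anything after ``#`` is a comment.

    With ``single_source=True`` the string describes one haplotype:
    substitutions must be unambiguous (single-allele) and all indels are
    treated as fixed.
    """
    text = text.split("#", 1)[0]
    tokens = _join_del_tokens(text.split())
    calls = []
    for raw in tokens:
        tok = raw.upper()
        m = _SUB_RE.match(tok)
        if m:
            pos = int(m.group(1))
            try:
                alleles = expand_iupac(m.group(2))
            except VariantParseError:
                raise VariantParseError(
                    f"unrecognized variant token: {raw!r} "
                    f"({m.group(2)!r} is not an IUPAC code)"
                ) from None
            if pos > reference.length:
                raise PositionBoundsError(
                    f"token {raw!r}: position {pos} outside reference "
                    f"1..{reference.length}"
                )
            if single_source and len(alleles) != 1:
                raise ProfileConsistencyError(
                    f"token {raw!r}: ambiguity codes are not allowed in a "
                    f"single-source haplotype"
                )
            calls.append(VariantCall.substitution(pos, alleles, reference))
            continue
        m = _INS_RE.match(tok)
        if m:
            pos, idx, seq, bang = (
                int(m.group(1)),
                int(m.group(2)),
                m.group(3),
                m.group(4),
            )
            if not set(seq) <= DNA_BASES:
                raise VariantParseError(
                    f"token {raw!r}: inserted sequence must be over ACGT"
                )
            retained = not bang and not single_source
            calls.append(
                VariantCall.insertion(pos, seq, reference_retained=retained,
                                      insert_index=idx)
            )
            continue
        m = _DEL_RE.match(tok)
        if m:
            pos, bang = int(m.group(1)), m.group(2)
            retained = not bang and not single_source
            calls.append(VariantCall.deletion(pos, reference_retained=retained))
            continue
        raise VariantParseError(f"unrecognized variant token: {raw!r}")
    return MixtureProfile.from_calls(reference, calls)


def format_variant_string(profile: MixtureProfile) -> str:
    """Format a profile back into an EMPOP-style string.

    Substitutions collapse their allele sets to IUPAC codes; multi-base
    deletions are written per position (``5 del 6 del``); fixed indels get
    the ``!`` suffix.  ``parse_variant_string(format_variant_string(p)) == p``.
    """
    tokens = []
    for c in profile.calls:
        bang = "" if c.reference_retained else "!"
        if c.kind == SUBSTITUTION:
            tokens.append(f"{c.position}{iupac_for(c.alleles)}")
        elif c.kind == INSERTION:
            tokens.append(f"{c.position}.{c.insert_index}{c.inserted}{bang}")
        else:
            tokens.extend(
                f"{p} del{bang}" for p in range(c.position, c.end_position + 1)
            )
    return " ".join(tokens)


# --------------------------------------------------------------------------
# Decoding single-source call sets into sequences
# --------------------------------------------------------------------------

def decode_haplotype(reference: ReferenceSequence, calls) -> str:
    """Apply single-allele difference operations to the reference and return
    the resulting haplotype string.

    Equivalent encodings (e.g. a deletion placed anywhere in a homopolymer
    run) decode to identical strings.
    """
    if isinstance(calls, MixtureProfile):
        calls = calls.calls
    calls = _normalize_calls(reference, calls)
    subs, dels, ins_at = {}, set(), {}
    for c in calls:
        if c.kind == SUBSTITUTION:
            if len(c.alleles) != 1:
                raise ProfileConsistencyError(
                    f"cannot decode ambiguous substitution at {c.position}: "
                    f"{sorted(c.alleles)}"
                )
            subs[c.position] = next(iter(c.alleles))
        elif c.kind == DELETION:
            dels.update(range(c.position, c.end_position + 1))
        else:
            ins_at[c.position] = c.inserted
    conflict = set(subs) & dels
    if conflict:
        raise ProfileConsistencyError(
            f"substitution inside deleted span at position(s) {sorted(conflict)}"
        )
    parts = []
    for p in range(1, reference.length + 1):
        if p not in dels:
            parts.append(subs.get(p, reference.bases[p - 1]))
        if p in ins_at:
            parts.append(ins_at[p])
    return "".join(parts)


# --------------------------------------------------------------------------
# Masking
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MaskIntervalSet:
    """Normalized (sorted, merged) 1-based inclusive intervals on the
    reference; variation falling in them is removed before analysis."""

    intervals: tuple = ()

    @classmethod
    def from_pairs(cls, pairs) -> "MaskIntervalSet":
        pairs = sorted((int(s), int(e)) for s, e in pairs)
        merged = []
        for s, e in pairs:
            if e < s:
                raise ValueError(f"invalid interval ({s}, {e})")
            if merged and s <= merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return cls(tuple(merged))

    @classmethod
    def from_bed(cls, path) -> "MaskIntervalSet":
        """Read BED (0-based, half-open) intervals; the chromosome column is
        ignored (the reference is a single sequence)."""
        pairs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                start, end = int(fields[1]), int(fields[2])
                if end > start:
                    pairs.append((start + 1, end))
        return cls.from_pairs(pairs)

    def overlaps(self, start: int, end: int) -> bool:
        return any(s <= end and start <= e for s, e in self.intervals)

    def union(self, other: "MaskIntervalSet") -> "MaskIntervalSet":
        return MaskIntervalSet.from_pairs(list(self.intervals) + list(other.intervals))


def mask_profile(profile_or_calls, mask: MaskIntervalSet):
    """Drop every call whose reference footprint intersects a mask interval.

    Applied identically to mixture profiles and to database haplotype call
    sets; an empty mask is the identity.
    """
    if isinstance(profile_or_calls, MixtureProfile):
        kept = [
            c
            for c in profile_or_calls.calls
            if not mask.overlaps(*c.footprint())
        ]
        return MixtureProfile.from_calls(profile_or_calls.reference, kept)
    return tuple(c for c in profile_or_calls if not mask.overlaps(*c.footprint()))
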