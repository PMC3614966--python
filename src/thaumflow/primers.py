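"""In-silico evaluation of degenerate PCR primers against template sequences.

Degenerate primers such as the thaumarchaeal *accA* pair Cren529F/Cren981R
carry IUPAC ambiguity codes (W = A/T, Y = C/T, ...). Whether such a primer
"covers" a template is decided position by position: a template base matches
a primer position when every base the template character could be is inside
the degeneracy set of the primer character (subset rule). Scanning a primer
along a template at every ungapped offset and keeping the offset with the
fewest mismatches yields a *mismatch pattern* — one token per primer
position, ``=`` for a match, otherwise the template base observed opposite
that primer position, written in primer 5'→3' coordinates. Patterns are the
unit in which primer-coverage surveys tabulate their results, and per-clade
summaries of the mismatch counts (mean ± SE, fraction of perfect hits)
quantify how evenly a primer pair covers the phylogenetic groups it is
meant to amplify.

Reverse primers are evaluated as the reverse complement of the primer
scanned along the plus strand of the template; the resulting pattern is
reported back in primer coordinates, so token 1 always refers to the primer
5' end regardless of orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .errors import (
    InconsistentPatternError,
    InputSizeError,
    InvalidAlphabetError,
    PatternParseError,
)

__all__ = [
    "Orientation",
    "DegeneratePrimer",
    "TemplateRecord",
    "MismatchPattern",
    "BindingSite",
    "GroupMismatchSummary",
    "MATCH",
    "IUPAC_SETS",
    "expand_iupac",
    "position_matches",
    "reverse_complement",
    "align_primer",
    "render_pattern",
    "parse_pattern",
    "reconstruct_site",
    "summarize_groups",
    "CREN529F",
    "CREN981R",
]

MATCH = "="

#: Degeneracy sets of the IUPAC nucleotide alphabet.
IUPAC_SETS: Mapping[str, frozenset[str]] = {
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

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class Orientation(str, Enum):
    FORWARD = "forward"
    REVERSE = "reverse"


def expand_iupac(code: str, position: int | None = None, context: str = "") -> frozenset[str]:
    """Return the set of concrete bases an IUPAC character denotes.

    Raises :class:`InvalidAlphabetError` (naming the character and, when
    given, its position) for anything outside the 15-letter alphabet.
    """
    try:
        return IUPAC_SETS[code.upper()]
    except (KeyError, AttributeError):
        raise InvalidAlphabetError(code, position, context) from None


def position_matches(primer_char: str, template_char: str) -> bool:
    """Subset match rule for one primer/template position.

    True iff every base the (possibly ambiguous) template character could be
    lies within the primer character's degeneracy set. An ambiguous template
    base therefore only matches when the primer covers all its readings.
    """
    return expand_iupac(template_char) <= expand_iupac(primer_char)


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement (W↔W, Y↔R, K↔M, ...)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _validate_nt(seq: str, context: str) -> str:
    seq = seq.upper()
    for i, c in enumerate(seq):
        if c not in IUPAC_SETS:
            raise InvalidAlphabetError(c, i, context)
    return seq


@dataclass(frozen=True)
class DegeneratePrimer:
    """A degenerate oligo, written 5'→3' in primer orientation."""

    name: str
    sequence: str
    orientation: Orientation

    def __post_init__(self):
        if not self.sequence:
            raise InputSizeError(f"primer {self.name!r} has an empty sequence")
        object.__setattr__(self, "sequence", _validate_nt(self.sequence, f"primer {self.name!r}"))
        object.__setattr__(self, "orientation", Orientation(self.orientation))

    def __len__(self) -> int:
        return len(self.sequence)


#: The 'universal' thaumarchaeal accA primer pair evaluated throughout.
CREN529F = DegeneratePrimer("Cren529F", "GCWATGACWGAYTTTGTYRTAATG", Orientation.FORWARD)
CREN981R = DegeneratePrimer("Cren981R", "TGGWTKRYTTGCAAYTATWCC", Orientation.REVERSE)


@dataclass(frozen=True)
class TemplateRecord:
    """A template sequence with an optional phylogenetic group label."""

    id: str
    sequence: str
    clade: str = ""

    def __post_init__(self):
        object.__setattr__(self, "sequence", _validate_nt(self.sequence, f"template {self.id!r}"))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MismatchPattern:
    """Per-primer-position tokens: ``=`` for match, else the template base.

    ``count`` is always recomputed from the tokens, never stored.
    """

    primer_name: str
    tokens: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "tokens", tuple(t.upper() for t in self.tokens))
        for i, t in enumerate(self.tokens):
            if t != MATCH and t not in IUPAC_SETS:
                raise InvalidAlphabetError(t, i, f"pattern for {self.primer_name!r}")

    @property
    def count(self) -> int:
        """Number of mismatching positions."""
        return sum(t != MATCH for t in self.tokens)

    def mismatch_positions(self) -> tuple[int, ...]:
        """1-based primer positions that mismatch."""
        return tuple(i + 1 for i, t in enumerate(self.tokens) if t != MATCH)

    def three_prime_mismatches(self, window: int = 3) -> int:
        """Mismatches within the last ``window`` primer positions (3' end).

        Flagged in reports because 3'-terminal mismatches are the most
        detrimental to extension; they carry no extra weight in ``count``.
        """
        return sum(t != MATCH for t in self.tokens[-window:])

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class BindingSite:
    """Localized best hit of a primer on one template."""

    template_id: str
    start: int  # 0-based inclusive plus-strand offset
    strand: str  # "+" or "-"
    pattern: MismatchPattern


@dataclass(frozen=True)
class GroupMismatchSummary:
    """Per-(clade, primer) mismatch statistics across a reference set."""

    clade: str
    primer_name: str
    n: int
    mean: float
    sd: float
    se: float
    perfect_fraction: float


def align_primer(primer: DegeneratePrimer, template: TemplateRecord) -> BindingSite:
    """Ungapped scan of ``primer`` along ``template``; return the best site.

    Forward primers are scanned as given against the plus strand; reverse
    primers are scanned as their reverse complement against the plus strand.
    Every offset is evaluated with the subset match rule and the offset with
    the minimum mismatch count wins, ties broken by the smallest plus-strand
    offset. The returned pattern is in primer coordinates (token 1 = primer
    5' end); for reverse primers the mismatch tokens are therefore the
    complements of the plus-strand template bases.
    """
    tseq = template.sequence
    L = len(primer)
    if len(tseq) < L:
        raise InputSizeError(
            f"template {template.id!r} ({len(tseq)} nt) shorter than primer "
            f"{primer.name!r} ({L} nt)"
        )
    query = primer.sequence if primer.orientation is Orientation.FORWARD else reverse_complement(primer.sequence)
    qsets = [IUPAC_SETS[c] for c in query]

    best_start = 0
    best_flags: list[bool] | None = None
    best_count = L + 1
    for start in range(len(tseq) - L + 1):
        flags = [not (IUPAC_SETS[tseq[start + j]] <= qsets[j]) for j in range(L)]
        count = sum(flags)
        if count < best_count:
            best_count, best_start, best_flags = count, start, flags
    assert best_flags is not None

    if primer.orientation is Orientation.FORWARD:
        tokens = tuple(
            tseq[best_start + j] if best_flags[j] else MATCH for j in range(L)
        )
        strand = "+"
    else:
        # primer position i sits at window index L-1-i; report the template
        # base in primer sense, i.e. complemented.
        tokens = tuple(
            tseq[best_start + L - 1 - i].translate(_COMPLEMENT)
            if best_flags[L - 1 - i]
            else MATCH
            for i in range(L)
        )
        strand = "-"
    pattern = MismatchPattern(primer.name, tokens)
    return BindingSite(template.id, best_start, strand, pattern)


NO_MISMATCH = "No mismatch"


def render_pattern(pattern: MismatchPattern) -> str:
    """Render a pattern in survey-table notation.

    Space-separated tokens (``=`` for match, else the template base); a
    perfect site renders as ``"No mismatch"``.
    """
    if pattern.count == 0:
        return NO_MISMATCH
    return " ".join(pattern.tokens)


def parse_pattern(text: str, primer: DegeneratePrimer) -> MismatchPattern:
    """Inverse of :func:`render_pattern` for a given primer.

    ``"No mismatch"`` parses to the all-match pattern; otherwise the token
    count must equal the primer length.
    """
    stripped = text.strip()
    if stripped.lower() == NO_MISMATCH.lower():
        return MismatchPattern(primer.name, (MATCH,) * len(primer))
    tokens = stripped.split()
    if len(tokens) != len(primer):
        raise PatternParseError(
            f"pattern for {primer.name!r}: expected {len(primer)} tokens, got {len(tokens)}"
        )
    return MismatchPattern(primer.name, tuple(tokens))


def reconstruct_site(primer: DegeneratePrimer, pattern: MismatchPattern) -> str:
    """Build a concrete binding site (primer orientation) realizing a pattern.

    Match positions take the alphabetically first base of the primer's
    degeneracy set (a fixed rule keeps fixtures byte-stable; any compatible
    base would reproduce the count). Mismatch tokens are emitted verbatim
    after checking they are genuinely incompatible with the primer position.
    Guarantee: re-aligning the primer to the returned site reproduces
    ``pattern.count`` exactly.
    """
    if len(pattern) != len(primer):
        raise PatternParseError(
            f"pattern length {len(pattern)} != primer length {len(primer)}"
        )
    site = []
    for i, (pc, tok) in enumerate(zip(primer.sequence, pattern.tokens)):
        if tok == MATCH:
            site.append(min(IUPAC_SETS[pc]))
        else:
            if position_matches(pc, tok):
                raise InconsistentPatternError(
                    f"token {tok!r} at position {i + 1} is compatible with primer "
                    f"base {pc!r}; it would not be a mismatch"
                )
            site.append(tok)
    return "".join(site)


def summarize_groups(
    results: Iterable[tuple[str, str, int]]
) -> list[GroupMismatchSummary]:
    """Per-(clade, primer) mismatch statistics.

    ``results`` are (clade, primer_name, mismatch_count) triples. Reports n,
    mean, sample SD (n−1 denominator; 0 by convention for n=1), SE = SD/√n
    and the fraction of perfect (zero-mismatch) sequences. Groups appear in
    first-seen order; an empty input yields an empty list.
    """
    order: list[tuple[str, str]] = []
    groups: dict[tuple[str, str], list[int]] = {}
    for clade, primer_name, count in results:
        key = (clade, primer_name)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(int(count))

    out = []
    for clade, primer_name in order:
        counts = groups[(clade, primer_name)]
        n = len(counts)
        mean = sum(counts) / n
        if n > 1:
            sd = math.sqrt(sum((c - mean) ** 2 for c in counts) / (n - 1))
        else:
            sd = 0.0
        se = sd / math.sqrt(n)
        perfect = sum(c == 0 for c in counts) / n
        out.append(GroupMismatchSummary(clade, primer_name, n, mean, sd, se, perfect))
    return out
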