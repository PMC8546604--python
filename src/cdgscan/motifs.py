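"""Spacing-constrained activity motifs for c-di-GMP signaling domains.

Diguanylate cyclases (DGCs) carry a GGDEF domain whose catalytic
competence is predicted from a conserved active-site motif: essential
residues (D, N, D, R and the terminal A-site block [G/S/A]-G-[D/E]-E-F)
separated by spacers of fixed or bounded width.  Analogous motifs exist
for the EAL phosphodiesterase domain and the PilZ c-di-GMP receptor
domain.  A domain in which at least one essential residue deviates from
its allowed set is called *degenerate* and presumed enzymatically
inactive.  GGDEF domains may additionally carry an allosteric
inhibition site (I-site), an RxxD motif whose aspartate sits exactly
five residues upstream of the A-site block.

This module compiles motif specifications written in a small text
grammar, scans amino-acid sequences for full matches, finds the best
partial alignment (which essential residues fail), and turns the result
into an ACTIVE/DEGENERATE activity call.

Motif grammar
-------------
Whitespace-separated tokens, one per motif element:

* a single amino-acid letter, e.g. ``D`` — an essential residue;
* a bracketed alternative set, e.g. ``[GSA]`` — an essential residue
  drawn from several allowed letters;
* ``x(n)`` — an anonymous spacer of exactly *n* residues;
* ``x(n,m)`` — an anonymous spacer of *n* to *m* residues inclusive.

The first and last element must be residue classes: motifs are anchored
on residues, never on spacers.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

RESIDUE_CLASS = "RESIDUE_CLASS"
SPACER = "SPACER"

ACTIVE = "ACTIVE"
DEGENERATE = "DEGENERATE"
ABSENT = "ABSENT"

#: Residue reported for an essential position that falls beyond the end
#: of the scanned sequence (possible only for partial alignments on
#: sequences shorter than the motif).
OUT_OF_BOUNDS = "-"


class MotifParseError(ValueError):
    """Malformed motif specification; carries the offending token position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (token {position})")
        self.position = position


@dataclass(frozen=True)
class MotifElement:
    """One element of a motif: an essential residue class or a spacer."""

    kind: str
    allowed: frozenset[str] = frozenset()
    span_min: int = 0
    span_max: int = 0

    def __post_init__(self):
        if self.kind == RESIDUE_CLASS:
            if not self.allowed:
                raise ValueError("residue class with empty allowed set")
            bad = set(self.allowed) - AMINO_ACIDS
            if bad:
                raise ValueError(f"non-standard residue letters {sorted(bad)}")
        elif self.kind == SPACER:
            if not (0 <= self.span_min <= self.span_max):
                raise ValueError(
                    f"invalid spacer range ({self.span_min}, {self.span_max})"
                )
        else:
            raise ValueError(f"unknown element kind {self.kind!r}")

    @classmethod
    def residue_class(cls, letters: str) -> "MotifElement":
        return cls(kind=RESIDUE_CLASS, allowed=frozenset(letters))

    @classmethod
    def spacer(cls, span_min: int, span_max: int | None = None) -> "MotifElement":
        if span_max is None:
            span_max = span_min
        return cls(kind=SPACER, span_min=span_min, span_max=span_max)

    @property
    def is_ranged(self) -> bool:
        return self.kind == SPACER and self.span_min != self.span_max

    @property
    def min_width(self) -> int:
        return 1 if self.kind == RESIDUE_CLASS else self.span_min

    @property
    def max_width(self) -> int:
        return 1 if self.kind == RESIDUE_CLASS else self.span_max


@dataclass(frozen=True)
class MotifPattern:
    """An ordered grammar of essential residue classes and spacers."""

    name: str
    elements: tuple[MotifElement, ...]

    def __post_init__(self):
        if not self.elements:
            raise ValueError("empty pattern")
        if self.elements[0].kind != RESIDUE_CLASS or self.elements[-1].kind != RESIDUE_CLASS:
            raise ValueError("pattern must start and end on a residue class")

    @property
    def essential_indices(self) -> tuple[int, ...]:
        return tuple(
            i for i, e in enumerate(self.elements) if e.kind == RESIDUE_CLASS
        )

    @property
    def n_essentials(self) -> int:
        return len(self.essential_indices)

    @property
    def min_width(self) -> int:
        return sum(e.min_width for e in self.elements)

    @property
    def max_width(self) -> int:
        return sum(e.max_width for e in self.elements)

    @property
    def ranged_spacers(self) -> tuple[int, ...]:
        """Element indices of spacers whose width is not fixed."""
        return tuple(i for i, e in enumerate(self.elements) if e.is_ranged)


@dataclass(frozen=True)
class MotifMatch:
    """A full motif occurrence on a scanned sequence (1-based inclusive)."""

    start: int
    end: int
    residue_positions: tuple[int, ...]
    spacer_widths: tuple[int, ...]


@dataclass(frozen=True)
class PartialMatch:
    """Best-scoring alignment of a pattern, possibly with essential mismatches.

    ``mismatched_essentials`` pairs the 0-based index of the failing
    essential (its rank among the pattern's residue classes) with the
    observed residue at that alignment position.
    """

    start: int
    end: int
    residue_positions: tuple[int, ...]
    spacer_widths: tuple[int, ...]
    matched_count: int
    mismatched_essentials: tuple[tuple[int, str], ...]


@dataclass(frozen=True)
class ActivityCall:
    """ACTIVE/DEGENERATE classification of one domain sequence."""

    status: str
    mismatched_essentials: tuple[tuple[int, str], ...] = ()
    i_site_present: bool = False
    best_match: MotifMatch | PartialMatch | None = None

    def __post_init__(self):
        if (self.status == ACTIVE) != (not self.mismatched_essentials):
            raise ValueError("ACTIVE iff no mismatched essentials")


_TOKEN_RE = re.compile(
    r"^(?:(?P<single>[A-Z])|\[(?P<multi>[A-Z]+)\]"
    r"|x\((?P<lo>\d+)(?:,(?P<hi>\d+))?\))$"
)


def compile_pattern(spec: str, name: str = "pattern") -> MotifPattern:
    """Compile a motif-spec string into a :class:`MotifPattern`.

    >>> p = compile_pattern("D x(7) N x(8) D x(21) R x(1) [GSA] G [DE] E F")
    >>> len(p.elements), p.n_essentials
    (13, 9)
    """
    tokens = spec.split()
    if not tokens:
        raise MotifParseError("empty pattern specification", 0)
    elements: list[MotifElement] = []
    for pos, tok in enumerate(tokens, start=1):
        m = _TOKEN_RE.match(tok)
        if m is None:
            raise MotifParseError(f"unrecognized token {tok!r}", pos)
        try:
            if m.group("single"):
                elements.append(MotifElement.residue_class(m.group("single")))
            elif m.group("multi"):
                elements.append(MotifElement.residue_class(m.group("multi")))
            else:
                lo = int(m.group("lo"))
                hi = int(m.group("hi")) if m.group("hi") else lo
                elements.append(MotifElement.spacer(lo, hi))
        except ValueError as exc:
            raise MotifParseError(str(exc), pos) from exc
    try:
        return MotifPattern(name=name, elements=tuple(elements))
    except ValueError as exc:
        raise MotifParseError(str(exc), len(tokens)) from exc


def serialize_pattern(pattern: MotifPattern) -> str:
    """Render a pattern back into the motif grammar (inverse of compile)."""
    parts = []
    for e in pattern.elements:
        if e.kind == RESIDUE_CLASS:
            letters = "".join(sorted(e.allowed))
            parts.append(letters if len(letters) == 1 else f"[{letters}]")
        elif e.span_min == e.span_max:
            parts.append(f"x({e.span_min})")
        else:
            parts.append(f"x({e.span_min},{e.span_max})")
    return " ".join(parts)


def _width_combinations(pattern: MotifPattern):
    """Yield (ranged_widths, element_widths) for every admissible choice."""
    ranged = pattern.ranged_spacers
    ranges = [
        range(pattern.elements[i].span_min, pattern.elements[i].span_max + 1)
        for i in ranged
    ]
    base = [e.min_width for e in pattern.elements]
    for combo in itertools.product(*ranges):
        widths = list(base)
        for idx, w in zip(ranged, combo):
            widths[idx] = w
        yield combo, widths


def _check_inputs(sequence: str, pattern: MotifPattern) -> None:
    if not sequence:
        raise ValueError("empty sequence")
    if not pattern.elements:
        raise ValueError("empty pattern")


def scan(sequence: str, pattern: MotifPattern) -> list[MotifMatch]:
    """Find every full occurrence of *pattern* in *sequence*.

    Enumerates all start positions and all admissible ranged-spacer
    width combinations; overlapping matches are all reported, sorted by
    ascending (start, end).  The ambiguity letter ``X`` never satisfies
    a residue class.
    """
    _check_inputs(sequence, pattern)
    n = len(sequence)
    matches = []
    combos = list(_width_combinations(pattern))
    for start0 in range(n):
        for combo, widths in combos:
            total = sum(widths)
            if start0 + total > n:
                continue
            pos = start0
            residue_positions = []
            ok = True
            for elem, w in zip(pattern.elements, widths):
                if elem.kind == RESIDUE_CLASS:
                    if sequence[pos] not in elem.allowed:
                        ok = False
                        break
                    residue_positions.append(pos + 1)
                pos += w
            if ok:
                matches.append(
                    MotifMatch(
                        start=start0 + 1,
                        end=start0 + total,
                        residue_positions=tuple(residue_positions),
                        spacer_widths=combo,
                    )
                )
    matches.sort(key=lambda m: (m.start, m.end, m.spacer_widths))
    return matches


def best_partial_match(sequence: str, pattern: MotifPattern) -> PartialMatch:
    """Alignment maximizing the number of essential residues that match.

    All start positions and ranged-spacer width choices are considered;
    ties are broken by earlier start, then smaller total spacer width.
    Essential positions falling beyond the end of the sequence count as
    mismatches (observed residue ``-``), so short sequences still yield
    a well-defined best alignment.
    """
    _check_inputs(sequence, pattern)
    n = len(sequence)
    best: PartialMatch | None = None
    best_spacer_total = 0
    for start0 in range(n):
        for combo, widths in _width_combinations(pattern):
            pos = start0
            residue_positions = []
            mismatches = []
            matched = 0
            ess_rank = 0
            for elem, w in zip(pattern.elements, widths):
                if elem.kind == RESIDUE_CLASS:
                    residue_positions.append(pos + 1)
                    if pos < n and sequence[pos] in elem.allowed:
                        matched += 1
                    else:
                        observed = sequence[pos] if pos < n else OUT_OF_BOUNDS
                        mismatches.append((ess_rank, observed))
                    ess_rank += 1
                pos += w
            spacer_total = sum(
                w for elem, w in zip(pattern.elements, widths)
                if elem.kind == SPACER
            )
            cand = PartialMatch(
                start=start0 + 1,
                end=start0 + sum(widths),
                residue_positions=tuple(residue_positions),
                spacer_widths=combo,
                matched_count=matched,
                mismatched_essentials=tuple(mismatches),
            )
            if (
                best is None
                or cand.matched_count > best.matched_count
                or (
                    cand.matched_count == best.matched_count
                    and (cand.start, spacer_total) < (best.start, best_spacer_total)
                )
            ):
                best = cand
                best_spacer_total = spacer_total
    assert best is not None
    return best


# --- activity classification -------------------------------------------------

#: Number of trailing essentials forming the GGDEF A-site block
#: ([G/S/A], G, [D/E], E, F).
_A_SITE_ESSENTIALS = 5

#: The I-site aspartate (the D of RxxD) sits exactly this many residues
#: upstream of the first residue of the A-site block.
I_SITE_OFFSET = 5


def _has_i_site(sequence: str, a_site_start: int) -> bool:
    """RxxD with its terminal D exactly I_SITE_OFFSET before the A-site."""
    d_pos = a_site_start - I_SITE_OFFSET
    r_pos = d_pos - 3
    if r_pos < 1 or d_pos > len(sequence):
        return False
    return sequence[r_pos - 1] == "R" and sequence[d_pos - 1] == "D"


def _classify(
    sequence: str,
    pattern: MotifPattern,
    check_i_site: bool = False,
) -> ActivityCall:
    if len(sequence) < 10:
        raise ValueError(
            f"sequence of {len(sequence)} aa is too short to classify (< 10)"
        )
    matches = scan(sequence, pattern) if len(sequence) >= pattern.min_width else []
    if matches:
        i_site = False
        if check_i_site:
            i_site = any(
                _has_i_site(sequence, m.residue_positions[-_A_SITE_ESSENTIALS])
                for m in matches
            )
        return ActivityCall(
            status=ACTIVE,
            mismatched_essentials=(),
            i_site_present=i_site,
            best_match=matches[0],
        )
    partial = best_partial_match(sequence, pattern)
    i_site = False
    if check_i_site and len(partial.residue_positions) >= _A_SITE_ESSENTIALS:
        i_site = _has_i_site(
            sequence, partial.residue_positions[-_A_SITE_ESSENTIALS]
        )
    return ActivityCall(
        status=DEGENERATE,
        mismatched_essentials=partial.mismatched_essentials,
        i_site_present=i_site,
        best_match=partial,
    )


def classify_ggdef(domain_sequence: str, pattern: MotifPattern | None = None) -> ActivityCall:
    """Call a GGDEF domain ACTIVE or DEGENERATE; also reports the I-site.

    ACTIVE means the full DGC active-site motif occurs somewhere in the
    domain.  The I-site flag is true when an RxxD motif places its D
    exactly five residues upstream of the A-site block of a motif match.
    """
    return _classify(domain_sequence, pattern or GGDEF_PATTERN, check_i_site=True)


def classify_eal(domain_sequence: str, pattern: MotifPattern | None = None) -> ActivityCall:
    """Call an EAL domain ACTIVE (putative PDE) or DEGENERATE."""
    return _classify(domain_sequence, pattern or EAL_PATTERN)


def classify_pilz(domain_sequence: str, pattern: MotifPattern | None = None) -> ActivityCall:
    """Call a PilZ domain ACTIVE (c-di-GMP receptor motif present) or DEGENERATE."""
    return _classify(domain_sequence, pattern or PILZ_PATTERN)


# --- motif files -------------------------------------------------------------

def load_motifs(path: str | Path) -> dict[str, MotifPattern]:
    """Load a motif file: one ``name<TAB>spec`` per line, '#' comments."""
    motifs: dict[str, MotifPattern] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            name, spec = line.split("\t", 1)
        except ValueError:
            raise ValueError(
                f"{path}:{lineno}: expected 'name<TAB>spec', got {line!r}"
            ) from None
        motifs[name] = compile_pattern(spec, name=name)
    return motifs


def _load_default_motifs() -> dict[str, MotifPattern]:
    ref = resources.files("cdgscan") / "data" / "default_motifs.tsv"
    with resources.as_file(ref) as path:
        return load_motifs(path)


DEFAULT_MOTIFS = _load_default_motifs()
GGDEF_PATTERN = DEFAULT_MOTIFS["GGDEF"]
EAL_PATTERN = DEFAULT_MOTIFS["EAL"]
PILZ_PATTERN = DEFAULT_MOTIFS["PILZ"]
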