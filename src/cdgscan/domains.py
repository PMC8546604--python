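"""Locate GGDEF, EAL and PilZ domain instances on proteins.

Domain instances come either from an external hit table (hmmscan
domtblout, or a generic 5-column TSV) or from a built-in heuristic that
slides the activity motif over the protein and reports the span of the
best partial alignment.  Overlapping same-type hits are resolved to the
maximum-score non-overlapping selection; cross-type overlaps (e.g. a
GGDEF-EAL tandem) are always kept.

Coordinates are 1-based inclusive on the protein, matching hmmscan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

from cdgscan.motifs import MotifPattern, best_partial_match

GGDEF = "GGDEF"
EAL = "EAL"
PILZ = "PILZ"

TABLE = "TABLE"
HEURISTIC = "HEURISTIC"

#: Canonical-type aliases; user tables extend/override these.
#: CDD and Pfam call the same domains by different names.
DEFAULT_ALIASES = {
    "GGDEF": GGDEF,
    "PF00990": GGDEF,
    "EAL": EAL,
    "PF00563": EAL,
    "PILZ": PILZ,
    "PF07238": PILZ,
}

DEFAULT_EVALUE_THRESHOLD = 1e-5
DEFAULT_MIN_MATCH_FRACTION = 0.6
DEFAULT_FLANK = 15


@dataclass(frozen=True)
class DomainHit:
    """A located domain instance on a protein."""

    protein_id: str
    domain_type: str  # GGDEF / EAL / PILZ, or any other name verbatim
    start: int
    end: int
    score: float  # E-value (TABLE) or match fraction (HEURISTIC)
    source: str = TABLE

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid coordinates {self.start}-{self.end}")
        if self.source == TABLE and self.score < 0:
            raise ValueError("E-value must be >= 0")
        if self.source == HEURISTIC and not (0 <= self.score <= 1):
            raise ValueError("match fraction must be in [0, 1]")

    @property
    def goodness(self) -> float:
        """Larger is better, regardless of score convention."""
        if self.source == HEURISTIC:
            return self.score
        return -math.log10(max(self.score, 1e-300))

    def overlaps(self, other: "DomainHit") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class DomainArchitecture:
    """Ordered domain content of one protein (e.g. ``HAMP-PAS-GGDEF``)."""

    protein_id: str
    ordered_domains: tuple[str, ...]

    @property
    def architecture_string(self) -> str:
        return "-".join(self.ordered_domains)


def load_alias_table(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (name, canonical type) extending the defaults."""
    aliases = dict(DEFAULT_ALIASES)
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
        aliases[fields[0].upper()] = fields[1].upper()
    return aliases


def _canonical_type(name: str, aliases: dict[str, str]) -> str:
    return aliases.get(name.upper(), name)


def _parse_generic_tsv(lines, aliases):
    hits = []
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split("\t")
        if len(fields) < 5:
            raise ValueError(
                f"line {lineno}: expected 5 columns "
                "(protein_id, domain_name, start, end, evalue)"
            )
        try:
            hits.append(
                DomainHit(
                    protein_id=fields[0],
                    domain_type=_canonical_type(fields[1], aliases),
                    start=int(fields[2]),
                    end=int(fields[3]),
                    score=float(fields[4]),
                    source=TABLE,
                )
            )
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
    return hits


def _parse_domtblout(lines, aliases):
    # hmmscan --domtblout: 22 fixed whitespace-delimited fields + free-text
    # description.  Per-domain independent E-value is field 13 (1-based);
    # alignment coordinates on the query protein are fields 18-19.
    hits = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split(None, 22)
        if len(fields) < 22:
            raise ValueError(
                f"line {lineno}: expected >= 22 whitespace-delimited fields"
            )
        try:
            hits.append(
                DomainHit(
                    protein_id=fields[3],
                    domain_type=_canonical_type(fields[0], aliases),
                    start=int(fields[17]),
                    end=int(fields[18]),
                    score=float(fields[12]),
                    source=TABLE,
                )
            )
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
    return hits


def read_domain_table(
    path: str | Path,
    evalue_threshold: float = DEFAULT_EVALUE_THRESHOLD,
    aliases: dict[str, str] | None = None,
    protein_lengths: dict[str, int] | None = None,
) -> list[DomainHit]:
    """Read domain hits from a domtblout or generic TSV file.

    Hits with E-value above *evalue_threshold* are dropped; domain names
    are mapped to canonical types through *aliases* (unknown names are
    kept verbatim).  If *protein_lengths* is given, hits whose
    coordinates exceed the protein length raise an error.
    """
    if evalue_threshold <= 0:
        raise ValueError("evalue_threshold must be > 0")
    aliases = aliases if aliases is not None else DEFAULT_ALIASES
    lines = Path(path).read_text().splitlines()
    # A generic TSV has tab-separated data rows; domtblout is space-aligned.
    data = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    if data and "\t" in data[0]:
        hits = _parse_generic_tsv(lines, aliases)
    else:
        hits = _parse_domtblout(lines, aliases)
    hits = [h for h in hits if h.score <= evalue_threshold]
    if protein_lengths is not None:
        for h in hits:
            plen = protein_lengths.get(h.protein_id)
            if plen is not None and h.end > plen:
                raise ValueError(
                    f"hit {h.protein_id}:{h.start}-{h.end} exceeds protein "
                    f"length {plen}"
                )
    return hits


def write_domain_table(hits: list[DomainHit], path: str | Path) -> None:
    """Write hits in the generic 5-column TSV format."""
    with open(path, "w") as fh:
        fh.write("# protein_id\tdomain_name\tstart\tend\tevalue\n")
        for h in hits:
            fh.write(
                f"{h.protein_id}\t{h.domain_type}\t{h.start}\t{h.end}\t{h.score:g}\n"
            )


def _best_subset(hits: list[DomainHit]) -> list[DomainHit]:
    """Max-total-goodness pairwise-non-overlapping subset of same-type hits.

    Ties broken toward more hits, then lexicographically earliest starts.
    Include/exclude recursion over hits sorted by start; hit lists per
    protein are small, so exact search is cheap.
    """
    hits = sorted(hits, key=lambda h: (h.start, h.end))

    def key(subset):
        return (
            sum(h.goodness for h in subset),
            len(subset),
            tuple(-h.start for h in subset),
        )

    best: list[DomainHit] = []

    def rec(i, chosen):
        nonlocal best
        if i == len(hits):
            if key(chosen) > key(best):
                best = list(chosen)
            return
        h = hits[i]
        if all(not h.overlaps(c) for c in chosen):
            chosen.append(h)
            rec(i + 1, chosen)
            chosen.pop()
        rec(i + 1, chosen)

    rec(0, [])
    return best


def resolve_overlaps(hits: list[DomainHit]) -> list[DomainHit]:
    """Drop inferior overlapping same-type hits; keep cross-type overlaps.

    Within each domain type, retains the pairwise-non-overlapping subset
    of maximum total score (lowest E-values / highest match fractions
    win).  Never increases the hit count and never drops a hit that
    overlaps nothing of its own type.
    """
    if not hits:
        return []
    protein_ids = {h.protein_id for h in hits}
    if len(protein_ids) != 1:
        raise ValueError("resolve_overlaps expects hits from a single protein")
    by_type: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_type.setdefault(h.domain_type, []).append(h)
    kept: list[DomainHit] = []
    for same_type in by_type.values():
        kept.extend(_best_subset(same_type))
    kept.sort(key=lambda h: (h.start, h.end, h.domain_type))
    return kept


def heuristic_locate(
    protein_sequence: str,
    pattern: MotifPattern,
    min_match_fraction: float = DEFAULT_MIN_MATCH_FRACTION,
    protein_id: str = "protein",
    flank: int = DEFAULT_FLANK,
) -> list[DomainHit]:
    """Motif-based fallback domain finder (no external hit table needed).

    Runs the best partial motif alignment over the protein and emits one
    hit covering the alignment span, padded by *flank* residues and
    clipped to the sequence, when the fraction of matching essential
    residues reaches *min_match_fraction*.  The hit score is that
    fraction, so downstream classification can still call the located
    domain DEGENERATE.
    """
    if not (0 < min_match_fraction <= 1):
        raise ValueError("min_match_fraction must be in (0, 1]")
    partial = best_partial_match(protein_sequence, pattern)
    fraction = partial.matched_count / pattern.n_essentials
    if fraction < min_match_fraction:
        return []
    start = max(1, partial.start - flank)
    end = min(len(protein_sequence), partial.end + flank)
    return [
        DomainHit(
            protein_id=protein_id,
            domain_type=pattern.name,
            start=start,
            end=end,
            score=fraction,
            source=HEURISTIC,
        )
    ]


def architecture(protein_id: str, hits: list[DomainHit]) -> DomainArchitecture:
    """Hyphen-joined domain names by ascending start position."""
    ordered = tuple(
        h.domain_type for h in sorted(hits, key=lambda h: (h.start, h.end))
    )
    return DomainArchitecture(protein_id=protein_id, ordered_domains=ordered)
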