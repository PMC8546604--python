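import itertools
import re

import numpy as np
import pytest

from cdgscan.motifs import RESIDUE_CLASS, MotifPattern


def oracle_scan(sequence: str, pattern: MotifPattern):
    """Brute-force motif scan used as an independent oracle.

    For every admissible combination of ranged-spacer widths it builds a
    plain regular expression and collects all (overlapping) matches via
    a lookahead, independently of the package's matching code.

    Returns a sorted list of (start, end, spacer_widths) 1-based tuples.
    """
    ranged = [
        (i, e) for i, e in enumerate(pattern.elements) if e.is_ranged
    ]
    found = []
    for combo in itertools.product(
        *[range(e.span_min, e.span_max + 1) for _, e in ranged]
    ):
        widths = dict(zip((i for i, _ in ranged), combo))
        parts = []
        for i, e in enumerate(pattern.elements):
            if e.kind == RESIDUE_CLASS:
                parts.append("[" + "".join(sorted(e.allowed)) + "]")
            else:
                w = widths.get(i, e.span_min)
                parts.append(f".{{{w}}}")
        body = "".join(parts)
        total = sum(
            1 if e.kind == RESIDUE_CLASS else widths.get(i, e.span_min)
            for i, e in enumerate(pattern.elements)
        )
        for m in re.finditer(f"(?=({body}))", sequence):
            found.append((m.start() + 1, m.start() + total, combo))
    return sorted(found)


def oracle_best_partial(sequence: str, pattern: MotifPattern):
    """Exhaustive (start x widths) enumeration of essential-match counts.

    Returns (matched_count, start, widths, mismatches) of the best
    alignment under the documented tie-break (earlier start, then
    smaller total spacer width); essentials beyond the sequence end are
    mismatches observed as '-'.
    """
    n = len(sequence)
    ranged = [(i, e) for i, e in enumerate(pattern.elements) if e.is_ranged]
    best = None
    for start0 in range(n):
        for combo in itertools.product(
            *[range(e.span_min, e.span_max + 1) for _, e in ranged]
        ):
            widths = dict(zip((i for i, _ in ranged), combo))
            pos = start0
            matched, mismatches, spacer_total = 0, [], 0
            rank = 0
            for i, e in enumerate(pattern.elements):
                if e.kind == RESIDUE_CLASS:
                    if pos < n and sequence[pos] in e.allowed:
                        matched += 1
                    else:
                        mismatches.append(
                            (rank, sequence[pos] if pos < n else "-")
                        )
                    rank += 1
                    pos += 1
                else:
                    w = widths.get(i, e.span_min)
                    spacer_total += w
                    pos += w
            key = (-matched, start0, spacer_total)
            if best is None or key < best[0]:
                best = (key, matched, start0 + 1, combo, tuple(mismatches))
    _, matched, start, combo, mismatches = best
    return matched, start, combo, mismatches


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_protein(rng, length):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
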