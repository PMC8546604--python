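"""Upstream intergenic regions, %GC, and baseline comparisons.

MucR-family repressors prefer low-GC target sequences, so the %GC of
the intergenic region upstream of a gene's translation start — relative
to the genome or replicon average — is a useful proxy for direct
regulation.  Extraction walks 5'-ward from the gene's start on its own
strand until it meets the nearest boundary of any other annotated gene
on the same replicon (either strand); circular replicons wrap across
the origin.  Genes whose upstream neighbor abuts or overlaps them have
a zero-length region and are excluded from group statistics.

The group of per-gene %GC values is compared with the fixed baseline by
a one-sample two-sided t test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from cdgscan.census import CIRCULAR, GeneRecord, GenomeAnnotation


@dataclass(frozen=True)
class IntergenicRegion:
    """Intergenic stretch abutting a gene's 5' translation start.

    Coordinates are 1-based inclusive on the forward strand; an
    origin-wrapping region on a circular replicon has ``end`` < ``start``
    and is stored as the concatenation tail + head.
    """

    gene_id: str
    replicon_id: str
    start: int
    end: int
    sequence: str
    gene_strand: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc_percent(self) -> float:
        return gc_content(self.sequence)


@dataclass(frozen=True)
class GcComparison:
    """One-sample t test of a %GC group against a fixed baseline."""

    group_label: str
    values: tuple[float, ...]
    baseline_label: str
    baseline_value: float
    t_statistic: float  # NaN when not available
    p_value: float  # NaN when not available

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def group_mean(self) -> float:
        return float(np.mean(self.values)) if self.values else float("nan")


def gc_content(sequence: str) -> float:
    """%GC of a nucleotide sequence; N bases are excluded entirely.

    Returns NaN (not available) on an empty or all-N sequence.
    """
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    effective = len(seq) - seq.count("N")
    if effective == 0:
        return float("nan")
    return 100.0 * gc / effective


def baseline_gc(annotation: GenomeAnnotation, scope: str = "genome") -> float:
    """%GC over the full nucleotide sequence of the genome or one replicon.

    *scope* is ``"genome"`` or ``"replicon:<id>"`` (a bare replicon id
    also works).  The average is sequence-wide, not gene-averaged.
    """
    if scope == "genome":
        return gc_content("".join(r.sequence for r in annotation.replicons))
    rid = scope.removeprefix("replicon:")
    return gc_content(annotation.replicon(rid).sequence)


def _occupied(annotation: GenomeAnnotation, replicon_id: str, exclude: str):
    """Boolean occupancy mask (0-based) of all genes except *exclude*."""
    n = len(annotation.replicon(replicon_id))
    mask = np.zeros(n, dtype=bool)
    for g in annotation.genes:
        if g.replicon_id != replicon_id or g.gene_id == exclude:
            continue
        if g.end <= n:
            mask[g.start - 1 : g.end] = True
        else:  # origin-wrapping gene stored unwrapped
            mask[g.start - 1 :] = True
            mask[: g.end - n] = True
    return mask


def upstream_intergenic(
    gene: GeneRecord, annotation: GenomeAnnotation
) -> IntergenicRegion:
    """Extract the intergenic region 5' of *gene*'s translation start.

    Walks upstream on the gene's own strand to the nearest boundary of
    any other annotated gene on the same replicon; wraps across the
    origin of circular replicons; linear replicons stop at the sequence
    edge.  Returns a zero-length region when the neighbor abuts or
    overlaps the gene.
    """
    try:
        annotation.gene(gene.gene_id)
    except KeyError:
        raise ValueError(f"gene {gene.gene_id} not in annotation") from None
    rep = annotation.replicon(gene.replicon_id)
    n = len(rep)
    mask = _occupied(annotation, gene.replicon_id, exclude=gene.gene_id)
    circular = rep.topology == CIRCULAR

    if gene.strand == "+":
        # walk left from the base before the gene start
        pos = (gene.start - 2) % n if circular else gene.start - 2
        step = -1
    else:
        pos = gene.end % n if circular else gene.end
        step = 1

    positions: list[int] = []
    for _ in range(n - 1):
        if not circular and (pos < 0 or pos >= n):
            break
        if mask[pos]:
            break
        positions.append(pos)
        pos += step
        if circular:
            pos %= n

    if not positions:
        anchor = gene.start if gene.strand == "+" else gene.end
        return IntergenicRegion(
            gene_id=gene.gene_id,
            replicon_id=gene.replicon_id,
            start=anchor,
            end=anchor,
            sequence="",
            gene_strand=gene.strand,
        )

    if gene.strand == "+":
        positions.reverse()  # collected right-to-left
    start0, end0 = positions[0], positions[-1]
    seq = "".join(rep.sequence[p] for p in positions)
    return IntergenicRegion(
        gene_id=gene.gene_id,
        replicon_id=gene.replicon_id,
        start=start0 + 1,
        end=end0 + 1,
        sequence=seq,
        gene_strand=gene.strand,
    )


def group_gc(
    gene_ids: list[str], annotation: GenomeAnnotation
) -> dict[str, float]:
    """Per-gene upstream-intergenic %GC; zero-length regions are dropped."""
    out = {}
    for gid in gene_ids:
        region = upstream_intergenic(annotation.gene(gid), annotation)
        if region.length > 0:
            out[gid] = region.gc_percent
    return out


def compare_to_baseline(
    values: list[float],
    baseline: float,
    group_label: str = "group",
    baseline_label: str = "baseline",
) -> GcComparison:
    """Two-sided one-sample t test of the group mean against *baseline*.

    With n < 2 or zero within-group variance the t statistic is not
    defined; both statistics are reported as NaN with a warning.
    """
    values = [float(v) for v in values]
    nan = float("nan")
    if len(values) < 2:
        warnings.warn(f"{group_label}: n = {len(values)} < 2; t test not available")
        t, p = nan, nan
    elif np.std(values, ddof=1) == 0:
        if np.isclose(values[0], baseline):
            t, p = 0.0, 1.0
        else:
            warnings.warn(f"{group_label}: zero variance; t test not available")
            t, p = nan, nan
    else:
        res = stats.ttest_1samp(values, popmean=baseline)
        t, p = float(res.statistic), float(res.pvalue)
    return GcComparison(
        group_label=group_label,
        values=tuple(values),
        baseline_label=baseline_label,
        baseline_value=float(baseline),
        t_statistic=t,
        p_value=p,
    )
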