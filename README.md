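# cdgscan

Genome-wide census of cyclic di-GMP (c-di-GMP) signaling components in
bacterial genomes, built for multipartite rhizobial genomes such as
*Sinorhizobium fredii* but applicable to any annotated prokaryote
genome.

c-di-GMP is a ubiquitous second messenger synthesized from two GTP by
diguanylate cyclases (DGCs, GGDEF domain) and degraded by
phosphodiesterases (PDEs, EAL domain); PilZ domains act as receptors.
Whether a GGDEF or EAL domain is catalytically competent can be
predicted from conserved active-site residues: a domain with at least
one essential residue substituted is *degenerate* and presumed
inactive. `cdgscan` turns that rule into a reproducible pipeline:

* **Motif engine** — spacing-constrained activity motifs with essential
  residue classes and fixed or bounded anonymous spacers:
  * GGDEF (DGC): `D x(7) N x(8) D x(21) R x(1) [GSA] G [DE] E F`,
    where `[GSA] G [DE] E F` is the active (A-)site block; an `RxxD`
    whose D sits exactly five residues upstream of the A-site block is
    reported as an allosteric inhibition (I-)site;
  * EAL (PDE): `E x(55,58) N x(31) E x(2) E x(26) D x(20) K x(35) E`;
  * PilZ (receptor): `R x(3) R x(20,30) [DN] x(1) [SA] x(2) G`.

  Scanning enumerates every start position and admissible spacer-width
  combination; the best partial alignment reports exactly which
  essential residues fail, so every DEGENERATE call is diagnosable.
* **Domain locator** — domain instances from hmmscan `--domtblout` or
  generic TSV hit tables (E-value threshold, configurable name aliases)
  or from a built-in motif heuristic; same-type overlaps resolved to
  the best-scoring non-overlapping selection.
* **Genome census** — GenBank or GFF3+FASTA parsing, per-protein
  ACTIVE/DEGENERATE/ABSENT calls, and per-genome tallies of DGC-only,
  PDE-only, DGC-PDE bifunctional, and PilZ-like proteins, with
  panel-level mean ± SD.
* **Promoter %GC** — upstream-intergenic region extraction (strand- and
  origin-aware on circular replicons), %GC, and one-sample two-sided
  *t* tests against genome or replicon baselines — the sequence
  statistic relevant to low-GC-preferring MucR-family repressors.
* **Expression summary** — RPKM from gene-level count tables and the
  classical two-way (gene × condition) ANOVA variance partition (%SS
  per effect) with per-condition Bonferroni pairwise comparisons.
* **Synthetic data** — generators for motif-planted proteins, annotated
  multi-replicon genomes with controlled intergenic GC, and
  negative-binomial count tables, each with machine-readable ground
  truth, so the whole pipeline is testable offline.

## Worked example

```python
from cdgscan import classify_ggdef

domain = "D" + "A"*7 + "N" + "A"*8 + "D" + "A"*21 + "R" + "A" + "GGDEF"
call = classify_ggdef(domain)
print(call.status, call.i_site_present)
# ACTIVE False

broken = domain[:-1] + "A"          # substitute the terminal F
call = classify_ggdef(broken)
print(call.status, call.mismatched_essentials)
# DEGENERATE ((8, 'A'),)
```

The minimal 46-residue motif instance is called ACTIVE; substituting a
single essential residue flips the call to DEGENERATE and names the
failing essential (rank 8, the terminal F of the A-site block, observed
as `A`). See `examples/` for one narrative script per capability
(domain classification, genome census, promoter %GC, expression ANOVA);
each prints the numbers it computes and what they mean. A thin CLI
(`cdg-scan census|panel|gc|express|synth`) wraps the same functions for
shell use.

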