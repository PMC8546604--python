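# Methods

## Activity motifs and the matching model

A motif is an ordered grammar of *essential residue classes* (a single
amino acid or a small set of alternatives) and *anonymous spacers* of
fixed width `x(n)` or bounded width `x(n,m)`. The three shipped motifs
describe the catalytic requirements of the GGDEF (diguanylate cyclase),
EAL (phosphodiesterase) and PilZ (receptor) domains:

| domain | motif | essentials | width |
|---|---|---|---|
| GGDEF | `D x(7) N x(8) D x(21) R x(1) [GSA] G [DE] E F` | 9 | 46 |
| EAL | `E x(55,58) N x(31) E x(2) E x(26) D x(20) K x(35) E` | 7 | 176–179 |
| PilZ | `R x(3) R x(20,30) [DN] x(1) [SA] x(2) G` | 5 | 31–41 |

Spacer widths written without a range are read as exact counts; only
ranged notations are ranges. Matching is purely combinatorial — no
PSSM, profile HMM or structural scoring. `scan` enumerates every start
position and every admissible combination of ranged-spacer widths and
reports all full matches, which makes it directly comparable to a
brute-force oracle; `best_partial_match` maximizes the number of
essential residues matching their class, breaking ties by earlier start
and then smaller total spacer width, and reports the failing essentials
of that alignment. A domain is ACTIVE if and only if a full motif match
exists; otherwise it is DEGENERATE with the best alignment's mismatches
as diagnostics. The ambiguity letter `X` in input sequences never
satisfies a residue class (conservative calling). Sequences shorter
than the motif are still classified (essential positions beyond the end
count as mismatches, observed as `-`); sequences under 10 residues are
rejected as unclassifiable.

The I-site (allosteric product-inhibition site) of a GGDEF domain is an
`RxxD` whose terminal D lies exactly five residues upstream of the
first residue of the A-site block `[GSA] G [DE] E F`; the anchor is the
A-site block start, and only the exact offset counts. The flag is
evaluated against every full motif match (or the best partial alignment
when the domain is degenerate).

Two readings of the source notation were genuinely open and were fixed
as follows: the EAL `E_XX_E` segment is compiled as `E x(2) E` (the
X-as-spacer convention), and the `G/S/A` alternatives apply to the
first A-site position only. Exact spacer widths may undercall ACTIVE on
real proteomes whose alignments contain one-residue indels; this is an
accepted property of the exact-width model, not a bug, and a custom
motif file can relax any spacer to a range.

## Domain location

Domain instances come from external hit tables — hmmscan
`--domtblout` (per-domain independent E-value, alignment coordinates)
or a generic 5-column TSV — filtered at a configurable E-value
threshold (default 1e-5; the appropriate CDD/Pfam cutoff is
data-dependent and deliberately exposed). Domain names map to canonical
types through a user-extensible alias table (e.g. `PF00990` → GGDEF).
Protein coordinates are 1-based inclusive throughout, matching hmmscan.

Overlapping same-type hits are resolved to the pairwise-non-overlapping
subset of maximum total score (match fraction for heuristic hits,
−log10 E-value for table hits; ties prefer more hits, then earlier
starts), found by exact include/exclude search — per-protein hit lists
are small, so exhaustive resolution is cheap and well-defined even on
chains of overlaps. Cross-type overlaps (e.g. GGDEF–EAL tandems) are
always retained.

When no hit table is available, `heuristic_locate` slides the activity
motif itself: it emits a hit over the best partial alignment's span
(padded by a 15-residue flank) when the matched-essential fraction
reaches a threshold (default 0.6 — permissive enough to surface
degenerate domains for diagnosis). Note the false-positive rate of the
heuristic grows as motifs get shorter: with only 5 essentials (PilZ) a
random 300-residue protein usually reaches 4/5 somewhere, so
short-motif location should use a stricter threshold or an external hit
table; category tallies are unaffected because they count only ACTIVE
(full-motif) calls.

## Census semantics

Per protein and domain type the call is ABSENT (no located domain) or
the classifier's ACTIVE/DEGENERATE on the hit sub-sequence; a protein
with several same-type instances is ACTIVE if any instance is (the
census counts proteins, not domains, and one functional catalytic site
suffices). Degeneracy is judged only inside a located domain — a
protein with no hit is ABSENT, never DEGENERATE. Categories: DGC-only
(GGDEF ACTIVE, EAL not ACTIVE), PDE-only (the converse), bifunctional
(both ACTIVE), PilZ-like (PilZ ACTIVE) — the PilZ series is tallied
independently and may overlap the catalytic categories. Both the
activity-filtered layer (`ggdef_active`) and the raw domain-presence
layer (`ggdef_total`, `eal_total`) are reported, so either reading of a
published per-strain count is recoverable. Panel summaries use the
sample (n−1) standard deviation; a single-genome panel reports SD as
not available.

## Upstream-intergenic %GC

The upstream region of a gene walks 5′-ward from its translation start
on its own strand to the nearest boundary of any other annotated gene
on the same replicon, regardless of that gene's strand (divergent
promoter sharing is therefore included); circular replicons wrap across
the origin, linear replicons stop at the sequence edge. No maximum
length is imposed. Abutting or overlapping neighbors give a zero-length
region, which is excluded from group statistics. %GC excludes `N` from
numerator and denominator; an empty or all-N region is not available.
Baselines are computed over the full nucleotide sequence of the genome
or a replicon (not gene-averaged). The group-versus-baseline comparison
is a one-sample two-sided *t* test of the per-gene values against the
fixed baseline constant — a one-sample reading was chosen because the
baseline is a single sequence-wide constant, not a sampled group; with
n < 2 or zero variance the test is reported as not available rather
than fabricated.

## Expression summaries

RPKM[g, l] = count / ((length_bp/10³) · (total_l/10⁶)) with the
per-library total defaulting to the column sum of the supplied table
(totals beyond the annotated genes are usually unavailable downstream
of counting; per-library overrides are accepted). A zero-total library
yields a not-available column with a warning.

The two-way ANOVA requires a balanced complete gene × condition design
with r ≥ 2 replicates per cell and uses the classical factorial
decomposition from cell means: SS_gene + SS_condition + SS_interaction
+ SS_residual = SS_total, %SS = 100·SS/SS_total (summing to 100 by
construction), F = MS_effect/MS_residual with the corresponding
p-values. The response is untransformed RPKM by default; a log2(x+1)
transform is available. Pairwise gene comparisons within each condition
use the pooled residual mean square and df (t = Δmean/√(2·MS_E/r)), and
Bonferroni correction is applied per condition family (multiplier =
number of gene pairs within one condition), each condition corrected
independently.

Note that RPKM divides out library-wide scaling: a condition effect
shared by every gene in the table is invisible after normalization.
Condition effects on a focal gene set are therefore measurable only
relative to the rest of the table, which is why the demonstration
analyses embed the focal genes among stable background genes — as in a
real transcriptome, where a few DGC genes are a negligible fraction of
the library total.

## Synthetic data and what it does (not) show

`make_protein` plants one motif instance (spacer widths drawn uniformly
from their ranges) in a uniform-composition random background; listed
essentials are mutated to a uniformly chosen disallowed residue.
Uniform background maximizes the detectability of accidental matches.
Rejection sampling (cap 1,000 attempts) enforces two guarantees: the
background contains no accidental full-motif match, and — because the
truth label also asserts *which* essentials were mutated — the planted
alignment is the unambiguous best partial alignment within its span
(an alternative ranged-spacer width can tie the match count by chance
and would otherwise carry a different mismatch set, making the label
itself wrong). When no I-site is planted, an accidental `RxxD` at the
exact planted-motif I-site position is removed.

`make_genome` lays out genes separated by intergenic spacers whose
bases are drawn Bernoulli(G/C vs A/T) at per-region GC targets, so a
600-bp region concentrates within ~2 percentage points of its target;
replicons end immediately after their last gene so that every gene's
upstream region is exactly its own spacer (on circular replicons the
first gene's region abuts the last gene across the origin, which is
what the rotation-equivalence tests exercise). Proteins are
back-translated with one fixed codon per residue (genetic code 11), so
GenBank and GFF3+FASTA outputs describe identical content and the
GFF3 path exercises translation from coordinates. `make_counts` draws
negative-binomial counts (variance μ + φμ²) around cell means
exp(grand + gene + condition + interaction) in a balanced design.

What passing on synthetic data does *not* show: real GGDEF/EAL domains
diverge from the exact spacer widths (alignments contain indels), real
backgrounds are compositionally biased, real intergenic regions contain
regulatory structure beyond base composition, and real RNA-seq has
gene-length and GC biases that RPKM does not remove. The synthetic
layer validates the machinery — parsing, matching arithmetic,
bookkeeping, statistics — not biological recall on real proteomes.

## Problem sizes and numerical choices

Default analysis scales were chosen as representative for the scientific
setting: motif-scan validation on 200–400-residue random proteins
(roughly single-domain protein scale), planted-truth panels of 500
proteins per motif with 0–3 mutations, census genomes of 20–50 genes
across 1–2 replicons with 500–700-bp intergenic regions, and an
8-gene × 3-condition × 3-replicate expression design (the scale on
which such DGC comparisons are typically made). Determinism: every
generator is reproducible from (seed, parameters); scanning and
classification are deterministic with documented tie-breaks; %SS
components are exact partitions, so their sum to 100 is used as an
internal consistency check with a 1e-9 tolerance on balanced designs.
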