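"""Per-genome census of c-di-GMP signaling components.

Parses annotated genomes (GenBank, or GFF3 plus genomic FASTA), applies
the motif-based activity classifiers to every protein with a GGDEF, EAL
or PilZ domain hit, and tallies the census categories: DGC-only
(active GGDEF, no active EAL), PDE-only, DGC-PDE bifunctional, and
PilZ-like receptor proteins.  PilZ-like proteins are tallied as an
independent series and may overlap the catalytic categories.

A protein with no domain hit of a given type is ABSENT for that type;
degeneracy (>= 1 essential residue substituted) is judged only within a
located domain.  When a protein carries several instances of the same
domain type, one ACTIVE instance suffices for an ACTIVE protein-level
call: the census counts proteins, not domains.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

from cdgscan import motifs
from cdgscan.motifs import ABSENT, ACTIVE, DEGENERATE, MotifPattern
from cdgscan.domains import (
    DomainHit,
    EAL,
    GGDEF,
    PILZ,
    architecture,
    heuristic_locate,
    resolve_overlaps,
)

logger = logging.getLogger(__name__)

CIRCULAR = "circular"
LINEAR = "linear"


@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding gene: genomic location plus protein sequence."""

    gene_id: str
    replicon_id: str
    start: int  # 1-based inclusive, forward strand
    end: int
    strand: str  # '+' or '-'
    product: str = ""
    protein_sequence: str = ""
    wraps_origin: bool = False

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


@dataclass(frozen=True)
class Replicon:
    replicon_id: str
    sequence: str
    topology: str = LINEAR
    role_label: str = "unknown"  # chromosome / chromid / plasmid / unknown

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.replicon_id}: empty sequence")
        if self.topology not in (CIRCULAR, LINEAR):
            raise ValueError(f"{self.replicon_id}: bad topology {self.topology!r}")

    def __len__(self):
        return len(self.sequence)


@dataclass(frozen=True)
class GenomeAnnotation:
    genome_id: str
    replicons: tuple[Replicon, ...]
    genes: tuple[GeneRecord, ...]

    def __post_init__(self):
        by_id = {r.replicon_id for r in self.replicons}
        for g in self.genes:
            if g.replicon_id not in by_id:
                raise ValueError(f"{g.gene_id}: unknown replicon {g.replicon_id}")

    def replicon(self, replicon_id: str) -> Replicon:
        for r in self.replicons:
            if r.replicon_id == replicon_id:
                return r
        raise KeyError(replicon_id)

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass(frozen=True)
class ProteinCall:
    """Per-protein activity calls for the three domain types."""

    gene_id: str
    ggdef: str = ABSENT
    eal: str = ABSENT
    pilz: str = ABSENT
    i_site: bool = False
    architecture_string: str = ""

    def __post_init__(self):
        if self.ggdef == ABSENT and self.i_site:
            raise ValueError("i_site requires a GGDEF domain")


@dataclass
class SignalingInventory:
    """Per-genome tallies of c-di-GMP signaling components."""

    genome_id: str
    ggdef_total: int = 0
    ggdef_active: int = 0
    eal_total: int = 0
    pilz_total: int = 0
    dgc_only: list[str] = field(default_factory=list)
    pde_only: list[str] = field(default_factory=list)
    bifunctional: list[str] = field(default_factory=list)
    pilz_like: list[str] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        return {
            "DGC_only": len(self.dgc_only),
            "PDE_only": len(self.pde_only),
            "bifunctional": len(self.bifunctional),
            "PilZ_like": len(self.pilz_like),
        }

    @property
    def component_total(self) -> int:
        """Proteins carrying any GGDEF, EAL or PilZ domain (union count)."""
        return self._component_total

    _component_total: int = 0


# --- genome loading ----------------------------------------------------------

def _translate_cds(dna: str, gene_id: str) -> str | None:
    if len(dna) % 3 != 0:
        warnings.warn(
            f"{gene_id}: CDS length {len(dna)} not a multiple of 3; skipped"
        )
        return None
    protein = str(Seq(dna).translate(table=11))
    return protein.rstrip("*")


def _load_genbank(path: str | Path, genome_id: str) -> GenomeAnnotation:
    replicons = []
    genes = []
    for record in SeqIO.parse(str(path), "genbank"):
        topology = record.annotations.get("topology", LINEAR)
        replicons.append(
            Replicon(
                replicon_id=record.id,
                sequence=str(record.seq).upper(),
                topology=CIRCULAR if topology == CIRCULAR else LINEAR,
            )
        )
        n = len(record.seq)
        for feat in record.features:
            if feat.type != "CDS":
                continue
            q = feat.qualifiers
            gene_id = (
                q.get("locus_tag", q.get("protein_id", q.get("gene", [None])))[0]
            )
            if gene_id is None:
                gene_id = f"{record.id}_{int(feat.location.start) + 1}"
            start = int(feat.location.start) + 1
            end = int(feat.location.end)
            wraps = False
            parts = feat.location.parts
            if len(parts) > 1 and int(parts[0].end) == n and int(parts[-1].start) == 0:
                # origin-spanning CDS on a circular replicon: unwrap
                wraps = True
                start = int(parts[0].start) + 1
                end = n + int(parts[-1].end)
            strand = "+" if feat.location.strand != -1 else "-"
            if "translation" in q:
                protein = q["translation"][0]
            else:
                dna = str(feat.extract(record.seq))
                protein = _translate_cds(dna, gene_id)
                if protein is None:
                    continue
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    replicon_id=record.id,
                    start=start,
                    end=end,
                    strand=strand,
                    product=q.get("product", [""])[0],
                    protein_sequence=protein,
                    wraps_origin=wraps,
                )
            )
    return GenomeAnnotation(
        genome_id=genome_id, replicons=tuple(replicons), genes=tuple(genes)
    )


def _load_gff3_fasta(
    gff_path: str | Path, fasta_path: str | Path, genome_id: str
) -> GenomeAnnotation:
    import gffutils

    seqs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    topologies = {}
    for line in Path(gff_path).read_text().splitlines():
        # topology carried in ##sequence-region-adjacent pragma comments:
        #   #!topology <seqid> circular
        if line.startswith("#!topology"):
            fields = line.split()
            if len(fields) == 3:
                topologies[fields[1]] = fields[2]
    db = gffutils.create_db(
        str(gff_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    replicons = tuple(
        Replicon(
            replicon_id=rid,
            sequence=seq,
            topology=CIRCULAR if topologies.get(rid) == CIRCULAR else LINEAR,
        )
        for rid, seq in seqs.items()
    )
    genes = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [f"{feat.seqid}_{feat.start}"])[0]
        if feat.seqid not in seqs:
            raise ValueError(f"{gene_id}: sequence {feat.seqid} not in FASTA")
        dna = seqs[feat.seqid][feat.start - 1 : feat.end]
        if feat.strand == "-":
            dna = str(Seq(dna).reverse_complement())
        protein = _translate_cds(dna, gene_id)
        if protein is None:
            continue
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                replicon_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand="+" if feat.strand != "-" else "-",
                product=feat.attributes.get("product", [""])[0],
                protein_sequence=protein,
            )
        )
    return GenomeAnnotation(genome_id=genome_id, replicons=replicons, genes=tuple(genes))


def load_genome(
    path: str | Path,
    fasta: str | Path | None = None,
    fmt: str | None = None,
    genome_id: str | None = None,
) -> GenomeAnnotation:
    """Load an annotated genome from GenBank or GFF3 + genomic FASTA.

    Protein sequences come from the annotation's translation when
    present, otherwise they are translated from the genomic coordinates
    with the bacterial genetic code (table 11), trimming the stop.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gff3" if fasta is not None or path.suffix.lower() in (
            ".gff", ".gff3") else "genbank"
    genome_id = genome_id or path.stem
    if fmt == "genbank":
        return _load_genbank(path, genome_id)
    if fmt == "gff3":
        if fasta is None:
            raise ValueError("GFF3 input requires the genomic FASTA")
        return _load_gff3_fasta(path, fasta, genome_id)
    raise ValueError(f"unknown format {fmt!r}")


# --- classification ----------------------------------------------------------

_CLASSIFIERS = {
    GGDEF: motifs.classify_ggdef,
    EAL: motifs.classify_eal,
    PILZ: motifs.classify_pilz,
}


def locate_domains_heuristic(
    annotation: GenomeAnnotation,
    min_match_fraction: float | None = None,
    patterns: dict[str, MotifPattern] | None = None,
) -> list[DomainHit]:
    """Run the motif heuristic over every protein (no hit table needed)."""
    from cdgscan.domains import DEFAULT_MIN_MATCH_FRACTION

    frac = DEFAULT_MIN_MATCH_FRACTION if min_match_fraction is None else min_match_fraction
    pats = patterns or {
        GGDEF: motifs.GGDEF_PATTERN,
        EAL: motifs.EAL_PATTERN,
        PILZ: motifs.PILZ_PATTERN,
    }
    hits: list[DomainHit] = []
    for gene in annotation.genes:
        for pattern in pats.values():
            hits.extend(
                heuristic_locate(
                    gene.protein_sequence, pattern,
                    min_match_fraction=frac, protein_id=gene.gene_id,
                )
            )
    return hits


def classify_proteome(
    annotation: GenomeAnnotation, hits: list[DomainHit]
) -> list[ProteinCall]:
    """Classify every gene's domains from its located hits.

    Each domain type is ABSENT (no hit), or ACTIVE/DEGENERATE from the
    motif classifier applied to the hit sub-sequence; with multiple
    same-type instances, any ACTIVE instance makes the protein-level
    call ACTIVE.
    """
    genes = {g.gene_id: g for g in annotation.genes}
    unknown = sorted({h.protein_id for h in hits} - set(genes))
    if unknown:
        raise ValueError(f"hits reference unknown proteins: {unknown}")
    by_protein: dict[str, list[DomainHit]] = {g: [] for g in genes}
    for h in hits:
        by_protein[h.protein_id].append(h)
    calls = []
    for gene_id, gene in genes.items():
        kept = resolve_overlaps(by_protein[gene_id]) if by_protein[gene_id] else []
        status = {GGDEF: ABSENT, EAL: ABSENT, PILZ: ABSENT}
        i_site = False
        for hit in kept:
            classifier = _CLASSIFIERS.get(hit.domain_type)
            if classifier is None:
                continue  # OTHER domains contribute to architecture only
            sub = gene.protein_sequence[hit.start - 1 : hit.end]
            call = classifier(sub)
            logger.debug(
                "%s %s %d-%d -> %s", gene_id, hit.domain_type, hit.start,
                hit.end, call.status,
            )
            if call.status == ACTIVE or status[hit.domain_type] == ABSENT:
                status[hit.domain_type] = call.status
            if hit.domain_type == GGDEF and call.i_site_present:
                i_site = True
        calls.append(
            ProteinCall(
                gene_id=gene_id,
                ggdef=status[GGDEF],
                eal=status[EAL],
                pilz=status[PILZ],
                i_site=i_site if status[GGDEF] != ABSENT else False,
                architecture_string=architecture(gene_id, kept).architecture_string,
            )
        )
    calls.sort(key=lambda c: c.gene_id)
    return calls


def build_inventory(
    calls: list[ProteinCall], genome_id: str = "genome"
) -> SignalingInventory:
    """Tally the census categories from per-protein calls."""
    inv = SignalingInventory(genome_id=genome_id)
    for c in calls:
        if c.ggdef != ABSENT:
            inv.ggdef_total += 1
            if c.ggdef == ACTIVE:
                inv.ggdef_active += 1
        if c.eal != ABSENT:
            inv.eal_total += 1
        if c.pilz != ABSENT:
            inv.pilz_total += 1
        if c.ggdef == ACTIVE and c.eal == ACTIVE:
            inv.bifunctional.append(c.gene_id)
        elif c.ggdef == ACTIVE:
            inv.dgc_only.append(c.gene_id)
        elif c.eal == ACTIVE:
            inv.pde_only.append(c.gene_id)
        if c.pilz == ACTIVE:
            inv.pilz_like.append(c.gene_id)
        if (c.ggdef, c.eal, c.pilz) != (ABSENT, ABSENT, ABSENT):
            inv._component_total += 1
    return inv


def summarize_panel(
    inventories: list[SignalingInventory] | None = None,
    counts: dict[str, list[float]] | None = None,
):
    """Mean and sample SD of census counts across a panel of genomes.

    Accepts either a list of inventories or a pre-extracted mapping of
    series name to per-genome counts.  SD uses the n-1 denominator; a
    single genome yields SD = NaN (not available).
    """
    import pandas as pd

    if counts is None:
        if not inventories:
            raise ValueError("empty panel")
        counts = {
            "ggdef_total": [i.ggdef_total for i in inventories],
            "ggdef_active": [i.ggdef_active for i in inventories],
            "eal_total": [i.eal_total for i in inventories],
            "DGC_only": [len(i.dgc_only) for i in inventories],
            "PDE_only": [len(i.pde_only) for i in inventories],
            "bifunctional": [len(i.bifunctional) for i in inventories],
            "PilZ_like": [len(i.pilz_like) for i in inventories],
            "component_total": [i.component_total for i in inventories],
        }
    if not counts or any(len(v) == 0 for v in counts.values()):
        raise ValueError("empty panel")
    rows = {}
    for label, values in counts.items():
        arr = np.asarray(values, dtype=float)
        sd = float(np.std(arr, ddof=1)) if arr.size > 1 else float("nan")
        rows[label] = {"mean": float(np.mean(arr)), "sd": sd, "n": arr.size}
    return pd.DataFrame(rows).T


def rotate_genome(annotation: GenomeAnnotation, offset: int) -> GenomeAnnotation:
    """Rotate every circular replicon by *offset* bases.

    Position ``offset + 1`` of the old sequence becomes position 1.
    Genes are re-coordinated accordingly; a gene that would span the new
    origin is unwrapped (end > replicon length) and flagged.  Useful for
    verifying that origin-spanning extraction is rotation-invariant.
    """
    new_replicons = []
    new_genes = []
    for rep in annotation.replicons:
        if rep.topology != CIRCULAR:
            new_replicons.append(rep)
            continue
        n = len(rep.sequence)
        k = offset % n
        new_replicons.append(
            replace(rep, sequence=rep.sequence[k:] + rep.sequence[:k])
        )
    circ = {r.replicon_id for r in annotation.replicons if r.topology == CIRCULAR}
    for g in annotation.genes:
        if g.replicon_id not in circ:
            new_genes.append(g)
            continue
        n = len(annotation.replicon(g.replicon_id))
        k = offset % n
        new_start = (g.start - 1 - k) % n + 1
        new_end = new_start + (g.end - g.start)
        new_genes.append(
            replace(g, start=new_start, end=new_end, wraps_origin=new_end > n)
        )
    return GenomeAnnotation(
        genome_id=annotation.genome_id,
        replicons=tuple(new_replicons),
        genes=tuple(new_genes),
    )
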