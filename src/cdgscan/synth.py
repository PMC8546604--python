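"""Synthetic proteins, genomes and count tables with known ground truth.

Every generated object carries a :class:`TruthRecord` describing exactly
what was planted — motif type, chosen spacer widths, mutated essential
residues, I-site, census category, upstream-intergenic GC target, or
expression cell means — so every pipeline stage can be validated
offline against planted truth.

Backgrounds are uniform over the 20 amino acids (configurable), which
maximizes the detectability of accidental motif matches; rejection
sampling guarantees that no full motif occurs outside the planted span.
All generators are deterministic given (seed, parameters).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from cdgscan import motifs as _motifs
from cdgscan.motifs import (
    AMINO_ACIDS,
    RESIDUE_CLASS,
    MotifPattern,
    scan,
)
from cdgscan.domains import GGDEF, EAL, PILZ, TABLE, DomainHit
from cdgscan.census import (
    CIRCULAR,
    LINEAR,
    GeneRecord,
    GenomeAnnotation,
    Replicon,
)
from cdgscan.expression import CountTable

logger = logging.getLogger(__name__)

_AA_LIST = sorted(AMINO_ACIDS)

#: One unambiguous codon per amino acid (all valid under genetic code 11).
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

_REJECTION_CAP = 1000


@dataclass
class TruthRecord:
    """Planted attributes of one synthetic object (TSV round-trippable)."""

    object_id: str
    kind: str  # protein / gene / counts-cell
    motif: str = ""  # pattern name, empty when none planted
    motif_start: int = 0  # 1-based on the protein; 0 when none
    motif_end: int = 0
    spacer_widths: str = ""  # comma-joined chosen ranged-spacer widths
    mutated_essentials: str = ""  # comma-joined 0-based essential ranks
    i_site_planted: bool = False
    category: str = ""  # census category label for genes
    gc_target: float = float("nan")  # upstream-intergenic GC target (%)
    cell_mean: float = float("nan")  # expected expression for counts cells

    @property
    def mutated_indices(self) -> list[int]:
        return [int(x) for x in self.mutated_essentials.split(",") if x != ""]

    @property
    def widths(self) -> list[int]:
        return [int(x) for x in self.spacer_widths.split(",") if x != ""]


def truth_to_tsv(records: list[TruthRecord], path: str | Path) -> None:
    pd.DataFrame([asdict(r) for r in records]).to_csv(path, sep="\t", index=False)


def truth_from_tsv(path: str | Path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    records = []
    for row in df.to_dict("records"):
        row["gc_target"] = float(row["gc_target"]) if row["gc_target"] != "" else float("nan")
        row["cell_mean"] = float(row["cell_mean"]) if row["cell_mean"] != "" else float("nan")
        row["i_site_planted"] = str(row["i_site_planted"]) in ("True", "true", "1")
        for key in ("motif_start", "motif_end"):
            row[key] = int(row[key])
        for key in ("motif", "spacer_widths", "mutated_essentials", "category"):
            row[key] = str(row[key]) if row[key] != "" else ""
        records.append(TruthRecord(**row))
    return records


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _random_background(rng, length, composition=None) -> list[str]:
    if composition is None:
        return list(rng.choice(_AA_LIST, size=length))
    letters, probs = zip(*sorted(composition.items()))
    return list(rng.choice(letters, size=length, p=np.asarray(probs) / sum(probs)))


def _build_motif_instance(
    rng, pattern: MotifPattern, mutate_essentials, plant_i_site
):
    """Return (residue list, chosen ranged widths, essential rel. positions)."""
    widths = []
    chars: list[str] = []
    essential_rel: list[int] = []
    spacer_rel: set[int] = set()
    ess_rank = 0
    for elem in pattern.elements:
        if elem.kind == RESIDUE_CLASS:
            allowed = sorted(elem.allowed)
            if ess_rank in mutate_essentials:
                disallowed = sorted(AMINO_ACIDS - elem.allowed)
                chars.append(str(rng.choice(disallowed)))
            else:
                chars.append(str(rng.choice(allowed)))
            essential_rel.append(len(chars) - 1)
            ess_rank += 1
        else:
            w = (
                int(rng.integers(elem.span_min, elem.span_max + 1))
                if elem.is_ranged
                else elem.span_min
            )
            if elem.is_ranged:
                widths.append(w)
            start = len(chars)
            chars.extend(_random_background(rng, w))
            spacer_rel.update(range(start, start + w))

    if len(essential_rel) >= _motifs._A_SITE_ESSENTIALS:
        a_site_rel = essential_rel[-_motifs._A_SITE_ESSENTIALS]
        d_rel = a_site_rel - _motifs.I_SITE_OFFSET
        r_rel = d_rel - 3
        if r_rel >= 0 and {d_rel, r_rel} <= spacer_rel:
            if plant_i_site:
                chars[d_rel] = "D"
                chars[r_rel] = "R"
            else:
                # forbid an accidental I-site at the planted position
                if chars[d_rel] == "D":
                    chars[d_rel] = "A"
        elif plant_i_site:
            raise ValueError(
                f"pattern {pattern.name} cannot host a planted I-site"
            )
    elif plant_i_site:
        raise ValueError(f"pattern {pattern.name} cannot host a planted I-site")
    return chars, widths


def make_protein(
    seed,
    length: int,
    pattern: MotifPattern,
    mutate_essentials: list[int] | None = None,
    plant_i_site: bool = False,
    object_id: str = "protein",
    composition: dict[str, float] | None = None,
) -> tuple[str, TruthRecord]:
    """Random protein with one planted motif instance.

    The background is free of accidental full-motif matches (verified by
    scanning, with rejection sampling); listed essential residues (by
    0-based rank) are mutated to a uniformly chosen disallowed letter,
    making the planted domain degenerate.
    """
    mutate_essentials = sorted(set(mutate_essentials or []))
    for idx in mutate_essentials:
        if not (0 <= idx < pattern.n_essentials):
            raise ValueError(f"essential index {idx} out of range")
    if length < pattern.max_width + 20:
        raise ValueError(
            f"length {length} < pattern max width {pattern.max_width} + 20"
        )
    rng = _rng(seed)
    for attempt in range(1, _REJECTION_CAP + 1):
        chars, widths = _build_motif_instance(
            rng, pattern, mutate_essentials, plant_i_site
        )
        motif_len = len(chars)
        offset = int(rng.integers(1, length - motif_len + 1))  # keep pos 1 free
        background = _random_background(rng, length, composition)
        protein = background[:offset] + chars + background[offset + motif_len:]
        protein[0] = "M"  # translatable start codon
        seq = "".join(protein)
        matches = scan(seq, pattern)
        planted_span = (offset + 1, offset + motif_len)
        if mutate_essentials:
            ok = not matches
            if ok:
                # The truth label also asserts WHICH essentials fail, so the
                # planted alignment must be the unambiguous best partial
                # alignment within its span: an alternative spacer-width
                # alignment that ties the match count by chance would carry a
                # different mismatch set and falsify the label.
                span_seq = seq[offset : offset + motif_len]
                best = _motifs.best_partial_match(span_seq, pattern)
                ok = best.start == 1 and tuple(
                    i for i, _ in best.mismatched_essentials
                ) == tuple(mutate_essentials)
        else:
            ok = all(
                (m.start, m.end) == planted_span for m in matches
            ) and bool(matches)
        if ok:
            if attempt > 1:
                logger.debug("%s: accepted after %d attempts", object_id, attempt)
            truth = TruthRecord(
                object_id=object_id,
                kind="protein",
                motif=pattern.name,
                motif_start=planted_span[0],
                motif_end=planted_span[1],
                spacer_widths=",".join(map(str, widths)),
                mutated_essentials=",".join(map(str, mutate_essentials)),
                i_site_planted=plant_i_site,
            )
            return seq, truth
    raise RuntimeError(
        f"rejection cap ({_REJECTION_CAP}) exceeded for {object_id}; "
        "try a longer protein length"
    )


def make_plain_protein(
    seed, length: int, object_id: str = "protein",
    patterns: list[MotifPattern] | None = None,
    composition: dict[str, float] | None = None,
) -> tuple[str, TruthRecord]:
    """Random protein guaranteed to contain no full motif of any pattern."""
    pats = patterns or [
        _motifs.GGDEF_PATTERN, _motifs.EAL_PATTERN, _motifs.PILZ_PATTERN
    ]
    rng = _rng(seed)
    for _ in range(_REJECTION_CAP):
        seq = "M" + "".join(_random_background(rng, length - 1, composition))
        if all(not scan(seq, p) for p in pats if len(seq) >= p.min_width):
            return seq, TruthRecord(object_id=object_id, kind="protein")
    raise RuntimeError(f"rejection cap exceeded for {object_id}")


# --- genomes -----------------------------------------------------------------

#: Census category -> list of (pattern name, mutated essential count)
CATEGORY_RECIPES = {
    "dgc": [(GGDEF, 0)],
    "dgc_degenerate": [(GGDEF, 2)],
    "pde": [(EAL, 0)],
    "pde_degenerate": [(EAL, 2)],
    "bifunctional": [(GGDEF, 0), (EAL, 0)],
    "pilz": [(PILZ, 0)],
    "none": [],
}


def _back_translate(protein: str) -> str:
    return "".join(_CODON[aa] for aa in protein) + "TAA"


def _revcomp(dna: str) -> str:
    comp = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}
    return "".join(comp[b] for b in reversed(dna))


def _spacer_dna(rng, length: int, gc_target: float) -> str:
    is_gc = rng.random(length) < gc_target / 100.0
    strong = rng.choice(["G", "C"], size=length)
    weak = rng.choice(["A", "T"], size=length)
    return "".join(np.where(is_gc, strong, weak))


def make_genome(
    seed,
    n_replicons: int = 1,
    genes_per_replicon: int = 10,
    architecture_mix: list[str] | dict[str, int] | None = None,
    intergenic_gc_targets: list[float] | float = 50.0,
    topology: str = LINEAR,
    intergenic_length: int = 500,
    segment_length: int = 80,
    minus_strand_fraction: float = 0.0,
    genome_id: str = "synthetic",
) -> tuple[GenomeAnnotation, list[TruthRecord]]:
    """Multi-replicon synthetic genome with planted domains and GC targets.

    Genes alternate with intergenic spacers of *intergenic_length* bp
    whose bases are drawn Bernoulli(G/C vs A/T) at the per-region GC
    target; each gene's protein is assembled from motif-bearing segments
    according to its census category label (see CATEGORY_RECIPES).
    Replicons end immediately after their last gene, so on a circular
    replicon the first gene's upstream region is exactly its own spacer.
    """
    if not (0 < n_replicons and 0 < genes_per_replicon):
        raise ValueError("positive replicon and gene counts required")
    rng = _rng(seed)
    if architecture_mix is None:
        labels = ["dgc"] * (genes_per_replicon * n_replicons)
    elif isinstance(architecture_mix, dict):
        labels = [lab for lab, k in architecture_mix.items() for _ in range(k)]
        if len(labels) != genes_per_replicon * n_replicons:
            raise ValueError(
                "architecture_mix counts must sum to the total gene count"
            )
    else:
        labels = list(architecture_mix)
        if len(labels) != genes_per_replicon * n_replicons:
            raise ValueError("architecture_mix length must equal gene count")
    if np.isscalar(intergenic_gc_targets):
        gc_targets = [float(intergenic_gc_targets)]
    else:
        gc_targets = [float(g) for g in intergenic_gc_targets]
    if not all(0 < g < 100 for g in gc_targets):
        raise ValueError("GC targets must lie in (0, 100)")

    replicons, genes, truths = [], [], []
    gene_no = 0
    for rep_idx in range(n_replicons):
        rid = f"{genome_id}_rep{rep_idx + 1}"
        parts: list[str] = []
        cursor = 0
        for i in range(genes_per_replicon):
            label = labels[gene_no]
            gid = f"{genome_id}_g{gene_no + 1:04d}"
            gc_target = gc_targets[gene_no % len(gc_targets)]
            gene_no += 1

            protein, segments, seg_truths = _category_protein(
                rng, label, gid, segment_length
            )
            strand = "-" if rng.random() < minus_strand_fraction else "+"
            cds = _back_translate(protein)
            spacer = _spacer_dna(rng, intergenic_length, gc_target)
            parts.append(spacer)
            cursor += len(spacer)
            start = cursor + 1
            parts.append(cds if strand == "+" else _revcomp(cds))
            cursor += len(cds)
            genes.append(
                GeneRecord(
                    gene_id=gid,
                    replicon_id=rid,
                    start=start,
                    end=cursor,
                    strand=strand,
                    product=f"synthetic {label} protein",
                    protein_sequence=protein,
                )
            )
            truths.append(
                TruthRecord(
                    object_id=gid,
                    kind="gene",
                    motif=";".join(t.motif for t in seg_truths if t.motif),
                    category=label,
                    gc_target=gc_target if strand == "+" else float("nan"),
                )
            )
            truths.extend(seg_truths)
        replicons.append(
            Replicon(
                replicon_id=rid,
                sequence="".join(parts),
                topology=CIRCULAR if topology == CIRCULAR else LINEAR,
            )
        )
    annotation = GenomeAnnotation(
        genome_id=genome_id, replicons=tuple(replicons), genes=tuple(genes)
    )
    return annotation, truths


def _category_protein(rng, label, gene_id, segment_length):
    """Assemble a protein from one motif segment per recipe entry."""
    if label not in CATEGORY_RECIPES:
        raise ValueError(f"unknown category label {label!r}")
    recipe = CATEGORY_RECIPES[label]
    if not recipe:
        seq, truth = make_plain_protein(rng, max(segment_length, 60), gene_id)
        return seq, [], []
    patterns = {GGDEF: _motifs.GGDEF_PATTERN, EAL: _motifs.EAL_PATTERN,
                PILZ: _motifs.PILZ_PATTERN}
    segments, seg_truths = [], []
    offset = 0
    for seg_idx, (pname, n_mut) in enumerate(recipe):
        pattern = patterns[pname]
        mutated = (
            sorted(rng.choice(pattern.n_essentials, size=n_mut, replace=False).tolist())
            if n_mut
            else []
        )
        length = pattern.max_width + max(segment_length, 40)
        seg, truth = make_protein(
            rng, length, pattern,
            mutate_essentials=mutated,
            object_id=f"{gene_id}.seg{seg_idx + 1}",
        )
        truth.motif_start += offset
        truth.motif_end += offset
        segments.append(seg)
        seg_truths.append(truth)
        offset += len(seg)
    return "".join(segments), segments, seg_truths


def truth_domain_hits(truths: list[TruthRecord]) -> list[DomainHit]:
    """Domain-hit table derived from planted truth (replaces a CDD query).

    Each planted motif segment becomes one hit covering the planted span
    (synthetic E-value 1e-50), keyed by the gene id the segment belongs to.
    """
    hits = []
    for t in truths:
        if t.kind != "protein" or not t.motif or ".seg" not in t.object_id:
            continue
        gene_id = t.object_id.rsplit(".seg", 1)[0]
        hits.append(
            DomainHit(
                protein_id=gene_id,
                domain_type=t.motif,
                start=max(1, t.motif_start - 10),
                end=t.motif_end + 10,
                score=1e-50,
                source=TABLE,
            )
        )
    return hits


# --- genome writers ----------------------------------------------------------

def write_genome(
    annotation: GenomeAnnotation, out_dir: str | Path, stem: str | None = None
) -> dict[str, Path]:
    """Write GenBank, GFF3 and FASTA files describing identical content."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio.SeqFeature import SeqFeature, SimpleLocation
    from Bio import SeqIO

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or annotation.genome_id
    paths = {
        "genbank": out_dir / f"{stem}.gbk",
        "gff3": out_dir / f"{stem}.gff3",
        "fasta": out_dir / f"{stem}.fasta",
    }

    records = []
    for rep in annotation.replicons:
        rec = SeqRecord(
            Seq(rep.sequence), id=rep.replicon_id, name=rep.replicon_id[:16],
            description="synthetic replicon",
            annotations={"molecule_type": "DNA", "topology": rep.topology},
        )
        for g in annotation.genes:
            if g.replicon_id != rep.replicon_id:
                continue
            loc = SimpleLocation(g.start - 1, g.end, strand=1 if g.strand == "+" else -1)
            rec.features.append(
                SeqFeature(
                    loc, type="CDS",
                    qualifiers={
                        "locus_tag": [g.gene_id],
                        "product": [g.product],
                        "transl_table": ["11"],
                        "translation": [g.protein_sequence],
                    },
                )
            )
        records.append(rec)
    SeqIO.write(records, str(paths["genbank"]), "genbank")

    with open(paths["fasta"], "w") as fh:
        for rep in annotation.replicons:
            fh.write(f">{rep.replicon_id}\n")
            for i in range(0, len(rep.sequence), 70):
                fh.write(rep.sequence[i : i + 70] + "\n")

    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for rep in annotation.replicons:
            fh.write(f"##sequence-region {rep.replicon_id} 1 {len(rep)}\n")
            fh.write(f"#!topology {rep.replicon_id} {rep.topology}\n")
        for g in annotation.genes:
            fh.write(
                "\t".join(
                    [
                        g.replicon_id, "cdgscan", "CDS", str(g.start),
                        str(g.end), ".", g.strand, "0",
                        f"ID={g.gene_id};product={g.product}",
                    ]
                )
                + "\n"
            )
    return paths


# --- count tables ------------------------------------------------------------

def make_counts(
    seed,
    gene_effects: dict[str, float] | list[float],
    condition_effects: dict[str, float] | list[float],
    interaction_effects: np.ndarray | None = None,
    r: int = 3,
    dispersion: float = 0.05,
    grand_log_mean: float = np.log(100.0),
    gene_length_bp: int = 1000,
) -> tuple[CountTable, list[TruthRecord]]:
    """Negative-binomial count table with known two-factor structure.

    Cell means are exp(grand + gene_i + condition_j + interaction_ij);
    the design is balanced with *r* replicate libraries per condition;
    counts are NB with variance mu + dispersion * mu^2.
    """
    if r < 2:
        raise ValueError("need r >= 2 replicates")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = _rng(seed)
    if not isinstance(gene_effects, dict):
        gene_effects = {f"g{i + 1}": float(v) for i, v in enumerate(gene_effects)}
    if not isinstance(condition_effects, dict):
        condition_effects = {
            f"c{j + 1}": float(v) for j, v in enumerate(condition_effects)
        }
    genes = list(gene_effects)
    conds = list(condition_effects)
    inter = (
        np.zeros((len(genes), len(conds)))
        if interaction_effects is None
        else np.asarray(interaction_effects, dtype=float)
    )
    if inter.shape != (len(genes), len(conds)):
        raise ValueError("interaction_effects must be genes x conditions")

    libraries = [f"{c}_r{k + 1}" for c in conds for k in range(r)]
    lib_cond = pd.Series({lib: lib.rsplit("_r", 1)[0] for lib in libraries})
    data = np.zeros((len(genes), len(libraries)), dtype=int)
    truths = []
    nb_n = 1.0 / dispersion
    for i, g in enumerate(genes):
        for j, c in enumerate(conds):
            mu = float(
                np.exp(grand_log_mean + gene_effects[g] + condition_effects[c] + inter[i, j])
            )
            p = nb_n / (nb_n + mu)
            col0 = j * r
            data[i, col0 : col0 + r] = rng.negative_binomial(nb_n, p, size=r)
            truths.append(
                TruthRecord(
                    object_id=f"{g}:{c}", kind="counts-cell", cell_mean=mu
                )
            )
    counts = pd.DataFrame(data, index=genes, columns=libraries)
    table = CountTable(
        counts=counts,
        gene_lengths=pd.Series(gene_length_bp, index=genes),
        library_conditions=lib_cond,
    )
    return table, truths
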