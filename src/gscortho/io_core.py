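"""Core data model and I/O: annotated genomes, phylogeny config, call matrices.

Internal coordinates are 0-based, half-open. All on-disk annotation follows
GFF3's 1-based inclusive convention; conversion happens only at the I/O
boundary. One representative protein is kept per gene (the longest CDS).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from ._codons import translate_cds

logger = logging.getLogger("gscortho")

# ---------------------------------------------------------------------------
# Presence/absence call vocabulary
# ---------------------------------------------------------------------------

PRESENT_RBBH = "PRESENT_RBBH"
PRESENT_RESCUED = "PRESENT_RESCUED"
PRESENT = "PRESENT"  # generic call from imported external predictions
ABSENT_PRELIM = "ABSENT_PRELIM"
ABSENT_SYNTENY = "ABSENT_SYNTENY"
ABSENT_SYNTENY_VALIDATED = "ABSENT_SYNTENY_VALIDATED"
ABSENT_NO_SYNTENY = "ABSENT_NO_SYNTENY"
ABSENT = "ABSENT"  # generic absence from imported external predictions
UNRESOLVED_CONTIG_END = "UNRESOLVED_CONTIG_END"

CALL_VOCABULARY = frozenset(
    {
        PRESENT_RBBH,
        PRESENT_RESCUED,
        PRESENT,
        ABSENT_PRELIM,
        ABSENT_SYNTENY,
        ABSENT_SYNTENY_VALIDATED,
        ABSENT_NO_SYNTENY,
        ABSENT,
        UNRESOLVED_CONTIG_END,
    }
)
PRESENT_CALLS = frozenset({PRESENT_RBBH, PRESENT_RESCUED, PRESENT})
ABSENT_CALLS = frozenset(
    {ABSENT_PRELIM, ABSENT_SYNTENY, ABSENT_SYNTENY_VALIDATED, ABSENT_NO_SYNTENY, ABSENT}
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """A gene with its spliced CDS and representative protein.

    ``start``/``end`` delimit the gene span on its contig (0-based,
    half-open). ``cds_sequence`` is the spliced coding-strand CDS.
    ``protein_sequence`` is None for untranslatable genes (kept for
    nucleotide-level searches, excluded from protein searches).
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    cds_sequence: str
    protein_sequence: str | None
    untranslatable: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: span start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


@dataclass
class AnnotatedGenome:
    """Contig sequences plus the ordered gene models annotated on them."""

    species_id: str
    contigs: dict[str, str]
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            if g.contig_id not in self.contigs:
                raise ValueError(
                    f"gene {g.gene_id!r} references unknown contig {g.contig_id!r}"
                )
            if g.end > len(self.contigs[g.contig_id]):
                raise ValueError(f"gene {g.gene_id!r} extends past its contig end")
        self.genes.sort(key=lambda g: (g.contig_id, g.start))
        self._by_id = {g.gene_id: g for g in self.genes}

    def gene(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def genes_on_contig(self, contig_id: str) -> list[GeneModel]:
        return [g for g in self.genes if g.contig_id == contig_id]

    def proteome(self) -> dict[str, str]:
        """gene_id -> representative protein, translatable genes only."""
        return {
            g.gene_id: g.protein_sequence
            for g in self.genes
            if g.protein_sequence
        }


@dataclass
class PhylogenyConfig:
    """Species set with divergence times (My) from the reference species."""

    reference_species: str
    divergence_my: dict[str, float]
    clade_tree: str | None = None

    def __post_init__(self) -> None:
        if self.reference_species not in self.divergence_my:
            raise ValueError("reference species missing from divergence table")
        if self.divergence_my[self.reference_species] != 0:
            raise ValueError("reference species must have divergence 0")
        for sp, my in self.divergence_my.items():
            if my < 0:
                raise ValueError(f"negative divergence time for {sp!r}")

    @property
    def species(self) -> list[str]:
        return sorted(self.divergence_my)

    def targets(self) -> list[str]:
        return sorted(s for s in self.divergence_my if s != self.reference_species)


@dataclass
class GeneAnnotationTable:
    """Functional categories and RNAi defect types for the focal gene set.

    A gene may belong to several functional categories (semicolon separated
    on disk); it is counted once in each.
    """

    table: pd.DataFrame  # columns: gene_id, functional_categories, defect_type, is_focal

    def __post_init__(self) -> None:
        focal = self.table[self.table["is_focal"]]
        if focal["gene_id"].duplicated().any():
            dupes = focal.loc[focal["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"focal genes listed more than once: {dupes}")

    def categories_of(self, gene_id: str) -> list[str]:
        row = self.table[self.table["gene_id"] == gene_id]
        if row.empty:
            return []
        return list(row.iloc[0]["functional_categories"])

    @property
    def focal_genes(self) -> list[str]:
        return self.table.loc[self.table["is_focal"], "gene_id"].tolist()


@dataclass
class PresenceMatrix:
    """Gene x species grid of ortholog calls with per-cell provenance.

    ``calls`` has genes as the index, species as columns, values drawn from
    the call vocabulary. ``caller`` records the strategy that produced the
    matrix (``ensembl_import``, ``naive``, ``rbbh`` or ``rbbh_synteny``).
    """

    calls: pd.DataFrame
    caller: str = "rbbh_synteny"
    provenance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        bad = set(self.calls.to_numpy().ravel()) - CALL_VOCABULARY
        if bad:
            raise ValueError(f"unknown call tokens: {sorted(bad)}")
        if self.calls.isna().any().any():
            raise ValueError("presence matrix has missing cells")

    @property
    def genes(self) -> list[str]:
        return list(self.calls.index)

    @property
    def species(self) -> list[str]:
        return list(self.calls.columns)

    def status(self, gene_id: str, species_id: str) -> str:
        return self.calls.at[gene_id, species_id]

    def equals(self, other: "PresenceMatrix") -> bool:
        return self.calls.equals(other.calls)


# ---------------------------------------------------------------------------
# GFF3 + FASTA reading
# ---------------------------------------------------------------------------


def _representative_cds(db: gffutils.FeatureDB, gene) -> list | None:
    """CDS feature list of the longest-CDS transcript, or None."""
    candidates = []
    mrnas = list(db.children(gene, featuretype=("mRNA", "transcript")))
    if mrnas:
        for mrna in sorted(mrnas, key=lambda m: m.id):
            cds = list(db.children(mrna, featuretype="CDS", order_by="start"))
            if cds:
                candidates.append((sum(c.end - c.start + 1 for c in cds), mrna.id, cds))
    else:
        cds = list(db.children(gene, featuretype="CDS", order_by="start"))
        if cds:
            candidates.append((sum(c.end - c.start + 1 for c in cds), gene.id, cds))
    if not candidates:
        return None
    candidates.sort(key=lambda t: (-t[0], t[1]))
    return candidates[0][2]


def read_annotated_genome(
    fasta_path: str | Path, gff3_path: str | Path, species_id: str | None = None
) -> AnnotatedGenome:
    """Read a FASTA + GFF3 pair into an :class:`AnnotatedGenome`.

    GFF3 1-based inclusive coordinates are converted to the internal 0-based
    half-open convention. Minus-strand CDS are reverse-complemented and
    assembled in translation order; the phase of the first coding segment is
    honoured. Genes whose spliced CDS length is not a multiple of 3 are kept
    but marked untranslatable (a warning is emitted).

    Raises ``ValueError`` if the GFF3 references a contig absent from the
    FASTA.
    """
    fasta_path, gff3_path = Path(fasta_path), Path(gff3_path)
    contigs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        if gene.seqid not in contigs:
            raise ValueError(
                f"GFF3 feature {gene.id!r} references contig {gene.seqid!r} "
                f"not present in {fasta_path.name}"
            )
        cds_feats = _representative_cds(db, gene)
        if cds_feats is None:
            logger.warning("gene %s has no CDS; skipped", gene.id)
            continue
        contig_seq = contigs[gene.seqid]
        parts = [contig_seq[c.start - 1 : c.end] for c in cds_feats]
        if gene.strand == "-":
            spliced = str(Seq("".join(parts)).reverse_complement())
            first = cds_feats[-1]  # translation order: right-most segment first
        else:
            spliced = "".join(parts)
            first = cds_feats[0]
        phase = int(first.frame) if first.frame not in (None, ".", "") else 0
        spliced = spliced[phase:]

        untranslatable = False
        protein: str | None = None
        if len(spliced) % 3:
            warnings.warn(
                f"gene {gene.id}: CDS length not a multiple of 3; marked untranslatable"
            )
            untranslatable = True
        else:
            aa = translate_cds(spliced)
            aa = aa[:-1] if aa.endswith("*") else aa
            if "*" in aa:
                warnings.warn(
                    f"gene {gene.id}: internal stop codon; marked untranslatable"
                )
                untranslatable = True
            else:
                protein = aa
        genes.append(
            GeneModel(
                gene_id=gene.id,
                contig_id=gene.seqid,
                start=gene.start - 1,
                end=gene.end,
                strand=gene.strand if gene.strand in "+-" else "+",
                cds_sequence=spliced,
                protein_sequence=protein,
                untranslatable=untranslatable,
            )
        )
    genome = AnnotatedGenome(
        species_id=species_id or fasta_path.stem, contigs=contigs, genes=genes
    )
    logger.info(
        "read %s: %d contigs, %d genes (%d untranslatable)",
        genome.species_id,
        len(contigs),
        len(genes),
        sum(g.untranslatable for g in genes),
    )
    return genome


def write_annotated_genome(
    genome: AnnotatedGenome, fasta_path: str | Path, gff3_path: str | Path
) -> None:
    """Write FASTA + GFF3 for a genome whose genes are single-exon.

    Internal 0-based half-open spans are converted back to GFF3 1-based
    inclusive coordinates; a read -> write round trip preserves them exactly.
    """
    with open(fasta_path, "w") as fh:
        for cid in sorted(genome.contigs):
            fh.write(f">{cid}\n")
            seq = genome.contigs[cid]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genome.genes:
            start1, end1 = g.start + 1, g.end
            common = f"{g.contig_id}\tgscortho\t"
            fh.write(
                f"{common}gene\t{start1}\t{end1}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            fh.write(
                f"{common}mRNA\t{start1}\t{end1}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            fh.write(
                f"{common}CDS\t{start1}\t{end1}\t.\t{g.strand}\t0\t"
                f"ID={g.gene_id}.cds;Parent={g.gene_id}.t1\n"
            )


# ---------------------------------------------------------------------------
# Phylogeny / annotation / matrix I/O
# ---------------------------------------------------------------------------


def load_phylogeny_config(path: str | Path) -> PhylogenyConfig:
    """Load species divergence times from JSON or two-column TSV.

    The JSON form is ``{"reference_species": ..., "divergence_my": {...},
    "clade_tree": optional newick}``. The TSV form has columns ``species``
    and ``divergence_my``; the reference is the single species at 0 My.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        return PhylogenyConfig(
            reference_species=data["reference_species"],
            divergence_my={k: float(v) for k, v in data["divergence_my"].items()},
            clade_tree=data.get("clade_tree"),
        )
    df = pd.read_csv(path, sep="\t")
    if df["species"].duplicated().any():
        raise ValueError("duplicate species in phylogeny table")
    div = dict(zip(df["species"], df["divergence_my"].astype(float)))
    zeros = [s for s, my in div.items() if my == 0]
    if len(zeros) != 1:
        raise ValueError("phylogeny table must contain exactly one species at 0 My")
    return PhylogenyConfig(reference_species=zeros[0], divergence_my=div)


def load_gene_annotations(path: str | Path) -> GeneAnnotationTable:
    """Read the gene list TSV: gene_id, functional_category, defect_type, is_focal.

    ``functional_category`` may hold several categories separated by ';'.
    Missing category/defect fields are allowed and read as empty.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    cats = [
        [c.strip() for c in cell.split(";") if c.strip()]
        for cell in df.get("functional_category", pd.Series([""] * len(df)))
    ]
    focal_raw = df.get("is_focal_gsc_gene", pd.Series(["1"] * len(df)))
    table = pd.DataFrame(
        {
            "gene_id": df["gene_id"],
            "functional_categories": cats,
            "defect_type": df.get("defect_type", pd.Series([""] * len(df))),
            "is_focal": focal_raw.astype(str).str.lower().isin({"1", "true", "yes"}),
        }
    )
    return GeneAnnotationTable(table)


def write_presence_matrix(matrix: PresenceMatrix, path: str | Path) -> None:
    """Write a presence matrix as TSV, genes as rows and species as columns."""
    matrix.calls.to_csv(path, sep="\t", index_label="gene_id")


def read_presence_matrix(path: str | Path, caller: str = "rbbh_synteny") -> PresenceMatrix:
    """Read a presence matrix TSV; rejects ragged rows and unknown tokens."""
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines() if ln]
    header = lines[0].split("\t")
    ncol = len(header)
    rows = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        if len(cells) != ncol:
            raise ValueError(f"ragged row in presence matrix: {cells[0]!r}")
        rows.append(cells)
    df = pd.DataFrame(rows, columns=header).set_index(header[0])
    df.index.name = "gene_id"
    return PresenceMatrix(calls=df, caller=caller)
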