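"""Forge annotated genome clades, fertility counts and codon sets with known truth.

The forge descends a reference genome down a star phylogeny: conserved genes
accumulate amino-acid substitutions at a clock rate (with a crude
exchangeability bias), synonymous changes accrue independently at a faster
rate, and intergenic sequence drifts with substitutions and small indels.
Planted events create the situations the ortholog pipeline must resolve:

* ``loss``      - gene body excised cleanly (plus 50 bp margins), flanks intact
* ``split``     - CDS cut mid-gene across two contigs, gene left unannotated
* ``contig_end``- contig breaks at the locus, only a CDS stub survives
* ``diverged_extreme`` - protein identity pushed very low while nucleotide
  similarity stays detectable; left unannotated (annotation pipelines miss
  such genes), so only a nucleotide-level rescue can find it

Every (gene, species) pair receives exactly one truth-ledger entry with the
final call the pipeline is expected to make.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import io_core
from ._codons import (
    AA_GROUP_OF,
    AMINO_ACIDS,
    CODONS_BY_AA,
    GENETIC_CODE,
    NUCLEOTIDES,
    STOP_CODONS,
    nonsynonymous_neighbors,
    synonymous_neighbors,
    translate_cds,
)
from .io_core import AnnotatedGenome, GeneModel, PhylogenyConfig

EVENT_KINDS = ("conserved", "loss", "split", "contig_end", "diverged_extreme")

EXPECTED_CALL = {
    "conserved": io_core.PRESENT_RBBH,
    "loss": io_core.ABSENT_SYNTENY,
    "split": io_core.PRESENT_RESCUED,
    "contig_end": io_core.UNRESOLVED_CONTIG_END,
    "diverged_extreme": io_core.PRESENT_RESCUED,
}

DEFAULT_DIVERGENCE_MODEL: dict[str, float] = {
    # Amino-acid substitution clock: identity ~ exp(-rate * MY); 0.005/My
    # gives ~70% protein identity at 70 My, the depth of the clade modelled.
    "aa_rate_per_my": 0.005,
    # Synonymous-site changes accrue ~3x faster than amino-acid changes.
    "syn_factor": 3.0,
    # Intergenic nucleotide substitution rate per My.
    "spacer_rate_per_my": 0.004,
    # Small (1-5 bp) intergenic indels per bp per My.
    "indel_rate_per_my": 2e-5,
}

LOSS_MARGIN_BP = 50  # excised with the gene body, mirroring clean deletions


@dataclass(frozen=True)
class PlantedEvent:
    gene_id: str
    species_id: str
    kind: str  # one of EVENT_KINDS other than "conserved"

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS or self.kind == "conserved":
            raise ValueError(f"unknown planted event kind {self.kind!r}")


@dataclass
class TruthLedger:
    """Per (gene, species) planted event and the final call it implies."""

    table: pd.DataFrame  # columns: gene_id, species_id, event, expected_call

    def __post_init__(self) -> None:
        if self.table.duplicated(["gene_id", "species_id"]).any():
            raise ValueError("truth ledger has duplicate (gene, species) entries")

    def event(self, gene_id: str, species_id: str) -> str:
        row = self.table[
            (self.table.gene_id == gene_id) & (self.table.species_id == species_id)
        ]
        return row.iloc[0]["event"]

    def expected_call(self, gene_id: str, species_id: str) -> str:
        row = self.table[
            (self.table.gene_id == gene_id) & (self.table.species_id == species_id)
        ]
        return row.iloc[0]["expected_call"]

    def expected_matrix(self, reference_species: str | None = None) -> pd.DataFrame:
        wide = self.table.pivot(
            index="gene_id", columns="species_id", values="expected_call"
        )
        if reference_species is not None:
            wide[reference_species] = io_core.PRESENT_RBBH
        return wide.sort_index()[sorted(wide.columns)]


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------


def _random_codon(rng: np.random.Generator) -> str:
    while True:
        codon = "".join(rng.choice(list(NUCLEOTIDES), size=3))
        if codon not in STOP_CODONS:
            return codon


def _random_spacer(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(NUCLEOTIDES), size=length))


def random_reference(
    n_genes: int = 40,
    n_contigs: int = 2,
    gene_length_codons: tuple[int, int] = (60, 120),
    spacer_bp: int = 300,
    seed: int = 0,
    species_id: str = "reference",
) -> AnnotatedGenome:
    """Build a toy reference genome with evenly spaced single-exon genes."""
    if n_genes < 1 or n_contigs < 1:
        raise ValueError("need at least one gene and one contig")
    rng = np.random.default_rng(seed)
    per_contig = [n_genes // n_contigs] * n_contigs
    for i in range(n_genes % n_contigs):
        per_contig[i] += 1
    contigs: dict[str, str] = {}
    genes: list[GeneModel] = []
    gene_no = 0
    for ci, count in enumerate(per_contig):
        cid = f"ctg{ci + 1}"
        parts = [_random_spacer(rng, spacer_bp)]
        pos = spacer_bp
        for _ in range(count):
            gene_no += 1
            n_codons = int(rng.integers(gene_length_codons[0], gene_length_codons[1] + 1))
            body = "".join(_random_codon(rng) for _ in range(n_codons - 2))
            stop = str(rng.choice(sorted(STOP_CODONS)))
            cds = "ATG" + body + stop
            strand = "+" if rng.random() < 0.5 else "-"
            block = cds if strand == "+" else str(Seq(cds).reverse_complement())
            genes.append(
                GeneModel(
                    gene_id=f"g{gene_no:03d}",
                    contig_id=cid,
                    start=pos,
                    end=pos + len(block),
                    strand=strand,
                    cds_sequence=cds,
                    protein_sequence=translate_cds(cds)[:-1],
                )
            )
            parts.append(block)
            pos += len(block)
            spacer = _random_spacer(rng, spacer_bp)
            parts.append(spacer)
            pos += spacer_bp
        contigs[cid] = "".join(parts)
    return AnnotatedGenome(species_id=species_id, contigs=contigs, genes=genes)


# ---------------------------------------------------------------------------
# Sequence divergence
# ---------------------------------------------------------------------------


def _biased_replacement_aa(aa: str, rng: np.random.Generator) -> str:
    group = [x for x in AA_GROUP_OF.get(aa, "") if x != aa]
    if group and rng.random() < 0.7:
        return str(rng.choice(group))
    others = [x for x in AMINO_ACIDS if x != aa]
    return str(rng.choice(others))


def _mutate_cds(
    cds: str, p_aa: float, syn_factor: float, rng: np.random.Generator
) -> str:
    """Substitute amino acids at rate p_aa and synonymous sites faster."""
    p_syn = min(1.0, syn_factor * p_aa)
    out = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon in STOP_CODONS:
            out.append(codon)
            continue
        if rng.random() < p_aa:
            new_aa = _biased_replacement_aa(GENETIC_CODE[codon], rng)
            codon = str(rng.choice(CODONS_BY_AA[new_aa]))
        elif rng.random() < p_syn:
            alts = synonymous_neighbors(codon)
            if alts:
                codon = str(rng.choice(alts))
        out.append(codon)
    return "".join(out)


def _extreme_cds(cds: str, rng: np.random.Generator, p_change: float = 0.9) -> str:
    """Drive protein identity very low with one-nucleotide codon steps.

    Single-nucleotide nonsynonymous steps keep ~2/3 nucleotide identity per
    codon, emulating a gene whose protein has drifted beyond protein-search
    detection while its DNA remains recognisably similar.
    """
    out = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon not in STOP_CODONS and rng.random() < p_change:
            alts = nonsynonymous_neighbors(codon) or synonymous_neighbors(codon)
            if alts:
                codon = str(rng.choice(alts))
        out.append(codon)
    return "".join(out)


def _mutate_spacer(
    seq: str, p_nt: float, indel_rate: float, rng: np.random.Generator
) -> str:
    out = []
    i = 0
    nts = list(NUCLEOTIDES)
    while i < len(seq):
        r = rng.random()
        if indel_rate > 0 and r < indel_rate:
            size = int(rng.integers(1, 6))
            if rng.random() < 0.5:
                i += size  # deletion
            else:
                out.append("".join(rng.choice(nts, size=size)))
            continue
        base = seq[i]
        if rng.random() < p_nt:
            base = str(rng.choice([n for n in nts if n != seq[i]]))
        out.append(base)
        i += 1
    return "".join(out)


# ---------------------------------------------------------------------------
# Clade forging
# ---------------------------------------------------------------------------


class _ContigAssembler:
    """Accumulates sequence parts and flushes contigs on planted breaks."""

    def __init__(self, species_id: str, ref_contig_id: str):
        self.species_id = species_id
        self.ref_contig_id = ref_contig_id
        self.part = 0
        self.pieces: list[str] = []
        self.pos = 0
        self.contigs: dict[str, str] = {}
        self.genes: list[GeneModel] = []
        self._pending: list[tuple[str, int, int, str, str]] = []

    @property
    def contig_name(self) -> str:
        return f"{self.ref_contig_id}_p{self.part + 1}"

    def append(self, seq: str) -> None:
        self.pieces.append(seq)
        self.pos += len(seq)

    def add_gene(self, gene: GeneModel, block: str) -> None:
        self._pending.append(
            (gene.gene_id, self.pos, self.pos + len(block), gene.strand, block)
        )
        self.append(block)

    def break_contig(self) -> None:
        self.flush()

    def flush(self) -> None:
        seq = "".join(self.pieces)
        if seq:
            name = self.contig_name
            self.contigs[name] = seq
            for gid, start, end, strand, block in self._pending:
                cds = block if strand == "+" else str(Seq(block).reverse_complement())
                protein = translate_cds(cds)
                protein = protein[:-1] if protein.endswith("*") else protein
                untranslatable = "*" in protein
                self.genes.append(
                    GeneModel(
                        gene_id=gid,
                        contig_id=name,
                        start=start,
                        end=end,
                        strand=strand,
                        cds_sequence=cds,
                        protein_sequence=None if untranslatable else protein,
                        untranslatable=untranslatable,
                    )
                )
        self.part += 1
        self.pieces, self.pos, self._pending = [], 0, []


def _contig_layout(
    reference: AnnotatedGenome, contig_id: str
) -> tuple[list[GeneModel], list[str]]:
    seq = reference.contigs[contig_id]
    genes = reference.genes_on_contig(contig_id)
    spacers = []
    prev = 0
    for g in genes:
        spacers.append(seq[prev : g.start])
        prev = g.end
    spacers.append(seq[prev:])
    return genes, spacers


def forge_clade(
    reference: AnnotatedGenome,
    phylo: PhylogenyConfig,
    divergence_model: Mapping[str, float] | None = None,
    events: Iterable[PlantedEvent] = (),
    seed: int = 0,
) -> tuple[dict[str, AnnotatedGenome], TruthLedger]:
    """Descend ``reference`` into one genome per non-reference species.

    Returns the forged genomes and a :class:`TruthLedger` covering every
    (reference gene, forged species) pair. Same seed, same inputs ->
    byte-identical genomes.
    """
    model = dict(DEFAULT_DIVERGENCE_MODEL)
    if divergence_model:
        model.update(divergence_model)
    events = list(events)
    targets = phylo.targets()
    by_species: dict[str, dict[str, str]] = {s: {} for s in targets}
    for ev in events:
        if ev.species_id not in by_species:
            raise ValueError(f"event references unknown species {ev.species_id!r}")
        if ev.gene_id not in reference:
            raise ValueError(f"event references unknown gene {ev.gene_id!r}")
        if ev.gene_id in by_species[ev.species_id]:
            raise ValueError(
                f"multiple events for gene {ev.gene_id!r} in {ev.species_id!r}"
            )
        gene = reference.gene(ev.gene_id)
        siblings = reference.genes_on_contig(gene.contig_id)
        if gene.gene_id in (siblings[0].gene_id, siblings[-1].gene_id):
            # edge genes lack flanking anchors on one side, so the expected
            # final call would not be well-defined
            raise ValueError(
                f"planted event on {ev.gene_id!r}: events must target interior "
                "genes (at least one flanking gene on each side)"
            )
        by_species[ev.species_id][ev.gene_id] = ev.kind

    max_my = max(phylo.divergence_my[s] for s in targets) if targets else 0.0
    if math.exp(-model["aa_rate_per_my"] * max_my) < 0.05:
        raise ValueError(
            "requested divergence drives expected protein identity below 5%; "
            "this regime is untestable"
        )

    seeds = np.random.SeedSequence(seed).spawn(len(targets))
    genomes: dict[str, AnnotatedGenome] = {}
    ledger_rows: list[dict[str, str]] = []

    for sp, sub_seed in zip(targets, seeds):
        rng = np.random.default_rng(sub_seed)
        my = phylo.divergence_my[sp]
        p_aa = 1.0 - math.exp(-model["aa_rate_per_my"] * my)
        p_nt = 1.0 - math.exp(-model["spacer_rate_per_my"] * my)
        indel = model["indel_rate_per_my"] * my
        sp_events = by_species[sp]

        contigs: dict[str, str] = {}
        gene_models: list[GeneModel] = []
        for contig_id in sorted(reference.contigs):
            genes, spacers = _contig_layout(reference, contig_id)
            asm = _ContigAssembler(sp, contig_id)
            asm.append(_mutate_spacer(spacers[0], p_nt, indel, rng))
            for i, g in enumerate(genes):
                kind = sp_events.get(g.gene_id, "conserved")
                spacer_after = _mutate_spacer(spacers[i + 1], p_nt, indel, rng)
                if kind == "loss":
                    # excise gene body plus margins; flanks stay adjacent
                    if asm.pieces and len(asm.pieces[-1]) > LOSS_MARGIN_BP:
                        tail = asm.pieces.pop()
                        asm.pos -= len(tail)
                        asm.append(tail[:-LOSS_MARGIN_BP])
                    asm.append(spacer_after[LOSS_MARGIN_BP:])
                    continue
                mutated = (
                    _extreme_cds(g.cds_sequence, rng)
                    if kind == "diverged_extreme"
                    else _mutate_cds(g.cds_sequence, p_aa, model["syn_factor"], rng)
                )
                block = (
                    mutated
                    if g.strand == "+"
                    else str(Seq(mutated).reverse_complement())
                )
                if kind == "split":
                    half = len(block) // 2
                    asm.append(block[:half])
                    asm.break_contig()
                    asm.append(block[half:])
                    asm.append(spacer_after)
                elif kind == "contig_end":
                    stub = block[: max(12, int(0.3 * len(block)))]
                    asm.append(stub)
                    asm.break_contig()
                    asm.append(spacer_after)
                elif kind == "diverged_extreme":
                    asm.append(block)  # present in sequence, not annotated
                    asm.append(spacer_after)
                else:
                    asm.add_gene(g, block)
                    asm.append(spacer_after)
            asm.flush()
            contigs.update(asm.contigs)
            gene_models.extend(asm.genes)

        genomes[sp] = AnnotatedGenome(
            species_id=sp, contigs=contigs, genes=gene_models
        )
        for g in reference.genes:
            kind = sp_events.get(g.gene_id, "conserved")
            ledger_rows.append(
                {
                    "gene_id": g.gene_id,
                    "species_id": sp,
                    "event": kind,
                    "expected_call": EXPECTED_CALL[kind],
                }
            )

    ledger = TruthLedger(pd.DataFrame(ledger_rows))
    return genomes, ledger


def write_forged_clade(
    genomes: Mapping[str, AnnotatedGenome], ledger: TruthLedger, out_dir: str | Path
) -> None:
    """Write one FASTA+GFF3 pair per species plus the truth ledger TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sp in sorted(genomes):
        io_core.write_annotated_genome(
            genomes[sp], out / f"{sp}.fasta", out / f"{sp}.gff3"
        )
    ledger.table.to_csv(out / "truth_ledger.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Fertility counts
# ---------------------------------------------------------------------------

STERILE = "sterile"


def simulate_fertility(
    group_params: Mapping[str, object],
    n_per_group: int | Mapping[str, int] = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw adult progeny counts per fly for each genotype.

    ``group_params`` maps genotype label -> ``(mean, dispersion)`` for a
    negative-binomial draw, or the string ``"sterile"`` for an all-zero
    class (the completely sterile null phenotype). Groups with identical
    parameters and the same seed receive identical draws regardless of
    label. Returns a tidy frame with columns fly_id, genotype, progeny.
    """
    if len(group_params) < 2:
        raise ValueError("need at least two genotypes")
    rows = []
    for genotype in sorted(group_params):
        params = group_params[genotype]
        n = n_per_group if isinstance(n_per_group, int) else n_per_group[genotype]
        if n < 2:
            raise ValueError(f"need n >= 2 per group, got {n} for {genotype!r}")
        if params == STERILE:
            counts = np.zeros(n, dtype=int)
        else:
            mean, dispersion = params  # type: ignore[misc]
            if dispersion <= 0:
                raise ValueError(f"dispersion must be > 0 for {genotype!r}")
            if mean < 0:
                raise ValueError(f"mean must be >= 0 for {genotype!r}")
            if mean == 0:
                counts = np.zeros(n, dtype=int)
            else:
                rng = np.random.default_rng(
                    [seed, int(round(mean * 1e6)) % 2**31,
                     int(round(dispersion * 1e6)) % 2**31, n]
                )
                p = dispersion / (dispersion + mean)
                counts = rng.negative_binomial(dispersion, p, size=n)
        for i, c in enumerate(counts):
            rows.append(
                {"fly_id": f"{genotype}_{i + 1}", "genotype": genotype, "progeny": int(c)}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Codon sets with planted change counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedChanges:
    """Planted fixed / polymorphic change counts for a simulated codon set.

    Polymorphic changes are given as minor-allele frequencies, one entry per
    planted polymorphism; each must be representable as k/n with
    1 <= k <= n/2 for the requested ingroup size.
    """

    fixed_nonsyn: int = 0
    fixed_syn: int = 0
    poly_nonsyn: tuple[float, ...] = ()
    poly_syn: tuple[float, ...] = ()

    @property
    def n_sites(self) -> int:
        return (
            self.fixed_nonsyn
            + self.fixed_syn
            + len(self.poly_nonsyn)
            + len(self.poly_syn)
        )


@dataclass
class SimulatedCodonSet:
    """n ingroup sequences + ancestor + outgroup with known change counts."""

    ingroup: list[str]
    ancestor: str
    outgroup: str
    truth: dict[str, float]  # Dn, Ds, Pn, Ps as planted

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.ingroup} | {len(self.ancestor), len(self.outgroup)}
        if len(lengths) != 1 or next(iter(lengths)) % 3:
            raise ValueError("sequences must share a length divisible by 3")


def _carriers(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    return rng.permutation(n)[:k]


def simulate_codon_set(
    length_codons: int,
    n_ingroup: int,
    planted: PlantedChanges,
    seed: int = 0,
) -> SimulatedCodonSet:
    """Build a codon alignment in which the planted 2x2 is exactly recoverable.

    Every planted change is a single-nucleotide codon step at its own codon
    site, so a downstream tabulation with frequency cutoff 0 returns the
    planted (Dn, Ds, Pn, Ps) exactly. Raises ``ValueError`` when a requested
    frequency is not representable as k/n or the sites do not fit.
    """
    if planted.n_sites > length_codons:
        raise ValueError("more planted changes than codon sites")
    if n_ingroup < 2:
        raise ValueError("need at least 2 ingroup sequences")
    for f in tuple(planted.poly_nonsyn) + tuple(planted.poly_syn):
        k = f * n_ingroup
        if abs(k - round(k)) > 1e-9 or not (1 <= round(k) <= n_ingroup - 1):
            raise ValueError(f"frequency {f} not representable as k/{n_ingroup}")
        if f > 0.5:
            raise ValueError(f"minor-allele frequency {f} exceeds 0.5")

    rng = np.random.default_rng(seed)
    ancestor = [_random_codon(rng) for _ in range(length_codons)]
    sites = list(rng.permutation(length_codons)[: planted.n_sites])

    # (site, needs_synonymous_step, minor-allele frequency or None for fixed)
    plan: list[tuple[int, bool, float | None]] = []
    cursor = 0
    for need_syn, count in ((True, planted.fixed_syn), (False, planted.fixed_nonsyn)):
        for _ in range(count):
            plan.append((sites[cursor], need_syn, None))
            cursor += 1
    for need_syn, fs in ((True, planted.poly_syn), (False, planted.poly_nonsyn)):
        for f in fs:
            plan.append((sites[cursor], need_syn, f))
            cursor += 1

    # fix up the ancestor first (a codon may lack the required neighbour
    # type, e.g. ATG has no synonymous single-step neighbour), so the
    # ingroup copies below agree with the final ancestor everywhere
    for site, need_syn, _ in plan:
        while True:
            alts = (
                synonymous_neighbors(ancestor[site])
                if need_syn
                else nonsynonymous_neighbors(ancestor[site])
            )
            if alts:
                break
            ancestor[site] = _random_codon(rng)

    ingroup = [list(ancestor) for _ in range(n_ingroup)]
    for site, need_syn, f in plan:
        alts = (
            synonymous_neighbors(ancestor[site])
            if need_syn
            else nonsynonymous_neighbors(ancestor[site])
        )
        derived = str(rng.choice(alts))
        if f is None:
            for seq in ingroup:
                seq[site] = derived
        else:
            k = int(round(f * n_ingroup))
            for idx in _carriers(n_ingroup, k, rng):
                ingroup[idx][site] = derived

    return SimulatedCodonSet(
        ingroup=["".join(seq) for seq in ingroup],
        ancestor="".join(ancestor),
        outgroup="".join(ancestor),
        truth={
            "Dn": float(planted.fixed_nonsyn),
            "Ds": float(planted.fixed_syn),
            "Pn": float(len(planted.poly_nonsyn)),
            "Ps": float(len(planted.poly_syn)),
        },
    )
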