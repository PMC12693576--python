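"""Stage 2: syntenic re-evaluation of preliminary absences, plus validation.

Each preliminary absence is re-examined in the neighbourhood where the gene
ought to sit: up to three flanking genes per side are located in the target
by reciprocal protein search (anchors must hit back, so paralogs do not
anchor), the interval between the innermost located anchors is extracted,
and the missing gene is re-sought by nucleotide and translated-frame
alignment inside that block and on every contig carrying a located anchor.
Partial nucleotide hits on two or more contigs whose combined query
coverage reaches the split threshold rescue genes fragmented across
contigs. Finally an in-silico analogue of anchored PCR extracts the
inter-anchor "amplicon" and scans it for any trace of the focal gene.

Anchor order and orientation are not required to be conserved, only
co-location on one contig; local inversions therefore do not produce false
absences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from . import io_core
from .io_core import AnnotatedGenome, GeneModel, PresenceMatrix
from .rbbh import RBBHCall, Thresholds, _ReverseSearchCache, call_matrix, reciprocal_call
from .similarity_search import (
    DEFAULT_MIN_NUCLEOTIDE_SCORE,
    DEFAULT_MIN_PROTEIN_SCORE,
    LocalAlignment,
    NUCLEOTIDE_SCORING,
    PROTEIN_SCORING,
    Scoring,
    align_local,
)

logger = logging.getLogger("gscortho")


@dataclass(frozen=True)
class SyntenyConfig:
    """Tunables for the synteny stage.

    ``rescue_combined_coverage`` is the minimum (union) query coverage for a
    rescue, including split-gene rescues summed over contigs.
    ``max_amplicon`` mirrors the practical upper limit on PCR product size;
    larger inter-anchor gaps are reported NOT_VALIDATED.
    """

    k_anchors: int = 3
    min_nt_score: float = 30.0
    min_nt_identity: float = 60.0
    min_protein_score: float = DEFAULT_MIN_PROTEIN_SCORE
    rescue_combined_coverage: float = 0.8
    validation_min_coverage: float = 0.3
    max_amplicon: int = 50_000


# Rescue searches tolerate heavy synonymous-site divergence: a +1/-1 scheme
# keeps the expected per-base score positive down to ~50% identity, where
# the BLAST-like +2/-3 defaults fragment alignments.
RESCUE_NT_SCORING = Scoring(
    alphabet="nucleotide", gap_open=2, gap_extend=1, match=1, mismatch=-1
)


@dataclass
class AnchorSet:
    """Up to k reference genes per side of a focal gene, nearest first."""

    gene_id: str
    upstream: list[GeneModel]
    downstream: list[GeneModel]
    truncated: bool  # fewer than k anchors available on some side

    @property
    def is_empty(self) -> bool:
        return not self.upstream and not self.downstream


@dataclass
class LocatedAnchor:
    anchor_id: str
    contig_id: str
    start: int
    end: int
    strand: str


@dataclass
class SyntenyBlock:
    """Where the anchors landed in the target, and the interval between them."""

    species_id: str
    gene_id: str
    upstream_located: list[LocatedAnchor]
    downstream_located: list[LocatedAnchor]
    contig_id: str | None
    interval: tuple[int, int] | None
    retained_synteny: bool
    end_of_contig: bool
    anchors_split_across_contigs: bool

    @property
    def interval_length(self) -> int | None:
        return None if self.interval is None else self.interval[1] - self.interval[0]


@dataclass
class RescueEvidence:
    rescued: bool
    mode: str | None  # full | split | protein
    combined_query_coverage: float
    n_contigs_hit: int
    best_score: float


@dataclass
class AbsenceCall:
    gene_id: str
    species_id: str
    status: str
    evidence: dict = field(default_factory=dict)


@dataclass
class ValidationRecord:
    gene_id: str
    species_id: str
    status: str  # VALIDATED_ABSENT | CONTRADICTED | NOT_VALIDATED
    interval_length: int | None
    best_score: float = 0.0


VALIDATED_ABSENT = "VALIDATED_ABSENT"
CONTRADICTED = "CONTRADICTED"
NOT_VALIDATED = "NOT_VALIDATED"


# ---------------------------------------------------------------------------
# Anchors
# ---------------------------------------------------------------------------


def flanking_anchors(
    gene: GeneModel | str, reference: AnnotatedGenome, k: int = 3
) -> AnchorSet:
    """Up to ``k`` reference genes per side of ``gene``, nearest first.

    A gene close to its contig end yields fewer anchors and sets
    ``truncated``; a gene alone on its contig yields an empty set.
    """
    gid = gene if isinstance(gene, str) else gene.gene_id
    model = reference.gene(gid)
    neighbours = reference.genes_on_contig(model.contig_id)
    idx = next(i for i, g in enumerate(neighbours) if g.gene_id == gid)
    upstream = [neighbours[i] for i in range(idx - 1, max(-1, idx - 1 - k), -1)]
    downstream = neighbours[idx + 1 : idx + 1 + k]
    return AnchorSet(
        gene_id=gid,
        upstream=upstream,
        downstream=downstream,
        truncated=len(upstream) < k or len(downstream) < k,
    )


class _AnchorLocator:
    """Locates reference anchors in one target by cached reciprocal search."""

    def __init__(
        self,
        reference: AnnotatedGenome,
        target: AnnotatedGenome,
        thresholds: Thresholds,
    ):
        self.reference = reference
        self.target = target
        self.thresholds = thresholds
        self._proteome = target.proteome()
        self._reverse = _ReverseSearchCache(
            reference.proteome(), PROTEIN_SCORING, thresholds.min_score
        )
        self._cache: dict[str, LocatedAnchor | None] = {}

    def locate(self, anchor: GeneModel) -> LocatedAnchor | None:
        if anchor.gene_id in self._cache:
            return self._cache[anchor.gene_id]
        call = reciprocal_call(
            anchor,
            self.reference,
            self.target,
            self.thresholds,
            _reverse_cache=self._reverse,
            _target_proteome=self._proteome,
        )
        located = None
        if call.status == io_core.PRESENT_RBBH and call.forward_hit is not None:
            hit_gene = self.target.gene(call.forward_hit.subject_id)
            located = LocatedAnchor(
                anchor_id=anchor.gene_id,
                contig_id=hit_gene.contig_id,
                start=hit_gene.start,
                end=hit_gene.end,
                strand=hit_gene.strand,
            )
        self._cache[anchor.gene_id] = located
        return located


def locate_block(
    anchors: AnchorSet,
    target: AnnotatedGenome,
    reference: AnnotatedGenome,
    thresholds: Thresholds = Thresholds(),
    locator: _AnchorLocator | None = None,
) -> SyntenyBlock:
    """Seek each anchor reciprocally in the target and frame the focal locus.

    ``retained_synteny`` requires at least one located anchor on each side
    sharing a contig (so the inter-anchor interval is defined). Located
    anchors confined to different contigs flag a contig boundary at the
    locus instead.
    """
    if anchors.is_empty:
        return SyntenyBlock(
            species_id=target.species_id,
            gene_id=anchors.gene_id,
            upstream_located=[],
            downstream_located=[],
            contig_id=None,
            interval=None,
            retained_synteny=False,
            end_of_contig=False,
            anchors_split_across_contigs=False,
        )
    locator = locator or _AnchorLocator(reference, target, thresholds)
    up = [a for a in (locator.locate(g) for g in anchors.upstream) if a]
    down = [a for a in (locator.locate(g) for g in anchors.downstream) if a]

    contig = None
    interval = None
    # nearest-first ordering makes the first co-located pair the innermost one
    for u in up:
        for d in down:
            if u.contig_id == d.contig_id:
                contig = u.contig_id
                left, right = (u, d) if u.start <= d.start else (d, u)
                interval = (min(left.end, right.start), max(left.end, right.start))
                break
        if contig:
            break

    retained = contig is not None
    split = bool(up and down and not retained)
    return SyntenyBlock(
        species_id=target.species_id,
        gene_id=anchors.gene_id,
        upstream_located=up,
        downstream_located=down,
        contig_id=contig,
        interval=interval,
        retained_synteny=retained,
        end_of_contig=split,
        anchors_split_across_contigs=split,
    )


# ---------------------------------------------------------------------------
# Rescue
# ---------------------------------------------------------------------------


def _six_frame_proteins(seq: str) -> list[str]:
    frames = []
    rc = str(Seq(seq).reverse_complement())
    for src in (seq, rc):
        for off in range(3):
            sub = src[off : off + 3 * ((len(src) - off) // 3)]
            if len(sub) >= 3:
                frames.append(str(Seq(sub).translate()))
    return frames


def _union_coverage(spans: Iterable[tuple[int, int]], length: int) -> float:
    merged: list[list[int]] = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return sum(e - s for s, e in merged) / length if length else 0.0


def _nt_scan(cds: str, region: str, config: SyntenyConfig) -> LocalAlignment | None:
    """Best local nucleotide alignment of the CDS on either strand."""
    best: LocalAlignment | None = None
    for query in (cds, str(Seq(cds).reverse_complement())):
        al = align_local(query, region, RESCUE_NT_SCORING)
        if al.score < config.min_nt_score or al.percent_identity < config.min_nt_identity:
            continue
        if best is None or al.score > best.score:
            # report spans on the forward CDS for coverage bookkeeping
            if query is not cds:
                n = len(cds)
                al.query_span = (n - al.query_span[1], n - al.query_span[0])
            best = al
    return best


def _frame_scan(
    protein: str, region: str, config: SyntenyConfig
) -> LocalAlignment | None:
    """Best protein alignment against the six translated frames of a region."""
    best: LocalAlignment | None = None
    for frame in _six_frame_proteins(region):
        if len(frame) < 10:
            continue
        al = align_local(protein, frame, PROTEIN_SCORING)
        if al.score < config.min_protein_score:
            continue
        if best is None or al.score > best.score:
            best = al
    return best


def rescue_search(
    gene: GeneModel,
    block: SyntenyBlock,
    target: AnnotatedGenome,
    config: SyntenyConfig = SyntenyConfig(),
) -> RescueEvidence:
    """Re-seek a preliminarily absent gene inside its syntenic neighbourhood.

    Searches the gene CDS (nucleotide, both strands) and its product
    (against all six translated frames) over (a) the inter-anchor interval
    and (b) every contig carrying a located anchor. A single hit covering
    ``rescue_combined_coverage`` of the gene rescues it outright; partial
    hits on >= 2 contigs whose union coverage reaches the same threshold
    rescue a gene split across contigs.
    """
    regions: dict[str, str] = {}
    if block.interval is not None and block.contig_id is not None:
        lo, hi = block.interval
        if hi > lo:
            regions["__interval__"] = target.contigs[block.contig_id][lo:hi]
    for anchor in block.upstream_located + block.downstream_located:
        regions.setdefault(anchor.contig_id, target.contigs[anchor.contig_id])

    cds = gene.cds_sequence
    nt_spans: dict[str, list[tuple[int, int]]] = {}
    aa_spans: dict[str, list[tuple[int, int]]] = {}
    best_score = 0.0
    best_single_cov = 0.0
    for name in sorted(regions):
        seq = regions[name]
        if not seq:
            continue
        contig_name = (block.contig_id if name == "__interval__" else name) or name
        nt_hit = _nt_scan(cds, seq, config)
        if nt_hit is not None:
            best_score = max(best_score, nt_hit.score)
            best_single_cov = max(best_single_cov, nt_hit.query_coverage)
            nt_spans.setdefault(contig_name, []).append(nt_hit.query_span)
        if gene.protein_sequence:
            aa_hit = _frame_scan(gene.protein_sequence, seq, config)
            if aa_hit is not None:
                best_score = max(best_score, aa_hit.score)
                best_single_cov = max(best_single_cov, aa_hit.query_coverage)
                aa_spans.setdefault(contig_name, []).append(aa_hit.query_span)

    nt_cov = _union_coverage(
        [s for spans in nt_spans.values() for s in spans], len(cds)
    )
    aa_cov = _union_coverage(
        [s for spans in aa_spans.values() for s in spans],
        len(gene.protein_sequence) if gene.protein_sequence else 0,
    )
    combined = max(nt_cov, aa_cov)
    n_contigs = max(len(nt_spans), len(aa_spans))

    if best_single_cov >= config.rescue_combined_coverage:
        return RescueEvidence(True, "full", combined, n_contigs, best_score)
    if (
        combined >= config.rescue_combined_coverage
        and (len(nt_spans) >= 2 or len(aa_spans) >= 2)
    ):
        return RescueEvidence(True, "split", combined, n_contigs, best_score)
    return RescueEvidence(False, None, combined, n_contigs, best_score)


# ---------------------------------------------------------------------------
# Classification and validation
# ---------------------------------------------------------------------------


def classify_absence(
    prelim: RBBHCall, block: SyntenyBlock, rescue: RescueEvidence | None
) -> AbsenceCall:
    """Resolve one preliminary absence to exactly one final status."""
    if prelim.status != io_core.ABSENT_PRELIM:
        raise ValueError("classify_absence expects a preliminary absence")
    evidence = {
        "prelim_flag": prelim.flag,
        "retained_synteny": block.retained_synteny,
        "end_of_contig": block.end_of_contig,
        "rescue_mode": rescue.mode if rescue else None,
        "rescue_coverage": rescue.combined_query_coverage if rescue else 0.0,
    }
    if rescue is not None and rescue.rescued:
        status = io_core.PRESENT_RESCUED
    elif block.retained_synteny:
        status = io_core.ABSENT_SYNTENY
    elif block.end_of_contig:
        status = io_core.UNRESOLVED_CONTIG_END
    else:
        status = io_core.ABSENT_NO_SYNTENY
    return AbsenceCall(prelim.gene_id, prelim.species_id, status, evidence)


def in_silico_validation(
    gene: GeneModel,
    block: SyntenyBlock,
    target: AnnotatedGenome,
    config: SyntenyConfig = SyntenyConfig(),
) -> ValidationRecord:
    """In-silico analogue of anchored PCR across the inter-anchor interval.

    Extracts the "amplicon" between the innermost located anchors, then
    scans it by nucleotide alignment of the CDS and by protein alignment
    against all six translated frames. VALIDATED_ABSENT when nothing above
    threshold is found; a hit flags a contradiction with the absence call.
    Intervals longer than ``max_amplicon`` are NOT_VALIDATED.
    """
    if not block.retained_synteny or block.interval is None or block.contig_id is None:
        raise ValueError("validation requires a retained syntenic block")
    length = block.interval_length or 0
    if length > config.max_amplicon:
        return ValidationRecord(
            gene.gene_id, target.species_id, NOT_VALIDATED, length
        )
    lo, hi = block.interval
    amplicon = target.contigs[block.contig_id][lo:hi]
    best = 0.0
    if amplicon:
        nt_hit = _nt_scan(gene.cds_sequence, amplicon, config)
        if nt_hit is not None:
            best = max(best, nt_hit.score)
            if nt_hit.query_coverage >= config.validation_min_coverage:
                return ValidationRecord(
                    gene.gene_id, target.species_id, CONTRADICTED, length, nt_hit.score
                )
        if gene.protein_sequence:
            aa_hit = _frame_scan(gene.protein_sequence, amplicon, config)
            if aa_hit is not None:
                best = max(best, aa_hit.score)
                if aa_hit.query_coverage >= config.validation_min_coverage:
                    return ValidationRecord(
                        gene.gene_id, target.species_id, CONTRADICTED, length,
                        aa_hit.score,
                    )
    return ValidationRecord(gene.gene_id, target.species_id, VALIDATED_ABSENT, length, best)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    matrix: PresenceMatrix  # final calls (caller rbbh_synteny)
    prelim_matrix: PresenceMatrix  # stage-1 calls (caller rbbh)
    rbbh_calls: dict[tuple[str, str], RBBHCall]
    absence_calls: dict[tuple[str, str], AbsenceCall]
    blocks: dict[tuple[str, str], SyntenyBlock]
    validations: list[ValidationRecord]

    def validated_pairs(self) -> set[tuple[str, str]]:
        return {
            (v.gene_id, v.species_id)
            for v in self.validations
            if v.status == VALIDATED_ABSENT
        }


def run_pipeline(
    genes: Sequence[str],
    reference: AnnotatedGenome,
    targets: Mapping[str, AnnotatedGenome],
    thresholds: Thresholds = Thresholds(),
    config: SyntenyConfig = SyntenyConfig(),
) -> PipelineResult:
    """RBBH calling, syntenic re-evaluation, and in-silico validation.

    Every stage-1 ABSENT_PRELIM resolves to exactly one of PRESENT_RESCUED,
    ABSENT_SYNTENY, ABSENT_NO_SYNTENY or UNRESOLVED_CONTIG_END; retained
    absences with amplifiable intervals also get a validation record.
    """
    prelim, rbbh_calls = call_matrix(genes, reference, targets, thresholds)
    final = prelim.calls.copy()
    provenance = pd.DataFrame("rbbh", index=final.index, columns=final.columns)
    absence_calls: dict[tuple[str, str], AbsenceCall] = {}
    blocks: dict[tuple[str, str], SyntenyBlock] = {}
    validations: list[ValidationRecord] = []

    for sp in sorted(targets):
        target = targets[sp]
        locator = _AnchorLocator(reference, target, thresholds)
        for gid in genes:
            call = rbbh_calls[(gid, sp)]
            if call.status != io_core.ABSENT_PRELIM:
                continue
            gene = reference.gene(gid)
            anchors = flanking_anchors(gene, reference, config.k_anchors)
            block = locate_block(anchors, target, reference, thresholds, locator)
            rescue = rescue_search(gene, block, target, config)
            resolved = classify_absence(call, block, rescue)
            blocks[(gid, sp)] = block
            absence_calls[(gid, sp)] = resolved
            final.at[gid, sp] = resolved.status
            provenance.at[gid, sp] = "rbbh_synteny"
            if resolved.status == io_core.ABSENT_SYNTENY:
                validations.append(in_silico_validation(gene, block, target, config))
        n_abs = int((final[sp].isin(io_core.ABSENT_CALLS)).sum())
        logger.info("synteny %s: %d final absences", sp, n_abs)

    matrix = PresenceMatrix(calls=final, caller="rbbh_synteny", provenance=provenance)
    return PipelineResult(
        matrix=matrix,
        prelim_matrix=prelim,
        rbbh_calls=rbbh_calls,
        absence_calls=absence_calls,
        blocks=blocks,
        validations=validations,
    )
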