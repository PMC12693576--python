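"""Stage 1 ortholog calling: reciprocal best-hit protein searches.

A reference gene is PRESENT_RBBH in a target species iff its protein's
rank-1 hit in the target proteome, searched back against the reference
proteome, returns the original gene at rank 1. Reciprocity is judged on
rank 1 only; a tied top score in either direction is treated conservatively
as ABSENT_PRELIM (flag ``ambiguous_tie``) and pushed to the synteny stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import io_core
from .io_core import AnnotatedGenome, GeneModel, PresenceMatrix
from .similarity_search import (
    DEFAULT_MIN_PROTEIN_SCORE,
    Hit,
    HitTable,
    PROTEIN_SCORING,
    Scoring,
    search,
)

logger = logging.getLogger("gscortho")

PRESENT_RBBH = io_core.PRESENT_RBBH
ABSENT_PRELIM = io_core.ABSENT_PRELIM


@dataclass(frozen=True)
class Thresholds:
    """Hit-acceptance thresholds for the forward search.

    ``min_identity`` (percent) is an optional Ensembl-style filter,
    disabled by default.
    """

    min_score: float = DEFAULT_MIN_PROTEIN_SCORE
    min_query_coverage: float = 0.5
    min_identity: float | None = None

    def passes(self, hit: Hit) -> bool:
        if hit.score < self.min_score:
            return False
        if hit.query_coverage < self.min_query_coverage:
            return False
        if self.min_identity is not None and hit.percent_identity < self.min_identity:
            return False
        return True


@dataclass
class RBBHCall:
    gene_id: str
    species_id: str
    status: str  # PRESENT_RBBH | ABSENT_PRELIM
    forward_hit: Hit | None = None
    reverse_hit: Hit | None = None
    flag: str | None = None  # no_protein | empty_proteome | ambiguous_tie | ...


class _ReverseSearchCache:
    """Memoises reverse searches of target proteins vs the reference proteome."""

    def __init__(self, reference_proteome: Mapping[str, str], scoring: Scoring,
                 min_score: float):
        self._proteome = dict(reference_proteome)
        self._scoring = scoring
        self._min_score = min_score
        self._cache: dict[str, HitTable] = {}

    def search(self, subject_id: str, subject_seq: str) -> HitTable:
        if subject_id not in self._cache:
            self._cache[subject_id] = search(
                subject_seq,
                self._proteome,
                self._scoring,
                self._min_score,
                query_id=subject_id,
            )
        return self._cache[subject_id]


def reciprocal_call(
    gene: GeneModel,
    reference: AnnotatedGenome,
    target: AnnotatedGenome,
    thresholds: Thresholds = Thresholds(),
    scoring: Scoring = PROTEIN_SCORING,
    _reverse_cache: _ReverseSearchCache | None = None,
    _target_proteome: Mapping[str, str] | None = None,
) -> RBBHCall:
    """Forward/reverse best-hit call for one reference gene in one target."""
    if gene.gene_id not in reference:
        raise ValueError(f"gene {gene.gene_id!r} does not belong to the reference")
    if gene.protein_sequence is None:
        return RBBHCall(gene.gene_id, target.species_id, ABSENT_PRELIM, flag="no_protein")
    target_proteome = (
        dict(_target_proteome) if _target_proteome is not None else target.proteome()
    )
    if not target_proteome:
        return RBBHCall(
            gene.gene_id, target.species_id, ABSENT_PRELIM, flag="empty_proteome"
        )
    forward = search(
        gene.protein_sequence,
        target_proteome,
        scoring,
        thresholds.min_score,
        query_id=gene.gene_id,
    )
    best = forward.best
    if best is None or not thresholds.passes(best):
        return RBBHCall(
            gene.gene_id,
            target.species_id,
            ABSENT_PRELIM,
            forward_hit=best,
            flag="no_forward_hit" if best is None else "sub_threshold",
        )
    if forward.has_tie_at_rank1():
        return RBBHCall(
            gene.gene_id,
            target.species_id,
            ABSENT_PRELIM,
            forward_hit=best,
            flag="ambiguous_tie",
        )
    cache = _reverse_cache or _ReverseSearchCache(
        reference.proteome(), scoring, thresholds.min_score
    )
    reverse = cache.search(best.subject_id, target_proteome[best.subject_id])
    rbest = reverse.best
    if rbest is None:
        return RBBHCall(
            gene.gene_id,
            target.species_id,
            ABSENT_PRELIM,
            forward_hit=best,
            flag="no_reverse_hit",
        )
    if reverse.has_tie_at_rank1():
        return RBBHCall(
            gene.gene_id,
            target.species_id,
            ABSENT_PRELIM,
            forward_hit=best,
            reverse_hit=rbest,
            flag="ambiguous_tie",
        )
    if rbest.subject_id == gene.gene_id:
        return RBBHCall(
            gene.gene_id, target.species_id, PRESENT_RBBH, forward_hit=best,
            reverse_hit=rbest,
        )
    return RBBHCall(
        gene.gene_id,
        target.species_id,
        ABSENT_PRELIM,
        forward_hit=best,
        reverse_hit=rbest,
        flag="reciprocity_broken",
    )


def call_matrix(
    genes: Sequence[str],
    reference: AnnotatedGenome,
    targets: Mapping[str, AnnotatedGenome],
    thresholds: Thresholds = Thresholds(),
    scoring: Scoring = PROTEIN_SCORING,
) -> tuple[PresenceMatrix, dict[tuple[str, str], RBBHCall]]:
    """One RBBH call per (gene, species); the reference column is all present.

    Returns the preliminary presence matrix (caller ``rbbh``) and the
    underlying calls keyed by (gene_id, species_id).
    """
    missing = [g for g in genes if g not in reference]
    if missing:
        raise ValueError(f"genes not in reference: {missing}")
    calls: dict[tuple[str, str], RBBHCall] = {}
    data: dict[str, dict[str, str]] = {}
    ref_proteome = reference.proteome()
    for sp in sorted(targets):
        target = targets[sp]
        cache = _ReverseSearchCache(ref_proteome, scoring, thresholds.min_score)
        proteome = target.proteome()
        n_present = 0
        for gid in genes:
            call = reciprocal_call(
                reference.gene(gid),
                reference,
                target,
                thresholds,
                scoring,
                _reverse_cache=cache,
                _target_proteome=proteome,
            )
            calls[(gid, sp)] = call
            data.setdefault(sp, {})[gid] = call.status
            n_present += call.status == PRESENT_RBBH
        logger.info(
            "rbbh %s: %d/%d present", sp, n_present, len(genes)
        )
    df = pd.DataFrame(data, index=list(genes))
    df[reference.species_id] = PRESENT_RBBH
    df = df[sorted(df.columns)]
    df.index.name = "gene_id"
    matrix = PresenceMatrix(calls=df, caller="rbbh")
    return matrix, calls


def naive_identity_calls(
    genes: Sequence[str],
    reference: AnnotatedGenome,
    targets: Mapping[str, AnnotatedGenome],
    min_identity: float = 50.0,
    min_query_coverage: float = 0.8,
    scoring: Scoring = PROTEIN_SCORING,
) -> PresenceMatrix:
    """Single-direction identity-threshold caller (no reciprocity, no synteny).

    Emulates taking an ortholog export at face value with only an identity
    cutoff: a gene is PRESENT iff its best forward hit reaches
    ``min_identity`` percent identity and ``min_query_coverage`` coverage.
    """
    data: dict[str, dict[str, str]] = {}
    for sp in sorted(targets):
        proteome = targets[sp].proteome()
        for gid in genes:
            gene = reference.gene(gid)
            status = io_core.ABSENT
            if gene.protein_sequence and proteome:
                table = search(gene.protein_sequence, proteome, scoring, 0.0)
                best = table.best
                if (
                    best is not None
                    and best.percent_identity >= min_identity
                    and best.query_coverage >= min_query_coverage
                ):
                    status = io_core.PRESENT
            data.setdefault(sp, {})[gid] = status
    df = pd.DataFrame(data, index=list(genes))
    df[reference.species_id] = io_core.PRESENT
    df = df[sorted(df.columns)]
    df.index.name = "gene_id"
    return PresenceMatrix(calls=df, caller="naive")
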