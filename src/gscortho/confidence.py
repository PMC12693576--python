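"""Confidence tiering of final absences.

An absence validated in-silico outranks everything (VALIDATED). Otherwise an
absence in species *s* is HIGH confidence when the same gene has a present
ortholog in some species at least as divergent as *s* — a deeper present
witness argues for genuine loss rather than detection failure. Absences
with no such witness (typically those confined to the deepest outgroups)
are LOW confidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from . import io_core
from .io_core import PhylogenyConfig, PresenceMatrix
from .synteny import VALIDATED_ABSENT, ValidationRecord

VALIDATED = "VALIDATED"
HIGH = "HIGH"
LOW = "LOW"


@dataclass
class ConfidenceLabel:
    gene_id: str
    species_id: str
    tier: str
    rationale: str
    gene_level_support: bool


def tier_absences(
    matrix: PresenceMatrix,
    phylo: PhylogenyConfig,
    validations: Iterable[ValidationRecord] = (),
) -> list[ConfidenceLabel]:
    """Tier every absent cell of a final matrix by evidential strength.

    Precedence is VALIDATED > HIGH > LOW; a validated absence that also has
    lineage support notes the support in its rationale. "More or equally
    divergent" is compared on divergence times with ties allowed (>=).
    ``gene_level_support`` reports the per-gene reading: whether even the
    gene's deepest absence has a present witness at equal or deeper
    divergence. Raises ``ValueError`` for species missing from the
    phylogeny.
    """
    missing = [s for s in matrix.species if s not in phylo.divergence_my]
    if missing:
        raise ValueError(f"species missing from phylogeny: {missing}")
    validated = {
        (v.gene_id, v.species_id)
        for v in validations
        if v.status == VALIDATED_ABSENT
    }
    div = phylo.divergence_my
    labels: list[ConfidenceLabel] = []
    for gid in matrix.genes:
        row = matrix.calls.loc[gid]
        present_div = [
            div[sp] for sp in matrix.species if row[sp] in io_core.PRESENT_CALLS
        ]
        absent_species = [
            sp for sp in matrix.species if row[sp] in io_core.ABSENT_CALLS
        ]
        if not absent_species:
            continue
        deepest_absence = max(div[sp] for sp in absent_species)
        gene_support = any(d >= deepest_absence for d in present_div)
        for sp in absent_species:
            supported = any(d >= div[sp] for d in present_div)
            if (gid, sp) in validated:
                tier = VALIDATED
                rationale = "absence verified in-silico across the syntenic interval"
                if supported:
                    rationale += "; present ortholog in an equally or more divergent lineage"
            elif supported:
                tier = HIGH
                rationale = (
                    f"present ortholog at >= {div[sp]:g} My argues for loss "
                    "rather than detection failure"
                )
            else:
                tier = LOW
                rationale = (
                    "no present ortholog at equal or deeper divergence; "
                    "detection failure cannot be excluded"
                )
            labels.append(
                ConfidenceLabel(
                    gene_id=gid,
                    species_id=sp,
                    tier=tier,
                    rationale=rationale,
                    gene_level_support=gene_support,
                )
            )
    return labels


def labels_to_frame(labels: Iterable[ConfidenceLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": l.gene_id,
                "species_id": l.species_id,
                "tier": l.tier,
                "rationale": l.rationale,
                "gene_level_support": l.gene_level_support,
            }
            for l in labels
        ]
    )
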