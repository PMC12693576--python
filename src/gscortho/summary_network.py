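"""Headline summaries: per-species absence counts, category breakdowns,
interaction-network co-absence, and import of external ortholog predictions.

Unresolved contig-end cells are counted as present in the headline absence
totals (conservative; switchable). Percentages are reported to two
decimals. A gene belonging to several functional categories is counted
once in each.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from . import io_core
from .io_core import GeneAnnotationTable, PresenceMatrix

logger = logging.getLogger("gscortho")


@dataclass
class InteractionNetwork:
    """Physical/genetic interactors per focal gene; no self-edges."""

    edges: dict[str, set[tuple[str, str]]]  # focal -> {(interactor, kind)}

    def __post_init__(self) -> None:
        for focal, partners in self.edges.items():
            for interactor, kind in partners:
                if interactor == focal:
                    raise ValueError(f"self-edge on {focal!r}")
                if kind not in {"physical", "genetic"}:
                    raise ValueError(f"unknown edge kind {kind!r}")

    def interactors_of(self, focal: str) -> set[str]:
        return {i for i, _ in self.edges.get(focal, set())}


def load_interaction_network(path) -> InteractionNetwork:
    """TSV with columns gene_id, interactor_id, kind (physical|genetic)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    edges: dict[str, set[tuple[str, str]]] = {}
    for row in df.itertuples(index=False):
        edges.setdefault(row.gene_id, set()).add((row.interactor_id, row.kind))
    return InteractionNetwork(edges)


def _absent_mask(matrix: PresenceMatrix, count_unresolved: bool) -> pd.DataFrame:
    absent = matrix.calls.isin(io_core.ABSENT_CALLS)
    if count_unresolved:
        absent |= matrix.calls == io_core.UNRESOLVED_CONTIG_END
    return absent


def per_species_summary(
    matrix: PresenceMatrix, count_unresolved_as_absent: bool = False
) -> pd.DataFrame:
    """Absence count and percentage of the focal gene total, per species."""
    absent = _absent_mask(matrix, count_unresolved_as_absent)
    n_genes = len(matrix.genes)
    n_absent = absent.sum(axis=0)
    return pd.DataFrame(
        {
            "species": matrix.species,
            "n_absent": [int(n_absent[sp]) for sp in matrix.species],
            "pct_absent": [
                round(100.0 * n_absent[sp] / n_genes, 2) for sp in matrix.species
            ],
        }
    )


def any_absence_genes(
    matrix: PresenceMatrix, count_unresolved_as_absent: bool = False
) -> set[str]:
    """Genes absent in at least one species."""
    absent = _absent_mask(matrix, count_unresolved_as_absent)
    return set(matrix.calls.index[absent.any(axis=1)])


def category_summary(
    matrix: PresenceMatrix,
    annotations: GeneAnnotationTable,
    count_unresolved_as_absent: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genes-with-any-absence breakdown per functional category and defect type.

    Returns (category table, defect-type table), each with columns
    name, n_genes, n_with_absence, pct.
    """
    absent_genes = any_absence_genes(matrix, count_unresolved_as_absent)

    def summarise(groups: Mapping[str, set[str]]) -> pd.DataFrame:
        rows = []
        for name in sorted(groups):
            members = groups[name] & set(matrix.genes)
            if not members:
                continue
            hit = len(members & absent_genes)
            rows.append(
                {
                    "name": name,
                    "n_genes": len(members),
                    "n_with_absence": hit,
                    "pct": round(100.0 * hit / len(members), 2),
                }
            )
        return pd.DataFrame(rows, columns=["name", "n_genes", "n_with_absence", "pct"])

    cats: dict[str, set[str]] = {}
    defects: dict[str, set[str]] = {}
    for row in annotations.table.itertuples(index=False):
        categories = row.functional_categories or ["No functional category"]
        for cat in categories:
            cats.setdefault(cat, set()).add(row.gene_id)
        if row.defect_type:
            defects.setdefault(row.defect_type, set()).add(row.gene_id)
    return summarise(cats), summarise(defects)


def network_cooccurrence(
    matrix: PresenceMatrix,
    network: InteractionNetwork,
    count_unresolved_as_absent: bool = False,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Interaction-network absence statistics for every absent focal gene.

    The matrix must carry calls for the interactors too; interactors without
    calls are counted "unevaluated" and excluded from denominators. Returns
    a per-gene table (network size, interactors absent anywhere, co-absent
    in the same species as the focal absence) and global tallies.
    """
    absent = _absent_mask(matrix, count_unresolved_as_absent)
    focal_absent = sorted(any_absence_genes(matrix, count_unresolved_as_absent))
    rows = []
    n_with_network = 0
    n_with_network_absence = 0
    same_species_pairs = 0
    for gene in focal_absent:
        interactors = sorted(network.interactors_of(gene))
        evaluated = [i for i in interactors if i in matrix.calls.index]
        unevaluated = len(interactors) - len(evaluated)
        gene_absent_species = set(matrix.calls.columns[absent.loc[gene]])
        n_int_absent = 0
        n_co_absent = 0
        for interactor in evaluated:
            int_absent_species = set(matrix.calls.columns[absent.loc[interactor]])
            if int_absent_species:
                n_int_absent += 1
            if int_absent_species & gene_absent_species:
                n_co_absent += 1
                same_species_pairs += 1
        if interactors:
            n_with_network += 1
            if n_int_absent:
                n_with_network_absence += 1
        rows.append(
            {
                "gene_id": gene,
                "network_size": len(interactors),
                "n_evaluated": len(evaluated),
                "n_unevaluated": unevaluated,
                "n_interactors_absent": n_int_absent,
                "n_co_absent_same_species": n_co_absent,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "network_size",
            "n_evaluated",
            "n_unevaluated",
            "n_interactors_absent",
            "n_co_absent_same_species",
        ],
    )
    tallies = {
        "n_absent_genes": len(focal_absent),
        "n_with_interactions": n_with_network,
        "n_with_network_absences": n_with_network_absence,
        "n_same_species_co_absences": same_species_pairs,
    }
    return table, tallies


def import_external_predictions(
    table: pd.DataFrame,
    min_identity: float = 25.0,
    gene_col: str = "gene_id",
    species_col: str = "species",
    identity_cols: tuple[str, ...] = ("target_pct_id", "query_pct_id"),
) -> PresenceMatrix:
    """Import an external ortholog export as a presence matrix.

    A predicted ortholog is kept as PRESENT when its alignment identity is
    greater than or equal to ``min_identity`` percent (boundary inclusive);
    rows below the cutoff, and (gene, species) pairs with no row at all,
    are ABSENT. When several identity columns are present the smaller value
    is used. Malformed rows are skipped with a count.
    """
    ident_cols = [c for c in identity_cols if c in table.columns]
    if not ident_cols:
        ident_cols = [c for c in ("percent_identity", "pct_id") if c in table.columns]
    if not ident_cols:
        raise ValueError("no identity column found in external prediction table")
    genes = sorted(table[gene_col].dropna().unique())
    species = sorted(table[species_col].dropna().unique())
    if not genes or not species:
        warnings.warn("empty external prediction table: all cells absent")
    calls = pd.DataFrame(io_core.ABSENT, index=genes, columns=species)
    calls.index.name = "gene_id"
    skipped = 0
    for row in table.itertuples(index=False):
        vals = []
        try:
            for c in ident_cols:
                v = float(getattr(row, c))
                if not 0 <= v <= 100:
                    raise ValueError
                vals.append(v)
        except (TypeError, ValueError):
            skipped += 1
            continue
        if min(vals) >= min_identity:
            calls.at[getattr(row, gene_col), getattr(row, species_col)] = io_core.PRESENT
    if skipped:
        warnings.warn(f"skipped {skipped} malformed external prediction rows")
    return PresenceMatrix(calls=calls, caller="ensembl_import")
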