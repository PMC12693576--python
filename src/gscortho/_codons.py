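"""Codon-level helpers shared by the forge and the McDonald-Kreitman machinery.

The standard nuclear genetic code is taken from Biopython; everything here is
a thin convenience layer (codon -> amino acid lookups, synonymous neighbours,
shortest-pathway classification of multi-step codon differences).
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

from Bio.Data.CodonTable import standard_dna_table

NUCLEOTIDES = "ACGT"

GENETIC_CODE: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)
for _stop in STOP_CODONS:
    GENETIC_CODE[_stop] = "*"

AMINO_ACIDS = sorted({aa for aa in GENETIC_CODE.values() if aa != "*"})

CODONS_BY_AA: dict[str, tuple[str, ...]] = {}
for _codon in sorted(GENETIC_CODE):
    CODONS_BY_AA.setdefault(GENETIC_CODE[_codon], tuple())
CODONS_BY_AA = {
    aa: tuple(c for c in sorted(GENETIC_CODE) if GENETIC_CODE[c] == aa)
    for aa in CODONS_BY_AA
}

# Crude physico-chemical neighbourhoods used by the forge's exchangeability
# bias; membership, not chemistry, is what matters here.
AA_GROUPS = (
    "AGPST",   # small
    "ILMV",    # aliphatic hydrophobic
    "FWY",     # aromatic
    "DENQ",    # acidic / amide
    "HKR",     # basic
    "C",
)
AA_GROUP_OF = {aa: grp for grp in AA_GROUPS for aa in grp}


def translate_codon(codon: str) -> str:
    """Amino acid for a codon; '*' for stops. Raises KeyError on ambiguity."""
    return GENETIC_CODE[codon]


def is_valid_codon(codon: str) -> bool:
    return len(codon) == 3 and all(n in NUCLEOTIDES for n in codon)


def translate_cds(cds: str) -> str:
    """Translate an in-frame CDS, keeping internal stops as '*'."""
    if len(cds) % 3:
        raise ValueError("CDS length not a multiple of 3")
    return "".join(GENETIC_CODE[cds[i : i + 3]] for i in range(0, len(cds), 3))


@lru_cache(maxsize=None)
def single_step_neighbors(codon: str) -> tuple[str, ...]:
    """All codons one nucleotide substitution away, stops included."""
    out = []
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt != codon[pos]:
                out.append(codon[:pos] + nt + codon[pos + 1 :])
    return tuple(out)


@lru_cache(maxsize=None)
def synonymous_neighbors(codon: str) -> tuple[str, ...]:
    """Single-substitution neighbours encoding the same amino acid."""
    aa = GENETIC_CODE[codon]
    return tuple(
        c for c in single_step_neighbors(codon)
        if c not in STOP_CODONS and GENETIC_CODE[c] == aa
    )


@lru_cache(maxsize=None)
def nonsynonymous_neighbors(codon: str) -> tuple[str, ...]:
    """Single-substitution, non-stop neighbours changing the amino acid."""
    aa = GENETIC_CODE[codon]
    return tuple(
        c for c in single_step_neighbors(codon)
        if c not in STOP_CODONS and GENETIC_CODE[c] != aa
    )


@lru_cache(maxsize=None)
def pathway_changes(codon_from: str, codon_to: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) step counts between two codons.

    Multi-step differences are averaged over all shortest mutational pathways
    with equal weights, excluding pathways that pass through a stop codon
    (Nei-Gojobori convention).  If every pathway passes through a stop, the
    stop exclusion is dropped so the difference is still counted.
    """
    if codon_from == codon_to:
        return (0.0, 0.0)
    diff_positions = [i for i in range(3) if codon_from[i] != codon_to[i]]

    def walk(exclude_stops: bool):
        paths = []
        for order in permutations(diff_positions):
            cur = codon_from
            syn = nonsyn = 0
            ok = True
            for pos in order:
                nxt = cur[:pos] + codon_to[pos] + cur[pos + 1 :]
                if exclude_stops and nxt in STOP_CODONS and nxt != codon_to:
                    ok = False
                    break
                if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                    syn += 1
                else:
                    nonsyn += 1
                cur = nxt
            if ok:
                paths.append((syn, nonsyn))
        return paths

    paths = walk(exclude_stops=True)
    if not paths:
        paths = walk(exclude_stops=False)
    n = len(paths)
    return (sum(p[0] for p in paths) / n, sum(p[1] for p in paths) / n)
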