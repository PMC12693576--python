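"""McDonald-Kreitman test with low-frequency polymorphism exclusion.

The test contrasts nonsynonymous and synonymous changes that are polymorphic
within the focal species against those fixed along its lineage. Divergence
is lineage-specific: fixed changes are counted against a supplied common
ancestor sequence (inferred elsewhere, e.g. by codeml; a parsimony fallback
is provided). Polymorphic sites segregating below a minor-allele frequency
cutoff (default 12%, treated as slightly deleterious alleles not yet purged
by purifying selection) are excluded before building the 2x2 table. The
neutrality index NI = (Pn/Ps)/(Dn/Ds) and alpha = 1 - NI summarise the
departure from neutrality; significance comes from a two-tailed Fisher's
exact test.

Multi-nucleotide codon differences are averaged over all shortest
mutational pathways with equal weights, excluding pathways through stop
codons (Nei-Gojobori convention), so fractional counts are possible; the
Fisher test runs on the rounded table (rounding is recorded).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from math import comb
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from ._codons import GENETIC_CODE, STOP_CODONS, pathway_changes

logger = logging.getLogger("gscortho")

DEFAULT_FREQ_CUTOFF = 0.12
_GAPLIKE = set("-.")
_UNAMBIGUOUS = set("ACGT")


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class CodonAlignment:
    """In-frame alignment: ingroup polymorphism sample + ancestor (+ outgroup).

    All sequences must share a length divisible by 3; gaps may only occur in
    whole-codon units.
    """

    ingroup: list[str]
    ancestor: str
    outgroup: str | None = None

    def __post_init__(self) -> None:
        if len(self.ingroup) < 2:
            raise ValueError("need at least two ingroup sequences")
        self.ingroup = [s.upper() for s in self.ingroup]
        self.ancestor = self.ancestor.upper()
        if self.outgroup is not None:
            self.outgroup = self.outgroup.upper()
        seqs = self.ingroup + [self.ancestor] + ([self.outgroup] if self.outgroup else [])
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must have equal lengths")
        if next(iter(lengths)) % 3:
            raise ValueError("alignment length must be divisible by 3")
        for s in seqs:
            for i in range(0, len(s), 3):
                codon = s[i : i + 3]
                n_gap = sum(c in _GAPLIKE for c in codon)
                if n_gap not in (0, 3):
                    raise ValueError("gaps must occupy whole codons")

    @property
    def n_codons(self) -> int:
        return len(self.ancestor) // 3

    @property
    def n_ingroup(self) -> int:
        return len(self.ingroup)


@dataclass
class SiteChange:
    """One segregating or fixed change at a codon site.

    ``synonymous``/``nonsynonymous`` are the (possibly fractional) step
    counts summed over the shortest-pathway average; together they equal the
    number of mutational steps at the site.
    """

    codon_index: int
    kind: str  # "fixed" | "polymorphic"
    synonymous: float
    nonsynonymous: float
    minor_allele_frequency: float | None = None  # polymorphic only


@dataclass
class TabulationResult:
    changes: list[SiteChange]
    excluded_codons: list[int]  # gap/ambiguity/stop exclusions


@dataclass
class MKTTable:
    """2x2 MKT counts with the statistics derived from them.

    ``ni`` and ``alpha`` are None when a denominator is zero. The Fisher
    p-value is computed on the rounded integer table (``rounded``).
    """

    Dn: float
    Ds: float
    Pn: float
    Ps: float
    freq_cutoff: float
    p_value: float
    ni: float | None
    alpha: float | None
    rounded: tuple[int, int, int, int]
    excluded_codons: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "Dn": self.Dn,
            "Ds": self.Ds,
            "Pn": self.Pn,
            "Ps": self.Ps,
            "freq_cutoff": self.freq_cutoff,
            "p_value": self.p_value,
            "NI": self.ni,
            "alpha": self.alpha,
            "rounded_table": list(self.rounded),
            "n_excluded_codons": len(self.excluded_codons),
        }


# ---------------------------------------------------------------------------
# Tabulation
# ---------------------------------------------------------------------------


def _usable(codon: str) -> bool:
    return all(c in _UNAMBIGUOUS for c in codon)


def tabulate_changes(aln: CodonAlignment) -> TabulationResult:
    """Classify every codon column as fixed, polymorphic, or unchanged.

    A column is polymorphic when >= 2 ingroup alleles segregate; each minor
    allele contributes the shortest-pathway average of its steps from the
    major allele, at its minor-allele frequency. A column is fixed when the
    ingroup is monomorphic and differs from the ancestor (lineage-specific
    by construction). Columns with gaps or ambiguity in any used sequence
    are excluded and reported; an internal stop in the ancestor is an
    error, a stop allele in the ingroup excludes its codon with a warning.
    """
    n = aln.n_ingroup
    changes: list[SiteChange] = []
    excluded: list[int] = []
    last = aln.n_codons - 1
    for ci in range(aln.n_codons):
        anc = aln.ancestor[3 * ci : 3 * ci + 3]
        ing = [s[3 * ci : 3 * ci + 3] for s in aln.ingroup]
        if anc in STOP_CODONS:
            if ci == last and all(c in STOP_CODONS or not _usable(c) for c in ing):
                continue  # shared terminal stop codon
            raise ValueError(f"internal stop codon in ancestor at codon {ci}")
        if not _usable(anc) or any(not _usable(c) for c in ing):
            excluded.append(ci)
            continue
        if any(c in STOP_CODONS for c in ing):
            warnings.warn(f"stop codon in ingroup allele at codon {ci}; excluded")
            excluded.append(ci)
            continue
        counts: dict[str, int] = {}
        for c in ing:
            counts[c] = counts.get(c, 0) + 1
        if len(counts) >= 2:
            major = min(counts, key=lambda c: (-counts[c], c))
            for allele in sorted(counts):
                if allele == major:
                    continue
                syn, nonsyn = pathway_changes(major, allele)
                k = counts[allele]
                changes.append(
                    SiteChange(
                        codon_index=ci,
                        kind="polymorphic",
                        synonymous=syn,
                        nonsynonymous=nonsyn,
                        minor_allele_frequency=min(k, n - k) / n,
                    )
                )
        else:
            allele = next(iter(counts))
            if allele != anc:
                syn, nonsyn = pathway_changes(anc, allele)
                changes.append(
                    SiteChange(
                        codon_index=ci,
                        kind="fixed",
                        synonymous=syn,
                        nonsynonymous=nonsyn,
                    )
                )
    return TabulationResult(changes=changes, excluded_codons=excluded)


def apply_frequency_filter(
    changes: Iterable[SiteChange], cutoff: float = DEFAULT_FREQ_CUTOFF
) -> list[SiteChange]:
    """Drop polymorphic changes segregating below ``cutoff``.

    The exclusion is strict ("less than"): a polymorphism at exactly the
    cutoff frequency is retained. Fixed changes pass through untouched.
    """
    if not 0 <= cutoff <= 0.5:
        raise ValueError("cutoff must lie in [0, 0.5]")
    return [
        ch
        for ch in changes
        if ch.kind != "polymorphic" or ch.minor_allele_frequency >= cutoff
    ]


def build_mkt(
    changes: Iterable[SiteChange],
    freq_cutoff: float = DEFAULT_FREQ_CUTOFF,
    excluded_codons: Sequence[int] = (),
) -> MKTTable:
    """Sum classified changes into the 2x2 table and derive NI/alpha/p.

    ``changes`` should already be frequency-filtered; ``freq_cutoff`` is
    recorded for bookkeeping. Fisher's exact test runs on the
    rounded-to-nearest-integer table; the unrounded sums are kept.
    """
    Dn = Ds = Pn = Ps = 0.0
    for ch in changes:
        if ch.kind == "fixed":
            Dn += ch.nonsynonymous
            Ds += ch.synonymous
        else:
            Pn += ch.nonsynonymous
            Ps += ch.synonymous
    rounded = tuple(int(round(x)) for x in (Dn, Ds, Pn, Ps))
    p = fisher_two_tailed(((rounded[0], rounded[1]), (rounded[2], rounded[3])))
    ni = alpha = None
    if Ds > 0 and Ps > 0 and Dn > 0:
        ni = (Pn / Ps) / (Dn / Ds)
        alpha = 1.0 - ni
    return MKTTable(
        Dn=Dn,
        Ds=Ds,
        Pn=Pn,
        Ps=Ps,
        freq_cutoff=freq_cutoff,
        p_value=p,
        ni=ni,
        alpha=alpha,
        rounded=rounded,  # type: ignore[arg-type]
        excluded_codons=list(excluded_codons),
    )


def mkt_from_alignment(
    aln: CodonAlignment, freq_cutoff: float = DEFAULT_FREQ_CUTOFF
) -> MKTTable:
    """Tabulate, frequency-filter, and build the MKT table in one step."""
    tab = tabulate_changes(aln)
    filtered = apply_frequency_filter(tab.changes, freq_cutoff)
    return build_mkt(filtered, freq_cutoff, tab.excluded_codons)


# ---------------------------------------------------------------------------
# Fisher's exact test (two-tailed)
# ---------------------------------------------------------------------------


@lru_cache(maxsize=200_000)
def _hypergeom_numerators(n1: int, n2: int, m: int) -> tuple[int, tuple[int, ...]]:
    """Integer numerators C(n1,k)C(n2,m-k) over the support, plus k_min."""
    k_min = max(0, m - n2)
    k_max = min(m, n1)
    return k_min, tuple(comb(n1, k) * comb(n2, m - k) for k in range(k_min, k_max + 1))


def fisher_two_tailed(table: Sequence[Sequence[int]]) -> float:
    """Exact two-tailed Fisher p for a 2x2 integer table.

    Sums, over all tables with the observed margins, the hypergeometric
    probabilities no larger than the observed one. Probabilities are
    compared as exact integers (common denominator), so ties are decided
    exactly. Degenerate tables (a zero margin) return 1.0.
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n1, n2, m = a + b, c + d, a + c
    if n1 == 0 or n2 == 0 or m == 0 or b + d == 0:
        return 1.0
    k_min, numerators = _hypergeom_numerators(n1, n2, m)
    observed = numerators[a - k_min]
    total = sum(numerators)
    return sum(x for x in numerators if x <= observed) / total


# ---------------------------------------------------------------------------
# Ancestor fallback and FASTA I/O
# ---------------------------------------------------------------------------


def parsimony_ancestor(
    focal_consensus: str, sister: str, outgroup: str
) -> tuple[str, list[int]]:
    """Parsimony ancestor of focal and sister, polarised by the outgroup.

    Per site, the ancestral base is any base shared by at least two of the
    three sequences; sites where all three disagree are unresolvable and
    emitted as 'N' (their codons will be excluded downstream). Returns the
    ancestor string and the list of unresolved site indices.
    """
    if not (len(focal_consensus) == len(sister) == len(outgroup)):
        raise ValueError("sequences must have equal lengths")
    out = []
    unresolved: list[int] = []
    for i, (f, s, o) in enumerate(zip(focal_consensus, sister, outgroup)):
        if f == s or f == o:
            out.append(f)
        elif s == o:
            out.append(s)
        else:
            out.append("N")
            unresolved.append(i)
    return "".join(out), unresolved


def consensus(sequences: Sequence[str]) -> str:
    """Per-site majority consensus (ties broken alphabetically)."""
    if not sequences:
        raise ValueError("no sequences")
    out = []
    for col in zip(*sequences):
        counts: dict[str, int] = {}
        for c in col:
            counts[c] = counts.get(c, 0) + 1
        out.append(min(counts, key=lambda c: (-counts[c], c)))
    return "".join(out)


def read_codon_alignment(path: str | Path) -> CodonAlignment:
    """Read an aligned in-frame FASTA with roles tagged in the headers.

    A record whose description contains ``role=ancestor`` (or whose id
    starts with ``ancestor``) supplies the ancestor; ``role=outgroup``
    likewise; everything else is ingroup.
    """
    ingroup: list[str] = []
    ancestor: str | None = None
    outgroup: str | None = None
    for rec in SeqIO.parse(str(path), "fasta"):
        text = f"{rec.id} {rec.description}".lower()
        seq = str(rec.seq)
        if "role=ancestor" in text or rec.id.lower().startswith("ancestor"):
            ancestor = seq
        elif "role=outgroup" in text or rec.id.lower().startswith("outgroup"):
            outgroup = seq
        else:
            ingroup.append(seq)
    if ancestor is None:
        raise ValueError("no record tagged role=ancestor in alignment")
    return CodonAlignment(ingroup=ingroup, ancestor=ancestor, outgroup=outgroup)
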