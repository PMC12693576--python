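"""Deterministic local-alignment search standing in for BLASTp/BLASTn.

The engine computes exact Smith-Waterman alignments with affine gaps
(no seeding heuristics) through Biopython's C ``PairwiseAligner``, with
BLAST-like default scoring: BLOSUM62 + gap open 11 / extend 1 for protein,
+2/-3 with gap open 5 / extend 2 for nucleotide. A gap of length L costs
``gap_open + L * gap_extend``.

Percent identity is identical aligned columns over all aligned columns,
gap columns included in the denominator. Thresholds operate on raw score
and coverage; no E-values are computed. Any external engine producing
(query, subject, score, identity, coverages) tuples satisfies the adapter
contract; BLAST tabular (outfmt 6) files can be imported directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping

from Bio import Align
from Bio.Align import substitution_matrices

PROTEIN_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
NUCLEOTIDE_ALPHABET = "ACGTN"


@dataclass(frozen=True)
class Scoring:
    """Alignment scoring parameters.

    ``matrix`` names a substitution matrix (protein); ``match``/``mismatch``
    build one (nucleotide). Gap of length L costs ``gap_open + L*gap_extend``.
    """

    alphabet: str  # "protein" | "nucleotide"
    gap_open: float
    gap_extend: float
    matrix: str | None = None
    match: float = 2.0
    mismatch: float = -3.0


PROTEIN_SCORING = Scoring(alphabet="protein", gap_open=11, gap_extend=1, matrix="BLOSUM62")
NUCLEOTIDE_SCORING = Scoring(alphabet="nucleotide", gap_open=5, gap_extend=2)

# Default minimum raw scores for a hit to be reported at all; chosen so that
# chance local matches between unrelated sequences fall below them.
DEFAULT_MIN_PROTEIN_SCORE = 50.0
DEFAULT_MIN_NUCLEOTIDE_SCORE = 40.0


@dataclass
class LocalAlignment:
    """Optimal local alignment of a query/subject pair."""

    score: float
    query_aligned: str
    subject_aligned: str
    percent_identity: float  # 0..100 over aligned columns (gaps in denominator)
    query_coverage: float  # aligned query span / query length
    subject_coverage: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]

    @property
    def is_empty(self) -> bool:
        return self.score <= 0


@dataclass
class Hit:
    query_id: str
    subject_id: str
    score: float
    percent_identity: float
    query_coverage: float
    subject_coverage: float
    subject_span: tuple[int, int]


@dataclass
class HitTable:
    """Hits sorted by descending score, then descending identity, then id."""

    hits: list[Hit] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.hits.sort(key=lambda h: (-h.score, -h.percent_identity, h.subject_id))

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits)

    def __getitem__(self, i: int) -> Hit:
        return self.hits[i]

    @property
    def best(self) -> Hit | None:
        return self.hits[0] if self.hits else None

    def has_tie_at_rank1(self) -> bool:
        """True when two hits share the top raw score."""
        return len(self.hits) >= 2 and self.hits[0].score == self.hits[1].score


@lru_cache(maxsize=None)
def _aligner(scoring: Scoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if scoring.alphabet == "protein":
        aligner.substitution_matrix = substitution_matrices.load(
            scoring.matrix or "BLOSUM62"
        )
    else:
        arr = substitution_matrices.Array(NUCLEOTIDE_ALPHABET, dims=2)
        arr[:, :] = scoring.mismatch
        for nt in "ACGT":
            arr[nt, nt] = scoring.match
        # 'N' is a mismatch-only symbol, even against itself.
        aligner.substitution_matrix = arr
    aligner.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def _sanitize(seq: str, scoring: Scoring) -> str:
    seq = seq.upper()
    allowed = PROTEIN_ALPHABET if scoring.alphabet == "protein" else NUCLEOTIDE_ALPHABET
    if all(ch in allowed for ch in seq):
        return seq
    stand_in = "X" if scoring.alphabet == "protein" else "N"
    unknown = sorted({ch for ch in seq if ch not in allowed})
    warnings.warn(
        f"unknown residues {unknown} treated as mismatch-only symbol {stand_in!r}"
    )
    return "".join(ch if ch in allowed else stand_in for ch in seq)


_EMPTY = LocalAlignment(0.0, "", "", 0.0, 0.0, 0.0, (0, 0), (0, 0))


def align_local(
    a: str, b: str, scoring: Scoring = PROTEIN_SCORING
) -> LocalAlignment:
    """Optimal Smith-Waterman local alignment of ``a`` (query) vs ``b``.

    Returns an empty alignment (score 0) when no positive-scoring local
    alignment exists. Raises ``ValueError`` on empty input sequences.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    a, b = _sanitize(a, scoring), _sanitize(b, scoring)
    aligner = _aligner(scoring)
    score = aligner.score(a, b)
    if score <= 0:
        return _EMPTY
    best = aligner.align(a, b)[0]
    qblocks, sblocks = best.aligned
    matches = 0
    aligned_pairs = 0
    for (qs, qe), (ss, se) in zip(qblocks, sblocks):
        aligned_pairs += qe - qs
        matches += sum(a[qi] == b[si] for qi, si in zip(range(qs, qe), range(ss, se)))
    q_span = (int(qblocks[0][0]), int(qblocks[-1][1]))
    s_span = (int(sblocks[0][0]), int(sblocks[-1][1]))
    q_len_aln = q_span[1] - q_span[0]
    s_len_aln = s_span[1] - s_span[0]
    columns = aligned_pairs + (q_len_aln - aligned_pairs) + (s_len_aln - aligned_pairs)
    qa, sa = [], []
    prev_q, prev_s = q_span[0], s_span[0]
    for (qs, qe), (ss, se) in zip(qblocks, sblocks):
        qa.append(a[prev_q:qs] + "-" * (ss - prev_s))
        sa.append("-" * (qs - prev_q) + b[prev_s:ss])
        qa.append(a[qs:qe])
        sa.append(b[ss:se])
        prev_q, prev_s = qe, se
    return LocalAlignment(
        score=float(score),
        query_aligned="".join(qa),
        subject_aligned="".join(sa),
        percent_identity=100.0 * matches / columns if columns else 0.0,
        query_coverage=q_len_aln / len(a),
        subject_coverage=s_len_aln / len(b),
        query_span=q_span,
        subject_span=s_span,
    )


def search(
    query: str,
    database: Mapping[str, str],
    scoring: Scoring = PROTEIN_SCORING,
    min_score: float = DEFAULT_MIN_PROTEIN_SCORE,
    query_id: str = "query",
) -> HitTable:
    """Align ``query`` against every database entry; keep hits >= min_score.

    The resulting table is sorted by (score desc, identity desc, subject id),
    so the rank-1 subject does not depend on database input order.
    """
    if not database:
        raise ValueError("empty search database")
    aligner = _aligner(scoring)
    q = _sanitize(query, scoring)
    hits: list[Hit] = []
    for name in sorted(database):
        subj = _sanitize(database[name], scoring)
        if not subj:
            continue
        if aligner.score(q, subj) < min_score:
            continue
        al = align_local(q, subj, scoring)
        hits.append(
            Hit(
                query_id=query_id,
                subject_id=name,
                score=al.score,
                percent_identity=al.percent_identity,
                query_coverage=al.query_coverage,
                subject_coverage=al.subject_coverage,
                subject_span=al.subject_span,
            )
        )
    return HitTable(hits)


def read_blast_tab(
    path: str | Path,
    query_lengths: Mapping[str, int] | None = None,
    subject_lengths: Mapping[str, int] | None = None,
) -> dict[str, HitTable]:
    """Import BLAST outfmt-6 tabular output as HitTables keyed by query id.

    Columns expected: qseqid sseqid pident length mismatch gapopen qstart
    qend sstart send evalue bitscore. Coverages are computed from the
    aligned spans when sequence lengths are supplied, else reported as 0.
    """
    per_query: dict[str, list[Hit]] = {}
    skipped = 0
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 12:
            skipped += 1
            continue
        try:
            qid, sid = parts[0], parts[1]
            pident = float(parts[2])
            qstart, qend = int(parts[6]), int(parts[7])
            sstart, send = int(parts[8]), int(parts[9])
            bitscore = float(parts[11])
        except ValueError:
            skipped += 1
            continue
        qcov = scov = 0.0
        if query_lengths and qid in query_lengths:
            qcov = abs(qend - qstart + 1) / query_lengths[qid]
        if subject_lengths and sid in subject_lengths:
            scov = abs(send - sstart + 1) / subject_lengths[sid]
        lo, hi = sorted((sstart, send))
        per_query.setdefault(qid, []).append(
            Hit(qid, sid, bitscore, pident, qcov, scov, (lo - 1, hi))
        )
    if skipped:
        warnings.warn(f"skipped {skipped} malformed BLAST tabular rows")
    return {qid: HitTable(hits) for qid, hits in per_query.items()}
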