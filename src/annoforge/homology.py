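"""All-by-all protein similarity evidence.

Two routes produce the same :class:`HitTable` surface: parsing standard
12/13-column BLAST tabular output, or an internal Smith-Waterman-style local
aligner (BLOSUM62, affine gaps, no low-complexity masking) so that synthetic
fixtures need no external search tool.  The internal aligner reports a
pseudo-E-value from a Karlin-Altschul-shaped transform of the alignment
score, calibrated so that genuinely homologous proteins fall far below the
E <= 1e-10 cutoff and unrelated random proteins fall far above it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

from Bio.Align import PairwiseAligner, substitution_matrices

from .io_model import Config, DEFAULT_CONFIG, FormatError

# Gapped BLOSUM62 (open 11 / extend 1) Karlin-Altschul constants used by the
# pseudo-E-value transform: E = K * m * n * exp(-lambda * S).
_KA_LAMBDA = 0.267
_KA_K = 0.041

_GAP_OPEN = -11.0
_GAP_EXTEND = -1.0


@dataclass(frozen=True)
class HitRecord:
    """One pairwise protein similarity hit (best HSP for the pair)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bitscore: float
    query_coverage: Optional[float] = None  # aligned query residues / query length

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if not 0 <= self.percent_identity <= 100:
            raise ValueError("percent_identity must be in [0, 100]")
        if self.query_coverage is not None and not 0 <= self.query_coverage <= 1 + 1e-9:
            raise ValueError("query_coverage must be in [0, 1]")


class HitTable:
    """Deduplicated, E-value-filtered hits between one ordered species pair."""

    def __init__(self, query_species: str, subject_species: str,
                 records: list[HitRecord] | None = None):
        self.query_species = query_species
        self.subject_species = subject_species
        self.records: list[HitRecord] = list(records or [])
        seen = set()
        for r in self.records:
            key = (r.query_id, r.subject_id)
            if key in seen:
                raise ValueError(f"duplicate (query, subject) pair {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def by_query(self) -> dict[str, list[HitRecord]]:
        out: dict[str, list[HitRecord]] = {}
        for r in self.records:
            out.setdefault(r.query_id, []).append(r)
        return out

    def get(self, query_id: str, subject_id: str) -> Optional[HitRecord]:
        for r in self.records:
            if r.query_id == query_id and r.subject_id == subject_id:
                return r
        return None


def dedupe_hits(records: list[HitRecord]) -> list[HitRecord]:
    """Keep, per (query, subject), the minimum-E-value record.

    Ties break to the maximum bitscore, then first occurrence.  Input order
    of distinct pairs is preserved.
    """
    best: dict[tuple[str, str], HitRecord] = {}
    for r in records:
        key = (r.query_id, r.subject_id)
        prev = best.get(key)
        if prev is None or (r.evalue, -r.bitscore) < (prev.evalue, -prev.bitscore):
            best[key] = r
    order: list[tuple[str, str]] = []
    seen = set()
    for r in records:
        key = (r.query_id, r.subject_id)
        if key not in seen:
            seen.add(key)
            order.append(key)
    return [best[k] for k in order]


def parse_hit_table(path: str | Path, query_species: str, subject_species: str,
                    config: Config = DEFAULT_CONFIG) -> HitTable:
    """Parse BLAST outfmt-6-style tabular hits.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend sstart
    send evalue bitscore [qlen].  With the optional 13th column, query
    coverage is computed as alignment_length / qlen.  Rows above the E-value
    cutoff are dropped and duplicates collapse to the best E-value per pair.
    """
    raw: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(f"line {lineno}: expected >=12 columns, got {len(cols)}")
            try:
                pident = float(cols[2])
                length = int(cols[3])
                evalue = float(cols[10])
                bitscore = float(cols[11])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-numeric field") from exc
            coverage = None
            if len(cols) >= 13 and cols[12] != "":
                qlen = int(cols[12])
                coverage = min(1.0, length / qlen)
            raw.append(HitRecord(cols[0], cols[1], pident, length, evalue,
                                 bitscore, coverage))
    kept = [r for r in dedupe_hits(raw) if r.evalue <= config.evalue_max]
    return HitTable(query_species, subject_species, kept)


def write_hit_table(table: HitTable, path: str | Path) -> None:
    """Write hits in 13-column tabular form (qlen recovered from coverage)."""
    with open(path, "w") as fh:
        for r in table.records:
            qlen = ""
            if r.query_coverage:
                qlen = str(round(r.alignment_length / r.query_coverage))
            fh.write("\t".join([
                r.query_id, r.subject_id, f"{r.percent_identity:.2f}",
                str(r.alignment_length), "0", "0", "0", "0", "0", "0",
                f"{r.evalue:.3g}", f"{r.bitscore:.1f}", qlen]) + "\n")


# ---------------------------------------------------------------------------
# Internal aligner
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentResult:
    percent_identity: float
    alignment_length: int
    score: float
    pseudo_evalue: float
    query_aligned: int    # query residues inside the local alignment
    subject_aligned: int


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = _GAP_OPEN
    aligner.extend_gap_score = _GAP_EXTEND
    return aligner


_ALIGNER = _make_aligner()


def pseudo_evalue(score: float, query_len: int, subject_len: int) -> float:
    """Monotone-decreasing score -> E-value transform (Karlin-Altschul shape)."""
    return _KA_K * query_len * subject_len * math.exp(-_KA_LAMBDA * score)


def align_pair(seq_a: str, seq_b: str) -> AlignmentResult:
    """Best local alignment of two protein sequences.

    BLOSUM62 with affine gaps (-11/-1); identity and length are measured over
    alignment columns including gaps, as in BLAST tabular output.
    """
    if not seq_a or not seq_b:
        raise ValueError("align_pair requires non-empty sequences")
    alignments = _ALIGNER.align(seq_a, seq_b)
    aln = alignments[0]
    counts = aln.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    pident = 100.0 * counts.identities / length if length else 0.0
    q_aligned = int(sum(e - s for s, e in aln.aligned[0]))
    s_aligned = int(sum(e - s for s, e in aln.aligned[1]))
    return AlignmentResult(
        percent_identity=pident,
        alignment_length=int(length),
        score=float(aln.score),
        pseudo_evalue=pseudo_evalue(float(aln.score), len(seq_a), len(seq_b)),
        query_aligned=q_aligned,
        subject_aligned=s_aligned,
    )


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def all_by_all(proteome_a: Mapping[str, str], proteome_b: Mapping[str, str],
               config: Config = DEFAULT_CONFIG, query_species: str = "A",
               subject_species: str = "B", kmer_size: int = 4,
               min_shared_kmers: int = 3,
               exclude_self: bool | None = None) -> HitTable:
    """Align every promising ordered pair between two proteomes.

    A shared-k-mer seed prefilter (BLAST-style seeding) selects candidate
    pairs before full local alignment; pairs sharing fewer than
    ``min_shared_kmers`` exact k-mers are skipped, which loses nothing at
    detectable divergences (a pair near the E-value cutoff shares dozens of
    4-mers) while keeping all-by-all quadratic only in the cheap seed stage.
    Hits above ``config.evalue_max`` are excluded.  When the two proteomes
    are the same set (within-species search), a gene's hit to itself is
    skipped; ``exclude_self`` overrides that default.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("all_by_all requires non-empty proteomes")
    if exclude_self is None:
        exclude_self = proteome_a is proteome_b or query_species == subject_species
    index: dict[str, set[str]] = {}
    for sid in sorted(proteome_b):
        for kmer in _kmer_set(proteome_b[sid], kmer_size):
            index.setdefault(kmer, set()).add(sid)

    records: list[HitRecord] = []
    for qid in sorted(proteome_a):
        qseq = proteome_a[qid]
        shared: dict[str, int] = {}
        for kmer in _kmer_set(qseq, kmer_size):
            for sid in index.get(kmer, ()):
                shared[sid] = shared.get(sid, 0) + 1
        for sid in sorted(s for s, n in shared.items() if n >= min_shared_kmers):
            if exclude_self and sid == qid:
                continue
            res = align_pair(qseq, proteome_b[sid])
            if res.pseudo_evalue <= config.evalue_max:
                records.append(HitRecord(
                    query_id=qid, subject_id=sid,
                    percent_identity=res.percent_identity,
                    alignment_length=res.alignment_length,
                    evalue=res.pseudo_evalue,
                    bitscore=res.score,
                    query_coverage=min(1.0, res.query_aligned / len(qseq))))
    return HitTable(query_species, subject_species, records)
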