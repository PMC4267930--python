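"""Domain types and readers/writers for annotations, sequences, coverage and expression.

All genomic intervals are held internally as 0-based half-open ``[start, end)``
on a named scaffold; GFF3 and bedGraph conventions are converted at the I/O
boundary.  Gene models follow the usual gene -> mRNA -> {exon, CDS, UTR}
hierarchy, with one :class:`TranscriptModel` per mRNA and features stored as
flat :class:`FeatureInterval` lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger("annoforge")

FEATURE_KINDS = ("exon", "CDS", "five_prime_UTR", "three_prime_UTR")
CHROMOSOME_CLASSES = ("major_arm", "minor", "unplaced")
STRANDS = ("+", "-")


class AnnoforgeError(Exception):
    """Base class for all package errors."""


class GFF3ParseError(AnnoforgeError):
    """Malformed GFF3 row or attribute column (message names the line number)."""


class GFF3StructuralError(AnnoforgeError):
    """Parent attribute referencing a missing ID, or an otherwise broken hierarchy."""


class FormatError(AnnoforgeError):
    """Malformed tabular input (bedGraph, TSV, BLAST tabular)."""


class ConsistencyError(AnnoforgeError):
    """Cross-file inconsistency, e.g. a scaffold present in GFF but not the genome."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class Config:
    """Analysis thresholds.

    Defaults encode the study conditions: a predicted model matches a
    reference model when it covers >=85% of the reference CDS/protein at
    >=90% amino-acid identity with E <= 1e-10; near-tied similarity hits
    within one log10 unit of E-value share a rank; unmatched reference
    models are rescued at FPKM >= 2; differential expression is called at
    Benjamini-Hochberg FDR <= 0.1; a gene model counts as supported when
    >=60% of its features have read coverage.
    """

    cds_coverage_min: float = 0.85
    aa_similarity_min: float = 0.90
    evalue_max: float = 1e-10
    log_unit: float = 1.0
    fpkm_rescue_min: float = 2.0
    fdr_alpha: float = 0.1
    feature_support_min: float = 0.60
    feature_depth_min: float = 1.0
    feature_covered_fraction_min: float = 0.5
    evalue_floor: float = 1e-200
    rng_seed: int = 0
    # open design knobs exposed as configuration
    rank_grouping: str = "anchored"     # {"anchored", "chained"}
    require_same_strand: bool = True
    coverage_side: str = "reference"    # which protein the 85% coverage applies to

    def __post_init__(self) -> None:
        for name in ("cds_coverage_min", "aa_similarity_min", "fdr_alpha",
                     "feature_support_min", "feature_covered_fraction_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.evalue_floor <= 0:
            raise ValueError("evalue_floor must be positive")
        if self.rank_grouping not in ("anchored", "chained"):
            raise ValueError("rank_grouping must be 'anchored' or 'chained'")


DEFAULT_CONFIG = Config()


# ---------------------------------------------------------------------------
# Gene-model types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class FeatureInterval:
    """One exon/CDS/UTR interval, 0-based half-open."""

    scaffold: str
    start: int
    end: int
    strand: str
    kind: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.start}..{self.end}")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    features: list[FeatureInterval]
    source: str = "predicted"  # {"predicted", "reference"}
    partial: bool = False      # CDS length not a multiple of 3

    def __post_init__(self) -> None:
        if self.features:
            scaffolds = {f.scaffold for f in self.features}
            strands = {f.strand for f in self.features}
            if len(scaffolds) > 1 or len(strands) > 1:
                raise ValueError(
                    f"transcript {self.transcript_id}: features span multiple "
                    f"scaffolds/strands ({scaffolds}, {strands})")
        self.features = sorted(self.features, key=lambda f: (f.start, f.end, f.kind))
        cds = self.cds_intervals
        for a, b in zip(cds, cds[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping CDS intervals")
        if self.cds_length % 3 != 0:
            self.partial = True

    @property
    def scaffold(self) -> str:
        return self.features[0].scaffold

    @property
    def strand(self) -> str:
        return self.features[0].strand

    @property
    def cds_intervals(self) -> list[FeatureInterval]:
        return [f for f in self.features if f.kind == "CDS"]

    @property
    def cds_length(self) -> int:
        return sum(len(f) for f in self.cds_intervals)

    @property
    def span(self) -> tuple[int, int]:
        return (min(f.start for f in self.features), max(f.end for f in self.features))


@dataclass
class GeneModel:
    gene_id: str
    species: str
    scaffold: str
    transcripts: list[TranscriptModel]
    chromosome_class: str = "unplaced"

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        if any(t.scaffold != self.scaffold for t in self.transcripts):
            raise ValueError(f"gene {self.gene_id}: transcripts on multiple scaffolds")
        if self.chromosome_class not in CHROMOSOME_CLASSES:
            raise ValueError(f"unknown chromosome_class {self.chromosome_class!r}")

    @property
    def span(self) -> tuple[int, int]:
        starts, ends = zip(*(t.span for t in self.transcripts))
        return (min(starts), max(ends))

    def longest_cds_transcript(self) -> TranscriptModel:
        """Representative isoform: the transcript with the longest total CDS."""
        return max(self.transcripts, key=lambda t: (t.cds_length, t.transcript_id))

    def unique_features(self) -> list[FeatureInterval]:
        """Union of features over all transcripts, deduplicated by coordinates."""
        return sorted(set(f for t in self.transcripts for f in t.features))


# ---------------------------------------------------------------------------
# Coverage and expression
# ---------------------------------------------------------------------------

class CoverageTrack:
    """Per-scaffold read-depth intervals (0-based half-open, non-overlapping).

    Positions absent from the track have depth 0.
    """

    def __init__(self, intervals: Mapping[str, Sequence[tuple[int, int, float]]] | None = None):
        self._data: dict[str, list[tuple[int, int, float]]] = {}
        if intervals:
            for scaffold, ivs in intervals.items():
                for start, end, depth in ivs:
                    self.add(scaffold, start, end, depth)
        self._validate()

    def add(self, scaffold: str, start: int, end: int, depth: float) -> None:
        if depth < 0:
            raise FormatError(f"negative depth {depth} on {scaffold}:{start}-{end}")
        if start >= end:
            raise FormatError(f"empty coverage interval {scaffold}:{start}-{end}")
        self._data.setdefault(scaffold, []).append((start, end, float(depth)))

    def _validate(self) -> None:
        for scaffold, ivs in self._data.items():
            ivs.sort()
            for (s1, e1, _), (s2, e2, _) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise FormatError(
                        f"overlapping coverage intervals on {scaffold}: "
                        f"[{s1},{e1}) and [{s2},{e2})")

    def scaffolds(self) -> list[str]:
        return sorted(self._data)

    def covered_bases(self, scaffold: str, start: int, end: int,
                      min_depth: float = 1.0) -> int:
        """Number of bases of [start, end) with depth >= min_depth."""
        total = 0
        for s, e, d in self._data.get(scaffold, []):
            if e <= start:
                continue
            if s >= end:
                break
            if d >= min_depth:
                total += min(e, end) - max(s, start)
        return total

    def covered_fraction(self, feature: FeatureInterval, min_depth: float = 1.0) -> float:
        n = self.covered_bases(feature.scaffold, feature.start, feature.end, min_depth)
        return n / len(feature)


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-gene, per-sample expression; at least one of count/fpkm is present."""

    gene_id: str
    sample_id: str
    count: Optional[int] = None
    fpkm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.count is None and self.fpkm is None:
            raise ValueError(f"{self.gene_id}/{self.sample_id}: neither count nor fpkm")
        if self.count is not None and self.count < 0:
            raise ValueError("negative count")
        if self.fpkm is not None and self.fpkm < 0:
            raise ValueError("negative fpkm")


# ---------------------------------------------------------------------------
# Coordinate conversion
# ---------------------------------------------------------------------------

def gff_to_internal(start_1based: int, end_1based: int) -> tuple[int, int]:
    """GFF3 1-based inclusive -> 0-based half-open."""
    return start_1based - 1, end_1based


def internal_to_gff(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> GFF3 1-based inclusive."""
    return start + 1, end


# ---------------------------------------------------------------------------
# GFF3 reader / writer
# ---------------------------------------------------------------------------

_GFF_KIND_ALIASES = {
    "exon": "exon",
    "cds": "CDS",
    "five_prime_utr": "five_prime_UTR",
    "three_prime_utr": "three_prime_UTR",
}


def _parse_attributes(col: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in col.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise GFF3ParseError(f"line {lineno}: malformed attribute {item!r}")
        key, _, value = item.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def parse_gff3(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 file into gene models.

    gene/mRNA rows define the hierarchy via ID/Parent; exon, CDS and UTR rows
    attach to their mRNA.  Coordinates are converted to 0-based half-open.
    Rows of any other feature type are skipped with a logged warning.
    """
    genes: dict[str, dict] = {}          # gene_id -> {row attrs}
    transcripts: dict[str, dict] = {}    # transcript_id -> {gene_id, features, source}
    order: list[str] = []                # gene ids in file order
    pending: list[tuple[int, str, FeatureInterval]] = []  # (lineno, parent, feature)
    skipped_kinds: set[str] = set()

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GFF3ParseError(f"line {lineno}: expected 9 columns, got {len(cols)}")
            scaffold, source, ftype, start_s, end_s, _score, strand, _phase, attr_col = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GFF3ParseError(f"line {lineno}: non-integer coordinates") from exc
            attrs = _parse_attributes(attr_col, lineno)
            start, end = gff_to_internal(start1, end1)

            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise GFF3ParseError(f"line {lineno}: gene row without ID")
                genes[gid] = {
                    "scaffold": scaffold,
                    "species": attrs.get("species", ""),
                    "chromosome_class": attrs.get("chromosome_class", "unplaced"),
                }
                order.append(gid)
            elif ftype in ("mRNA", "transcript"):
                tid, parent = attrs.get("ID"), attrs.get("Parent")
                if tid is None or parent is None:
                    raise GFF3ParseError(f"line {lineno}: mRNA row needs ID and Parent")
                transcripts[tid] = {"gene_id": parent, "features": [],
                                    "source": attrs.get("source_class", source)}
            elif ftype.lower() in _GFF_KIND_ALIASES:
                parent = attrs.get("Parent")
                if parent is None:
                    raise GFF3ParseError(f"line {lineno}: {ftype} row without Parent")
                kind = _GFF_KIND_ALIASES[ftype.lower()]
                if strand not in STRANDS:
                    raise GFF3ParseError(f"line {lineno}: undefined strand {strand!r}")
                pending.append((lineno, parent,
                                FeatureInterval(scaffold, start, end, strand, kind)))
            else:
                if ftype not in skipped_kinds:
                    logger.warning("skipping unknown GFF3 feature kind %r", ftype)
                    skipped_kinds.add(ftype)

    for lineno, parent, feature in pending:
        if parent not in transcripts:
            raise GFF3StructuralError(
                f"line {lineno}: Parent={parent!r} references no mRNA ID")
        transcripts[parent]["features"].append(feature)

    by_gene: dict[str, list[TranscriptModel]] = {}
    for tid, rec in transcripts.items():
        gid = rec["gene_id"]
        if gid not in genes:
            raise GFF3StructuralError(f"mRNA {tid}: Parent={gid!r} references no gene ID")
        source = rec["source"] if rec["source"] in ("predicted", "reference") else "predicted"
        by_gene.setdefault(gid, []).append(
            TranscriptModel(tid, gid, rec["features"], source=source))

    models = []
    for gid in order:
        if gid not in by_gene:
            logger.warning("gene %s has no mRNA children; skipped", gid)
            continue
        info = genes[gid]
        models.append(GeneModel(
            gene_id=gid, species=info["species"], scaffold=info["scaffold"],
            transcripts=sorted(by_gene[gid], key=lambda t: t.transcript_id),
            chromosome_class=info["chromosome_class"]))
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3, sorted by scaffold then start.

    Output is byte-deterministic for identical input, and round-trips through
    :func:`parse_gff3`.
    """
    lines = ["##gff-version 3"]
    for gene in sorted(models, key=lambda g: (g.scaffold, g.span[0], g.gene_id)):
        gstart, gend = gene.span
        g1, g2 = internal_to_gff(gstart, gend)
        strand = gene.transcripts[0].strand
        attrs = f"ID={gene.gene_id}"
        if gene.species:
            attrs += f";species={gene.species}"
        attrs += f";chromosome_class={gene.chromosome_class}"
        lines.append("\t".join([gene.scaffold, "annoforge", "gene", str(g1), str(g2),
                                ".", strand, ".", attrs]))
        for t in gene.transcripts:
            t1, t2 = internal_to_gff(*t.span)
            lines.append("\t".join([
                gene.scaffold, "annoforge", "mRNA", str(t1), str(t2), ".", t.strand,
                ".", f"ID={t.transcript_id};Parent={gene.gene_id};source_class={t.source}"]))
            cds_seen = 0
            ordered = t.features if t.strand == "+" else list(reversed(t.features))
            for f in ordered:
                f1, f2 = internal_to_gff(f.start, f.end)
                phase = "."
                if f.kind == "CDS":
                    phase = str((3 - cds_seen % 3) % 3)
                    cds_seen += len(f)
                lines.append("\t".join([
                    f.scaffold, "annoforge", f.kind, str(f1), str(f2), ".", f.strand,
                    phase, f"Parent={t.transcript_id}"]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Sequence operations
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# standard genetic code; '*' marks stop
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_cds_sequence(model: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Concatenate a transcript's CDS intervals in transcription order.

    Minus-strand transcripts are reverse-complemented, with the 3'-most
    genomic interval first.
    """
    if model.scaffold not in genome:
        raise ConsistencyError(f"scaffold {model.scaffold!r} absent from genome")
    seq = genome[model.scaffold]
    parts = []
    for f in model.cds_intervals:
        if f.end > len(seq):
            raise ConsistencyError(
                f"CDS interval {f.start}-{f.end} beyond end of {model.scaffold} "
                f"(length {len(seq)})")
        parts.append(seq[f.start:f.end])
    if model.strand == "+":
        return "".join(parts)
    return "".join(reverse_complement(p) for p in reversed(parts))


def translate_cds(cds: str) -> str:
    """Translate a CDS with the standard code, stopping at the first stop codon.

    Trailing bases beyond the last full codon are dropped with a warning;
    codons containing N (or otherwise unknown) translate to 'X'.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        logger.warning("CDS length %d not a multiple of 3; trailing bases dropped",
                       len(cds))
    residues = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        aa = CODON_TABLE.get(cds[i:i + 3], "X")
        if aa == "*":
            break
        residues.append(aa)
    return "".join(residues)


# ---------------------------------------------------------------------------
# FASTA, bedGraph and expression TSV
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping (id = first token)."""
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            seq = seqs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_coverage_bedgraph(path: str | Path) -> CoverageTrack:
    """Read a bedGraph (0-based half-open) into a :class:`CoverageTrack`."""
    track = CoverageTrack()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split()
            if len(cols) != 4:
                raise FormatError(f"line {lineno}: bedGraph needs 4 columns")
            scaffold, start_s, end_s, depth_s = cols
            try:
                start, end, depth = int(start_s), int(end_s), float(depth_s)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-numeric bedGraph fields") from exc
            if depth < 0:
                raise FormatError(f"line {lineno}: negative depth {depth}")
            track.add(scaffold, start, end, depth)
    track._validate()
    return track


def write_coverage_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for scaffold in track.scaffolds():
            for start, end, depth in track._data[scaffold]:
                fh.write(f"{scaffold}\t{start}\t{end}\t{depth:g}\n")


def read_expression_tsv(path: str | Path) -> list[ExpressionRecord]:
    """Read a headered TSV with columns gene_id, sample_id and count and/or fpkm."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "sample_id"):
        if col not in df.columns:
            raise FormatError(f"expression TSV missing column {col!r}")
    has_count, has_fpkm = "count" in df.columns, "fpkm" in df.columns
    if not has_count and not has_fpkm:
        raise FormatError("expression TSV needs a count and/or fpkm column")
    records = []
    for _, row in df.iterrows():
        count = None
        fpkm = None
        if has_count and not pd.isna(row["count"]):
            count = int(row["count"])
        if has_fpkm and not pd.isna(row["fpkm"]):
            fpkm = float(row["fpkm"])
        records.append(ExpressionRecord(str(row["gene_id"]), str(row["sample_id"]),
                                        count=count, fpkm=fpkm))
    return records


def write_expression_tsv(records: Iterable[ExpressionRecord], path: str | Path) -> None:
    rows = [{"gene_id": r.gene_id, "sample_id": r.sample_id,
             "count": r.count, "fpkm": r.fpkm} for r in records]
    pd.DataFrame(rows, columns=["gene_id", "sample_id", "count", "fpkm"]).to_csv(
        path, sep="\t", index=False)
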