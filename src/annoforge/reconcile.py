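"""Reconciliation of predicted gene models against a reference annotation.

A predicted model *matches* a reference model when their CDS intervals
physically overlap on the same scaffold and strand AND the predicted protein
aligns to the reference protein covering >=85% of it at >=90% identity with
E <= 1e-10.  Predicted models are then classified one_to_one (exactly one
match), polycistronic (>=2 matches: a single prediction spanning multiple
independent reference genes), or novel (no match).  Unmatched reference
models with expression evidence (FPKM >= 2) are rescued as orphans, and the
merged annotation carries both the fused prediction and its member reference
models whenever those members lack a one-to-one prediction of their own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from intervaltree import IntervalTree

from .homology import HitTable, align_pair
from .io_model import (Config, ConsistencyError, CoverageTrack, DEFAULT_CONFIG,
                       ExpressionRecord, GeneModel, extract_cds_sequence,
                       translate_cds)

logger = logging.getLogger("annoforge")

MATCH_CLASSES = ("one_to_one", "polycistronic", "novel")


@dataclass(frozen=True)
class MatchEvidence:
    overlap_bp: int
    query_coverage: float      # fraction of the reference protein aligned
    percent_identity: float
    evalue: float


@dataclass
class ReconciliationRecord:
    predicted_id: str
    matched_reference_ids: list[str]
    match_class: str = field(init=False)
    evidence: dict[str, MatchEvidence] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.matched_reference_ids)
        self.match_class = ("novel" if n == 0
                            else "one_to_one" if n == 1
                            else "polycistronic")


@dataclass(frozen=True)
class OrphanRecord:
    reference_id: str
    max_fpkm: float
    rescued: bool


@dataclass(frozen=True)
class SupportReport:
    gene_id: str
    n_features: int
    n_supported: int
    supported_fraction: float
    gene_supported: bool


# ---------------------------------------------------------------------------
# Model matching
# ---------------------------------------------------------------------------

def _check_scaffolds(models: Iterable[GeneModel], genome: Mapping[str, str]) -> None:
    missing = sorted({m.scaffold for m in models} - set(genome))
    if missing:
        raise ConsistencyError(f"scaffolds in GFF absent from genome: {missing}")


def _protein(model: GeneModel, genome: Mapping[str, str]) -> str:
    return translate_cds(extract_cds_sequence(model.longest_cds_transcript(), genome))


def match_models(predicted: list[GeneModel], reference: list[GeneModel],
                 genome: Mapping[str, str], hits: HitTable | None = None,
                 config: Config = DEFAULT_CONFIG) -> list[ReconciliationRecord]:
    """Classify every predicted model against the reference annotation.

    Matching is evaluated at the gene level on each gene's longest-CDS
    transcript.  Homology evidence comes from ``hits`` when supplied (a
    table whose *queries are reference gene ids* and subjects predicted gene
    ids, so ``query_coverage`` is reference-protein coverage), otherwise
    from the internal aligner on translated CDS sequences.
    """
    _check_scaffolds(predicted, genome)
    _check_scaffolds(reference, genome)

    trees: dict[tuple[str, str], IntervalTree] = {}
    ref_by_id = {g.gene_id: g for g in reference}
    for g in reference:
        t = g.longest_cds_transcript()
        key = (g.scaffold, t.strand if config.require_same_strand else ".")
        tree = trees.setdefault(key, IntervalTree())
        for f in t.cds_intervals:
            tree.addi(f.start, f.end, g.gene_id)

    hit_index: dict[tuple[str, str], object] = {}
    if hits is not None:
        for r in hits.records:
            hit_index[(r.query_id, r.subject_id)] = r

    protein_cache: dict[str, str] = {}

    def ref_protein(gid: str) -> str:
        if gid not in protein_cache:
            protein_cache[gid] = _protein(ref_by_id[gid], genome)
        return protein_cache[gid]

    records = []
    for pg in sorted(predicted, key=lambda g: g.gene_id):
        pt = pg.longest_cds_transcript()
        key = (pg.scaffold, pt.strand if config.require_same_strand else ".")
        overlaps: dict[str, int] = {}
        tree = trees.get(key)
        if tree is not None:
            for f in pt.cds_intervals:
                for iv in tree.overlap(f.start, f.end):
                    bp = min(iv.end, f.end) - max(iv.begin, f.start)
                    overlaps[iv.data] = overlaps.get(iv.data, 0) + bp

        matched: list[str] = []
        evidence: dict[str, MatchEvidence] = {}
        pred_protein: Optional[str] = None
        for ref_id in sorted(overlaps):
            if hits is not None:
                rec = hit_index.get((ref_id, pg.gene_id))
                if rec is None or rec.query_coverage is None:
                    continue
                coverage, pident, evalue = rec.query_coverage, rec.percent_identity, rec.evalue
            else:
                if pred_protein is None:
                    pred_protein = _protein(pg, genome)
                rp = ref_protein(ref_id)
                if not rp or not pred_protein:
                    continue
                res = align_pair(rp, pred_protein)
                if config.coverage_side == "reference":
                    coverage = res.query_aligned / len(rp)
                else:
                    coverage = res.subject_aligned / len(pred_protein)
                pident, evalue = res.percent_identity, res.pseudo_evalue
            ev = MatchEvidence(overlaps[ref_id], coverage, pident, evalue)
            if (coverage >= config.cds_coverage_min
                    and pident >= config.aa_similarity_min * 100.0
                    and evalue <= config.evalue_max):
                matched.append(ref_id)
                evidence[ref_id] = ev
        records.append(ReconciliationRecord(pg.gene_id, matched, evidence=evidence))
    return records


# ---------------------------------------------------------------------------
# Orphan rescue and annotation merge
# ---------------------------------------------------------------------------

def rescue_orphans(reference: list[GeneModel],
                   reconciliation: list[ReconciliationRecord],
                   expression: list[ExpressionRecord],
                   config: Config = DEFAULT_CONFIG) -> list[OrphanRecord]:
    """Reference genes matched by no prediction, rescued when max FPKM >= 2.

    The boundary is inclusive; genes without expression records get
    max_fpkm = 0.
    """
    matched = {rid for rec in reconciliation for rid in rec.matched_reference_ids}
    fpkm_by_gene: dict[str, float] = {}
    for r in expression:
        if r.fpkm is not None:
            fpkm_by_gene[r.gene_id] = max(fpkm_by_gene.get(r.gene_id, 0.0), r.fpkm)
    out = []
    for g in sorted(reference, key=lambda g: g.gene_id):
        if g.gene_id in matched:
            continue
        mx = fpkm_by_gene.get(g.gene_id, 0.0)
        out.append(OrphanRecord(g.gene_id, mx, mx >= config.fpkm_rescue_min))
    return out


def merge_annotations(predicted: list[GeneModel], reference: list[GeneModel],
                      reconciliation: list[ReconciliationRecord],
                      orphans: list[OrphanRecord]) -> list[GeneModel]:
    """Build the merged annotation.

    Output = all predicted models, plus rescued orphan reference models,
    plus — for every polycistronic prediction — each member reference model
    that has no one-to-one predicted match of its own (the dual-annotation
    rule: the fused transcript and the independent genes are both kept).
    Gene-id collisions after the merge are resolved by source-prefixing.
    """
    ref_by_id = {g.gene_id: g for g in reference}
    one_to_one_refs = {rec.matched_reference_ids[0] for rec in reconciliation
                       if rec.match_class == "one_to_one"}

    merged: list[GeneModel] = list(predicted)
    added: set[str] = set()
    for orphan in orphans:
        if orphan.rescued and orphan.reference_id not in added:
            merged.append(ref_by_id[orphan.reference_id])
            added.add(orphan.reference_id)
    for rec in reconciliation:
        if rec.match_class != "polycistronic":
            continue
        for member in rec.matched_reference_ids:
            if member not in one_to_one_refs and member not in added:
                merged.append(ref_by_id[member])
                added.add(member)

    seen: dict[str, int] = {}
    out: list[GeneModel] = []
    for g in merged:
        if g.gene_id in seen:
            prefix = "ref" if g.gene_id in added else "pred"
            new_id = f"{prefix}:{g.gene_id}"
            logger.warning("gene id collision on %s; renamed to %s", g.gene_id, new_id)
            g = GeneModel(new_id, g.species, g.scaffold, g.transcripts,
                          g.chromosome_class)
        seen[g.gene_id] = 1
        out.append(g)
    return out


def annotation_counts(models: list[GeneModel]) -> dict[str, int]:
    """Transcript and gene totals for a revised-annotation summary."""
    return {"genes": len(models),
            "transcripts": sum(len(g.transcripts) for g in models)}


# ---------------------------------------------------------------------------
# Expression normalization
# ---------------------------------------------------------------------------

def fpkm(counts: Mapping[str, int], cds_lengths: Mapping[str, int],
         normalization: str = "total") -> dict[str, float]:
    """Fragments per kilobase of exon model per million mapped fragments.

    FPKM_g = count_g * 1e9 / (length_g * N).  In ``total`` mode N is the
    summed count; in ``upper_quartile`` mode N is the 75th percentile of
    nonzero gene counts scaled by the number of genes (its library-size
    equivalent), which makes the normalizer robust to a few dominant genes.
    """
    import numpy as np

    if normalization not in ("total", "upper_quartile"):
        raise ValueError(f"unknown normalization {normalization!r}")
    values = [counts[g] for g in counts]
    if normalization == "total":
        n = float(sum(values))
        if n == 0:
            raise ValueError("zero total count: FPKM undefined")
    else:
        nonzero = [v for v in values if v > 0]
        if not nonzero:
            raise ValueError("upper_quartile normalization needs a nonzero count")
        n = float(np.percentile(nonzero, 75)) * len(values)
    out = {}
    for g, c in counts.items():
        length = cds_lengths[g]
        if length <= 0:
            raise ValueError(f"gene {g}: non-positive CDS length")
        out[g] = c * 1e9 / (length * n)
    return out


# ---------------------------------------------------------------------------
# Feature support
# ---------------------------------------------------------------------------

def feature_support(model: GeneModel, coverage: CoverageTrack,
                    config: Config = DEFAULT_CONFIG) -> SupportReport:
    """Score RNA-seq support over a gene's deduplicated feature set.

    A feature is supported when at least ``feature_covered_fraction_min`` of
    its bases reach depth ``feature_depth_min``; the gene is supported when
    the supported fraction of features reaches ``feature_support_min``
    (inclusive at the boundary).
    """
    features = model.unique_features()
    n_supported = sum(
        1 for f in features
        if coverage.covered_fraction(f, config.feature_depth_min)
        >= config.feature_covered_fraction_min)
    fraction = n_supported / len(features) if features else 0.0
    return SupportReport(model.gene_id, len(features), n_supported, fraction,
                         fraction >= config.feature_support_min)


def support_summary(models: list[GeneModel], coverage: CoverageTrack,
                    config: Config = DEFAULT_CONFIG) -> float:
    """Percent of gene models supported (0-100)."""
    if not models:
        return 0.0
    supported = sum(feature_support(g, coverage, config).gene_supported
                    for g in models)
    return 100.0 * supported / len(models)
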