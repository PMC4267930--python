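"""Fuzzy reciprocal-best-hit orthology and lineage-specific gene calls.

Hits for one query are ranked with a fuzz rule: hits whose E-values lie
within one log10 unit of the best hit in their group share a rank, so
near-tied paralogs are not arbitrarily split by tiny E-value differences.
Two genes are called orthologs when each appears in the other's ranked hit
list at the same rank; pairs at rank 1 on both sides are *first-order*
orthologs.  A gene is lineage-specific when it has no qualifying hit
(E <= 1e-10) against any outgroup proteome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .homology import HitTable
from .io_model import Config, DEFAULT_CONFIG, GeneModel


@dataclass
class RankedHits:
    """A query's hits grouped into ranks (rank index starts at 1)."""

    query_id: str
    groups: list[list[tuple[str, float]]] = field(default_factory=list)

    def rank_of(self, subject_id: str) -> Optional[int]:
        for i, group in enumerate(self.groups, start=1):
            if any(sid == subject_id for sid, _ in group):
                return i
        return None

    def flat(self) -> list[tuple[str, float]]:
        return [hit for group in self.groups for hit in group]


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    species_a: str
    species_b: str
    rank_a: int       # rank of gene_b in gene_a's hit list
    rank_b: int       # rank of gene_a in gene_b's hit list
    first_order: bool


@dataclass
class LineageSpecificCall:
    gene_id: str
    species: str
    on_major_arm: bool
    differentially_expressed: bool = False


def assign_ranks(query_id: str, hits: Iterable[tuple[str, float]],
                 config: Config = DEFAULT_CONFIG) -> RankedHits:
    """Group one query's hits into log-unit rank groups.

    Hits are sorted by E-value (ties broken by subject id); grouping is
    anchored at each group's best hit: a hit joins the current group iff
    log10(e) - log10(e_group_best) <= log_unit (inclusive), else it opens
    the next group.  ``config.rank_grouping = "chained"`` instead compares
    each hit with its predecessor, letting a chain of near-ties drift.
    E-values are floored at ``config.evalue_floor`` before the log.
    """
    floored = [(sid, max(e, config.evalue_floor)) for sid, e in hits]
    ordered = sorted(floored, key=lambda h: (h[1], h[0]))
    ranked = RankedHits(query_id)
    if not ordered:
        return ranked
    current = [ordered[0]]
    anchor_log = math.log10(ordered[0][1])
    prev_log = anchor_log
    for sid, e in ordered[1:]:
        log_e = math.log10(e)
        base = prev_log if config.rank_grouping == "chained" else anchor_log
        if log_e - base <= config.log_unit:
            current.append((sid, e))
        else:
            ranked.groups.append(current)
            current = [(sid, e)]
            anchor_log = log_e
        prev_log = log_e
    ranked.groups.append(current)
    return ranked


def rank_all_queries(table: HitTable, config: Config = DEFAULT_CONFIG
                     ) -> dict[str, RankedHits]:
    """Ranked hits for every query of a table (self-hits dropped for
    within-species tables)."""
    same_species = table.query_species == table.subject_species
    out = {}
    for qid, hits in table.by_query().items():
        pairs = [(r.subject_id, r.evalue) for r in hits
                 if not (same_species and r.subject_id == qid)]
        if pairs:
            out[qid] = assign_ranks(qid, pairs, config)
    return out


def fuzzy_rbh(table_ab: HitTable, table_ba: HitTable,
              config: Config = DEFAULT_CONFIG) -> list[OrthologPair]:
    """All (a, b) with b at rank r in a's hits and a at the same rank r in
    b's hits.  Many-to-many pairs are permitted; ``first_order`` marks
    rank-1/rank-1 pairs."""
    ranks_a = rank_all_queries(table_ab, config)
    ranks_b = rank_all_queries(table_ba, config)
    pairs = []
    for a in sorted(ranks_a):
        for r_a, group in enumerate(ranks_a[a].groups, start=1):
            for b, _e in group:
                rb = ranks_b.get(b)
                if rb is None:
                    continue
                r_b = rb.rank_of(a)
                if r_b is not None and r_b == r_a:
                    pairs.append(OrthologPair(
                        a, b, table_ab.query_species, table_ab.subject_species,
                        r_a, r_b, first_order=(r_a == 1)))
    return sorted(pairs, key=lambda p: (p.gene_a, p.gene_b))


def first_order_count(pairs: Sequence[OrthologPair]) -> int:
    """Number of distinct query-side genes with >=1 first-order ortholog."""
    return len({p.gene_a for p in pairs if p.first_order})


def ortholog_table(species: Sequence[str],
                   hit_tables: Mapping[tuple[str, str], HitTable],
                   config: Config = DEFAULT_CONFIG
                   ) -> tuple[dict[tuple[str, str], list[OrthologPair]],
                              dict[tuple[str, str], int]]:
    """Ortholog pairs and first-order gene counts for every ordered species pair.

    The count for (A, B) is the number of A genes having at least one
    first-order ortholog in B (a count of genes, not of pairs); the table
    need not be symmetric.
    """
    pairs_by: dict[tuple[str, str], list[OrthologPair]] = {}
    counts: dict[tuple[str, str], int] = {}
    for a in species:
        for b in species:
            if a == b:
                continue
            if (a, b) not in hit_tables or (b, a) not in hit_tables:
                raise KeyError(f"missing hit table for species pair ({a}, {b})")
            pairs = fuzzy_rbh(hit_tables[(a, b)], hit_tables[(b, a)], config)
            pairs_by[(a, b)] = pairs
            counts[(a, b)] = first_order_count(pairs)
    return pairs_by, counts


def lineage_specific(models: Sequence[GeneModel], focal_species: str,
                     outgroups: Sequence[str],
                     hit_tables: Mapping[str, HitTable],
                     de_flags: Mapping[str, bool] | None = None,
                     config: Config = DEFAULT_CONFIG) -> list[LineageSpecificCall]:
    """Genes of the focal species with zero qualifying hits in every outgroup.

    ``hit_tables`` maps each outgroup species name to the focal->outgroup
    table (already filtered at the E-value cutoff); a missing table raises,
    because absence of evidence must be explicit.  ``de_flags`` optionally
    marks genes differentially expressed in >=1 tissue contrast.
    """
    if not outgroups:
        raise ValueError("lineage_specific requires at least one outgroup")
    with_hits: set[str] = set()
    for og in outgroups:
        if og not in hit_tables:
            raise KeyError(f"missing hit table focal->{og}")
        with_hits.update(r.query_id for r in hit_tables[og].records)
    calls = []
    for g in sorted(models, key=lambda m: m.gene_id):
        if g.species and g.species != focal_species:
            continue
        if g.gene_id in with_hits:
            continue
        calls.append(LineageSpecificCall(
            gene_id=g.gene_id, species=focal_species,
            on_major_arm=(g.chromosome_class == "major_arm"),
            differentially_expressed=bool(de_flags.get(g.gene_id, False))
            if de_flags else False))
    return calls
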