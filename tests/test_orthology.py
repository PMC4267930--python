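"""Fuzzy-RBH ranking and pairing, checked against brute-force oracles."""

import math
import random

import pytest

from annoforge.homology import HitRecord, HitTable
from annoforge.io_model import Config
from annoforge.orthology import (assign_ranks, fuzzy_rbh, lineage_specific,
                                 ortholog_table)


def ranks_of(ranked):
    """subject -> rank index from a RankedHits."""
    return {sid: i for i, group in enumerate(ranked.groups, start=1)
            for sid, _ in group}


class TestAssignRanks:
    def test_log_unit_grouping(self):
        ranked = assign_ranks("q", [("a", 1e-50), ("b", 5e-50), ("c", 1e-30)])
        assert ranks_of(ranked) == {"a": 1, "b": 1, "c": 2}

    def test_single_hit_is_rank_one(self):
        assert ranks_of(assign_ranks("q", [("a", 1e-12)])) == {"a": 1}

    def test_boundary_gap_of_exactly_one_log_unit_shares_rank(self):
        ranked = assign_ranks("q", [("a", 1e-51), ("b", 1e-50)])
        assert ranks_of(ranked) == {"a": 1, "b": 1}

    def test_anchored_grouping_breaks_drifting_chain(self):
        # logs -21.2, -20.5, -20: each step <=1 but -20 is 1.2 from the anchor
        hits = [("a", 10 ** -21.2), ("b", 10 ** -20.5), ("c", 10 ** -20.0)]
        assert ranks_of(assign_ranks("q", hits)) == {"a": 1, "b": 1, "c": 2}
        chained = Config(rank_grouping="chained")
        assert ranks_of(assign_ranks("q", hits, chained)) == {"a": 1, "b": 1, "c": 1}

    def test_empty_hit_list(self):
        assert assign_ranks("q", []).groups == []

    def test_zero_evalues_floored_before_log(self):
        ranked = assign_ranks("q", [("a", 0.0), ("b", 1e-200)])
        assert ranks_of(ranked) == {"a": 1, "b": 1}

    def test_groups_partition_the_sorted_hit_list(self):
        rng = random.Random(17)
        for _ in range(100):
            hits = [(f"s{i}", 10 ** -rng.uniform(10, 80)) for i in range(rng.randint(0, 15))]
            ranked = assign_ranks("q", hits)
            flat = ranked.flat()
            assert sorted(flat, key=lambda h: (h[1], h[0])) == flat
            assert sorted(sid for sid, _ in flat) == sorted(s for s, _ in hits)


# ---------------------------------------------------------------------------
# Brute-force oracle for the reciprocal same-rank definition
# ---------------------------------------------------------------------------

def oracle_rank(hits, subject, log_unit=1.0, floor=1e-200):
    """Independent re-statement of the rank rule: sort, group greedily from
    each group's best hit, return the group index of `subject`."""
    ordered = sorted(((s, max(e, floor)) for s, e in hits),
                     key=lambda h: (h[1], h[0]))
    rank = 0
    anchor = None
    for sid, e in ordered:
        if anchor is None or math.log10(e) - math.log10(anchor) > log_unit:
            rank += 1
            anchor = e
        if sid == subject:
            return rank
    return None


def oracle_pairs(table_ab, table_ba):
    hits_a = {q: [(r.subject_id, r.evalue) for r in rs]
              for q, rs in table_ab.by_query().items()}
    hits_b = {q: [(r.subject_id, r.evalue) for r in rs]
              for q, rs in table_ba.by_query().items()}
    out = set()
    for a in hits_a:
        for b, _ in hits_a[a]:
            ra = oracle_rank(hits_a[a], b)
            rb = oracle_rank(hits_b.get(b, []), a)
            if ra is not None and rb is not None and ra == rb:
                out.add((a, b, ra == 1))
    return out


def random_tables(rng, n_genes=20, density=0.2):
    recs_ab, recs_ba = [], []
    for i in range(n_genes):
        for j in range(n_genes):
            if rng.random() < density:
                recs_ab.append(HitRecord(f"a{i}", f"b{j}", 50.0, 100,
                                         10 ** -rng.uniform(10, 80), 100.0))
            if rng.random() < density:
                recs_ba.append(HitRecord(f"b{j}", f"a{i}", 50.0, 100,
                                         10 ** -rng.uniform(10, 80), 100.0))
    return (HitTable("A", "B", recs_ab), HitTable("B", "A", recs_ba))


class TestFuzzyRBH:
    def test_smallest_mutual_pair_is_first_order(self):
        ab = HitTable("A", "B", [HitRecord("a", "b", 90.0, 100, 1e-80, 200.0)])
        ba = HitTable("B", "A", [HitRecord("b", "a", 90.0, 100, 1e-80, 200.0)])
        pairs = fuzzy_rbh(ab, ba)
        assert len(pairs) == 1 and pairs[0].first_order

    def test_rank_mismatch_gives_no_pair(self):
        ab = HitTable("A", "B", [HitRecord("a", "b", 90.0, 100, 1e-80, 200.0)])
        ba = HitTable("B", "A", [HitRecord("b", "c", 90.0, 100, 1e-90, 220.0),
                                 HitRecord("b", "a", 90.0, 100, 1e-40, 100.0)])
        assert fuzzy_rbh(ab, ba) == []

    def test_matches_exhaustive_oracle_on_random_instances(self):
        for seed in range(30):
            rng = random.Random(seed)
            ab, ba = random_tables(rng)
            got = {(p.gene_a, p.gene_b, p.first_order) for p in fuzzy_rbh(ab, ba)}
            assert got == oracle_pairs(ab, ba), f"seed {seed}"

    def test_reciprocity_symmetry_under_table_swap(self):
        rng = random.Random(123)
        ab, ba = random_tables(rng)
        fwd = {(p.gene_a, p.gene_b) for p in fuzzy_rbh(ab, ba)}
        rev = {(p.gene_b, p.gene_a) for p in fuzzy_rbh(ba, ab)}
        assert fwd == rev

    def test_tightening_evalue_cutoff_never_adds_pairs(self):
        rng = random.Random(77)
        ab, ba = random_tables(rng, density=0.3)
        loose = {(p.gene_a, p.gene_b) for p in fuzzy_rbh(ab, ba)}
        tight_cfg = Config(evalue_max=1e-40)

        def refilter(t):
            return HitTable(t.query_species, t.subject_species,
                            [r for r in t.records if r.evalue <= 1e-40])

        tight = {(p.gene_a, p.gene_b)
                 for p in fuzzy_rbh(refilter(ab), refilter(ba), tight_cfg)}
        # tightening may re-rank survivors, but cannot create hits; every
        # tight pair must involve hits that already existed
        ab_hits = {(r.query_id, r.subject_id) for r in ab.records}
        assert all((a, b) in ab_hits for a, b in tight)
        assert len(tight) <= len(ab_hits)


class TestLineageSpecific:
    def make_models(self, gene_ids, species="sp1"):
        from conftest import make_gene
        return [make_gene(g, "arm2L", "+", [(i * 100, i * 100 + 30)],
                          species=species)
                for i, g in enumerate(gene_ids)]

    def test_gene_with_no_hits_anywhere_is_called(self):
        models = self.make_models(["g1", "g2"])
        tables = {f"og{k}": HitTable("sp1", f"og{k}",
                                     [HitRecord("g2", "x", 90.0, 100, 1e-50, 200.0)])
                  for k in range(3)}
        calls = lineage_specific(models, "sp1", [f"og{k}" for k in range(3)], tables)
        assert [c.gene_id for c in calls] == ["g1"]
        assert calls[0].on_major_arm

    def test_single_qualifying_hit_disqualifies(self):
        models = self.make_models(["g1"])
        tables = {"og0": HitTable("sp1", "og0", []),
                  "og1": HitTable("sp1", "og1",
                                  [HitRecord("g1", "y", 90.0, 100, 1e-12, 80.0)])}
        assert lineage_specific(models, "sp1", ["og0", "og1"], tables) == []

    def test_missing_outgroup_table_is_an_error(self):
        models = self.make_models(["g1"])
        with pytest.raises(KeyError):
            lineage_specific(models, "sp1", ["og0", "og1"],
                             {"og0": HitTable("sp1", "og0", [])})

    def test_lineage_specific_set_never_shrinks_under_tighter_cutoff(self):
        rng = random.Random(55)
        models = self.make_models([f"g{i}" for i in range(20)])
        recs = [HitRecord(f"g{rng.randint(0, 19)}", f"x{j}", 50.0, 100,
                          10 ** -rng.uniform(10, 60), 100.0) for j in range(30)]
        loose_t = {"og0": HitTable("sp1", "og0", recs)}
        tight_t = {"og0": HitTable("sp1", "og0",
                                   [r for r in recs if r.evalue <= 1e-30])}
        loose = {c.gene_id for c in lineage_specific(models, "sp1", ["og0"], loose_t)}
        tight = {c.gene_id for c in lineage_specific(
            models, "sp1", ["og0"], tight_t, config=Config(evalue_max=1e-30))}
        assert loose <= tight


class TestOrthologTable:
    def test_identical_proteomes_count_every_gene(self):
        recs = [HitRecord(f"g{i}", f"g{i}", 100.0, 100, 1e-80, 300.0)
                for i in range(5)]
        tables = {("A", "B"): HitTable("A", "B", recs),
                  ("B", "A"): HitTable("B", "A", recs)}
        _, counts = ortholog_table(["A", "B"], tables)
        assert counts == {("A", "B"): 5, ("B", "A"): 5}

    def test_disjoint_proteomes_count_zero(self):
        tables = {("A", "B"): HitTable("A", "B", []),
                  ("B", "A"): HitTable("B", "A", [])}
        _, counts = ortholog_table(["A", "B"], tables)
        assert counts == {("A", "B"): 0, ("B", "A"): 0}

    def test_missing_pair_table_raises(self):
        with pytest.raises(KeyError):
            ortholog_table(["A", "B"], {("A", "B"): HitTable("A", "B", [])})
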