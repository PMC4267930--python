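"""Model matching, orphan rescue, merge, FPKM and feature support."""

import pytest
from conftest import make_gene

from annoforge.io_model import (Config, ConsistencyError, CoverageTrack,
                                ExpressionRecord, parse_gff3, read_fasta,
                                write_gff3)
from annoforge.reconcile import (feature_support, fpkm, match_models,
                                 merge_annotations, rescue_orphans,
                                 support_summary)
from annoforge.synthetic_data import back_translate, random_protein
import random


def _genome_for(protein, offset=100, scaffold="arm2L"):
    cds = back_translate(protein)
    seq = "A" * offset + cds + "A" * offset
    return {scaffold: seq}, offset, offset + len(cds)


class TestMatchModels:
    def test_identical_cds_is_one_to_one(self):
        rng = random.Random(0)
        prot = random_protein(100, rng)
        genome, s, e = _genome_for(prot)
        ref = make_gene("ref1", "arm2L", "+", [(s, e)])
        pred = make_gene("p1", "arm2L", "+", [(s, e)], source="predicted")
        recs = match_models([pred], [ref], genome)
        assert recs[0].match_class == "one_to_one"
        assert recs[0].matched_reference_ids == ["ref1"]
        ev = recs[0].evidence["ref1"]
        assert ev.query_coverage == pytest.approx(1.0)
        assert ev.percent_identity == 100.0

    def test_half_coverage_fails_85_percent_rule(self):
        rng = random.Random(1)
        prot = random_protein(120, rng)
        genome, s, e = _genome_for(prot)
        ref = make_gene("ref1", "arm2L", "+", [(s, e)])
        # prediction covers only the first half of the reference CDS
        pred = make_gene("p1", "arm2L", "+", [(s, s + (e - s) // 2)],
                         source="predicted")
        recs = match_models([pred], [ref], genome)
        assert recs[0].match_class == "novel"

    def test_opposite_strand_overlap_does_not_match(self):
        rng = random.Random(2)
        prot = random_protein(100, rng)
        genome, s, e = _genome_for(prot)
        ref = make_gene("ref1", "arm2L", "+", [(s, e)])
        pred = make_gene("p1", "arm2L", "-", [(s, e)], source="predicted")
        assert match_models([pred], [ref], genome)[0].match_class == "novel"

    def test_missing_scaffold_is_consistency_error(self):
        ref = make_gene("ref1", "armX", "+", [(0, 30)])
        with pytest.raises(ConsistencyError):
            match_models([], [ref], {"arm2L": "ACGT" * 100})

    def test_classification_partitions_predictions(self, sim_small):
        _, sim_dir, _ = sim_small
        genome = read_fasta(sim_dir / "sp1.genome.fa")
        recs = match_models(parse_gff3(sim_dir / "sp1.pred.gff3"),
                            parse_gff3(sim_dir / "sp1.ref.gff3"), genome)
        classes = [r.match_class for r in recs]
        assert len(classes) == len(recs)
        assert set(classes) <= {"one_to_one", "polycistronic", "novel"}
        for r in recs:
            n = len(r.matched_reference_ids)
            expected = "novel" if n == 0 else "one_to_one" if n == 1 else "polycistronic"
            assert r.match_class == expected

    def test_planted_fusions_are_polycistronic_with_their_members(self, sim_small):
        _, sim_dir, truth = sim_small
        genome = read_fasta(sim_dir / "sp1.genome.fa")
        recs = match_models(parse_gff3(sim_dir / "sp1.pred.gff3"),
                            parse_gff3(sim_dir / "sp1.ref.gff3"), genome)
        poly = {r.predicted_id: r for r in recs if r.match_class == "polycistronic"}
        assert set(poly) == set(truth.fusions["sp1"])
        for fid, (a, b) in truth.fusions["sp1"].items():
            assert sorted(poly[fid].matched_reference_ids) == sorted([a, b])


class TestRescueOrphans:
    def _run(self, fpkm_value, matched=False):
        ref = make_gene("refA", "arm2L", "+", [(0, 30)])
        from annoforge.reconcile import ReconciliationRecord
        recon = [ReconciliationRecord("p1", ["refA"])] if matched else []
        expr = [ExpressionRecord("refA", "ovary", fpkm=fpkm_value)]
        return rescue_orphans([ref], recon, expr)

    def test_fpkm_exactly_two_is_rescued(self):
        out = self._run(2.0)
        assert out[0].rescued and out[0].max_fpkm == 2.0

    def test_fpkm_just_below_two_is_not_rescued(self):
        assert not self._run(1.99)[0].rescued

    def test_matched_gene_is_not_an_orphan(self):
        assert self._run(100.0, matched=True) == []

    def test_missing_expression_means_zero(self):
        ref = make_gene("refA", "arm2L", "+", [(0, 30)])
        out = rescue_orphans([ref], [], [])
        assert out[0].max_fpkm == 0.0 and not out[0].rescued

    def test_raising_threshold_never_grows_rescued_set(self):
        ref = [make_gene(f"r{i}", "arm2L", "+", [(i * 100, i * 100 + 30)])
               for i in range(10)]
        expr = [ExpressionRecord(f"r{i}", "s", fpkm=float(i)) for i in range(10)]
        prev = None
        for threshold in (0.5, 2.0, 5.0, 9.0):
            cfg = Config(fpkm_rescue_min=threshold)
            rescued = {o.reference_id for o in rescue_orphans(ref, [], expr, cfg)
                       if o.rescued}
            if prev is not None:
                assert rescued <= prev
            prev = rescued


class TestMergeAnnotations:
    def test_no_fusions_no_orphans_gives_predictions_only(self):
        pred = [make_gene("p1", "arm2L", "+", [(0, 30)], source="predicted")]
        from annoforge.reconcile import ReconciliationRecord
        merged = merge_annotations(pred, [], [ReconciliationRecord("p1", [])], [])
        assert [g.gene_id for g in merged] == ["p1"]

    def test_dual_annotation_rule_on_planted_fusions(self, sim_small):
        _, sim_dir, truth = sim_small
        genome = read_fasta(sim_dir / "sp1.genome.fa")
        pred = parse_gff3(sim_dir / "sp1.pred.gff3")
        ref = parse_gff3(sim_dir / "sp1.ref.gff3")
        recs = match_models(pred, ref, genome)
        expr_path = sim_dir / "sp1.expression.tsv"
        from annoforge.io_model import read_expression_tsv
        orphans = rescue_orphans(ref, recs, read_expression_tsv(expr_path))
        merged = merge_annotations(pred, ref, recs, orphans)
        ids = {g.gene_id for g in merged}
        for fid, (a, b) in truth.fusions["sp1"].items():
            assert {fid, a, b} <= ids
        # arithmetic: predictions + rescued orphans + fusion members
        n_members = len({m for pair in truth.fusions["sp1"].values() for m in pair})
        n_rescued = sum(o.rescued for o in orphans)
        assert len(merged) == len(pred) + n_rescued + n_members

    def test_merged_round_trips_with_unique_ids(self, sim_small, tmp_path):
        _, sim_dir, _ = sim_small
        genome = read_fasta(sim_dir / "sp2.genome.fa")
        pred = parse_gff3(sim_dir / "sp2.pred.gff3")
        ref = parse_gff3(sim_dir / "sp2.ref.gff3")
        recs = match_models(pred, ref, genome)
        merged = merge_annotations(pred, ref, recs, [])
        out = tmp_path / "merged.gff3"
        write_gff3(merged, out)
        back = parse_gff3(out)
        ids = [g.gene_id for g in back]
        assert len(ids) == len(set(ids)) == len(merged)


class TestFPKM:
    def test_arithmetic_identity(self):
        out = fpkm({"g": 100}, {"g": 1000}, "total")
        # one gene: N = 100 => 100 * 1e9 / (1000 * 100) = 1e6; scale to the
        # classic identity with an explicit big library instead:
        out = fpkm({"g": 100, "rest": 10 ** 6 - 100}, {"g": 1000, "rest": 1000},
                   "total")
        assert out["g"] == pytest.approx(100.0)

    def test_zero_count_gives_zero(self):
        out = fpkm({"g": 0, "h": 10}, {"g": 500, "h": 500}, "total")
        assert out["g"] == 0.0

    def test_zero_total_is_an_error(self):
        with pytest.raises(ValueError):
            fpkm({"g": 0}, {"g": 100}, "total")

    def test_upper_quartile_scale_invariance(self):
        rng = random.Random(5)
        counts = {f"g{i}": rng.randint(0, 500) for i in range(50)}
        lengths = {g: rng.randint(300, 3000) for g in counts}
        doubled = {g: 2 * c for g, c in counts.items()}
        a = fpkm(counts, lengths, "upper_quartile")
        b = fpkm(doubled, lengths, "upper_quartile")
        for g in counts:
            assert b[g] == pytest.approx(a[g], rel=1e-9)


class TestFeatureSupport:
    def test_three_of_five_is_supported_inclusive(self):
        from annoforge.io_model import FeatureInterval, GeneModel, TranscriptModel
        feats = [FeatureInterval("s", i * 100, i * 100 + 50, "+", "exon")
                 for i in range(5)]
        gene = GeneModel("g", "spX", "s",
                         [TranscriptModel("g.t1", "g", feats)])
        track = CoverageTrack({"s": [(i * 100, i * 100 + 50, 10.0)
                                     for i in range(3)]})
        report = feature_support(gene, track)
        assert report.n_features == 5 and report.n_supported == 3
        assert report.supported_fraction == pytest.approx(0.6)
        assert report.gene_supported

    def test_zero_depth_track_unsupported(self):
        gene = make_gene("g", "s", "+", [(10, 40)])
        report = feature_support(gene, CoverageTrack())
        assert report.n_supported == 0 and not report.gene_supported

    def test_uniform_deep_coverage_supports_everything(self):
        gene = make_gene("g", "s", "+", [(10, 40)],
                         utrs=[(0, 10, "five_prime_UTR"), (40, 50, "three_prime_UTR")])
        track = CoverageTrack({"s": [(0, 50, 50.0)]})
        report = feature_support(gene, track)
        assert report.n_supported == report.n_features
        assert report.gene_supported

    def test_support_summary_extremes(self):
        gene = make_gene("g", "s", "+", [(10, 40)])
        assert support_summary([gene], CoverageTrack({"s": [(0, 50, 10.0)]})) == 100.0
        assert support_summary([gene], CoverageTrack()) == 0.0
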