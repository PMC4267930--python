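"""Seeded multi-species generator with a machine-readable truth table.

The generator emulates the statistical structure of a comparative
RNA-seq-reannotation study: several species descend from a common ancestral
gene set by per-residue protein substitution; each species additionally
carries planted lineage-specific genes (random proteins with no homolog
anywhere), planted gene-model fusions (a single predicted model spanning two
adjacent reference genes — a polycistronic prediction), and planted orphan
reference models (expressed but missing from the predicted set, with FPKM
values straddling the rescue threshold of 2).  Per-gene read coverage
realizes a target support fraction and per-gene p-values for four tissue
contrasts are drawn from an explicit null (Uniform(0,1)) or alternative
(one-sided normal shift), with orthologous genes sharing their planted bias
with a tunable probability.

Everything is driven by one seeded RNG, and equal seeds produce
byte-identical output trees.
"""

from __future__ import annotations

import dataclasses
import json
import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from .homology import all_by_all, write_hit_table
from .io_model import (CODON_TABLE, Config, ExpressionRecord, FeatureInterval,
                       GeneModel, TranscriptModel, reverse_complement,
                       write_expression_tsv, write_fasta, write_gff3)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# deterministic back-translation: lexicographically first codon per residue
_BACK_CODON = {}
for _codon in sorted(CODON_TABLE):
    _aa = CODON_TABLE[_codon]
    if _aa != "*" and _aa not in _BACK_CODON:
        _BACK_CODON[_aa] = _codon

CONTRASTS = (
    "ovary_vs_female_carcass",
    "testes_vs_male_carcass",
    "female_carcass_vs_male_carcass",
    "ovary_vs_testes",
)

SAMPLES = ("ovary", "female_carcass", "testes", "male_carcass")

_UTR_LEN = 60
_INTRON_LEN = 60


@dataclass
class SimulationParams:
    """Study conditions for one synthetic dataset.

    Defaults mirror the structure of the real study at desk scale: a
    multi-species clade (four species), moderate protein divergence per
    branch, tens of planted lineage-specific genes, fusions and orphans,
    ~80% of gene models with read support, a large fraction of genes
    tissue-biased in the gonad-vs-carcass contrasts, and ~60% sharing of
    tissue bias between orthologs.
    """

    n_species: int = 4
    n_ancestral_genes: int = 200
    substitution_probability: float = 0.15   # per residue, per branch
    n_lineage_specific: int = 25             # per species
    n_fusions: int = 10                      # per species
    n_orphans: int = 30                      # per species
    fraction_supported_features: float = 0.8
    fraction_de: float | dict[str, float] = 0.6   # per contrast or scalar
    shared_bias_probability: float = 0.6
    effect_size: float = 6.0                 # normal shift of the DE statistic
    protein_length_min: int = 80
    protein_length_max: int = 160
    spacer_length_min: int = 100
    spacer_length_max: int = 300
    supported_depth: float = 10.0
    rng_seed: int = 42

    def __post_init__(self) -> None:
        for name in ("substitution_probability", "fraction_supported_features",
                     "shared_bias_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        for c in CONTRASTS:
            if not 0.0 <= self.de_fraction(c) <= 1.0:
                raise ValueError("fraction_de must lie in [0, 1]")
        if self.n_species < 1:
            raise ValueError("need at least one species")
        if min(self.n_ancestral_genes, self.n_lineage_specific,
               self.n_fusions, self.n_orphans) < 0:
            raise ValueError("counts must be >= 0")
        if self.n_fusions > self.n_ancestral_genes // 2:
            raise ValueError("n_fusions may not exceed n_ancestral_genes / 2")
        if 2 * self.n_fusions + self.n_orphans > self.n_ancestral_genes:
            raise ValueError("fusion members and orphans must be disjoint gene sets")

    def de_fraction(self, contrast: str) -> float:
        if isinstance(self.fraction_de, dict):
            return self.fraction_de.get(contrast, 0.0)
        return self.fraction_de

    @property
    def species_names(self) -> list[str]:
        return [f"sp{i + 1}" for i in range(self.n_species)]


@dataclass
class TruthTable:
    """Planted ground truth emitted alongside the data files."""

    # ancestral index -> {species: reference gene id}
    orthologs: dict[int, dict[str, str]] = field(default_factory=dict)
    # species -> [gene ids]
    lineage_specific: dict[str, list[str]] = field(default_factory=dict)
    # species -> {fused predicted id: (member_ref_a, member_ref_b)}
    fusions: dict[str, dict[str, tuple[str, str]]] = field(default_factory=dict)
    # species -> {reference id: planted FPKM}
    orphans: dict[str, dict[str, float]] = field(default_factory=dict)
    # species -> {(gene_id, contrast): direction in {-1, 0, +1}}
    bias: dict[str, dict[tuple[str, str], int]] = field(default_factory=dict)
    # species -> {gene_id: gene-level support flag}
    support: dict[str, dict[str, bool]] = field(default_factory=dict)

    def ortholog_pairs(self, species_a: str, species_b: str
                       ) -> list[tuple[str, str]]:
        out = []
        for mapping in self.orthologs.values():
            if species_a in mapping and species_b in mapping:
                out.append((mapping[species_a], mapping[species_b]))
        return sorted(out)

    def write(self, truth_dir: Path) -> None:
        truth_dir.mkdir(parents=True, exist_ok=True)
        with open(truth_dir / "orthologs.tsv", "w") as fh:
            fh.write("ancestor\tspecies\tgene_id\n")
            for idx in sorted(self.orthologs):
                for sp in sorted(self.orthologs[idx]):
                    fh.write(f"{idx}\t{sp}\t{self.orthologs[idx][sp]}\n")
        with open(truth_dir / "lineage_specific.tsv", "w") as fh:
            fh.write("species\tgene_id\n")
            for sp in sorted(self.lineage_specific):
                for gid in sorted(self.lineage_specific[sp]):
                    fh.write(f"{sp}\t{gid}\n")
        with open(truth_dir / "fusions.tsv", "w") as fh:
            fh.write("species\tfused_id\tmember_a\tmember_b\n")
            for sp in sorted(self.fusions):
                for fid in sorted(self.fusions[sp]):
                    a, b = self.fusions[sp][fid]
                    fh.write(f"{sp}\t{fid}\t{a}\t{b}\n")
        with open(truth_dir / "orphans.tsv", "w") as fh:
            fh.write("species\treference_id\tfpkm\trescued\n")
            for sp in sorted(self.orphans):
                for gid in sorted(self.orphans[sp]):
                    v = self.orphans[sp][gid]
                    fh.write(f"{sp}\t{gid}\t{v:.4f}\t{int(v >= 2.0)}\n")
        with open(truth_dir / "bias.tsv", "w") as fh:
            fh.write("species\tgene_id\tcontrast\tdirection\n")
            for sp in sorted(self.bias):
                for (gid, contrast) in sorted(self.bias[sp]):
                    fh.write(f"{sp}\t{gid}\t{contrast}\t"
                             f"{self.bias[sp][(gid, contrast)]}\n")
        with open(truth_dir / "support.tsv", "w") as fh:
            fh.write("species\tgene_id\tsupported\n")
            for sp in sorted(self.support):
                for gid in sorted(self.support[sp]):
                    fh.write(f"{sp}\t{gid}\t{int(self.support[sp][gid])}\n")


# ---------------------------------------------------------------------------
# Primitive generators
# ---------------------------------------------------------------------------

def mutate_protein(seq: str, substitution_probability: float,
                   rng: random.Random) -> str:
    """Independently replace each residue (with the given probability) by a
    uniformly chosen *different* residue; length is preserved."""
    if not 0.0 <= substitution_probability <= 1.0:
        raise ValueError("substitution probability must lie in [0, 1]")
    out = []
    for aa in seq:
        if rng.random() < substitution_probability:
            choices = [c for c in AA_ALPHABET if c != aa]
            out.append(rng.choice(choices))
        else:
            out.append(aa)
    return "".join(out)


def random_protein(length: int, rng: random.Random) -> str:
    return "".join(rng.choice(AA_ALPHABET) for _ in range(length))


def back_translate(protein: str) -> str:
    """Deterministic back-translation (fixed codon per residue) + TAA stop."""
    return "".join(_BACK_CODON[aa] for aa in protein) + "TAA"


def _random_dna(length: int, rng: random.Random) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


# ---------------------------------------------------------------------------
# Gene placement
# ---------------------------------------------------------------------------

@dataclass
class _PlacedGene:
    gene_id: str
    scaffold: str
    strand: str
    protein: str
    start: int = 0                 # filled at assembly time
    features: list[FeatureInterval] = field(default_factory=list)


def _gene_segment(protein: str, strand: str, rng: random.Random
                  ) -> tuple[str, list[tuple[int, int, str]]]:
    """Build one gene's genomic segment and relative features.

    Layout (plus orientation): 5'UTR | exon1 = UTR+CDS1 | intron |
    exon2 = CDS2+3'UTR | with the CDS split at a codon boundary.  For minus
    strand the segment is reverse-complemented and coordinates mirrored;
    feature kinds are unchanged (the 5' UTR then sits at the higher genomic
    coordinates).
    """
    cds = back_translate(protein)
    half = (len(cds) // 6) * 3
    cds1, cds2 = cds[:half], cds[half:]
    utr5 = _random_dna(_UTR_LEN, rng)
    intron = _random_dna(_INTRON_LEN, rng)
    utr3 = _random_dna(_UTR_LEN, rng)
    seq = utr5 + cds1 + intron + cds2 + utr3
    u, c1, i, c2 = len(utr5), len(cds1), len(intron), len(cds2)
    feats = [
        (0, u, "five_prime_UTR"),
        (0, u + c1, "exon"),
        (u, u + c1, "CDS"),
        (u + c1 + i, u + c1 + i + c2, "CDS"),
        (u + c1 + i, len(seq), "exon"),
        (len(seq) - len(utr3), len(seq), "three_prime_UTR"),
    ]
    if strand == "-":
        n = len(seq)
        seq = reverse_complement(seq)
        feats = [(n - e, n - s, kind) for s, e, kind in feats]
    return seq, feats


def _make_transcript(gene_id: str, transcript_id: str, scaffold: str,
                     strand: str, offset: int,
                     rel_feats: list[tuple[int, int, str]], source: str
                     ) -> TranscriptModel:
    features = [FeatureInterval(scaffold, offset + s, offset + e, strand, kind)
                for s, e, kind in rel_feats]
    return TranscriptModel(transcript_id, gene_id, features, source=source)


# ---------------------------------------------------------------------------
# Main entry point
# ---------------------------------------------------------------------------

def simulate(params: SimulationParams, out_dir: str | Path) -> TruthTable:
    """Generate the full dataset under ``out_dir`` and return the truth table.

    Per species: ``{sp}.genome.fa``, ``{sp}.ref.gff3``, ``{sp}.pred.gff3``,
    ``{sp}.proteins.fa``, ``{sp}.coverage.bedgraph``, ``{sp}.expression.tsv``,
    ``{sp}.de.tsv``; pairwise hit tables under ``hits/``; truth TSVs under
    ``truth/``; the parameter snapshot as ``params.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = random.Random(params.rng_seed)
    species = params.species_names
    truth = TruthTable()

    # --- ancestral gene set -------------------------------------------------
    ancestral = [random_protein(
        rng.randint(params.protein_length_min, params.protein_length_max), rng)
        for _ in range(params.n_ancestral_genes)]

    fusion_members = [(2 * k, 2 * k + 1) for k in range(params.n_fusions)]
    fusion_idx = {i for pair in fusion_members for i in pair}
    orphan_idx = set(range(2 * params.n_fusions,
                           2 * params.n_fusions + params.n_orphans))

    proteomes: dict[str, dict[str, str]] = {}
    species_models: dict[str, dict] = {}

    for sp in species:
        proteins = {f"{sp}_g{i:04d}": mutate_protein(ancestral[i],
                                                     params.substitution_probability,
                                                     rng)
                    for i in range(params.n_ancestral_genes)}
        for i in range(params.n_ancestral_genes):
            truth.orthologs.setdefault(i, {})[sp] = f"{sp}_g{i:04d}"
        ls_ids = []
        for j in range(params.n_lineage_specific):
            gid = f"{sp}_ls{j:03d}"
            proteins[gid] = random_protein(
                rng.randint(params.protein_length_min, params.protein_length_max),
                rng)
            ls_ids.append(gid)
        truth.lineage_specific[sp] = ls_ids
        proteomes[sp] = proteins

        # --- placement ------------------------------------------------------
        # scaffold plan: fusion pairs first on major arm 1 (forced '+' so a
        # fused prediction can span both members in one reading direction),
        # remaining ancestral genes alternate between the two major arms,
        # lineage-specific genes alternate major arm 2 / minor scaffold.
        plan: dict[str, list[_PlacedGene]] = {"arm2L": [], "arm2R": [], "scafU": []}
        for a, b in fusion_members:
            for i in (a, b):
                plan["arm2L"].append(_PlacedGene(f"{sp}_g{i:04d}", "arm2L", "+",
                                                 proteins[f"{sp}_g{i:04d}"]))
        toggle = 0
        for i in range(params.n_ancestral_genes):
            if i in fusion_idx:
                continue
            scaf = "arm2L" if toggle == 0 else "arm2R"
            toggle ^= 1
            strand = "+" if rng.random() < 0.5 else "-"
            plan[scaf].append(_PlacedGene(f"{sp}_g{i:04d}", scaf, strand,
                                          proteins[f"{sp}_g{i:04d}"]))
        for j, gid in enumerate(ls_ids):
            scaf = "arm2R" if j % 2 == 0 else "scafU"
            strand = "+" if rng.random() < 0.5 else "-"
            plan[scaf].append(_PlacedGene(gid, scaf, strand, proteins[gid]))

        # --- assembly -------------------------------------------------------
        genome: dict[str, str] = {}
        placed: dict[str, _PlacedGene] = {}
        for scaf in ("arm2L", "arm2R", "scafU"):
            parts: list[str] = []
            pos = 0
            for pg in plan[scaf]:
                spacer = _random_dna(rng.randint(params.spacer_length_min,
                                                 params.spacer_length_max), rng)
                parts.append(spacer)
                pos += len(spacer)
                seg, rel_feats = _gene_segment(pg.protein, pg.strand, rng)
                pg.start = pos
                pg.features = rel_feats
                parts.append(seg)
                pos += len(seg)
                placed[pg.gene_id] = pg
            parts.append(_random_dna(params.spacer_length_min, rng))
            genome[scaf] = "".join(parts)

        # --- reference models ----------------------------------------------
        ref_models: list[GeneModel] = []
        for gid in sorted(placed):
            pg = placed[gid]
            chrom_class = "major_arm" if pg.scaffold in ("arm2L", "arm2R") else "minor"
            t = _make_transcript(gid, f"{gid}.t1", pg.scaffold, pg.strand,
                                 pg.start, pg.features, "reference")
            ref_models.append(GeneModel(gid, sp, pg.scaffold, [t], chrom_class))

        # --- predicted models ----------------------------------------------
        pred_models: list[GeneModel] = []
        truth.fusions[sp] = {}
        for gid in sorted(placed):
            i = int(gid[-4:]) if "_g" in gid else None
            if i is not None and (i in fusion_idx or i in orphan_idx):
                continue
            pg = placed[gid]
            pid = gid.replace(f"{sp}_g", f"{sp}_p").replace(f"{sp}_ls", f"{sp}_pls")
            chrom_class = "major_arm" if pg.scaffold in ("arm2L", "arm2R") else "minor"
            t = _make_transcript(pid, f"{pid}.t1", pg.scaffold, pg.strand,
                                 pg.start, pg.features, "predicted")
            pred_models.append(GeneModel(pid, sp, pg.scaffold, [t], chrom_class))
        for k, (a, b) in enumerate(fusion_members):
            gid_a, gid_b = f"{sp}_g{a:04d}", f"{sp}_g{b:04d}"
            pa, pb = placed[gid_a], placed[gid_b]
            fid = f"{sp}_fuse{k:02d}"
            feats = []
            for s, e, kind in pa.features:
                if kind == "three_prime_UTR":
                    continue
                if kind == "CDS" and e == max(fe for fs, fe, fk in pa.features
                                              if fk == "CDS"):
                    e -= 3  # drop the upstream member's stop codon
                feats.append(FeatureInterval(pa.scaffold, pa.start + s,
                                             pa.start + e, "+", kind))
            for s, e, kind in pb.features:
                if kind == "five_prime_UTR":
                    continue
                feats.append(FeatureInterval(pb.scaffold, pb.start + s,
                                             pb.start + e, "+", kind))
            t = TranscriptModel(f"{fid}.t1", fid, feats, source="predicted")
            pred_models.append(GeneModel(fid, sp, pa.scaffold, [t], "major_arm"))
            truth.fusions[sp][fid] = (gid_a, gid_b)

        # --- coverage (gene-level all-or-none support) ----------------------
        support_flags: dict[str, bool] = {}
        cov_lines: list[tuple[str, int, int, float]] = []
        for g in ref_models:
            supported = rng.random() < params.fraction_supported_features
            support_flags[g.gene_id] = supported
            if supported:
                depth = round(rng.uniform(5.0, 50.0), 1)
                s, e = g.span
                cov_lines.append((g.scaffold, s, e, depth))
        truth.support[sp] = support_flags

        # --- expression -----------------------------------------------------
        truth.orphans[sp] = {}
        orphan_list = sorted(f"{sp}_g{i:04d}" for i in orphan_idx)
        expr_records: list[ExpressionRecord] = []
        for n, gid in enumerate(orphan_list):
            if n % 2 == 0:
                value = round(rng.uniform(2.0, 30.0), 2)
            else:
                value = round(rng.uniform(0.0, 1.99), 2)
            truth.orphans[sp][gid] = value
            for sample in SAMPLES:
                expr_records.append(ExpressionRecord(gid, sample, count=None,
                                                    fpkm=value))
        for g in ref_models:
            if g.gene_id in truth.orphans[sp]:
                continue
            base = round(math.exp(rng.gauss(2.0, 1.0)), 2)
            length = g.longest_cds_transcript().cds_length
            for sample in SAMPLES:
                count = max(0, int(base * length / 100.0))
                expr_records.append(ExpressionRecord(g.gene_id, sample,
                                                    count=count, fpkm=base))

        species_models[sp] = {"genome": genome, "ref": ref_models,
                              "pred": pred_models, "coverage": cov_lines,
                              "expression": expr_records}

    # --- DE p-values (bias anchored on the first species) ---------------
    anchor = species[0]
    anchor_bias: dict[tuple[str, str], int] = {}
    for sp in species:
        truth.bias[sp] = {}
        gene_ids = sorted(proteomes[sp])
        de_rows: list[tuple[str, str, float, float]] = []
        for gid in gene_ids:
            is_ancestral = "_g" in gid
            idx = int(gid[-4:]) if is_ancestral else None
            for contrast in CONTRASTS:
                direction = 0
                if sp == anchor or not is_ancestral:
                    if rng.random() < params.de_fraction(contrast):
                        direction = 1 if rng.random() < 0.5 else -1
                else:
                    src = anchor_bias.get((f"{anchor}_g{idx:04d}", contrast), 0)
                    if src != 0 and rng.random() < params.shared_bias_probability:
                        direction = src
                if sp == anchor and is_ancestral:
                    anchor_bias[(gid, contrast)] = direction
                truth.bias[sp][(gid, contrast)] = direction
                if direction == 0:
                    p = rng.random()
                    lfc = rng.gauss(0.0, 0.3)
                else:
                    z = rng.gauss(params.effect_size, 1.0)
                    p = max(0.5 * math.erfc(z / math.sqrt(2.0)), 1e-300)
                    lfc = direction * abs(rng.gauss(2.0, 0.5))
                de_rows.append((gid, contrast, p, lfc))
        species_models[sp]["de"] = de_rows

    # --- write files ---------------------------------------------------
    for sp in species:
        data = species_models[sp]
        write_fasta(data["genome"], out / f"{sp}.genome.fa")
        write_fasta(proteomes[sp], out / f"{sp}.proteins.fa")
        write_gff3(data["ref"], out / f"{sp}.ref.gff3")
        write_gff3(data["pred"], out / f"{sp}.pred.gff3")
        with open(out / f"{sp}.coverage.bedgraph", "w") as fh:
            for scaf, s, e, d in sorted(data["coverage"]):
                fh.write(f"{scaf}\t{s}\t{e}\t{d:g}\n")
        write_expression_tsv(data["expression"], out / f"{sp}.expression.tsv")
        with open(out / f"{sp}.de.tsv", "w") as fh:
            fh.write("gene_id\tcontrast\tp_value\tlog2_fold\n")
            for gid, contrast, p, lfc in data["de"]:
                fh.write(f"{gid}\t{contrast}\t{p:.6e}\t{lfc:.4f}\n")

    hits_dir = out / "hits"
    hits_dir.mkdir(exist_ok=True)
    config = Config()
    for a in species:
        for b in species:
            if a == b:
                continue
            table = all_by_all(proteomes[a], proteomes[b], config,
                               query_species=a, subject_species=b)
            write_hit_table(table, hits_dir / f"{a}__vs__{b}.tsv")

    truth.write(out / "truth")
    with open(out / "params.json", "w") as fh:
        json.dump(dataclasses.asdict(params), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth


# ---------------------------------------------------------------------------
# Consistency check
# ---------------------------------------------------------------------------

def check_output(out_dir: str | Path) -> None:
    """Validate cross-references of a simulated directory; raises on failure."""
    from .io_model import parse_gff3, read_fasta

    out = Path(out_dir)
    with open(out / "params.json") as fh:
        params = SimulationParams(**json.load(fh))
    for sp in params.species_names:
        genome = read_fasta(out / f"{sp}.genome.fa")
        proteins = read_fasta(out / f"{sp}.proteins.fa")
        ref = parse_gff3(out / f"{sp}.ref.gff3")
        pred = parse_gff3(out / f"{sp}.pred.gff3")
        ref_ids = {g.gene_id for g in ref}
        if not set(proteins) == ref_ids:
            raise ValueError(f"{sp}: protein FASTA ids != reference GFF ids")
        for models in (ref, pred):
            for g in models:
                if g.scaffold not in genome:
                    raise ValueError(f"{sp}: scaffold {g.scaffold} missing")
                for t in g.transcripts:
                    if t.span[1] > len(genome[g.scaffold]):
                        raise ValueError(f"{sp}: {t.transcript_id} beyond scaffold")
    truth_dir = out / "truth"
    for name in ("orthologs.tsv", "lineage_specific.tsv", "fusions.tsv",
                 "orphans.tsv", "bias.tsv", "support.tsv"):
        if not (truth_dir / name).exists():
            raise ValueError(f"missing truth file {name}")
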