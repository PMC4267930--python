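"""End-to-end orchestration: reconcile -> merge -> orthologs ->
lineage-specific -> FDR/bias -> concordance, over a directory laid out like
:func:`annoforge.synthetic_data.simulate` output, with a run manifest and a
machine-readable summary echoing the study's headline tables (transcript and
gene counts, percent of models supported, first-order ortholog counts,
lineage-specific counts with their differential-expression tally, and
significant/tested per tissue contrast)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .expression import (CONTRASTS, apply_fdr, concordance, de_any_contrast,
                         read_de_tsv, significant_tested, write_de_tsv)
from .homology import parse_hit_table
from .io_model import (Config, DEFAULT_CONFIG, parse_gff3, read_coverage_bedgraph,
                       read_expression_tsv, read_fasta, write_gff3)
from .orthology import fuzzy_rbh, lineage_specific, ortholog_table
from .reconcile import (annotation_counts, match_models, merge_annotations,
                        rescue_orphans, support_summary)

logger = logging.getLogger("annoforge")


@dataclass
class RunManifest:
    subcommand: str
    config: dict
    inputs: dict[str, str] = field(default_factory=dict)   # path -> sha256
    outputs: list[str] = field(default_factory=list)
    version: str = __version__
    wall_clock_s: float = 0.0

    def digest_input(self, path: Path) -> None:
        self.inputs[str(path)] = hashlib.sha256(path.read_bytes()).hexdigest()

    def write(self, path: Path) -> None:
        for out in self.outputs:
            if not Path(out).exists():
                raise FileNotFoundError(f"manifest lists missing output {out}")
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                   sort_keys=True) + "\n")


def _species_from_dir(data_dir: Path) -> list[str]:
    with open(data_dir / "params.json") as fh:
        params = json.load(fh)
    return [f"sp{i + 1}" for i in range(params["n_species"])]


def run_pipeline(data_dir: str | Path, out_dir: str | Path,
                 config: Config = DEFAULT_CONFIG,
                 species: list[str] | None = None) -> tuple[RunManifest, dict]:
    """Run every stage over a simulate-layout directory.

    Returns the manifest and a summary dict; both are also written to
    ``out_dir`` (``manifest.json``, ``summary.json``) along with per-species
    merged GFF3s and per-contrast DE tables.
    """
    t0 = time.monotonic()
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if species is None:
        species = _species_from_dir(data_dir)
    manifest = RunManifest("run-all", dataclasses.asdict(config))
    summary: dict = {"species": {}, "orthologs": {}, "concordance": {}}

    calls_by_species = {}
    merged_by_species = {}
    for sp in species:
        logger.info("stage reconcile: %s", sp)
        genome = read_fasta(data_dir / f"{sp}.genome.fa")
        reference = parse_gff3(data_dir / f"{sp}.ref.gff3")
        predicted = parse_gff3(data_dir / f"{sp}.pred.gff3")
        expression = read_expression_tsv(data_dir / f"{sp}.expression.tsv")
        coverage = read_coverage_bedgraph(data_dir / f"{sp}.coverage.bedgraph")
        for name in ("genome.fa", "ref.gff3", "pred.gff3", "expression.tsv",
                     "coverage.bedgraph", "de.tsv"):
            manifest.digest_input(data_dir / f"{sp}.{name}")

        reconciliation = match_models(predicted, reference, genome, config=config)
        orphans = rescue_orphans(reference, reconciliation, expression, config)
        merged = merge_annotations(predicted, reference, reconciliation, orphans)
        merged_by_species[sp] = merged
        merged_path = out_dir / f"{sp}.merged.gff3"
        write_gff3(merged, merged_path)
        manifest.outputs.append(str(merged_path))

        by_class = {"one_to_one": 0, "polycistronic": 0, "novel": 0}
        for rec in reconciliation:
            by_class[rec.match_class] += 1

        logger.info("stage expression: %s", sp)
        calls = apply_fdr(read_de_tsv(data_dir / f"{sp}.de.tsv"), config)
        calls_by_species[sp] = calls
        de_path = out_dir / f"{sp}.de_calls.tsv"
        write_de_tsv(calls, de_path)
        manifest.outputs.append(str(de_path))

        summary["species"][sp] = {
            "reconciliation": by_class,
            "orphans_rescued": sum(o.rescued for o in orphans),
            "orphans_total": len(orphans),
            "merged": annotation_counts(merged),
            "percent_supported": support_summary(merged, coverage, config),
            "significant_tested": {
                c: list(v) for c, v in significant_tested(calls).items()},
        }

    logger.info("stage orthologs")
    hit_tables = {}
    for a in species:
        for b in species:
            if a != b:
                path = data_dir / "hits" / f"{a}__vs__{b}.tsv"
                manifest.digest_input(path)
                hit_tables[(a, b)] = parse_hit_table(path, a, b, config)
    pairs_by, counts = ortholog_table(species, hit_tables, config)
    summary["orthologs"] = {f"{a}->{b}": n for (a, b), n in counts.items()}

    logger.info("stage lineage-specific")
    summary["lineage_specific"] = {}
    for sp in species:
        models = parse_gff3(data_dir / f"{sp}.ref.gff3")
        outgroups = [s for s in species if s != sp]
        de_flags = de_any_contrast(calls_by_species[sp],
                                   [g.gene_id for g in models])
        calls = lineage_specific(models, sp, outgroups,
                                 {og: hit_tables[(sp, og)] for og in outgroups},
                                 de_flags, config)
        summary["lineage_specific"][sp] = {
            "total": len(calls),
            "major_arm": sum(c.on_major_arm for c in calls),
            "diff_exp": sum(c.differentially_expressed for c in calls),
        }

    if len(species) >= 2:
        a, b = species[0], species[1]
        logger.info("stage concordance: %s vs %s", a, b)
        orth = pairs_by[(a, b)]
        for contrast in CONTRASTS:
            s = concordance(calls_by_species[a], calls_by_species[b], orth, contrast)
            summary["concordance"][contrast] = {
                "n_biased_a_with_ortholog": s.n_biased_a_with_ortholog,
                "n_same_bias_b": s.n_same_bias_b,
                "fraction_concordant": s.fraction_concordant,
            }

    manifest.wall_clock_s = time.monotonic() - t0
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    manifest.outputs.append(str(summary_path))
    manifest.write(out_dir / "manifest.json")
    return manifest, summary
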