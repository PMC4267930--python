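import pytest

from annoforge.io_model import FeatureInterval, GeneModel, TranscriptModel
from annoforge.synthetic_data import SimulationParams, simulate


def make_gene(gene_id, scaffold, strand, cds, utrs=(), species="spX",
              source="reference", chromosome_class="major_arm"):
    """Build a one-transcript gene from (start, end) CDS and UTR interval lists."""
    features = [FeatureInterval(scaffold, s, e, strand, "CDS") for s, e in cds]
    features += [FeatureInterval(scaffold, s, e, strand, kind)
                 for s, e, kind in utrs]
    features += [FeatureInterval(scaffold, min(s for s, _ in cds),
                                 max(e for _, e in cds), strand, "exon")]
    t = TranscriptModel(f"{gene_id}.t1", gene_id, features, source=source)
    return GeneModel(gene_id, species, scaffold, [t], chromosome_class)


@pytest.fixture(scope="session")
def sim_small(tmp_path_factory):
    """Two-species dataset with planted fusions, orphans and novel genes."""
    out = tmp_path_factory.mktemp("sim_small")
    params = SimulationParams(n_species=2, n_ancestral_genes=60, n_fusions=5,
                              n_orphans=10, n_lineage_specific=8, rng_seed=7)
    truth = simulate(params, out)
    return params, out, truth
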