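import os

import pytest

import strainvar as sv
import strainvar.simulate as sim


@pytest.fixture(scope="session")
def small_config():
    return sv.SimConfig(
        seed=7,
        n_genes=20,
        contig_length=50_000,
        deleted_gene_ids=("g005", "g012"),
        unannotated_gene_ids=("g002",),
        family_spec=(("AA3_2", 4), ("GH5_5", 2), ("CBM13", 2)),
        group_spec=(("F-box", 3), ("kinase", 5)),
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return sv.generate_reference(small_config)


@pytest.fixture(scope="session")
def small_mutated(small_bundle, small_config):
    derived_genome, truth, derived_cds = sv.mutate(small_bundle, small_config)
    return derived_genome, truth, derived_cds


@pytest.fixture(scope="session")
def small_dir(tmp_path_factory, small_config):
    """The small simulation written to disk (reference + derived files)."""
    outdir = tmp_path_factory.mktemp("simdata")
    sim.simulate_to_dir(small_config, outdir)
    return outdir


@pytest.fixture(scope="session")
def small_parsed(small_dir):
    genome = sv.read_fasta(os.path.join(small_dir, "reference.fasta"))
    models = sv.read_gff3(os.path.join(small_dir, "genes.gff3"), genome)
    variants = sv.read_vcf(os.path.join(small_dir, "truth.vcf"), genome)
    return genome, models, variants


def write(path, text):
    with open(path, "w") as fh:
        fh.write(text)
    return str(path)
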