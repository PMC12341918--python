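import numpy as np
import pytest

from triploidcross.kinship import build_kinship_set
from triploidcross.models import build_model
from triploidcross.simulate import SimulationConfig, simulate_dataset

TOY_VCF = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1\tP2\tP3
chr1\t100\t.\tA\tT\t.\t.\t.\tGT\t0/0\t0/1\t1/1
chr1\t200\t.\tA\tAT\t.\t.\t.\tGT\t0/0\t0/1\t1/1
chr1\t300\t.\tA\tT,G\t.\t.\t.\tGT\t0/0\t0/1\t1/1
chr1\t400\t.\tG\tC\t.\t.\t.\tGT\t./.\t0/1\t1/1
chr1\t500\t.\tC\tG\t.\t.\t.\tGT\t0/1\t1/1\t0/0
chr1\t600\t.\tC\tA\t.\t.\t.\tGT\t0/0\t0/0\t0/0
"""


@pytest.fixture()
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return str(path)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact breeding study: 16 parents, 20 crosses, 10 progeny each."""
    cfg = SimulationConfig(
        n_parents2x=8, n_parents4x=8, n_crosses=20, family_sizes=10,
        n_markers=300, seed=42,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_kinships(small_dataset):
    ped = small_dataset.tables.pedigree
    crosses = sorted(set(zip(ped["parent2x_id"], ped["parent4x_id"])))
    return build_kinship_set(small_dataset.genotypes, crosses)


@pytest.fixture(scope="session")
def pheno_fit(small_dataset):
    bundle = build_model("PHENO", small_dataset.tables, "trait")
    return bundle.fit(), bundle


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
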