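import numpy as np
import pandas as pd
import pytest

from qtlallele.datatypes import GenotypeMatrix
from qtlallele import snpldb
from qtlallele.simulate import SimulationConfig, generate_population


def make_genotypes(calls, chrom="Chr01", start=1000, step=100, cm_per_bp=1e-5):
    """GenotypeMatrix from a (n_snps, n_acc) call array with evenly spaced
    positions on one chromosome."""
    calls = np.asarray(calls, dtype=np.int8)
    n_snps, n_acc = calls.shape
    pos = start + step * np.arange(n_snps)
    snps = pd.DataFrame(
        {
            "id": [f"s{i}" for i in range(n_snps)],
            "chrom": chrom,
            "pos": pos,
            "cM": pos * cm_per_bp,
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix([f"a{j}" for j in range(n_acc)], snps, calls)


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study reused across modules."""
    cfg = SimulationConfig(
        n_accessions=120, n_chromosomes=2, n_blocks_per_chrom=8, n_qtls=5,
        alleles_per_qtl=(3, 10), equalize_qtl_variance=True,
        genes_per_chromosome=25, rng_seed=11,
    )
    return generate_population(cfg)


@pytest.fixture(scope="session")
def small_snpldbs(small_study):
    gm, _ = snpldb.filter_snps(small_study.genotypes)
    gm = snpldb.impute_missing(gm)
    return snpldb.assemble_snpldb(gm)
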