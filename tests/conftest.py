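import numpy as np
import pytest

from tyshuffle import genome_model as gm
from tyshuffle import synthetic_data as sd


@pytest.fixture(scope="session")
def mini_genome():
    """Compressed 16-chromosome genome with 2000 SNPs (fast tests)."""
    return gm.default_hybrid_genome(1, n_snps=2_000, profile="mini")


@pytest.fixture(scope="session")
def full_genome():
    """Reference-scale genome with the default 55k SNP map."""
    return gm.default_hybrid_genome(1)


@pytest.fixture()
def baseline(mini_genome):
    return sd.baseline_karyotype(mini_genome)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def brute_force_profile(karyotype):
    """Independent per-SNP membership oracle for copy numbers."""
    genome = karyotype.genome
    rows = []
    for snp in genome.snps:
        w = y = 0
        for mol in karyotype.molecules:
            for seg in mol.segments:
                if (
                    seg.chromosome == snp.chromosome
                    and seg.start <= snp.position <= seg.end
                ):
                    if seg.homolog == "W":
                        w += 1
                    else:
                        y += 1
        rows.append((snp.chromosome, snp.position, w, y))
    return sorted(rows)


def profile_as_rows(profile_df):
    return sorted(
        (r.chromosome, int(r.position), int(r.W_copies), int(r.Y_copies))
        for r in profile_df.itertuples()
    )
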