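import numpy as np
import pytest

from epimine.genotype_data import GenotypeMatrix, PhenotypeVector


def make_matrix(codes, variant_ids=None, alleles=None) -> GenotypeMatrix:
    codes = np.asarray(codes, dtype=np.int8)
    m = codes.shape[1]
    if variant_ids is None:
        variant_ids = [f"v{j}" for j in range(m)]
    return GenotypeMatrix(codes, np.array(variant_ids, dtype=object), alleles)


def random_dataset(n_cases, n_controls, m, seed, missing_rate=0.0):
    """Label-independent random genotypes (null data)."""
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    mafs = rng.uniform(0.1, 0.5, size=m)
    geno = rng.binomial(2, mafs[None, :], size=(n, m)).astype(np.int8)
    if missing_rate > 0:
        geno[rng.random((n, m)) < missing_rate] = -1
    gm = make_matrix(geno)
    phen = PhenotypeVector(
        np.r_[np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)]
    )
    return gm, phen


@pytest.fixture
def toy_ped_map(tmp_path):
    """Hand-written 2-sample, 2-SNP PLINK text fixture.

    SNP rs1 alleles {A, T}: sample1 'A T' -> one copy of T (code 1),
    sample2 'T T' -> code 2.  SNP rs2 alleles {C, G}: sample1 'C C' ->
    code 0, sample2 '0 0' -> missing.  Sample1 is a control (1),
    sample2 a case (2).
    """
    (tmp_path / "toy.map").write_text(
        "1\trs1\t0\t100\n1\trs2\t0\t200\n"
    )
    (tmp_path / "toy.ped").write_text(
        "F1 I1 0 0 1 1 A T C C\n"
        "F2 I2 0 0 1 2 T T 0 0\n"
    )
    return tmp_path / "toy.ped"
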