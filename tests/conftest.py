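import numpy as np
import pytest

from nspa.data import Dataset, GenotypeMatrix, PhenotypeVector

SMALL_CSV = """subject_id,rs1,rs2,rs3,phenotype
s1,0,1,2,1
s2,1,1,0,1
s3,2,0,1,0
s4,0,2,1,0
"""

# same content in the PLINK .raw dialect (PHENOTYPE: 1=control, 2=case)
SMALL_RAW = """FID IID PAT MAT SEX PHENOTYPE rs1_A rs2_C rs3_G
f1 s1 0 0 1 2 0 1 2
f2 s2 0 0 2 2 1 1 0
f3 s3 0 0 1 1 2 0 1
f4 s4 0 0 2 1 0 2 1
"""


def make_dataset(codes, labels, prefix="rs"):
    codes = np.asarray(codes, dtype=np.int64)
    subject_ids = [f"s{i}" for i in range(codes.shape[0])]
    variant_ids = [f"{prefix}{j}" for j in range(codes.shape[1])]
    return Dataset(
        GenotypeMatrix(subject_ids, variant_ids, codes),
        PhenotypeVector(np.asarray(labels, dtype=np.int64)),
    )


@pytest.fixture
def small_csv(tmp_path):
    p = tmp_path / "small.csv"
    p.write_text(SMALL_CSV)
    return p


@pytest.fixture
def small_raw(tmp_path):
    p = tmp_path / "small.raw"
    p.write_text(SMALL_RAW)
    return p


@pytest.fixture
def cohort19():
    """Synthetic 19-subject cohort (10 cases / 9 controls, 3 SNPs).

    A deterministic stand-in for a small unbalanced illustration dataset;
    genotypes drawn once from a fixed generator.
    """
    rng = np.random.default_rng(42)
    codes = rng.integers(0, 3, size=(19, 3))
    labels = np.array([1] * 10 + [0] * 9)
    return make_dataset(codes, labels)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
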