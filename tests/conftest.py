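import numpy as np
import pytest

from panelassoc import (
    CASE,
    CONTROL,
    GenotypeCountRow,
    GenotypeMatrix,
    Sample,
    Variant,
)


def make_variant(vid="v1", chrom="1", pos=100, major="A", minor="G"):
    return Variant(id=vid, chrom=chrom, pos=pos,
                   allele_major=major, allele_minor=minor)


def make_matrix(codes, phenotypes=None, chrom="1"):
    """GenotypeMatrix from a plain 2-D code array (rows = samples)."""
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    phenotypes = phenotypes or [CASE] * n
    samples = [Sample(id=f"s{i}", phenotype=ph) for i, ph in enumerate(phenotypes)]
    variants = [make_variant(vid=f"v{j}", chrom=chrom, pos=100 * (j + 1))
                for j in range(m)]
    return GenotypeMatrix(samples=samples, variants=variants, codes=codes)


def make_row(case_counts, control_counts, vid="v1"):
    return GenotypeCountRow(variant=make_variant(vid=vid),
                            case_counts=tuple(case_counts),
                            control_counts=tuple(control_counts))


@pytest.fixture
def table2_rows():
    """The seven published top-signal rows: (id, model, case triple, control
    triple, printed p, printed OR)."""
    return [
        ("rs885863", "R", (56, 219, 159), (31, 59, 48), 0.0065, 0.51),
        ("rs3113275", "R", (30, 151, 249), (1, 54, 80), 0.0055, 10.0),
        ("rs11764092", "D", (15, 145, 273), (3, 31, 104), 0.0078, 1.79),
        ("rs135763", "D", (16, 103, 316), (4, 51, 82), 0.0046, 0.56),
        ("rs1534891", "D", (12, 96, 327), (5, 45, 88), 0.0090, 0.58),
        ("rs80136044", "D", (7, 101, 327), (1, 17, 120), 0.0036, 2.20),
        ("rs3754729", "D", (41, 202, 189), (12, 47, 78), 0.0071, 1.70),
    ]
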