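import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
"""

# 3 biallelic SNPs, 1 indel, 1 multiallelic, 1 unphased call, 1 missing call
VCF_BODY = """\
chr1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1\t0|0
chr1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t0|0\t0|1\t1|1
chr1\t250\trs_indel\tC\tCAT\t.\tPASS\t.\tGT\t0|0\t0|0\t0|0
chr1\t300\trs_multi\tA\tG,T\t.\tPASS\t.\tGT\t0|1\t0|2\t0|0
chr1\t400\trs3\tG\tA\t.\tPASS\t.\tGT\t1|0\t0|0\t0|1
chr1\t500\trs4\tT\tC\t.\tPASS\t.\tGT\t0/1\t0|0\t0|0
chr1\t600\trs5\tA\tC\t.\tPASS\t.\tGT\t.|.\t0|1\t1|0
"""


@pytest.fixture
def vcf_file(tmp_path):
    p = tmp_path / "tiny.vcf"
    p.write_text(VCF_HEADER + VCF_BODY)
    return p


@pytest.fixture
def panel_file(tmp_path):
    p = tmp_path / "panel.tsv"
    pd.DataFrame(
        {"sample": ["S1", "S2", "S3"], "population": ["EUR", "EUR", "AFR"]}
    ).to_csv(p, sep="\t", index=False)
    return p


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_strata_data(rng, n_strata=50, size=6, beta=(0.5,), n_cases=1):
    """Small stratified case-control table drawn from the exact conditional
    model, for regression tests."""
    p = len(beta)
    rows = []
    import itertools

    for s in range(n_strata):
        X = rng.normal(size=(size, p))
        eta = X @ np.asarray(beta)
        w = np.exp(eta - eta.max())
        if n_cases == 1:
            case_rows = [rng.choice(size, p=w / w.sum())]
        else:
            subsets = list(itertools.combinations(range(size), n_cases))
            ws = np.array([np.exp(eta[list(c)].sum() - eta.max() * n_cases)
                           for c in subsets])
            case_rows = list(subsets[rng.choice(len(subsets), p=ws / ws.sum())])
        for i in range(size):
            rows.append({"stratum": f"g{s}", "eqtl": i in case_rows,
                         **{f"x{j}": X[i, j] for j in range(p)}})
    return pd.DataFrame(rows)
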