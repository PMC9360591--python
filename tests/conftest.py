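import numpy as np
import pytest

from mrkit.harmonize import HarmonizedInstrument
from mrkit.instruments import LdMatrix
from mrkit.summary_io import ExclusionEntry, GwasSummaryRecord


def make_record(snp_id="rs1", chrom="1", pos=1000, ea="A", oa="G", eaf=0.3,
                beta=0.1, se=0.01, pval=1e-9, n=127_669) -> GwasSummaryRecord:
    return GwasSummaryRecord(snp_id, chrom, pos, ea, oa, eaf, beta, se, pval, n)


def make_instrument(snp_id="rs1", beta_exp=0.1, se_exp=0.005, beta_out=0.05,
                    se_out=0.01) -> HarmonizedInstrument:
    return HarmonizedInstrument(
        snp_id=snp_id, effect_allele="A", other_allele="G",
        beta_exp=beta_exp, se_exp=se_exp, beta_out=beta_out, se_out=se_out,
        eaf_exp=0.3, eaf_out=0.3, action="none",
    )


def random_instruments(rng: np.random.Generator, j: int) -> list[HarmonizedInstrument]:
    bx = rng.uniform(0.05, 0.3, j) * rng.choice([-1, 1], j)
    by = rng.normal(0.5 * bx, 0.02)
    sy = rng.uniform(0.005, 0.05, j)
    sx = rng.uniform(0.002, 0.01, j)
    return [
        make_instrument(f"rs{i}", float(bx[i]), float(sx[i]), float(by[i]), float(sy[i]))
        for i in range(j)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def sixteen_snp_exposure():
    """16 genome-wide-significant exposure hits mirroring a manual screen:
    one LD conflict and six curated exclusions leave nine instruments."""
    records = [
        make_record(snp_id=f"rs{100 + i}", chrom=str(i % 22 + 1), pos=10_000 * (i + 1),
                    beta=0.12, se=0.012, pval=10 ** -(9 + i % 5), eaf=0.25)
        for i in range(16)
    ]
    ids = [r.snp_id for r in records]
    r2 = np.zeros((16, 16))
    np.fill_diagonal(r2, 1.0)
    # rs100 and rs101 are in LD; rs101 has the larger p-value of the pair
    i, j = ids.index("rs100"), ids.index("rs101")
    r2[i, j] = r2[j, i] = 0.5
    ld = LdMatrix(snp_ids=tuple(ids), r2=r2)
    exclusions = [
        ExclusionEntry(f"rs{102 + k}", "confounder_associated", "risk-factor hit")
        for k in range(5)
    ] + [ExclusionEntry("rs107", "outcome_associated", "direct outcome association")]
    return records, ld, exclusions
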