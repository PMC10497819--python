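import numpy as np
import pytest

from mrmediate.instruments import HarmonizedRecord
from mrmediate.summstats import LdPanel, SnpAssociation, SummaryStats


def make_assoc(snp_id="rs1", chrom="1", pos=1000, ea="A", oa="G", eaf=0.3,
               beta=0.1, se=0.01, pval=1e-10, n=100000.0):
    return SnpAssociation(snp_id=snp_id, chrom=chrom, pos=pos,
                          effect_allele=ea, other_allele=oa, eaf=eaf,
                          beta=beta, se=se, pval=pval, n=n)


def make_records(gamma, se_gamma, Gamma, se_Gamma):
    return [HarmonizedRecord(snp_id=f"rs{i}", gamma=float(g), se_gamma=float(sg),
                             Gamma=float(G), se_Gamma=float(sG),
                             aligned_effect_allele="A")
            for i, (g, sg, G, sG) in enumerate(zip(gamma, se_gamma, Gamma, se_Gamma))]


def random_records(rng, j, theta=0.3):
    """Random harmonized records around a linear truth, for oracle checks."""
    gamma = rng.normal(0.1, 0.05, j)
    se_gamma = rng.uniform(0.005, 0.02, j)
    se_Gamma = rng.uniform(0.01, 0.05, j)
    Gamma = theta * gamma + rng.normal(0, se_Gamma)
    return make_records(gamma, se_gamma, Gamma, se_Gamma)


@pytest.fixture
def tiny_panel():
    """Four-variant panel with one perfect-LD pair and two independents."""
    rng = np.random.default_rng(7)
    panel = LdPanel(samples=[f"S{i}" for i in range(200)])
    base = rng.binomial(2, 0.3, 200).astype(float)
    panel.add_variant("rsA", base, chrom="1", pos=1_000_000)
    panel.add_variant("rsB", base.copy(), chrom="1", pos=1_001_000)
    panel.add_variant("rsC", rng.binomial(2, 0.4, 200).astype(float),
                      chrom="1", pos=2_000_000)
    panel.add_variant("rsD", rng.binomial(2, 0.25, 200).astype(float),
                      chrom="2", pos=1_000_000)
    return panel


@pytest.fixture
def simple_stats():
    ss = SummaryStats(trait="toy", unit="1-SD")
    for i, (snp, p) in enumerate([("rsA", 1e-12), ("rsB", 1e-10),
                                  ("rsC", 1e-9), ("rsD", 1e-8 / 2)]):
        ss.add(make_assoc(snp_id=snp, pos=1000 * (i + 1), beta=0.05 + 0.01 * i,
                          pval=p))
    return ss
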