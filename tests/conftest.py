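import numpy as np
import pytest

from xenopurity.mle import GenotypeClass, SnpSite
from xenopurity.simulate import make_synthetic_signature


@pytest.fixture(scope="session")
def signature():
    """Synthetic 141+141-gene signature with a partial ortholog map."""
    return make_synthetic_signature()


def hom_site(n_h: int, n_t: int, site_id: str = "s") -> SnpSite:
    return SnpSite(site_id=site_id, genotype_class=GenotypeClass.HOM_TT, n_H=n_h, n_T=n_t)


def het_site(n_h: int, n_t: int, t1: float = 0.5, site_id: str = "s") -> SnpSite:
    return SnpSite(
        site_id=site_id,
        genotype_class=GenotypeClass.HET_HT,
        n_H=n_h,
        n_T=n_t,
        H1=1.0 - t1,
        T1=t1,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
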