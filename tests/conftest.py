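import numpy as np
import pytest

from enose_sais import CarrierShiftConfig, DomainDataset, generate_domain_pair


@pytest.fixture(scope="session")
def default_pair():
    """Default synthetic carrier-shift scenario, seed 0 (source, target)."""
    return generate_domain_pair(CarrierShiftConfig(seed=0))


@pytest.fixture(scope="session")
def small_pair():
    """Reduced-size scenario for fast pipeline tests."""
    cfg = CarrierShiftConfig(
        n_source_per_class=20, n_target_per_class=20, seed=1
    )
    return generate_domain_pair(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_orthonormal(d, D, rng):
    """Random d x D matrix with orthonormal columns (QR of a Gaussian)."""
    q, r = np.linalg.qr(rng.standard_normal((d, D)))
    return q * np.sign(np.diag(r))


def make_dataset(X, labels=None, tag="source"):
    return DomainDataset(np.asarray(X, float), labels=labels, domain_tag=tag)
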