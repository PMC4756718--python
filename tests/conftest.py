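import numpy as np
import pytest

from routesurv import simulate
from routesurv.cohort import truncate_survival


@pytest.fixture(scope="session")
def null_cohort():
    """Small two-arm cohort with no route or gene effects (seeded)."""
    cfg = simulate.SimulationConfig(n_ip=100, n_iv=100, n_genes=5, route_log_hr=0.0, seed=7)
    return simulate.generate(cfg)


@pytest.fixture(scope="session")
def demo_cohort():
    """Cohort with one planted IV-arm predictive gene and one prognostic gene."""
    return simulate.make_fixture("predictive_gene_demo", seed=11)


@pytest.fixture(scope="session")
def demo_clinical(demo_cohort):
    return truncate_survival(demo_cohort.clinical)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def tiny_survival():
    """Hand-checkable uncensored sample: events at 1, 2, 3."""
    return np.array([1.0, 2.0, 3.0]), np.array([True, True, True])


def km_product_limit_oracle(times, events):
    """Brute-force product-limit recomputation (independent of the package)."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    grid = np.unique(times)
    s = 1.0
    out = []
    for t in grid:
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & events)
        if at_risk > 0:
            s *= 1.0 - d / at_risk
        out.append((t, s))
    return out


@pytest.fixture(scope="session")
def km_oracle():
    return km_product_limit_oracle
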