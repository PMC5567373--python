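import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_bundle():
    """A small generated benchmark plus its assembled, filtered feature matrix."""
    from metconc.features import assemble, preprocess
    from metconc.synthetic import SyntheticConfig, generate

    cfg = SyntheticConfig(seed=7, n_metabolites=60, n_molecular_descriptors=15, n_pathways=6)
    dataset, molecular, nets, members, truth = generate(cfg)
    topo = {org: net.descriptors_for(sorted(net.nodes)) for org, net in nets.items()}
    pathways = set().union(*truth.organism_pathways.values())
    fm = assemble(dataset, molecular, topo, members, pathways)
    fm, _ = preprocess(fm)
    y = dataset.neg_log_c().to_numpy()
    return dataset, fm, y, truth, members
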