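from types import SimpleNamespace

import pytest

import germdrift as gd
from germdrift.simulate import SimulationParams, simulate_counts


@pytest.fixture(scope="session")
def default_sim():
    """Desk-scale default simulation shared across test modules."""
    params = SimulationParams(n_genes=2000, seed=3)
    counts, design, annotation, truth = simulate_counts(params)
    return SimpleNamespace(
        params=params, counts=counts, design=design, annotation=annotation, truth=truth
    )


@pytest.fixture(scope="session")
def default_analysis(default_sim):
    """Normalization, log matrix, universe, WCA result and scores for the
    shared simulation."""
    s = default_sim
    factors = gd.estimate_size_factors(s.counts)
    lm = gd.log_transform(gd.normalize(s.counts, factors))
    universe = gd.filter_expressed(lm)
    sub = lm.loc[universe].T
    classes = s.design.classes_for(list(sub.index))
    severity = s.design.severity_rank_for(list(sub.index))
    result = gd.wca(sub, classes, severity_rank=severity)
    scores = gd.wca_scores(result)
    return SimpleNamespace(
        factors=factors,
        lm=lm,
        universe=universe,
        matrix=sub,
        classes=classes,
        severity=severity,
        result=result,
        scores=scores,
    )
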