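import numpy as np
import pytest

from netrsf import datasets, synthetic


@pytest.fixture
def toy_dataset():
    """20 tie-free samples with a prognostic first gene and noise second."""
    rng = np.random.default_rng(42)
    n = 20
    x1 = rng.standard_normal(n)
    x2 = rng.standard_normal(n)
    lp = 1.2 * x1
    times = -np.log(rng.random(n)) / (0.1 * np.exp(lp))
    # perturb to guarantee distinct observed times
    times = times * (1 + 1e-9 * np.arange(n))
    events = (rng.random(n) < 0.8).astype(int)
    samples = [f"s{i}" for i in range(n)]
    expr = datasets.ExpressionMatrix(["gA", "gB"], samples, np.vstack([x1, x2]))
    surv = datasets.SurvivalTable(samples, times, events)
    return datasets.Dataset(expr, surv)


@pytest.fixture(scope="session")
def hub_cohort():
    """Shared hub-signal cohort: 100 genes, 10 hub signal genes, 400 samples."""
    cfg = synthetic.SimulationConfig(
        n_genes=100, n_samples=400, n_signal=10, beta=1.0,
        censoring_rate=0.3, seed=1,
    )
    net, ds, truth = synthetic.simulate_dataset(cfg)
    train, test = datasets.split(ds, 0.5, seed=3)
    return {"net": net, "train": train, "test": test, "truth": truth, "cfg": cfg}
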