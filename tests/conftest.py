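import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from reefprior.annealer import Problem
from reefprior.reefscape import ReefscapeConfig, generate_reefscape

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def full_reef_config(rows=50, cols=50, classes=(2, 4, 8, 12, 20), seed=0):
    """A fully-reef rectangular reefscape (no edge trimming anywhere)."""
    return ReefscapeConfig(
        grid_rows=rows,
        grid_cols=cols,
        reef_fraction_target=1.0,
        n_patches=1,
        classes_per_level=classes,
        seed=seed,
    )


@pytest.fixture(scope="session")
def full_reef():
    return generate_reefscape(full_reef_config())


@pytest.fixture(scope="session")
def patchy_reef():
    """A moderate reefscape with partial-cover edge cells."""
    cfg = ReefscapeConfig(
        grid_rows=50,
        grid_cols=50,
        reef_fraction_target=0.6,
        n_patches=3,
        classes_per_level=(2, 4, 8, 12, 20),
        seed=11,
    )
    return generate_reefscape(cfg)


def random_toy_problem(rng, n_range=(12, 19), nf_range=(2, 5), spf=100.0) -> Problem:
    """A small random minimum-set instance: features scattered over units
    with uniform amounts, independent unit costs."""
    n = int(rng.integers(*n_range))
    nf = int(rng.integers(*nf_range))
    rows = []
    for f in range(nf):
        units = rng.choice(
            np.arange(1, n + 1), size=max(2, int(rng.integers(2, n))), replace=False
        )
        for u in units:
            rows.append((int(u), f, float(rng.uniform(0.1, 1.0))))
    feats = pd.DataFrame(rows, columns=["pu_id", "class_id", "amount_km2"])
    ids = pd.Index(range(1, n + 1))
    costs = pd.Series(rng.uniform(0.5, 2.0, n), index=ids)
    return Problem.from_tables(feats, costs, costs, spf=np.full(nf, spf))
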