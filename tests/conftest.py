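"""Shared fixtures: small simulated populations and the two recovery chains.

The recovery fits are session-scoped because several tests inspect the same
chains (truth recovery, draw-level invariants, convergence diagnostics).
"""

import numpy as np
import pandas as pd
import pytest

from wstripe.pedigree import Pedigree
from wstripe.simulate import SimulationConfig, simulate_population
from wstripe.threshold_model import McmcConfig, ModelSpec, gibbs_run


def recovery_config(rg: float, seed: int) -> SimulationConfig:
    """Divergent-selection scheme, ~3,000 birds over 4 generations:
    liability h² = 0.65 (σ²_e1 = 1), co-trait h² = 0.20 with a maternal
    fraction c² = 0.10, genetic correlation ``rg``."""
    g1 = 0.65 / 0.35
    g2, e2 = 0.2, 0.7
    g12 = rg * np.sqrt(g1 * g2)
    e12 = 0.1 * np.sqrt(1.0 * e2)
    return SimulationConfig(
        n_generations=4,
        base_size=520,
        sires_per_line=18,
        dams_per_line=52,
        offspring_per_dam=6,
        trait_names=("WS", "BW"),
        true_G=[[g1, g12], [g12, g2]],
        true_R=[[1.0, e12], [e12, e2]],
        maternal_trait="BW",
        c2=0.10,
        selection_trait="BW",
        seed=seed,
    )


REDUCED_SCHEDULE = dict(iterations=20_000, burnin=4_000, thin=10)


@pytest.fixture(scope="session")
def recovery_chain_rg068():
    ds = simulate_population(recovery_config(0.68, 101))
    chain = gibbs_run(
        ds.pedigree,
        ds.phenotypes,
        ModelSpec(trait1="WS", trait2="BW", maternal_traits=("BW",)),
        McmcConfig(seed=7, **REDUCED_SCHEDULE),
    )
    return ds, chain


@pytest.fixture(scope="session")
def recovery_chain_rg0():
    ds = simulate_population(recovery_config(0.0, 202))
    chain = gibbs_run(
        ds.pedigree,
        ds.phenotypes,
        ModelSpec(trait1="WS", trait2="BW", maternal_traits=("BW",)),
        McmcConfig(seed=8, **REDUCED_SCHEDULE),
    )
    return ds, chain


@pytest.fixture(scope="session")
def small_bivariate_dataset():
    """~650 birds, liability + quantitative trait, mild selection."""
    g1 = 1.5
    cfg = SimulationConfig(
        n_generations=2,
        base_size=250,
        sires_per_line=8,
        dams_per_line=20,
        offspring_per_dam=5,
        trait_names=("WS", "BMY"),
        true_G=[[g1, 0.5 * np.sqrt(g1 * 1.0)], [0.5 * np.sqrt(g1 * 1.0), 1.0]],
        true_R=[[1.0, 0.1], [0.1, 1.0]],
        selection_trait="BMY",
        seed=33,
    )
    return simulate_population(cfg)


def toy_pedigree_frame():
    """Trio plus one founder sibling pair; hand-checkable relationships."""
    return pd.DataFrame(
        {
            "id": [1, 2, 3, 4],
            "sire": [0, 0, 1, 1],
            "dam": [0, 0, 2, 2],
            "line": ["base"] * 4,
            "sex": ["M", "F", "M", "F"],
            "hatch": [1, 1, 2, 2],
            "generation": [0, 0, 1, 1],
        }
    )


def random_pedigree(seed: int, n: int) -> Pedigree:
    """Random valid pedigree: ~30% founders, parents drawn from the past."""
    rng = np.random.default_rng(seed)
    sex = rng.choice(["M", "F"], size=n)
    sire = np.zeros(n, dtype=int)
    dam = np.zeros(n, dtype=int)
    for i in range(1, n):
        males = np.where(sex[:i] == "M")[0]
        females = np.where(sex[:i] == "F")[0]
        if len(males) and len(females) and rng.random() > 0.3:
            sire[i] = males[rng.integers(len(males))] + 1
            dam[i] = females[rng.integers(len(females))] + 1
    df = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "sire": sire,
            "dam": dam,
            "line": "base",
            "sex": sex,
            "hatch": 1,
            "generation": 0,
        }
    )
    return Pedigree.from_frame(df)
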