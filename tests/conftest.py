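import numpy as np
import pandas as pd
import pytest

import threatspace as ts


@pytest.fixture(scope="session")
def decline_table():
    return ts.load_decline_table()


@pytest.fixture(scope="session")
def world_small():
    """A small full world (LC majority, some at-risk) for structural tests."""
    return ts.generate_world(n_species=120, seed=3)


@pytest.fixture(scope="session")
def risk_world():
    """An all-at-risk world sized for model fitting."""
    return ts.generate_world(n_species=300, at_risk_fraction=1.0, seed=11)


@pytest.fixture(scope="session")
def fitted(risk_world, decline_table):
    """One well-mixed ordinal fit shared across model and projection tests.

    The design is restricted to the generator's active (positive-effect)
    covariates so that scenario-monotonicity checks, which assume
    non-negative coefficients, apply.
    """
    w = risk_world
    design = ts.build_design(w.threats, w.at_risk, decline_table)
    active = w.truth["active_columns"]
    design = design[active]
    pc = ts.phylo_covariance(w.tree, 1.0)
    cfg = ts.OrdinalModelConfig(
        n_iterations=20_000, burn_in=2_000, thinning=18, seed=5,
        bin_width=w.truth["bin_width"],
    )
    samples = ts.fit_ordinal(
        design, pc, w.spatial, w.categories.loc[w.at_risk], cfg
    )
    return {"world": w, "design": design, "samples": samples, "pc": pc}


def make_records(seed, n_species=30, table=None):
    """Seeded random threat records spanning scopes/severities/timings."""
    table = table or ts.load_decline_table()
    cfg = ts.ThreatSimConfig()
    species = [f"s{i}" for i in range(n_species)]
    return ts.simulate_threats(species, cfg, seed=seed, table=table)
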