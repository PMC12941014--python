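"""Shared fixtures: small lattices and one reusable Model 1 fit."""

from __future__ import annotations

import numpy as np
import pytest

from stcar import (CountPanel, ModelSpec, SamplerConfig, fit,
                   make_grid_lattice, make_truth, simulate_covariates,
                   simulate_panel, simulate_populations)

STUDY_YEARS = [2018, 2019, 2020, 2021]
COVS2 = ("pct_public_insurance", "median_age")


@pytest.fixture(scope="session")
def grid5():
    return make_grid_lattice(5, 5, "rook")


@pytest.fixture(scope="session")
def grid33():
    return make_grid_lattice(3, 3, "rook")


@pytest.fixture(scope="session")
def yearly_dataset(grid5):
    """Simulated Model 1 dataset on a 5x5 lattice with known truth."""
    spec = ModelSpec.model(1, covariate_names=COVS2)
    covars = simulate_covariates(grid5, STUDY_YEARS, seed=101)
    pops = simulate_populations(grid5, seed=102)
    truth = make_truth(spec, grid5, 4, seed=103)
    panel = simulate_panel(spec, truth, grid5, covars, pops, seed=104)
    return dict(spec=spec, lattice=grid5, covars=covars, pops=pops,
                truth=truth, panel=panel)


@pytest.fixture(scope="session")
def model1_fit(yearly_dataset):
    """One short Model 1 fit shared across structural tests."""
    d = yearly_dataset
    return fit(d["spec"], d["panel"], d["covars"], d["lattice"],
               SamplerConfig(draws=400, warmup=400, chains=2, seed=7))


@pytest.fixture()
def tiny_panel():
    """2x2-lattice yearly panel with hand-set counts."""
    return CountPanel(
        Y=np.array([[5, 6, 4, 3], [2, 1, 0, 2], [7, 8, 9, 6], [1, 0, 1, 1]]),
        P=np.array([100, 50, 200, 40]),
        tract_ids=("r0c0", "r0c1", "r1c0", "r1c1"),
        period_labels=("2018", "2019", "2020", "2021"),
        granularity="year",
    )
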