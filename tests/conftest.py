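"""Shared fixtures: small synthetic datasets and constructed posterior draws."""

import numpy as np
import pandas as pd
import pytest

from careload import simulate as sim
from careload.glmm import ModelSpec, build_design
from careload.io import prepare_survival
from careload.mcmc import McmcOptions, PosteriorDraws


@pytest.fixture(scope="session")
def small_survival_table():
    """Prepared bean table from a reduced survival design (~350 rows)."""
    design = sim.SurvivalDesign(replicates=1, beans_total=400)
    beans = sim.gen_survival(design, sim.SurvivalParams(), seed=42)
    tab, _ = prepare_survival(beans)
    return tab


def make_posterior(spec: ModelSpec, data: pd.DataFrame,
                   coef_rows: np.ndarray) -> PosteriorDraws:
    """Wrap a fixed coefficient matrix as PosteriorDraws with design metadata.

    ``coef_rows``: (n_draws, n_fixed + n_random) array; random-variance
    columns follow the fixed-effect columns.
    """
    design = build_design(spec, data)
    labels = list(design.colnames) + [f"var[{f.name}]" for f in design.factors]
    coef_rows = np.atleast_2d(np.asarray(coef_rows, float))
    assert coef_rows.shape[1] == len(labels)
    scales = {"beta": 1.0, **{f.name: 1.0 for f in design.factors}}
    return PosteriorDraws(
        draws=pd.DataFrame(coef_rows, columns=labels),
        acceptance={}, scales_burnin_end=scales, scales_final=scales,
        options=McmcOptions(n_iterations=len(coef_rows), burn_in=0, thin=1),
        design=design,
    )


@pytest.fixture()
def survival_draw_maker(small_survival_table):
    """Factory: survival-model PosteriorDraws with chosen coefficients.

    Coefficient order: intercept (inbred at C=0), outbred offset, C slope,
    outbred:C interaction, duo variance.
    """
    from careload.pipeline import survival_spec

    def make(rows):
        return make_posterior(survival_spec(), small_survival_table,
                              np.asarray(rows, float))

    return make


@pytest.fixture(scope="session")
def tiny_binomial_df():
    """10-row, 3-group binomial table for quadrature oracles."""
    rng = np.random.default_rng(7)
    n = 10
    return pd.DataFrame({
        "y": rng.integers(0, 6, n),
        "n": np.full(n, 5),
        "x": rng.normal(size=n),
        "g": np.repeat(["a", "b", "c"], [4, 3, 3]),
    })
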