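"""Equilibrium genetic load in a two-habitat metapopulation.

A metapopulation occupies a predictable habitat j (frequency p_j,
productivity B_j) and an unpredictable habitat k (p_k = 1 - p_j, B_k).
Selection per unit of genetic load is s_j in j and s_k >= s_j in k: the
predictable habitat allows adaptive maternal-care plasticity that shields
offspring from competition, weakening selection against deleterious
recessives there.

Under soft selection each habitat contributes breeders in proportion to
p_i B_i, giving reproductive-value weights

    w_i = p_i B_i / (p_j B_j + p_k B_k),

so an allele experiences the effective (contribution-weighted) selection
s_bar = w_j s_j + w_k s_k.  With genomic deleterious mutation rate U and
multiplicative loci, mutation-selection balance tunes the equilibrium
amount of segregating load to U / s_bar per unit selection, and habitat
mean fitness is

    W_i = exp(-U s_i / s_bar),        L_i = 1 - W_i.

In a homogeneous habitat (s_i = s_bar) this is the classical
Haldane-Muller result W = e^(-U): the load depends only on the mutation
rate.  Heterogeneity redistributes it — as the predictable habitat becomes
more common (or more productive), s_bar falls toward s_j and the load
exposed in the unpredictable habitat, L_k = 1 - exp(-U s_k / s_bar), rises.
The dominance coefficient cancels from this genome-wide equilibrium and is
therefore not a parameter.

Defaults calibrate s_j to 0.48 with s_k = 1.33 s_j and compare U in {1, 2}
and B_j/B_k in {1.96, 1}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LoadModelError",
    "LoadModelParams",
    "contribution_weights",
    "effective_selection",
    "habitat_load",
    "load_curve",
    "DEFAULT_SCENARIOS",
]

S_J_DEFAULT = 0.48
S_RATIO_DEFAULT = 1.33
DEFAULT_SCENARIOS = tuple((u, b) for u in (1.0, 2.0) for b in (1.96, 1.0))


class LoadModelError(ValueError):
    pass


@dataclass(frozen=True)
class LoadModelParams:
    """Parameters of one load scenario.

    U: genomic deleterious mutation rate per generation.
    s_j, s_k: strength of selection per unit load in the predictable and
        unpredictable habitat.
    p_j: frequency of the predictable habitat (p_k = 1 - p_j).
    B_j, B_k: habitat productivities.
    """

    U: float = 1.0
    s_j: float = S_J_DEFAULT
    s_k: float = S_RATIO_DEFAULT * S_J_DEFAULT
    p_j: float = 0.5
    B_j: float = 1.96
    B_k: float = 1.0

    def validate(self) -> None:
        if self.U < 0:
            raise LoadModelError("U must be >= 0")
        if not (0.0 <= self.p_j <= 1.0):
            raise LoadModelError("p_j must lie in [0, 1]")
        if self.s_j <= 0 or self.s_k <= 0:
            raise LoadModelError("selection strengths must be > 0")
        if self.B_j <= 0 or self.B_k <= 0:
            raise LoadModelError("productivities must be > 0")


def contribution_weights(p_j: float, B_j: float, B_k: float) -> tuple[float, float]:
    """Soft-selection reproductive-value weights
    w_i = p_i B_i / (p_j B_j + p_k B_k)."""
    if not (0.0 <= p_j <= 1.0):
        raise LoadModelError("p_j must lie in [0, 1]")
    if B_j <= 0 or B_k <= 0:
        raise LoadModelError("productivities must be > 0")
    a = p_j * B_j
    b = (1.0 - p_j) * B_k
    tot = a + b
    if tot <= 0:
        raise LoadModelError("both contribution weights are zero")
    return a / tot, b / tot


def effective_selection(weights: tuple[float, float],
                        s_j: float, s_k: float) -> float:
    """Contribution-weighted mean selection s_bar = w_j s_j + w_k s_k."""
    w_j, w_k = weights
    if not np.isclose(w_j + w_k, 1.0):
        raise LoadModelError("weights must sum to 1")
    return w_j * s_j + w_k * s_k


def habitat_load(U: float, s_i: float, s_bar: float) -> tuple[float, float]:
    """Equilibrium mean fitness and load of one habitat:
    W_i = exp(-U s_i / s_bar), L_i = 1 - W_i."""
    if U < 0:
        raise LoadModelError("U must be >= 0")
    if U > 0 and s_bar <= 0:
        raise LoadModelError("effective selection is zero: load diverges")
    if U == 0:
        return 1.0, 0.0
    w = float(np.exp(-U * s_i / s_bar))
    return w, 1.0 - w


def load_curve(params: LoadModelParams | None = None,
               p_grid: Sequence[float] | None = None,
               scenarios: Sequence[tuple[float, float]] = DEFAULT_SCENARIOS,
               ) -> pd.DataFrame:
    """Evaluate the equilibrium across a grid of habitat frequencies.

    ``scenarios`` lists (U, B_j/B_k) pairs; the default four combine
    U in {1, 2} with B_j/B_k in {1.96, 1}.  ``params`` supplies s_j, s_k and
    B_k (B_j is overridden per scenario by the ratio).  Returns a tidy table
    with one row per scenario x grid point.
    """
    params = params or LoadModelParams()
    params.validate()
    if p_grid is None:
        p_grid = np.linspace(0.0, 1.0, 101)
    p_grid = np.asarray(p_grid, float)
    if np.any((p_grid < 0) | (p_grid > 1)):
        raise LoadModelError("p_grid values must lie in [0, 1]")

    rows = []
    for U, b_ratio in scenarios:
        B_j = b_ratio * params.B_k
        for p_j in p_grid:
            w = contribution_weights(p_j, B_j, params.B_k)
            s_bar = effective_selection(w, params.s_j, params.s_k)
            W_j, L_j = habitat_load(U, params.s_j, s_bar)
            W_k, L_k = habitat_load(U, params.s_k, s_bar)
            w_mean = w[0] * W_j + w[1] * W_k
            rows.append((p_j, U, b_ratio, w[0], s_bar,
                         W_j, W_k, L_j, L_k, w_mean))
    return pd.DataFrame(rows, columns=[
        "p_j", "U", "B_ratio", "w_j", "s_bar",
        "W_j", "W_k", "L_j", "L_k", "W_meta",
    ])
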