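"""Metropolis-within-Gibbs posterior sampling for the mixed models.

The sampler updates, per iteration:

* the fixed-effect vector by a single random-walk Metropolis block
  (multivariate normal proposal shaped by the GLM warm-start covariance),
* each factor's latent random intercepts by independent per-group
  random-walk Metropolis moves (groups are conditionally independent given
  the fixed effects, so the whole vector is proposed and accepted per group
  in one vectorized step),
* each variance component by its conjugate inverse-gamma conditional.

Priors default to Normal(0, 100) on fixed effects and InverseGamma(0.001,
0.001) on variance components; both are configurable.  Proposal scales adapt
toward standard target acceptance rates during burn-in only and are frozen
afterwards, preserving detailed balance for the stored draws.  The stored
chain holds ``n_iterations / thin`` draws taken after burn-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glmm import DesignInfo, GlmmError, ModelSpec, build_design, _fam_funcs

__all__ = [
    "McmcError",
    "TuningFailureError",
    "McmcOptions",
    "PriorSpec",
    "PosteriorDraws",
    "PosteriorSummary",
    "sample_posterior",
    "summarize",
    "pmcmc",
    "effective_sample_size",
]


class McmcError(ValueError):
    pass


class TuningFailureError(McmcError):
    """No proposal was accepted during the whole adaptation phase."""


@dataclass
class McmcOptions:
    n_iterations: int = 100_000
    burn_in: int = 50_000
    thin: int = 100
    seed: int = 0
    beta_scale: float = 0.3
    latent_scale: float = 0.8
    adapt_window: int = 50
    target_accept_beta: float = 0.25
    target_accept_latent: float = 0.44

    def validate(self) -> None:
        if self.n_iterations < 1 or self.thin < 1 or self.burn_in < 0:
            raise McmcError("n_iterations >= 1, thin >= 1, burn_in >= 0 required")
        if self.n_iterations % self.thin:
            raise McmcError("thin must divide n_iterations")

    @property
    def n_stored(self) -> int:
        return self.n_iterations // self.thin


@dataclass
class PriorSpec:
    beta_var: float = 100.0
    ig_shape: float = 0.001
    ig_scale: float = 0.001

    def validate(self) -> None:
        if self.beta_var <= 0 or self.ig_shape <= 0 or self.ig_scale <= 0:
            raise McmcError("prior hyperparameters must be > 0")


@dataclass
class PosteriorDraws:
    """Stored draws (rows) by labelled parameter (columns)."""

    draws: pd.DataFrame
    acceptance: dict[str, float]
    scales_burnin_end: dict[str, float]
    scales_final: dict[str, float]
    options: McmcOptions
    design: DesignInfo | None = None
    rhat: pd.Series | None = None

    @property
    def labels(self) -> list[str]:
        return list(self.draws.columns)

    @property
    def n_stored(self) -> int:
        return len(self.draws)

    @property
    def ess(self) -> pd.Series:
        return pd.Series(
            {c: effective_sample_size(self.draws[c].to_numpy())
             for c in self.draws.columns})

    def to_csv(self, path) -> None:
        self.draws.to_csv(path, index=False)


@dataclass
class PosteriorSummary:
    table: pd.DataFrame            # columns: mean, median, q2.5, q97.5
    degenerate: pd.Series          # True where the series is constant


def effective_sample_size(x: np.ndarray) -> float:
    """ESS via Geyer's initial positive sequence of autocorrelations."""
    x = np.asarray(x, float)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acov = np.correlate(xc, xc, mode="full")[n - 1:] / n
    rho = acov / acov[0]
    # sum consecutive pairs while positive
    s = 0.0
    for k in range(1, n - 1, 2):
        pair = rho[k] + rho[k + 1] if k + 1 < n else rho[k]
        if pair < 0:
            break
        s += pair
    return float(min(n, n / (1.0 + 2.0 * s)))


def _split_rhat(chains: list[np.ndarray]) -> float:
    halves = []
    for c in chains:
        m = len(c) // 2
        halves.extend([c[:m], c[m:2 * m]])
    halves = np.asarray(halves, float)
    m, n = halves.shape
    means = halves.mean(axis=1)
    w = halves.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


def sample_posterior(spec: ModelSpec, data: pd.DataFrame,
                     options: McmcOptions | None = None,
                     priors: PriorSpec | None = None,
                     n_chains: int = 1) -> PosteriorDraws:
    """Draw from the posterior of a binomial/Poisson mixed model.

    Stored columns are the fixed-effect design columns plus ``var[f]`` for
    each random factor f.  With ``n_chains > 1`` chains are run from
    jittered starts on shifted seeds, concatenated, and split-Rhat reported.
    """
    options = options or McmcOptions()
    priors = priors or PriorSpec()
    options.validate()
    priors.validate()
    design = build_design(spec, data)

    if n_chains > 1:
        parts = []
        for c in range(n_chains):
            opt_c = McmcOptions(**{**options.__dict__, "seed": options.seed + 7919 * c})
            parts.append(_run_chain(design, opt_c, priors, jitter=c))
        draws = pd.concat([p.draws for p in parts], ignore_index=True)
        rhat = pd.Series({
            col: _split_rhat([p.draws[col].to_numpy() for p in parts])
            for col in draws.columns})
        first = parts[0]
        return PosteriorDraws(draws, first.acceptance, first.scales_burnin_end,
                              first.scales_final, options, design, rhat)
    return _run_chain(design, options, priors)


def _run_chain(design: DesignInfo, options: McmcOptions, priors: PriorSpec,
               jitter: int = 0) -> PosteriorDraws:
    rng = np.random.default_rng(options.seed)
    ll_f, mean_f, _ = _fam_funcs(design.spec.family)
    y, n = design.y, design.trials
    X = design.X
    p = design.n_params
    nf = len(design.factors)
    empty = design.n_obs == 0

    # warm start and proposal shape from the independent-observation GLM
    beta = np.zeros(p)
    chol = np.eye(p)
    if not empty and p > 0:
        import statsmodels.api as sm
        try:
            if design.spec.family == "binomial":
                res = sm.GLM(np.column_stack([y, n - y]), X,
                             family=sm.families.Binomial()).fit()
            else:
                res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
            beta = np.clip(np.asarray(res.params, float), -10, 10)
            cov = np.asarray(res.cov_params(), float)
            chol = np.linalg.cholesky(cov + 1e-10 * np.eye(p))
        except Exception:
            pass
    if jitter:
        beta = beta + 0.1 * jitter * rng.standard_normal(p)

    u = [np.zeros(f.n_levels) for f in design.factors]
    sigma2 = np.full(nf, 0.5)

    def eta_random():
        out = np.zeros(design.n_obs)
        for i, f in enumerate(design.factors):
            out += u[i][f.codes]
        return out

    eta_fix = X @ beta if p else np.zeros(design.n_obs)
    eta_rand = eta_random()
    cur_rows = ll_f(eta_fix + eta_rand, y, n) if not empty else np.zeros(0)

    beta_scale = options.beta_scale
    latent_scales = [options.latent_scale] * nf

    labels = list(design.colnames) + [f"var[{f.name}]" for f in design.factors]
    stored = np.empty((options.n_stored, len(labels)))
    total_iter = options.burn_in + options.n_iterations

    acc_beta_adapt = acc_beta_post = 0
    acc_lat_adapt = np.zeros(nf)
    acc_lat_post = np.zeros(nf)
    n_post = 0
    win_beta = 0
    win_lat = np.zeros(nf)
    scales_burnin_end: dict[str, float] = {}
    store_row = 0

    for t in range(total_iter):
        adapting = t < options.burn_in

        # --- fixed-effect block ---
        if p > 0:
            prop = beta + beta_scale * (chol @ rng.standard_normal(p))
            eta_prop = X @ prop if not empty else eta_fix
            rows_prop = (ll_f(eta_prop + eta_rand, y, n) if not empty
                         else cur_rows)
            dprior = (np.sum(beta**2) - np.sum(prop**2)) / (2.0 * priors.beta_var)
            dll = float(np.sum(rows_prop) - np.sum(cur_rows)) + dprior
            if dll >= 0 or rng.random() < np.exp(dll):
                beta, eta_fix, cur_rows = prop, eta_prop, rows_prop
                if adapting:
                    acc_beta_adapt += 1
                    win_beta += 1
                else:
                    acc_beta_post += 1

        # --- latent intercepts, vectorized per factor ---
        for i, f in enumerate(design.factors):
            z = rng.standard_normal(f.n_levels)
            u_prop = u[i] + latent_scales[i] * z
            delta = (u_prop - u[i])[f.codes]
            rows_prop = ll_f(eta_fix + eta_rand + delta, y, n)
            dll_g = np.bincount(f.codes, weights=rows_prop - cur_rows,
                                minlength=f.n_levels)
            dll_g += (u[i]**2 - u_prop**2) / (2.0 * sigma2[i])
            accept = np.log(rng.random(f.n_levels)) < dll_g
            if accept.any():
                u_new = np.where(accept, u_prop, u[i])
                eta_rand += (u_new - u[i])[f.codes]
                u[i] = u_new
                cur_rows = ll_f(eta_fix + eta_rand, y, n)
            rate_contrib = accept.mean()
            if adapting:
                acc_lat_adapt[i] += rate_contrib
                win_lat[i] += rate_contrib
            else:
                acc_lat_post[i] += rate_contrib

        # --- conjugate variance components ---
        for i, f in enumerate(design.factors):
            shape = priors.ig_shape + 0.5 * f.n_levels
            rate = priors.ig_scale + 0.5 * float(np.sum(u[i]**2))
            sigma2[i] = 1.0 / rng.gamma(shape, 1.0 / rate)

        # --- adaptation (burn-in only) ---
        if adapting and (t + 1) % options.adapt_window == 0:
            w = options.adapt_window
            beta_scale *= float(np.exp(1.2 * (win_beta / w
                                              - options.target_accept_beta)))
            beta_scale = float(np.clip(beta_scale, 1e-4, 1e4))
            for i in range(nf):
                latent_scales[i] *= float(np.exp(
                    1.2 * (win_lat[i] / w - options.target_accept_latent)))
                latent_scales[i] = float(np.clip(latent_scales[i], 1e-4, 1e4))
            win_beta = 0
            win_lat[:] = 0.0

        if t == options.burn_in - 1:
            scales_burnin_end = _scale_dict(beta_scale, latent_scales, design)
            if options.burn_in >= options.adapt_window and p > 0 and not empty:
                if acc_beta_adapt == 0 and (nf == 0 or acc_lat_adapt.sum() == 0):
                    raise TuningFailureError(
                        "no proposal accepted during the adaptation phase")

        if not adapting:
            n_post += 1
            if n_post % options.thin == 0:
                stored[store_row, :p] = beta
                stored[store_row, p:] = sigma2
                store_row += 1

    if options.burn_in == 0:
        scales_burnin_end = _scale_dict(beta_scale, latent_scales, design)

    draws = pd.DataFrame(stored[:store_row], columns=labels)
    denom = max(options.n_iterations, 1)
    acceptance = {"beta": acc_beta_post / denom}
    for i, f in enumerate(design.factors):
        acceptance[f.name] = float(acc_lat_post[i] / denom)
    return PosteriorDraws(
        draws=draws, acceptance=acceptance,
        scales_burnin_end=scales_burnin_end,
        scales_final=_scale_dict(beta_scale, latent_scales, design),
        options=options, design=design,
    )


def _scale_dict(beta_scale, latent_scales, design) -> dict[str, float]:
    out = {"beta": float(beta_scale)}
    for f, s in zip(design.factors, latent_scales):
        out[f.name] = float(s)
    return out


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _as_frame(draws) -> pd.DataFrame:
    if isinstance(draws, PosteriorDraws):
        return draws.draws
    if isinstance(draws, pd.DataFrame):
        return draws
    arr = np.asarray(draws, float)
    if arr.ndim == 1:
        return pd.DataFrame({"value": arr})
    return pd.DataFrame(arr, columns=[f"p{i}" for i in range(arr.shape[1])])


def summarize(draws) -> PosteriorSummary:
    """Mean, median and equal-tail 95% interval per labelled parameter.

    Order-invariant; a constant series yields a zero-width interval and a
    degeneracy flag.
    """
    tab = _as_frame(draws)
    if len(tab) < 2:
        raise McmcError("need at least 2 draws to summarize")
    arr = tab.to_numpy(float)
    out = pd.DataFrame({
        "mean": arr.mean(axis=0),
        "median": np.median(arr, axis=0),
        "q2.5": np.quantile(arr, 0.025, axis=0),
        "q97.5": np.quantile(arr, 0.975, axis=0),
    }, index=tab.columns)
    degenerate = pd.Series(arr.ptp(axis=0) == 0, index=tab.columns) \
        if hasattr(arr, "ptp") else pd.Series(np.ptp(arr, axis=0) == 0,
                                              index=tab.columns)
    return PosteriorSummary(table=out, degenerate=degenerate)


def pmcmc(scalar_draws) -> float:
    """Two-sided posterior tail probability of a scalar contrast.

    2 x min(fraction > 0, fraction < 0), floored at 2 / n_draws.
    """
    x = np.asarray(scalar_draws, float)
    if x.size < 2:
        raise McmcError("need at least 2 draws")
    frac_pos = float(np.mean(x > 0))
    frac_neg = float(np.mean(x < 0))
    return max(2.0 * min(frac_pos, frac_neg), 2.0 / x.size)
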