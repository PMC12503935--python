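"""Selection coefficients, fitness, inbreeding depression, and IGE summaries.

The quantities estimated here convert fitted survival and egg-placement
models into the currency of natural selection:

* ``delta_omega`` — the relative viability cost of inbreeding at a given
  larval competition level c:  1 - v_I(c) / v_O(c), where v_I and v_O are
  egg-to-adult survival probabilities of inbred and outbred larvae.
* ``expected_fitness`` — egg-placement-weighted expected offspring
  production: eggs on uninfested seeds weighted by survival with no
  competitors (v0) plus eggs on infested seeds weighted by survival with
  three competitors (v3).
* ``selection_coefficient`` — the genome-wide strength of selection against
  deleterious alleles revealed by homozygosity in cue environment j:
  s_j = 1 - omega_I,j / omega_O,j.
* ``inbreeding_depression`` — proportionate fecundity reduction of inbred
  lines relative to their outcrosses, with a percentile bootstrap interval.
* ``care_survival_ellipse`` — the across-genotype covariance between
  maternal care (percent eggs on uninfested hosts) and expected offspring
  survival, summarized as a one-standard-deviation (68%) ellipse; the sign
  of the covariance is the direction of the indirect genetic effect.

Posterior uncertainty is propagated by applying each transformation draw by
draw to stored MCMC output and summarizing with the posterior mean and
equal-tail 95% interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import expit

from .mcmc import PosteriorDraws, pmcmc

__all__ = [
    "SelectionError",
    "SelectionEstimate",
    "EllipseSummary",
    "viability_at",
    "delta_omega",
    "delta_omega_posterior",
    "expected_fitness",
    "selection_coefficient",
    "treatment_selection",
    "TreatmentSelectionResult",
    "inbreeding_depression",
    "genotype_means",
    "care_survival_ellipse",
]

C_RANGE = (0, 6)        # admissible competition levels (observed maximum 6)
_P_EPS = 1e-15


class SelectionError(ValueError):
    pass


@dataclass
class SelectionEstimate:
    label: str
    draws: np.ndarray
    mean: float
    ci_low: float
    ci_high: float
    negative_cost: bool = False

    @classmethod
    def from_draws(cls, label: str, draws: np.ndarray) -> "SelectionEstimate":
        draws = np.asarray(draws, float)
        lo, hi = np.quantile(draws, [0.025, 0.975])
        m = float(draws.mean())
        return cls(label, draws, m, float(lo), float(hi),
                   negative_cost=m < 0)

    def to_dict(self) -> dict:
        return {"label": self.label, "mean": self.mean,
                "ci_low": self.ci_low, "ci_high": self.ci_high}


def _fixed_draw_matrix(draws) -> tuple[np.ndarray, object]:
    if isinstance(draws, PosteriorDraws):
        if draws.design is None:
            raise SelectionError("posterior draws carry no design metadata")
        cols = draws.design.colnames
        return draws.draws[cols].to_numpy(float), draws.design
    raise SelectionError("expected PosteriorDraws with an attached design")


def viability_at(draws: PosteriorDraws, cross_type: str, c: float) -> np.ndarray:
    """Per-draw egg-to-adult survival probability at (cross_type, c).

    Inverse-logit of the population-level linear predictor of the survival
    model (random effects at zero), clamped away from exact 0/1.
    """
    if not (C_RANGE[0] <= c <= C_RANGE[1]):
        raise SelectionError(
            f"competition level {c} outside admissible range {C_RANGE}")
    mat, design = _fixed_draw_matrix(draws)
    row = design.row({"cross_type": cross_type, "C": float(c)})
    eta = mat @ row
    return np.clip(expit(eta), _P_EPS, 1.0 - _P_EPS)


def delta_omega(v_inbred: float, v_outbred: float):
    """Relative fitness cost of inbreeding, 1 - v_I / v_O (unclamped)."""
    v_inbred = np.asarray(v_inbred, float)
    v_outbred = np.asarray(v_outbred, float)
    if np.any(v_outbred <= 0):
        raise SelectionError("outbred viability must be > 0")
    out = 1.0 - v_inbred / v_outbred
    return float(out) if out.ndim == 0 else out


def delta_omega_posterior(draws: PosteriorDraws, c: float) -> SelectionEstimate:
    """Posterior of the inbreeding viability cost at competition level c."""
    v_i = viability_at(draws, "inbred", c)
    v_o = viability_at(draws, "outbred", c)
    return SelectionEstimate.from_draws(f"delta_omega[C={c:g}]",
                                        delta_omega(v_i, v_o))


def expected_fitness(eggs_uninfested, eggs_infested, v0, v3):
    """Egg-weighted expected offspring production.

    omega = eggs_uninfested * v0 + eggs_infested * v3, with v0/v3 the
    survival probabilities at zero and three competitors.
    """
    eu = np.asarray(eggs_uninfested, float)
    ei = np.asarray(eggs_infested, float)
    if np.any(eu < 0) or np.any(ei < 0):
        raise SelectionError("egg counts must be >= 0")
    v0 = np.asarray(v0, float)
    v3 = np.asarray(v3, float)
    for v in (v0, v3):
        if np.any((v <= 0) | (v >= 1)):
            raise SelectionError("viabilities must lie in (0, 1)")
    out = eu * v0 + ei * v3
    return float(out) if out.ndim == 0 else out


def selection_coefficient(omega_inbred, omega_outbred):
    """Genome-wide selection against revealed deleterious alleles:
    s = 1 - omega_I / omega_O."""
    oi = np.asarray(omega_inbred, float)
    oo = np.asarray(omega_outbred, float)
    if np.any(oo <= 0):
        raise SelectionError("outbred fitness must be > 0")
    out = 1.0 - oi / oo
    return float(out) if out.ndim == 0 else out


@dataclass
class TreatmentSelectionResult:
    per_treatment: dict[str, SelectionEstimate]
    contrasts: dict[str, SelectionEstimate]
    pmcmc: dict[str, float]
    fitness: dict[str, SelectionEstimate] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "s": {k: v.to_dict() for k, v in self.per_treatment.items()},
            "contrasts": {k: v.to_dict() for k, v in self.contrasts.items()},
            "pmcmc": dict(self.pmcmc),
            "fitness": {k: v.to_dict() for k, v in self.fitness.items()},
        }


def _thin_to(draws: np.ndarray, m: int) -> np.ndarray:
    if len(draws) == m:
        return draws
    idx = np.linspace(0, len(draws) - 1, m).round().astype(int)
    return draws[idx]


def _egg_expectation(egg_draws: PosteriorDraws, treatment: str,
                     cross_type: str) -> np.ndarray:
    """Per-draw expected egg count for a (treatment, cross type) cell,
    marginal over the trial random intercept: exp(eta + sigma^2/2)."""
    mat, design = _fixed_draw_matrix(egg_draws)
    row = design.row({"treatment": treatment, "cross_type": cross_type})
    eta = mat @ row
    for f in design.factors:
        eta = eta + 0.5 * egg_draws.draws[f"var[{f.name}]"].to_numpy(float)
    return np.exp(eta)


def treatment_selection(eggs_uninfested_draws: PosteriorDraws,
                        eggs_infested_draws: PosteriorDraws,
                        survival_draws: PosteriorDraws,
                        treatments=("reliable", "unreliable", "none"),
                        allow_resample: bool = True) -> TreatmentSelectionResult:
    """Per-treatment selection coefficients with pairwise contrasts.

    Egg-model and survival-model draws are paired by index; if chains differ
    in length the longer is thinned to the shortest (``allow_resample``),
    otherwise a mismatch raises.  Per draw and treatment j:

        omega_X,j = E[eggs uninfested | j, X] * v_X(0)
                  + E[eggs infested | j, X] * v_X(3)
        s_j = 1 - omega_I,j / omega_O,j

    Contrasts are s_b - s_a for each treatment pair with their two-sided
    posterior tail probability.
    """
    lengths = {eggs_uninfested_draws.n_stored, eggs_infested_draws.n_stored,
               survival_draws.n_stored}
    if len(lengths) > 1 and not allow_resample:
        raise SelectionError(
            f"draw counts differ ({sorted(lengths)}) and resampling is disabled")
    m = min(lengths)

    v = {ct: {c: _thin_to(viability_at(survival_draws, ct, c), m)
              for c in (0, 3)}
         for ct in ("inbred", "outbred")}

    per_treatment: dict[str, SelectionEstimate] = {}
    fitness: dict[str, SelectionEstimate] = {}
    s_draws: dict[str, np.ndarray] = {}
    for j in treatments:
        omega = {}
        for ct in ("inbred", "outbred"):
            eu = _thin_to(_egg_expectation(eggs_uninfested_draws, j, ct), m)
            ei = _thin_to(_egg_expectation(eggs_infested_draws, j, ct), m)
            omega[ct] = expected_fitness(eu, ei, v[ct][0], v[ct][3])
            fitness[f"omega[{j},{ct}]"] = SelectionEstimate.from_draws(
                f"omega[{j},{ct}]", omega[ct])
        s_draws[j] = selection_coefficient(omega["inbred"], omega["outbred"])
        per_treatment[j] = SelectionEstimate.from_draws(f"s[{j}]", s_draws[j])

    contrasts: dict[str, SelectionEstimate] = {}
    pvals: dict[str, float] = {}
    for a, b in combinations(treatments, 2):
        diff = s_draws[b] - s_draws[a]
        key = f"s[{b}]-s[{a}]"
        contrasts[key] = SelectionEstimate.from_draws(key, diff)
        pvals[key] = 1.0 if np.all(np.abs(diff) < 1e-12) else pmcmc(diff)
    return TreatmentSelectionResult(per_treatment, contrasts, pvals, fitness)


# ---------------------------------------------------------------------------
# fecundity-based inbreeding depression
# ---------------------------------------------------------------------------

def inbreeding_depression(fecundity: pd.DataFrame, n_boot: int = 2000,
                          seed: int = 0) -> pd.DataFrame:
    """Proportionate fecundity reduction of each inbred line relative to its
    outcross, 1 - mean(inbred) / mean(outbred), with a percentile bootstrap
    95% interval; an ``overall`` row pools the three lines.
    """
    rng = np.random.default_rng(seed)
    labels = fecundity["cross_label"].astype(str)
    pairs = {}
    for lab in labels.unique():
        if lab.endswith("-inbred"):
            idx = lab[len("line"):-len("-inbred")]
            pairs.setdefault(idx, {})["inbred"] = \
                fecundity.loc[labels == lab, "hatched_eggs"].to_numpy(float)
        elif lab.endswith("-outbred"):
            idx = lab[len("cross"):-len("-outbred")]
            pairs.setdefault(idx, {})["outbred"] = \
                fecundity.loc[labels == lab, "hatched_eggs"].to_numpy(float)

    def estimate(inb, out):
        mo = out.mean()
        if mo <= 0:
            raise SelectionError("outbred mean fecundity is zero")
        return 1.0 - inb.mean() / mo

    rows = []
    all_inb, all_out = [], []
    for idx in sorted(pairs):
        d = pairs[idx]
        if "inbred" not in d or "outbred" not in d:
            continue
        inb, out = d["inbred"], d["outbred"]
        if len(inb) < 2 or len(out) < 2:
            raise SelectionError("need >= 2 females per cross")
        all_inb.append(inb)
        all_out.append(out)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            boots[b] = estimate(rng.choice(inb, len(inb)),
                                rng.choice(out, len(out)))
        lo, hi = np.quantile(boots, [0.025, 0.975])
        rows.append((f"line{idx}", estimate(inb, out), lo, hi))

    inb = np.concatenate(all_inb)
    out = np.concatenate(all_out)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = estimate(rng.choice(inb, len(inb)),
                            rng.choice(out, len(out)))
    lo, hi = np.quantile(boots, [0.025, 0.975])
    rows.append(("overall", estimate(inb, out), lo, hi))
    return pd.DataFrame(rows, columns=["line", "reduction", "ci_low", "ci_high"])


# ---------------------------------------------------------------------------
# indirect genetic effects: genotype means and confidence ellipses
# ---------------------------------------------------------------------------

def genotype_means(eggs: pd.DataFrame,
                   survival_draws: PosteriorDraws) -> pd.DataFrame:
    """Per-genotype (line x cross type) means of care and expected survival.

    Care is the percentage of eggs a genotype placed on uninfested hosts in
    a treatment.  Expected survival weights that placement by the posterior-
    mean survival at zero competitors (uninfested seeds) and three
    competitors (infested seeds), expressed as a percentage.
    """
    v = {ct: {c: float(viability_at(survival_draws, ct, c).mean())
              for c in (0, 3)}
         for ct in ("inbred", "outbred")}
    g = (eggs.groupby(["treatment", "line_id", "cross_type"], sort=True)
         [["eggs_uninfested", "eggs_infested"]].sum().reset_index())
    tot = g["eggs_uninfested"] + g["eggs_infested"]
    if (tot == 0).any():
        raise SelectionError("a genotype laid no eggs; care undefined")
    g["care"] = 100.0 * g["eggs_uninfested"] / tot
    surv = []
    for _, r in g.iterrows():
        vv = v[r["cross_type"]]
        surv.append(100.0 * (r["eggs_uninfested"] * vv[0]
                             + r["eggs_infested"] * vv[3])
                    / (r["eggs_uninfested"] + r["eggs_infested"]))
    g["survival"] = surv
    return g[["treatment", "line_id", "cross_type", "care", "survival"]]


@dataclass
class EllipseSummary:
    center: tuple[float, float]
    cov: np.ndarray
    semi_axes: tuple[float, float]
    angle: float                     # radians, major axis vs care axis
    degenerate: bool

    @property
    def ige_direction(self) -> float:
        """Sign of the care-survival covariance (the IGE direction)."""
        return float(np.sign(self.cov[0, 1]))


def care_survival_ellipse(points: pd.DataFrame) -> EllipseSummary:
    """One-standard-deviation (68%) ellipse of genotype means.

    ``points`` needs columns ``care`` and ``survival`` (>= 3 rows).  The
    ellipse axes come from the eigendecomposition of the sample covariance;
    collinear or coincident points set the degeneracy flag.
    """
    if len(points) < 3:
        raise SelectionError("need >= 3 genotype means for an ellipse")
    xy = points[["care", "survival"]].to_numpy(float)
    center = xy.mean(axis=0)
    cov = np.cov(xy.T, ddof=1)
    w, vecs = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    order = np.argsort(w)[::-1]
    w, vecs = w[order], vecs[:, order]
    angle = float(np.arctan2(vecs[1, 0], vecs[0, 0]))
    degenerate = bool(w[1] <= 1e-12 * max(w[0], 1.0))
    return EllipseSummary(
        center=(float(center[0]), float(center[1])),
        cov=cov,
        semi_axes=(float(np.sqrt(w[0])), float(np.sqrt(w[1]))),
        angle=angle,
        degenerate=degenerate,
    )
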