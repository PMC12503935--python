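"""Synthetic data generators for the seed-beetle maternal-care experiments.

Three experimental designs are emulated at the observation-model level:

1. **Behavioural arena trials** — groups of five mated females search a
   spatially structured arena for a patch of uninfested host seeds over five
   consecutive 10-minute runs, after receiving one of three environmental-cue
   treatments (``reliable``, ``unreliable``, ``none``).  The recorded response
   is the number of females (out of five) on the uninfested patch at each
   30-second scan, i.e. 20 observations per run.
2. **Egg placement** — the number of eggs a group lays on uninfested versus
   infested seeds per run (Poisson counts with a log-linear rate).
3. **Larval survival** — duos of females lay on mung beans pre-infested with
   0-4 competitor (*C. phaseoli*) eggs; egg-to-adult emergence of the focal
   species is binomial with a logit-linear predictor in inbreeding status and
   competition intensity.
4. **Fecundity** — hatched-egg counts per female for inbred lines, their
   between-line outcrosses, and the stock population (overdispersed counts).

All generators are deterministic given ``(design, params, seed)``.  Random
intercepts are Gaussian on the link scale.  Default parameter values are
calibration defaults chosen to reproduce the qualitative treatment ordering
(reliable > none > unreliable care; inbred deficits shrinking across runs)
and survival levels typical for this system; they are not fitted values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InvalidDesignError",
    "InvalidParamsError",
    "BehaviorDesign",
    "BehaviorParams",
    "EggParams",
    "SurvivalDesign",
    "SurvivalParams",
    "FecundityParams",
    "gen_behavior",
    "gen_eggs",
    "gen_survival",
    "gen_fecundity",
]

TREATMENTS = ("reliable", "unreliable", "none")
DEFAULT_LINES = ("L1", "L2", "L3")


class InvalidDesignError(ValueError):
    """Raised when an experimental design is internally inconsistent."""


class InvalidParamsError(ValueError):
    """Raised when generator parameters are inadmissible (e.g. negative sd)."""


def _scale_unit(idx: np.ndarray, n: int) -> np.ndarray:
    """Map an integer index 1..n onto [-1, 1] (constant 0 when n == 1)."""
    if n <= 1:
        return np.zeros_like(idx, dtype=float)
    return (idx - (n + 1) / 2.0) / ((n - 1) / 2.0)


# ---------------------------------------------------------------------------
# behaviour + eggs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BehaviorDesign:
    """Dimensions of a behavioural-arena experiment.

    The default matches the first cue experiment: 44 trials, each running all
    three cue treatments on separate groups of 5 females, observed over 5 runs
    of 20 scans -> 44 x 3 x 5 x 5 x 20 = 66,000 female-observations.  The
    inbreeding-by-cue experiment is the same design with ``n_trials=18`` and
    ``cross_types=("inbred", "outbred")`` -> 27,000 observations.
    """

    n_trials: int = 44
    treatments: tuple[str, ...] = TREATMENTS
    females_per_group: int = 5
    runs: int = 5
    obs_per_run: int = 20
    lines: tuple[str, ...] = DEFAULT_LINES
    cross_types: tuple[str, ...] = ("outbred",)

    def validate(self) -> None:
        for name in ("n_trials", "females_per_group", "runs", "obs_per_run"):
            if getattr(self, name) < 1:
                raise InvalidDesignError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("treatments", "lines", "cross_types"):
            vals = getattr(self, name)
            if len(vals) < 1 or len(set(vals)) != len(vals):
                raise InvalidDesignError(f"{name} must be a non-empty set of unique labels")
        if len(self.cross_types) > 1 and self.n_trials % len(self.cross_types):
            raise InvalidDesignError(
                "n_trials must be divisible by the number of cross types"
            )

    @property
    def n_females(self) -> int:
        return self.n_trials * len(self.treatments) * self.females_per_group

    @property
    def n_observations(self) -> int:
        """Total observation-female count (females x runs x scans)."""
        return self.n_females * self.runs * self.obs_per_run

    @property
    def n_rows(self) -> int:
        """Arena-level rows: one per trial x treatment x run x scan."""
        return self.n_trials * len(self.treatments) * self.runs * self.obs_per_run

    def _trial_frame(self) -> pd.DataFrame:
        """Trial-level assignment of line and cross type (blocked by cross)."""
        trials = np.arange(1, self.n_trials + 1)
        k = len(self.cross_types)
        block = self.n_trials // k
        cross = np.repeat(np.asarray(self.cross_types, dtype=object), block)
        lines = np.asarray(self.lines, dtype=object)[(trials - 1) % len(self.lines)]
        return pd.DataFrame(
            {"trial_id": trials, "line_id": lines, "cross_type": cross}
        )


def _treat_map(d: Mapping[str, float], treatments: Sequence[str]) -> dict[str, float]:
    return {t: float(d.get(t, 0.0)) for t in treatments}


@dataclass
class BehaviorParams:
    """Logit-scale coefficients of the behavioural observation model.

    ``time`` and ``run`` coefficients apply to the index scaled to [-1, 1];
    ``(linear, quadratic)`` tuples.  Treatment-keyed dicts hold one offset per
    treatment (missing keys are 0).  ``inbred`` terms apply to the inbred
    cross type relative to outbred.
    """

    intercept: float = -1.2
    time: tuple[float, float] = (1.2, -0.30)
    run: tuple[float, float] = (0.8, -0.15)
    treatment: dict[str, float] = field(
        default_factory=lambda: {"reliable": 0.6, "none": 0.0, "unreliable": -0.4}
    )
    treatment_time: dict[str, float] = field(
        default_factory=lambda: {"reliable": 0.30, "none": 0.0, "unreliable": -0.10}
    )
    treatment_run: dict[str, float] = field(
        default_factory=lambda: {"reliable": 0.35, "none": 0.0, "unreliable": -0.10}
    )
    treatment_run_time: dict[str, float] = field(
        default_factory=lambda: {"reliable": 0.15, "none": 0.0, "unreliable": 0.0}
    )
    line: dict[str, float] = field(
        default_factory=lambda: {"L1": 0.0, "L2": 0.10, "L3": -0.10}
    )
    inbred: float = -0.5
    inbred_treatment: dict[str, float] = field(
        default_factory=lambda: {"reliable": 0.2, "none": 0.0, "unreliable": 0.0}
    )
    inbred_run: float = 0.2
    sd_trial: float = 0.30
    sd_trial_treatment: float = 0.30

    @classmethod
    def null(cls) -> "BehaviorParams":
        """All effects and random-effect sds zero (intercept 0): p = 0.5."""
        return cls(
            intercept=0.0, time=(0.0, 0.0), run=(0.0, 0.0),
            treatment={}, treatment_time={}, treatment_run={},
            treatment_run_time={}, line={}, inbred=0.0, inbred_treatment={},
            inbred_run=0.0, sd_trial=0.0, sd_trial_treatment=0.0,
        )

    def validate(self) -> None:
        if self.sd_trial < 0 or self.sd_trial_treatment < 0:
            raise InvalidParamsError("random-effect standard deviations must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


def _behavior_grid(design: BehaviorDesign) -> pd.DataFrame:
    trial_info = design._trial_frame()
    grid = pd.MultiIndex.from_product(
        [
            trial_info["trial_id"],
            list(design.treatments),
            np.arange(1, design.runs + 1),
            np.arange(1, design.obs_per_run + 1),
        ],
        names=["trial_id", "treatment", "run", "time_index"],
    ).to_frame(index=False)
    return grid.merge(trial_info, on="trial_id", how="left")


def _behavior_eta(
    design: BehaviorDesign, params: BehaviorParams, tab: pd.DataFrame,
    b_trial: np.ndarray, b_cell: np.ndarray,
) -> np.ndarray:
    t = _scale_unit(tab["time_index"].to_numpy(float), design.obs_per_run)
    r = _scale_unit(tab["run"].to_numpy(float), design.runs)
    treat = tab["treatment"].to_numpy(object)
    tr_main = _treat_map(params.treatment, design.treatments)
    tr_time = _treat_map(params.treatment_time, design.treatments)
    tr_run = _treat_map(params.treatment_run, design.treatments)
    tr_rt = _treat_map(params.treatment_run_time, design.treatments)
    line_eff = {ln: float(params.line.get(ln, 0.0)) for ln in design.lines}
    inb_tr = _treat_map(params.inbred_treatment, design.treatments)

    eta = (
        params.intercept
        + params.time[0] * t + params.time[1] * t**2
        + params.run[0] * r + params.run[1] * r**2
        + np.vectorize(tr_main.__getitem__)(treat).astype(float)
        + np.vectorize(tr_time.__getitem__)(treat).astype(float) * t
        + np.vectorize(tr_run.__getitem__)(treat).astype(float) * r
        + np.vectorize(tr_rt.__getitem__)(treat).astype(float) * r * t
        + tab["line_id"].map(line_eff).to_numpy(float)
    )
    inbred = (tab["cross_type"].to_numpy(object) == "inbred").astype(float)
    eta += inbred * (
        params.inbred
        + np.vectorize(inb_tr.__getitem__)(treat).astype(float)
        + params.inbred_run * r
    )
    trial_idx = tab["trial_id"].to_numpy(int) - 1
    treat_idx = np.array(
        [list(design.treatments).index(x) for x in treat], dtype=int
    )
    eta += b_trial[trial_idx]
    eta += b_cell[trial_idx * len(design.treatments) + treat_idx]
    return eta


def gen_behavior(
    design: BehaviorDesign, params: BehaviorParams, seed: int
) -> pd.DataFrame:
    """Simulate arena scans: one row per trial x treatment x run x scan.

    ``n_on_uninfested`` ~ Binomial(females_per_group, logit^-1(eta)) with eta
    built from the fixed effects in ``params`` plus trial and trial-by-
    treatment Gaussian random intercepts.
    """
    design.validate()
    params.validate()
    rng = np.random.default_rng(seed)
    b_trial = rng.normal(0.0, params.sd_trial, design.n_trials)
    b_cell = rng.normal(
        0.0, params.sd_trial_treatment, design.n_trials * len(design.treatments)
    )
    tab = _behavior_grid(design)
    eta = _behavior_eta(design, params, tab, b_trial, b_cell)
    p = 1.0 / (1.0 + np.exp(-eta))
    tab["n_on_uninfested"] = rng.binomial(design.females_per_group, p)
    tab["n_females"] = design.females_per_group
    cols = [
        "trial_id", "treatment", "line_id", "cross_type",
        "run", "time_index", "n_on_uninfested", "n_females",
    ]
    return tab[cols]


@dataclass
class EggParams:
    """Log-scale rates for egg placement per group x run.

    ``intercept_uninfested``/``intercept_infested`` are log expected counts
    for a reference (outbred, reference-line) group in the ``none`` treatment
    in the middle run.  ``max_eggs_per_female`` caps each count at
    ``max_eggs_per_female x group size`` (generator convenience against
    unrealistic Poisson tails).
    """

    intercept_uninfested: float = 2.3
    intercept_infested: float = 1.8
    treatment_uninfested: dict[str, float] = field(
        default_factory=lambda: {"reliable": 0.7, "none": 0.0, "unreliable": -0.5}
    )
    treatment_infested: dict[str, float] = field(
        default_factory=lambda: {"reliable": -0.8, "none": 0.0, "unreliable": 0.5}
    )
    run_uninfested: float = 0.3
    run_infested: float = -0.1
    inbred_uninfested: float = -0.5
    inbred_infested: float = 0.25
    inbred_treatment_uninfested: dict[str, float] = field(
        default_factory=lambda: {"reliable": 0.3, "none": 0.0, "unreliable": 0.1}
    )
    sd_trial: float = 0.20
    max_eggs_per_female: int = 20

    @classmethod
    def null(cls, rate: float = 1.0) -> "EggParams":
        """Equal uninfested/infested rates, no effects."""
        lograte = float(np.log(rate))
        return cls(
            intercept_uninfested=lograte, intercept_infested=lograte,
            treatment_uninfested={}, treatment_infested={},
            run_uninfested=0.0, run_infested=0.0,
            inbred_uninfested=0.0, inbred_infested=0.0,
            inbred_treatment_uninfested={}, sd_trial=0.0,
        )

    def validate(self) -> None:
        if self.sd_trial < 0:
            raise InvalidParamsError("sd_trial must be >= 0")
        if self.max_eggs_per_female < 1:
            raise InvalidParamsError("max_eggs_per_female must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def gen_eggs(design: BehaviorDesign, params: EggParams, seed: int) -> pd.DataFrame:
    """Simulate egg placement: one row per trial x run.

    Unlike the arena scans, each egg trial is a single group of five females
    in one cue treatment (treatments cycle across trials), so a 96-trial
    design represents 480 females.  Counts on uninfested and on infested
    seeds are independent Poisson draws with log-linear rates sharing a
    trial-level random intercept.
    """
    design.validate()
    params.validate()
    rng = np.random.default_rng(seed)
    trial_info = design._trial_frame()
    k = len(design.treatments)
    # treatments advance every len(lines) trials so that lines (which cycle
    # trial by trial) stay crossed with treatment
    stride = len(design.lines)
    trial_info["treatment"] = [
        design.treatments[((i - 1) // stride) % k] for i in trial_info["trial_id"]
    ]
    b_trial = rng.normal(0.0, params.sd_trial, design.n_trials)
    tab = pd.MultiIndex.from_product(
        [trial_info["trial_id"], np.arange(1, design.runs + 1)],
        names=["trial_id", "run"],
    ).to_frame(index=False).merge(trial_info, on="trial_id", how="left")

    r = _scale_unit(tab["run"].to_numpy(float), design.runs)
    treat = tab["treatment"].to_numpy(object)
    inbred = (tab["cross_type"].to_numpy(object) == "inbred").astype(float)
    tr_u = _treat_map(params.treatment_uninfested, design.treatments)
    tr_i = _treat_map(params.treatment_infested, design.treatments)
    inb_tr_u = _treat_map(params.inbred_treatment_uninfested, design.treatments)
    b = b_trial[tab["trial_id"].to_numpy(int) - 1]

    log_mu_u = (
        params.intercept_uninfested
        + np.vectorize(tr_u.__getitem__)(treat).astype(float)
        + params.run_uninfested * r
        + inbred * (
            params.inbred_uninfested
            + np.vectorize(inb_tr_u.__getitem__)(treat).astype(float)
        )
        + b
    )
    log_mu_i = (
        params.intercept_infested
        + np.vectorize(tr_i.__getitem__)(treat).astype(float)
        + params.run_infested * r
        + inbred * params.inbred_infested
        + b
    )
    cap = params.max_eggs_per_female * design.females_per_group
    tab["eggs_uninfested"] = np.minimum(rng.poisson(np.exp(log_mu_u)), cap)
    tab["eggs_infested"] = np.minimum(rng.poisson(np.exp(log_mu_i)), cap)
    cols = [
        "trial_id", "treatment", "line_id", "cross_type",
        "run", "eggs_uninfested", "eggs_infested",
    ]
    return tab[cols]


# ---------------------------------------------------------------------------
# larval survival
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurvivalDesign:
    """Larval-competition experiment: duos of females per cell of
    line x cross type x pre-infestation level x replicate block.

    Defaults give 3 x 2 x 5 x 2 = 60 duos sharing 2,450 beans.
    """

    lines: tuple[str, ...] = DEFAULT_LINES
    cross_types: tuple[str, ...] = ("inbred", "outbred")
    infestation_levels: tuple[int, ...] = (0, 1, 2, 3, 4)
    replicates: int = 2
    beans_total: int = 2450

    def validate(self) -> None:
        if self.replicates < 1:
            raise InvalidDesignError("replicates must be >= 1")
        if min(self.infestation_levels) < 0:
            raise InvalidDesignError("infestation levels must be >= 0")
        if self.beans_total < self.n_duos:
            raise InvalidDesignError("beans_total must be >= number of duos")

    @property
    def n_duos(self) -> int:
        return (
            len(self.lines) * len(self.cross_types)
            * len(self.infestation_levels) * self.replicates
        )


@dataclass
class SurvivalParams:
    """Logit-scale emergence model and the focal egg-count distribution.

    ``egg_count_probs`` gives P(number of focal eggs on a bean); the default
    is concentrated on one egg with three eggs rare and a small tail beyond
    three (the prep stage discards beans with more than three focal eggs).
    Competition experienced by a focal egg is C = n_focal + n_competitor - 1.
    """

    intercept: float = 1.9
    inbred: float = -1.1
    competition: float = -0.35
    inbred_competition: float = -0.25
    sd_duo: float = 0.30
    egg_count_probs: dict[int, float] = field(
        default_factory=lambda: {0: 0.12, 1: 0.555, 2: 0.25, 3: 0.072,
                                 4: 0.0025, 5: 0.0005}
    )

    def validate(self) -> None:
        if self.sd_duo < 0:
            raise InvalidParamsError("sd_duo must be >= 0")
        probs = np.array(list(self.egg_count_probs.values()), dtype=float)
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise InvalidParamsError("egg_count_probs must be a probability vector")
        if min(self.egg_count_probs) < 0:
            raise InvalidParamsError("egg counts must be >= 0")

    def viability(self, inbred: bool, c: float) -> float:
        """Conditional (random effects at zero) emergence probability."""
        eta = self.intercept + self.competition * c
        if inbred:
            eta += self.inbred + self.inbred_competition * c
        return float(1.0 / (1.0 + np.exp(-eta)))

    def to_dict(self) -> dict:
        return asdict(self)


def gen_survival(
    design: SurvivalDesign, params: SurvivalParams, seed: int
) -> pd.DataFrame:
    """Simulate bean-level emergence: one row per bean.

    Beans are divided as evenly as possible across duos; each bean of a duo
    carries that duo's pre-laid competitor-egg level, a focal egg count drawn
    from ``egg_count_probs``, and a binomial emergence count with logit-linear
    probability in (inbreeding, competition, interaction) plus a duo-level
    random intercept.
    """
    design.validate()
    params.validate()
    rng = np.random.default_rng(seed)

    cells = pd.MultiIndex.from_product(
        [
            design.lines, design.cross_types,
            design.infestation_levels, np.arange(1, design.replicates + 1),
        ],
        names=["line_id", "cross_type", "n_competitor_eggs", "replicate"],
    ).to_frame(index=False)
    cells["duo_id"] = np.arange(1, len(cells) + 1)
    base, extra = divmod(design.beans_total, len(cells))
    beans_per_duo = np.full(len(cells), base, dtype=int)
    beans_per_duo[:extra] += 1

    tab = cells.loc[cells.index.repeat(beans_per_duo)].reset_index(drop=True)
    counts = np.array(sorted(params.egg_count_probs), dtype=int)
    probs = np.array([params.egg_count_probs[k] for k in counts], dtype=float)
    tab["n_focal_eggs"] = rng.choice(counts, size=len(tab), p=probs)

    b_duo = rng.normal(0.0, params.sd_duo, len(cells))
    inbred = (tab["cross_type"].to_numpy(object) == "inbred").astype(float)
    c = (
        tab["n_focal_eggs"].to_numpy(float)
        + tab["n_competitor_eggs"].to_numpy(float) - 1.0
    ).clip(min=0.0)
    eta = (
        params.intercept
        + params.inbred * inbred
        + params.competition * c
        + params.inbred_competition * inbred * c
        + b_duo[tab["duo_id"].to_numpy(int) - 1]
    )
    p = 1.0 / (1.0 + np.exp(-eta))
    tab["n_focal_emerged"] = rng.binomial(tab["n_focal_eggs"].to_numpy(int), p)
    cols = [
        "duo_id", "line_id", "cross_type",
        "n_focal_eggs", "n_competitor_eggs", "n_focal_emerged",
    ]
    return tab[cols]


# ---------------------------------------------------------------------------
# fecundity
# ---------------------------------------------------------------------------

@dataclass
class FecundityParams:
    """Negative-binomial hatched-egg counts by cross.

    Inbred-line means are ``outbred_mean x (1 - inbred_reduction)``; the
    default reduction of 0.575 mirrors a 55-60% fecundity drop on inbreeding.
    ``dispersion`` is the negative-binomial size parameter (larger = closer
    to Poisson).
    """

    outbred_mean: float = 60.0
    stock_mean: float = 60.0
    inbred_reduction: float = 0.575
    dispersion: float = 15.0
    line_effects: dict[str, float] = field(
        default_factory=lambda: {"L1": 1.0, "L2": 1.05, "L3": 0.95}
    )

    def validate(self) -> None:
        if not (0.0 <= self.inbred_reduction < 1.0):
            raise InvalidParamsError("inbred_reduction must be in [0, 1)")
        if self.outbred_mean <= 0 or self.stock_mean <= 0 or self.dispersion <= 0:
            raise InvalidParamsError("means and dispersion must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


def gen_fecundity(
    n_per_cross: int, params: FecundityParams, seed: int,
    lines: Sequence[str] = DEFAULT_LINES,
) -> pd.DataFrame:
    """Simulate hatched-egg counts for 2 x len(lines) crosses plus stock.

    With ``n_per_cross=15`` and the default three lines this yields 105 rows
    (15 females x 7 cross labels).
    """
    if n_per_cross < 1:
        raise InvalidDesignError("n_per_cross must be >= 1")
    params.validate()
    rng = np.random.default_rng(seed)
    labels, means = [], []
    for i, ln in enumerate(lines, start=1):
        mult = float(params.line_effects.get(ln, 1.0))
        labels.append(f"line{i}-inbred")
        means.append(params.outbred_mean * mult * (1.0 - params.inbred_reduction))
        labels.append(f"cross{i}-outbred")
        means.append(params.outbred_mean * mult)
    labels.append("stock")
    means.append(params.stock_mean)

    rows = []
    fid = 0
    k = params.dispersion
    for label, mu in zip(labels, means):
        p = k / (k + mu)
        counts = rng.negative_binomial(k, p, n_per_cross)
        for cnt in counts:
            fid += 1
            rows.append((fid, label, int(cnt)))
    return pd.DataFrame(rows, columns=["female_id", "cross_label", "hatched_eggs"])
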