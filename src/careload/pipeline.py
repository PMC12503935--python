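"""End-to-end orchestration: simulate -> fit -> posterior -> selection -> load.

``run_pipeline`` executes the stages in dependency order, derives every
stream of randomness from the single configured seed via
``numpy.random.SeedSequence`` spawning (stage order is fixed, so identical
config + seed gives byte-identical outputs), and writes CSV datasets, JSON
fit summaries, posterior draw CSVs, a selection report, the load-curve
table, and a run report with a file manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as cio
from . import simulate as sim
from .glmm import FitOptions, ModelSpec, fit_glmm, lr_test
from .load_model import LoadModelParams, DEFAULT_SCENARIOS, load_curve
from .mcmc import McmcOptions, PriorSpec, sample_posterior, summarize
from .selection import (care_survival_ellipse, delta_omega_posterior,
                        genotype_means, inbreeding_depression,
                        treatment_selection)

__all__ = [
    "PipelineConfig",
    "RunReport",
    "behavior_spec",
    "survival_spec",
    "egg_count_spec",
    "egg_fraction_spec",
    "run_pipeline",
]

log = logging.getLogger("careload")


# ---------------------------------------------------------------------------
# canonical model specifications
# ---------------------------------------------------------------------------

def behavior_spec(inbreeding: bool = False) -> ModelSpec:
    """Binomial model for arena counts.

    Degree-2 polynomials in scan time and run, cue-treatment interactions
    with both, a treatment x run x time three-way term (linear run by
    quadratic time, 4 columns), line as fixed effect, and trial plus
    trial-by-treatment random intercepts.  The inbreeding variant adds
    cross type and its treatment and run interactions.
    """
    fixed = [
        "poly(time_index,2)", "poly(run,2)", "treatment", "line_id",
        "treatment:poly(time_index,2)", "treatment:poly(run,2)",
        "treatment:run:poly(time_index,2)",
    ]
    if inbreeding:
        fixed += ["cross_type", "cross_type:treatment", "cross_type:poly(run,2)"]
    return ModelSpec(family="binomial", response="n_on_uninfested",
                     fixed=tuple(fixed), random=("trial_id", "trial_id:treatment"),
                     trials="n_females")


def survival_spec() -> ModelSpec:
    """Binomial emergence model: inbreeding x competition with duo
    random intercepts (fit on the prepared bean table carrying C)."""
    return ModelSpec(family="binomial", response="n_focal_emerged",
                     fixed=("cross_type", "C", "cross_type:C"),
                     random=("duo_id",), trials="n_focal_eggs")


def egg_count_spec(response: str, crossed: bool = False) -> ModelSpec:
    """Poisson model for per-run egg counts on one seed class."""
    fixed = ["treatment"]
    if crossed:
        fixed += ["cross_type", "treatment:cross_type"]
    return ModelSpec(family="poisson", response=response, fixed=tuple(fixed),
                     random=("trial_id",))


def egg_fraction_spec() -> ModelSpec:
    """Binomial model for the end-of-trial fraction of eggs on uninfested
    seeds (needs a computed column eggs_total)."""
    return ModelSpec(family="binomial", response="eggs_uninfested",
                     fixed=("treatment", "line_id"), random=("trial_id",),
                     trials="eggs_total")


def egg_run_spec() -> ModelSpec:
    """Poisson model for eggs on uninfested hosts per run: cue, run, and
    their interaction, with trial random intercepts."""
    return ModelSpec(family="poisson", response="eggs_uninfested",
                     fixed=("treatment", "run", "treatment:run"),
                     random=("trial_id",))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML or JSON.

    Dataset sizes default to the experimental design dimensions; the
    ``demo`` constructor scales them down for quick desk runs.  Existing
    CSV paths may be supplied instead of generation switches.
    """

    seed: int = 1
    out_dir: str = "careload_run"

    # generation switches (None -> generate; else path to an existing CSV)
    behavior_path: str | None = None
    eggs_path: str | None = None
    beans_path: str | None = None
    fecundity_path: str | None = None

    behavior_n_trials: int = 44
    egg_n_trials: int = 96
    inbreeding_egg_n_trials: int = 54
    beans_total: int = 2450
    survival_replicates: int = 2
    fecundity_n_per_cross: int = 15

    fit_behavior: bool = True
    n_nodes: int = 15

    mcmc_iterations: int = 100_000
    mcmc_burn_in: int = 50_000
    mcmc_thin: int = 100

    c_levels: tuple[float, ...] = (0.0, 6.0)
    load_scenarios: tuple[tuple[float, float], ...] = DEFAULT_SCENARIOS
    bootstrap_resamples: int = 2000
    quiet: bool = False

    @classmethod
    def demo(cls, seed: int = 1, out_dir: str = "careload_demo") -> "PipelineConfig":
        """Desk-scale configuration: reduced designs and a shorter chain."""
        return cls(seed=seed, out_dir=out_dir,
                   behavior_n_trials=12, egg_n_trials=24,
                   inbreeding_egg_n_trials=18, beans_total=900,
                   mcmc_iterations=20_000, mcmc_burn_in=10_000, mcmc_thin=20,
                   n_nodes=9, bootstrap_resamples=500)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError("config file must hold a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.c_levels = tuple(float(c) for c in cfg.c_levels)
        cfg.load_scenarios = tuple((float(u), float(b))
                                   for u, b in cfg.load_scenarios)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["c_levels"] = list(self.c_levels)
        d["load_scenarios"] = [list(s) for s in self.load_scenarios]
        return d


@dataclass
class RunReport:
    seed: int
    version: str
    config: dict
    row_counts: dict
    filters: dict
    estimates: dict
    manifest: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _spawn_seeds(root_seed: int, n: int) -> list[int]:
    """Deterministic child seeds below 2**31 from one root seed."""
    children = np.random.SeedSequence(root_seed).spawn(n)
    return [int(c.generate_state(1, np.uint64)[0] % (2**31)) for c in children]

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage; returns the report (also written to report.json)."""
    if config.quiet:
        log.setLevel(logging.WARNING)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _spawn_seeds(config.seed, 12)
    manifest_paths: list[Path] = []
    row_counts: dict = {}
    estimates: dict = {}
    filters: dict = {}

    mcmc_base = dict(n_iterations=config.mcmc_iterations,
                     burn_in=config.mcmc_burn_in, thin=config.mcmc_thin)

    # --- stage 1: simulate / load datasets -------------------------------
    log.info("stage simulate: generating datasets (seed=%d)", config.seed)
    stage = "simulate"
    try:
        if config.behavior_path:
            behavior = cio.read_table(config.behavior_path, cio.BEHAVIOR_SCHEMA)
        else:
            design1 = sim.BehaviorDesign(n_trials=config.behavior_n_trials)
            behavior = sim.gen_behavior(design1, sim.BehaviorParams(), seeds[0])
        egg_design = sim.BehaviorDesign(
            n_trials=config.inbreeding_egg_n_trials,
            cross_types=("inbred", "outbred"))
        if config.eggs_path:
            eggs = cio.read_table(config.eggs_path, cio.EGG_SCHEMA)
        else:
            eggs = sim.gen_eggs(egg_design, sim.EggParams(), seeds[1])
        choice_design = sim.BehaviorDesign(n_trials=config.egg_n_trials)
        eggs_choice = sim.gen_eggs(choice_design, sim.EggParams(), seeds[8])
        if config.beans_path:
            beans = cio.read_table(config.beans_path, cio.BEAN_SCHEMA)
        else:
            sdesign = sim.SurvivalDesign(beans_total=config.beans_total,
                                         replicates=config.survival_replicates)
            beans = sim.gen_survival(sdesign, sim.SurvivalParams(), seeds[2])
        if config.fecundity_path:
            fecundity = cio.read_table(config.fecundity_path, cio.FECUNDITY_SCHEMA)
        else:
            fecundity = sim.gen_fecundity(config.fecundity_n_per_cross,
                                          sim.FecundityParams(), seeds[3])

        for name, df, schema in [
            ("behavior", behavior, cio.BEHAVIOR_SCHEMA),
            ("eggs", eggs, cio.EGG_SCHEMA),
            ("eggs_choice", eggs_choice, cio.EGG_SCHEMA),
            ("beans", beans, cio.BEAN_SCHEMA),
            ("fecundity", fecundity, cio.FECUNDITY_SCHEMA),
        ]:
            p = out / "data" / f"{name}.csv"
            cio.write_table(df, p, schema)
            manifest_paths.append(p)
            row_counts[name] = int(len(df))

        # --- stage 2: data preparation -----------------------------------
        stage = "prepare"
        survival_tab, filter_log = cio.prepare_survival(beans)
        filters["survival"] = filter_log
        row_counts["beans_prepared"] = int(len(survival_tab))

        # --- stage 3: frequentist fits -----------------------------------
        stage = "fit"
        opts = FitOptions(n_nodes=config.n_nodes)
        fits_json: dict = {}

        surv_fit = fit_glmm(survival_spec(), survival_tab, opts)
        fits_json["survival"] = surv_fit.to_dict()
        lrts = {}
        full = surv_fit
        for term, label in [("C", "competition"), ("cross_type", "inbreeding"),
                            ("cross_type:C", "inbreeding_x_competition")]:
            red = fit_glmm(survival_spec().drop_terms([term]), survival_tab, opts)
            t = lr_test(full, red)
            lrts[label] = {"chi2": t.statistic, "df": t.df, "p": t.p_value}
        fits_json["survival_lrt"] = lrts
        estimates["survival_lrt"] = lrts

        # end-of-trial egg choice: fraction on uninfested (binomial) and
        # eggs on uninfested hosts per run (Poisson), cue tested by LRT
        choice_tot = (eggs_choice.groupby(
            ["trial_id", "treatment", "line_id", "cross_type"], sort=True)
            [["eggs_uninfested", "eggs_infested"]].sum().reset_index())
        choice_tot["eggs_total"] = (choice_tot["eggs_uninfested"]
                                    + choice_tot["eggs_infested"])
        choice_tot = choice_tot[choice_tot["eggs_total"] > 0]
        frac_full = fit_glmm(egg_fraction_spec(), choice_tot, opts)
        frac_red = fit_glmm(egg_fraction_spec().drop_terms(["treatment"]),
                            choice_tot, opts)
        t = lr_test(frac_full, frac_red)
        egg_lrts = {"fraction_treatment":
                    {"chi2": t.statistic, "df": t.df, "p": t.p_value}}
        run_full = fit_glmm(egg_run_spec(), eggs_choice, opts)
        run_red = fit_glmm(egg_run_spec().drop_terms(["treatment"]),
                           eggs_choice, opts)
        t = lr_test(run_full, run_red)
        egg_lrts["count_treatment"] = {"chi2": t.statistic, "df": t.df,
                                       "p": t.p_value}
        fits_json["egg_choice_lrt"] = egg_lrts
        estimates["egg_choice_lrt"] = egg_lrts

        if config.fit_behavior:
            log.info("stage fit: behavioural mixed model "
                     "(%d rows)", len(behavior))
            bspec = behavior_spec()
            bfit = fit_glmm(bspec, behavior, opts)
            fits_json["behavior"] = bfit.to_dict()
            blrts = {}
            for term, label in [
                ("treatment", "treatment"),
                ("treatment:poly(run,2)", "treatment_x_run"),
                ("treatment:run:poly(time_index,2)", "treatment_x_run_x_time"),
            ]:
                red = fit_glmm(bspec.drop_terms([term]), behavior, opts)
                t = lr_test(bfit, red)
                blrts[label] = {"chi2": t.statistic, "df": t.df, "p": t.p_value}
            fits_json["behavior_lrt"] = blrts
            estimates["behavior_lrt"] = blrts

        p = out / "fits" / "fits.json"
        _write_json(fits_json, p)
        manifest_paths.append(p)

        # --- stage 4: posterior sampling ---------------------------------
        stage = "posterior"
        log.info("stage posterior: survival and egg models")
        surv_draws = sample_posterior(
            survival_spec(), survival_tab,
            McmcOptions(seed=seeds[4], **mcmc_base))
        eggs_u_draws = sample_posterior(
            egg_count_spec("eggs_uninfested", crossed=True), eggs,
            McmcOptions(seed=seeds[5], **mcmc_base))
        eggs_i_draws = sample_posterior(
            egg_count_spec("eggs_infested", crossed=True), eggs,
            McmcOptions(seed=seeds[6], **mcmc_base))
        for name, dr in [("survival", surv_draws),
                         ("eggs_uninfested", eggs_u_draws),
                         ("eggs_infested", eggs_i_draws)]:
            p = out / "posterior" / f"{name}_draws.csv"
            p.parent.mkdir(parents=True, exist_ok=True)
            dr.to_csv(p)
            manifest_paths.append(p)

        # --- stage 5: selection estimates --------------------------------
        stage = "selection"
        log.info("stage selection: delta-omega, s per treatment, IGEs")
        sel_report: dict = {"delta_omega": {}}
        for c in config.c_levels:
            est = delta_omega_posterior(surv_draws, c)
            sel_report["delta_omega"][f"C={c:g}"] = est.to_dict()
        tsel = treatment_selection(eggs_u_draws, eggs_i_draws, surv_draws)
        sel_report["treatment_selection"] = tsel.to_dict()

        depr = inbreeding_depression(fecundity, config.bootstrap_resamples,
                                     seed=seeds[7])
        sel_report["inbreeding_depression"] = depr.to_dict(orient="records")

        gmeans = genotype_means(eggs, surv_draws)
        iges = {}
        for treat, grp in gmeans.groupby("treatment"):
            ell = care_survival_ellipse(grp)
            iges[str(treat)] = {
                "covariance": [[float(x) for x in row] for row in ell.cov],
                "care_survival_cov": float(ell.cov[0, 1]),
                "center": [float(c) for c in ell.center],
                "semi_axes": [float(a) for a in ell.semi_axes],
                "angle": float(ell.angle),
                "degenerate": bool(ell.degenerate),
            }
        sel_report["ige"] = iges

        p = out / "selection" / "selection_report.json"
        _write_json(sel_report, p)
        manifest_paths.append(p)
        estimates["delta_omega"] = sel_report["delta_omega"]
        estimates["s_per_treatment"] = {
            k: v.to_dict() for k, v in tsel.per_treatment.items()}
        estimates["s_contrasts"] = {
            k: v.to_dict() for k, v in tsel.contrasts.items()}
        estimates["pmcmc"] = dict(tsel.pmcmc)
        estimates["inbreeding_depression_overall"] = float(
            depr.loc[depr["line"] == "overall", "reduction"].iloc[0])
        estimates["ige_covariance"] = {
            k: v["care_survival_cov"] for k, v in iges.items()}

        # --- stage 6: load curves ----------------------------------------
        stage = "load"
        s_rel = tsel.per_treatment["reliable"].mean
        s_none = tsel.per_treatment["none"].mean
        lparams = LoadModelParams(s_j=max(s_rel, 1e-6), s_k=max(s_none, 1e-6))
        curve = load_curve(lparams, scenarios=config.load_scenarios)
        p = out / "load_curve.csv"
        curve.to_csv(p, index=False)
        manifest_paths.append(p)
        estimates["load_model"] = {
            "s_j": lparams.s_j, "s_k": lparams.s_k,
            "s_ratio": lparams.s_k / lparams.s_j,
            "L_k_at_pj_0.5_U2_B1.96": float(
                curve.query("U == 2 and B_ratio == 1.96 and abs(p_j-0.5) < 1e-9")
                ["L_k"].iloc[0]),
        }
    except Exception as err:
        partial = {"failed_stage": stage, "error": str(err),
                   "files": [str(p.relative_to(out)) for p in manifest_paths]}
        _write_json(partial, out / "partial_manifest.json")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err

    # --- report ----------------------------------------------------------
    report = RunReport(
        seed=config.seed, version=__version__, config=config.to_dict(),
        row_counts=row_counts, filters=filters, estimates=estimates)
    report.manifest = {
        str(p.relative_to(out)): _sha256(p) for p in manifest_paths}
    _write_json(report.to_dict(), out / "report.json")
    log.info("pipeline complete: %s", out / "report.json")
    return report
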