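"""Orchestration: synthesize/load data, fit per-SB-dose posteriors, z-tests,
activation curves and inhibition-failure scenarios.

Every entry point takes a config dict (see :mod:`meththerm.config`) and an
optional output directory; all randomness descends from one root seed so a
re-run with the same config reproduces every output file.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .circuit import CircuitParams, activation_curve
from .config import DEFAULTS, config_hash, load_config
from .inference import (
    FixedModel,
    MCMCSettings,
    ParamVectorW,
    PosteriorEnsemble,
    TemperatureSeries,
    compare_groups,
    mcmc_sample,
)
from .pharmacokinetics import InjectionSchedule, PKParams, meth_concentration
from .synthetic_data import DesignSpec, NoiseSpec, generate_study
from .thermodynamics import TemperatureTrajectory, ThermoParams, simulate_temperature

__all__ = [
    "ScenarioSpec",
    "FitReport",
    "DEFAULT_FAILURE_CIRCUIT",
    "run_fit",
    "run_inhibition_failure",
    "run_activation_curves",
    "build_fixed_model",
    "build_design",
    "build_noise",
]

logger = logging.getLogger("meththerm")

W_NAMES = ("w_S", "w_Exc", "w_Inh", "w_HD")


# -- config -> domain objects ------------------------------------------------

def build_fixed_model(cfg: Mapping | None = None) -> FixedModel:
    cfg = cfg or DEFAULTS
    pk = PKParams(**{k: cfg["pk"][k] for k in ("tau_u", "tau_d", "tau_s")})
    circ_cfg = dict(cfg["circuit"])
    circ = CircuitParams(
        w_S=circ_cfg["w_S"], w_Exc=circ_cfg["w_Exc"],
        w_Inh=circ_cfg["w_Inh"], w_HD=circ_cfg["w_HD"],
        gamma_Exc=circ_cfg["gamma_Exc"], gamma_Inh=circ_cfg["gamma_Inh"],
        gamma_HD=circ_cfg["gamma_HD"], gamma_SPN=circ_cfg["gamma_SPN"],
        w_Exc_Med=circ_cfg["w_Exc_Med"], w_Inh_Med=circ_cfg["w_Inh_Med"],
        w_HD_SPN=circ_cfg["w_HD_SPN"], variant=circ_cfg["variant"],
        w_Inh_HD=circ_cfg["w_Inh_HD"], inhib_cap=circ_cfg["inhib_cap"],
        raw_gamma_spn=circ_cfg["raw_gamma_spn"],
    )
    thermo = ThermoParams(tau_T=cfg["thermo"]["tau_T"], T0=cfg["thermo"]["T0"])
    return FixedModel(pk=pk, circuit=circ, thermo=thermo, dt=cfg["thermo"]["dt"])


def build_design(cfg: Mapping | None = None) -> DesignSpec:
    s = (cfg or DEFAULTS)["synth"]
    return DesignSpec(
        sb_doses=tuple(float(x) for x in s["sb_doses"]),
        meth_doses=tuple(float(x) for x in s["meth_doses"]),
        n_per_group=s["n_per_group"], t_start=s["t_start"], t_end=s["t_end"],
        dt_sample=s["dt_sample"], pretreat_time=s["pretreat_time"],
        meth_time=s["meth_time"],
        baseline=(cfg or DEFAULTS)["thermo"]["T0"],
    )


def build_noise(cfg: Mapping | None = None, seed: int | None = None) -> NoiseSpec:
    s = (cfg or DEFAULTS)["synth"]
    return NoiseSpec(noise_sd=s["noise_sd"], ar1=s["ar1"],
                     baseline_sd=s["baseline_sd"], seed=seed)


def build_scenario(cfg: Mapping | None = None) -> dict[float, ParamVectorW]:
    s = (cfg or DEFAULTS)["synth"]["scenario"]
    return {float(sb): ParamVectorW(**w) for sb, w in s.items()}


# -- fitting -----------------------------------------------------------------

@dataclass
class FitReport:
    """Per-SB-dose posterior ensembles, summary table and z-test table."""

    ensembles: dict[float, PosteriorEnsemble]
    summary: pd.DataFrame
    ztests: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sb, ens in self.ensembles.items():
            ens.to_dataframe().to_csv(out / f"ensemble_sb{sb:g}.csv", index=False)
        self.summary.to_csv(out / "summary.csv", index=False)
        self.ztests.to_csv(out / "ztests.csv", index=False)


def _sb_label(sb: float) -> str:
    return "vehicle" if sb == 0 else f"SB{sb:g}"


def run_fit(config: Mapping | None = None,
            data: Sequence[TemperatureSeries] | None = None,
            seed: int | None = None,
            init: Mapping[str, float] | None = None,
            out_dir: str | Path | None = None) -> FitReport:
    """Fit one posterior ensemble per SB dose and z-test all pairwise contrasts.

    ``data`` defaults to a synthetic study generated from the config's
    scenario truths.  Each SB dose's Meth-dose groups are fit jointly over
    (w_S, w_Exc, w_Inh, w_HD); vehicle/SB10/SB30 fits are independent.
    """
    cfg = load_config(overrides=config) if config is not None else load_config()
    t0 = time.perf_counter()
    fixed = build_fixed_model(cfg)
    mcmc_cfg = cfg["mcmc"]
    root_seed = seed if seed is not None else mcmc_cfg["seed"]
    logger.info("run_fit config=%s seed=%s", config_hash(cfg), root_seed)

    if data is None:
        noise = build_noise(cfg, seed=root_seed)
        groups = generate_study(build_scenario(cfg), build_design(cfg), noise,
                                seed=root_seed)
        data = list(groups.values())

    sb_doses = sorted({s.sb_dose for s in data})
    ensembles: dict[float, PosteriorEnsemble] = {}
    for i, sb in enumerate(sb_doses):
        sb_data = [s for s in data if s.sb_dose == sb]
        start = dict(init) if init is not None else {
            "w_S": 1.0, "w_Exc": 1.0, "w_Inh": 0.5, "w_HD": 0.5}
        settings = MCMCSettings(
            n_steps=mcmc_cfg["n_steps"], burn_in=mcmc_cfg["burn_in"],
            thin=mcmc_cfg["thin"], seed=root_seed + 101 * (i + 1),
        )
        ens = mcmc_sample(sb_data, fixed, start, settings, label=_sb_label(sb))
        logger.info("fit %s: acceptance %.3f, %d samples",
                    ens.label, ens.acceptance_rate, len(ens.samples))
        ensembles[sb] = ens

    summary = pd.concat([e.summary() for e in ensembles.values()],
                        ignore_index=True)
    rows = []
    for a in range(len(sb_doses)):
        for b in range(a + 1, len(sb_doses)):
            e1, e2 = ensembles[sb_doses[a]], ensembles[sb_doses[b]]
            for name in e1.names:
                r = compare_groups(e1, e2, name)
                rows.append({
                    "parameter": name, "group1": r.group_pair[0],
                    "group2": r.group_pair[1], "z": r.z,
                    "p_value": r.p_value, "significant": r.significant,
                })
    ztests = pd.DataFrame(rows)
    report = FitReport(ensembles=ensembles, summary=summary, ztests=ztests)
    if out_dir is not None:
        report.write(out_dir)
    logger.info("run_fit done in %.1f s", time.perf_counter() - t0)
    return report


# -- scenario simulations ----------------------------------------------------

@dataclass(frozen=True)
class ScenarioSpec:
    """Inhibition-failure scenario: Meth dose and Inhib activity ceilings."""

    meth_dose: float = 3.0
    fractions: tuple[float, ...] = (1.0, 0.5, 0.0)
    variant: str = "extended"
    t_grid: np.ndarray = field(
        default_factory=lambda: np.arange(-50.0, 180.0 + 1.0, 2.0))

    def __post_init__(self) -> None:
        fr = np.asarray(self.fractions, float)
        if np.any(fr < 0) or np.any(fr > 1):
            raise ValueError("inhibition fractions must lie in [0, 1]")
        if not (fr[0] == 1.0 and np.all(np.diff(fr) <= 0)):
            raise ValueError("fractions must be sorted descending from 1.0")


#: Vehicle-like parametrization for the extended (Inhib->HD) circuit used by
#: the inhibition-failure scenario: the inhibitory node tracks the
#: excitatory one closely enough that an intact circuit shows only a minor
#: response to 3 mg/kg, while capping Inhib uncovers strong hyperthermia.
DEFAULT_FAILURE_CIRCUIT = CircuitParams(variant="extended", w_Inh=1.5)


def run_inhibition_failure(scenario: ScenarioSpec = ScenarioSpec(),
                           fixed: FixedModel | None = None,
                           ) -> tuple[dict[float, TemperatureTrajectory],
                                      pd.DataFrame]:
    """Temperature trajectories per Inhib activity ceiling, plus peak summary.

    The ceiling is a hard cap on the Inhib node's activity (1.0 = intact,
    0.0 = silenced); disinhibition of both Med and, under the extended
    variant, HD drives the hyperthermic response to an otherwise mild dose.
    """
    fixed = fixed or FixedModel(circuit=DEFAULT_FAILURE_CIRCUIT)
    circ = replace(fixed.circuit, variant=scenario.variant)
    schedule = InjectionSchedule(meth_dose=scenario.meth_dose)
    trajs: dict[float, TemperatureTrajectory] = {}
    rows = []
    for frac in scenario.fractions:
        capped = replace(circ, inhib_cap=float(frac))
        traj = simulate_temperature(schedule, capped, fixed.pk, fixed.thermo,
                                    scenario.t_grid, dt=fixed.dt)
        trajs[float(frac)] = traj
        k = int(np.argmax(traj.temp))
        rows.append({"fraction": frac, "peak_temp_c": float(traj.temp[k]),
                     "peak_time_min": float(traj.times[k])})
    return trajs, pd.DataFrame(rows)


def run_activation_curves(params_by_label: Mapping[str, CircuitParams] | None = None,
                          conc_grid=None,
                          pk: PKParams | None = None,
                          meth_doses: Sequence[float] = (1.0, 5.0, 10.0),
                          t_grid=None,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node activation curves over a concentration grid, per parameter set,
    plus blood-concentration time courses for the study's Meth doses.
    """
    if params_by_label is None:
        params_by_label = {
            _sb_label(sb): replace(CircuitParams(), **w.as_dict())
            for sb, w in build_scenario().items()
        }
    conc_grid = np.linspace(0.0, 10.0, 201) if conc_grid is None else \
        np.asarray(conc_grid, float)
    rows = []
    for label, params in params_by_label.items():
        for node in ("Exc", "Inh", "HD", "SPN"):
            act = activation_curve(node, conc_grid, params)
            rows.extend(
                {"label": label, "node": node, "conc_mg_kg": c, "activity": a}
                for c, a in zip(conc_grid, act)
            )
    curves = pd.DataFrame(rows)
    pk = pk or PKParams()
    t_grid = np.arange(0.0, 180.0 + 1.0, 1.0) if t_grid is None else \
        np.asarray(t_grid, float)
    conc_rows = []
    for dose in meth_doses:
        conc = meth_concentration(t_grid, dose, pk)
        conc_rows.extend(
            {"dose_mg_kg": dose, "time_min": t, "conc_mg_kg": c}
            for t, c in zip(t_grid, conc)
        )
    return curves, pd.DataFrame(conc_rows)
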