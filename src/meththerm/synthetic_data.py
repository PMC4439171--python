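"""Synthetic per-animal and group temperature datasets.

Emulates the telemetry study design: two pretreatment series (vehicle,
SB 10, SB 30 mg/kg at t = -30 min) crossed with treatment (saline or
Meth 1/5/10 mg/kg at t = 0), n = 6-8 animals per group, samples every
2 minutes from -50 to 180 min, baseline near 37 degC.

Each animal is the noiseless model trajectory for the scenario's generating
parameters plus (i) a per-animal constant baseline offset and (ii) AR(1)
Gaussian noise (innovation SD ``noise_sd``, lag-1 coefficient ``ar1``,
started from its stationary distribution).  AR(1) noise mimics the smooth
residuals of telemetric temperature; setting ``ar1 = 0`` and
``baseline_sd = 0`` yields the iid-Gaussian noise the inference likelihood
assumes exactly.  Group mean and SD are the empirical statistics across
animals, which is what the inference module consumes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .circuit import CircuitParams
from .inference import ParamVectorW, TemperatureSeries, write_series
from .pharmacokinetics import InjectionSchedule, PKParams
from .thermodynamics import ThermoParams, simulate_temperature

__all__ = [
    "DesignSpec",
    "NoiseSpec",
    "generate_group",
    "generate_study",
    "DEFAULT_SCENARIO",
]

#: Generating truth per SB dose, chosen so the fitted study's qualitative
#: orderings hold: w_Exc and w_Inh decrease with SB dose, w_HD increases,
#: w_S drops from vehicle with little further change between SB doses.
DEFAULT_SCENARIO: dict[float, ParamVectorW] = {
    0.0: ParamVectorW(w_S=1.2, w_Exc=0.85, w_Inh=0.66, w_HD=0.70),
    10.0: ParamVectorW(w_S=0.85, w_Exc=0.62, w_Inh=0.60, w_HD=0.90),
    30.0: ParamVectorW(w_S=0.75, w_Exc=0.40, w_Inh=0.35, w_HD=1.15),
}


@dataclass(frozen=True)
class DesignSpec:
    """Experimental design: groups, sampling grid, injection times."""

    sb_doses: tuple[float, ...] = (0.0, 10.0, 30.0)
    meth_doses: tuple[float, ...] = (0.0, 1.0, 5.0, 10.0)
    n_per_group: int = 7
    t_start: float = -50.0
    t_end: float = 180.0
    dt_sample: float = 2.0
    pretreat_time: float = -30.0
    meth_time: float = 0.0
    baseline: float = 37.0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not (self.t_start < self.pretreat_time < self.meth_time < self.t_end):
            raise ValueError("sampling window must cover both injections")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.t_start, self.t_end + 0.5 * self.dt_sample,
                         self.dt_sample)


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model for synthetic animals.

    ``noise_sd`` is the AR(1) innovation SD (degC); the stationary per-point
    SD is noise_sd/sqrt(1 - ar1^2).  ``baseline_sd`` is the SD of the
    per-animal constant offset.
    """

    noise_sd: float = 0.3
    ar1: float = 0.5
    baseline_sd: float = 0.2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        if not 0.0 <= self.ar1 < 1.0:
            raise ValueError("AR(1) coefficient must lie in [0, 1)")

    @property
    def stationary_sd(self) -> float:
        return self.noise_sd / np.sqrt(1.0 - self.ar1 ** 2)

    def iid(self) -> "NoiseSpec":
        """The matched iid-Gaussian mode (no autocorrelation, no offsets)."""
        return replace(self, ar1=0.0, baseline_sd=0.0)


def _ar1_noise(rng: np.random.Generator, n_animals: int, n_times: int,
               noise: NoiseSpec) -> np.ndarray:
    if noise.noise_sd == 0.0:
        return np.zeros((n_animals, n_times))
    out = np.empty((n_animals, n_times))
    out[:, 0] = rng.normal(0.0, noise.stationary_sd, n_animals)
    innov = rng.normal(0.0, noise.noise_sd, (n_animals, n_times - 1))
    for k in range(1, n_times):
        out[:, k] = noise.ar1 * out[:, k - 1] + innov[:, k - 1]
    return out


def noiseless_trajectory(true_W: ParamVectorW | Mapping[str, float],
                         design: DesignSpec, meth_dose: float,
                         base: CircuitParams | None = None,
                         pk: PKParams | None = None,
                         thermo: ThermoParams | None = None) -> np.ndarray:
    """Model temperature on the sampling grid for the given generating truth."""
    w = true_W.as_dict() if isinstance(true_W, ParamVectorW) else dict(true_W)
    circ = replace(base or CircuitParams(), **w)
    schedule = InjectionSchedule(
        meth_dose=meth_dose, meth_time=design.meth_time,
        pretreat_time=design.pretreat_time,
    )
    thermo = thermo or ThermoParams(T0=design.baseline)
    traj = simulate_temperature(schedule, circ, pk or PKParams(), thermo,
                                design.times)
    return traj.temp


def generate_group(true_W: ParamVectorW | Mapping[str, float],
                   design: DesignSpec,
                   noise: NoiseSpec,
                   sb_dose: float,
                   meth_dose: float,
                   rng: np.random.Generator | None = None,
                   base: CircuitParams | None = None,
                   pk: PKParams | None = None,
                   thermo: ThermoParams | None = None,
                   ) -> tuple[TemperatureSeries, np.ndarray]:
    """One synthetic group: empirical mean/SD series plus the per-animal matrix."""
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    clean = noiseless_trajectory(true_W, design, meth_dose, base, pk, thermo)
    n, nt = design.n_per_group, clean.size
    offsets = (rng.normal(0.0, noise.baseline_sd, n)
               if noise.baseline_sd > 0 else np.zeros(n))
    animals = clean[None, :] + offsets[:, None] + _ar1_noise(rng, n, nt, noise)
    series = TemperatureSeries(
        times=design.times,
        mean=animals.mean(axis=0),
        sd=animals.std(axis=0, ddof=1),
        n=n,
        sb_dose=sb_dose,
        meth_dose=meth_dose,
    )
    return series, animals


def generate_study(scenario: Mapping[float, ParamVectorW] | None = None,
                   design: DesignSpec = DesignSpec(),
                   noise: NoiseSpec = NoiseSpec(),
                   seed: int | None = None,
                   out_dir: str | Path | None = None,
                   ) -> dict[tuple[float, float], TemperatureSeries]:
    """Full synthetic study: every SB x Meth dose combination.

    Returns a dict keyed by (sb_dose, meth_dose).  When ``out_dir`` is
    given, writes one CSV per group plus ``truth.json`` recording the
    generating parameters, noise settings and seed for recovery testing.
    """
    scenario = dict(scenario or DEFAULT_SCENARIO)
    missing = [sb for sb in design.sb_doses if sb not in scenario]
    if missing:
        raise ValueError(f"scenario lacks truth for SB doses {missing}")
    root_seed = seed if seed is not None else noise.seed
    rng = np.random.default_rng(root_seed)
    groups: dict[tuple[float, float], TemperatureSeries] = {}
    for sb in design.sb_doses:
        for meth in design.meth_doses:
            series, _ = generate_group(scenario[sb], design, noise, sb, meth,
                                       rng=rng)
            groups[(sb, meth)] = series
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for (sb, meth), series in groups.items():
            write_series(out / f"group_sb{sb:g}_meth{meth:g}.csv", series)
        truth = {
            "scenario": {f"{sb:g}": w.as_dict() for sb, w in scenario.items()},
            "design": asdict(design),
            "noise": asdict(noise),
            "seed": root_seed,
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=2))
    return groups
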