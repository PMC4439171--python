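"""Bayesian inference of the SB-affected parameters by random-walk MCMC.

The data are group-level temperature time series (mean, SD, group size on a
2-min grid from -50 to 180 min).  Assuming Gaussian residuals with the
group SD at each time point, the unnormalized log-posterior of a parameter
vector W is

    log p(W | {T_i}) = - sum_groups sum_i (T_i - T(W, i))^2 / (2 sigma_i^2)

with flat priors on the support (Meth sensitivities and time constants
nonnegative, w_S and gamma_HD unconstrained).  All Meth-dose groups sharing
one SB pretreatment are fit jointly with a single W; fits for different SB
doses are independent.

Sampling is random-walk Metropolis-Hastings with a diagonal Gaussian
proposal.  During burn-in the proposal is adapted (global scale toward a
25-40% acceptance rate, relative scales from the running chain spread);
adaptation is frozen afterwards so the retained chain satisfies detailed
balance.  The "standard error" of a parameter is the posterior standard
deviation of its ensemble, which is what the between-dose two-sample
z-tests consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .circuit import CircuitParams
from .pharmacokinetics import InjectionSchedule, PKParams
from .thermodynamics import ThermoParams, simulate_temperature

__all__ = [
    "TemperatureSeries",
    "ParamVectorW",
    "FixedModel",
    "MCMCSettings",
    "PosteriorEnsemble",
    "ZTestResult",
    "log_posterior",
    "log_posterior_named",
    "metropolis_hastings",
    "mcmc_sample",
    "compare_groups",
    "read_series",
    "write_series",
    "read_series_xlsx",
    "SIGMA_FLOOR",
]

#: floor on the per-point group SD (degC) to avoid singular weights
SIGMA_FLOOR = 0.05

#: sampleable parameter names -> (owning block, nonnegative support)
PARAM_SPACE: dict[str, tuple[str, bool]] = {
    "w_S": ("circuit", False),
    "w_Exc": ("circuit", True),
    "w_Inh": ("circuit", True),
    "w_HD": ("circuit", True),
    "gamma_HD": ("circuit", False),
    "w_Inh_HD": ("circuit", True),
    "tau_u": ("pk", True),
    "tau_d": ("pk", True),
    "tau_s": ("pk", True),
    "tau_T": ("thermo", True),
}


@dataclass(frozen=True)
class TemperatureSeries:
    """Group temperature time series: mean/SD/n on a common time grid."""

    times: np.ndarray       # minutes
    mean: np.ndarray        # degC
    sd: np.ndarray          # degC, across animals at each time point
    n: int                  # animals in the group
    sb_dose: float = 0.0    # mg/kg SB pretreatment (0 = vehicle)
    meth_dose: float = 0.0  # mg/kg Meth (0 = saline)

    def __post_init__(self) -> None:
        for name in ("times", "mean", "sd"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        if not (len(self.times) == len(self.mean) == len(self.sd)):
            raise ValueError("times/mean/sd must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.n < 2:
            raise ValueError("group size must be >= 2 for an SD to exist")

    @property
    def sem(self) -> np.ndarray:
        """Standard error of the group mean (recorded; inference uses SD)."""
        return self.sd / np.sqrt(self.n)

    @property
    def schedule(self) -> InjectionSchedule:
        return InjectionSchedule(meth_dose=self.meth_dose)


@dataclass(frozen=True)
class ParamVectorW:
    """SB-affected parameter vector (w_S, w_Exc, w_Inh, w_HD).

    Under the ``gamma_hd`` parametrization, gamma_HD replaces w_HD as the
    SB-dependent entry (pass ``gamma_HD=...`` and leave ``w_HD=None``).
    """

    w_S: float
    w_Exc: float
    w_Inh: float
    w_HD: float | None = None
    gamma_HD: float | None = None

    def __post_init__(self) -> None:
        if (self.w_HD is None) == (self.gamma_HD is None):
            raise ValueError("exactly one of w_HD / gamma_HD must be given")
        for name, val in self.as_dict().items():
            if not np.isfinite(val):
                raise ValueError(f"{name} must be finite")

    def as_dict(self) -> dict[str, float]:
        out = {"w_S": self.w_S, "w_Exc": self.w_Exc, "w_Inh": self.w_Inh}
        if self.w_HD is not None:
            out["w_HD"] = self.w_HD
        else:
            out["gamma_HD"] = self.gamma_HD
        return out


@dataclass(frozen=True)
class FixedModel:
    """All parameters held fixed during a fit, plus integrator settings."""

    pk: PKParams = field(default_factory=PKParams)
    circuit: CircuitParams = field(default_factory=CircuitParams)
    thermo: ThermoParams = field(default_factory=ThermoParams)
    dt: float = 0.1


def _apply_overrides(fixed: FixedModel, values: Mapping[str, float]) -> FixedModel:
    pk_over = {k: v for k, v in values.items() if PARAM_SPACE[k][0] == "pk"}
    circ_over = {k: v for k, v in values.items() if PARAM_SPACE[k][0] == "circuit"}
    th_over = {k: v for k, v in values.items() if PARAM_SPACE[k][0] == "thermo"}
    return FixedModel(
        pk=replace(fixed.pk, **pk_over) if pk_over else fixed.pk,
        circuit=replace(fixed.circuit, **circ_over) if circ_over else fixed.circuit,
        thermo=replace(fixed.thermo, **th_over) if th_over else fixed.thermo,
        dt=fixed.dt,
    )


def _in_support(values: Mapping[str, float]) -> bool:
    for name, val in values.items():
        if name not in PARAM_SPACE:
            raise KeyError(f"unknown parameter {name!r}")
        if not np.isfinite(val):
            return False
        if PARAM_SPACE[name][1] and val < 0:
            return False
        # time constants must stay strictly positive and non-confluent
        if name in ("tau_u", "tau_d", "tau_s", "tau_T") and val <= 0:
            return False
    return True


def log_posterior_named(values: Mapping[str, float],
                        data: Sequence[TemperatureSeries],
                        fixed: FixedModel) -> float:
    """Unnormalized log-posterior for named parameter overrides.

    Returns -inf outside the prior support or when the simulation fails.
    """
    if not _in_support(values):
        return -np.inf
    model = _apply_overrides(fixed, values)
    if abs(model.pk.tau_u - model.pk.tau_d) < 1e-9 * model.pk.tau_u:
        return -np.inf
    total = 0.0
    for series in data:
        try:
            traj = simulate_temperature(
                series.schedule, model.circuit, model.pk, model.thermo,
                series.times, dt=model.dt,
            )
        except (RuntimeError, FloatingPointError):
            return -np.inf
        sigma = np.maximum(series.sd, SIGMA_FLOOR)
        resid = series.mean - traj.temp
        total -= float(np.sum(resid * resid / (2.0 * sigma * sigma)))
    if not np.isfinite(total):
        return -np.inf
    return total


def log_posterior(W: ParamVectorW, data: Sequence[TemperatureSeries],
                  fixed: FixedModel) -> float:
    """Unnormalized log-posterior of the SB-affected vector W (always <= 0)."""
    return log_posterior_named(W.as_dict(), data, fixed)


@dataclass(frozen=True)
class MCMCSettings:
    n_steps: int = 50_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 42
    proposal_scales: Mapping[str, float] | None = None
    tune_interval: int = 200
    target_acceptance: tuple[float, float] = (0.25, 0.40)

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_steps:
            raise ValueError("burn_in must be smaller than n_steps")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class PosteriorEnsemble:
    """Thinned post-burn-in MCMC sample cloud over named parameters."""

    names: tuple[str, ...]
    samples: np.ndarray          # (n_samples, n_params)
    log_post: np.ndarray         # (n_samples,)
    acceptance_rate: float
    seed: int
    label: str = ""

    def mean(self) -> dict[str, float]:
        return dict(zip(self.names, self.samples.mean(axis=0)))

    def se(self) -> dict[str, float]:
        """Posterior SD per parameter (the ensemble standard error)."""
        return dict(zip(self.names, self.samples.std(axis=0, ddof=1)))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.samples, columns=list(self.names))
        df.insert(0, "sample", np.arange(len(df)))
        df["log_post"] = self.log_post
        return df

    def summary(self) -> pd.DataFrame:
        m, s = self.mean(), self.se()
        return pd.DataFrame(
            {"parameter": list(self.names),
             "mean": [m[k] for k in self.names],
             "se": [s[k] for k in self.names],
             "label": self.label}
        )


def metropolis_hastings(logpdf, init, scales, settings: MCMCSettings
                        ) -> tuple[np.ndarray, np.ndarray, float]:
    """Generic random-walk Metropolis-Hastings sampler.

    Symmetric diagonal Gaussian proposals; acceptance probability
    min(1, exp(delta log-density)).  The proposal adapts during burn-in
    (global scale toward the target acceptance window, relative scales
    from the running chain spread) and is frozen afterwards, so the
    retained thinned chain obeys detailed balance.  Returns
    ``(samples, log_densities, post_burn_in_acceptance_rate)``.
    """
    x = np.asarray(init, dtype=float).copy()
    scales = np.asarray(scales, dtype=float).copy()
    ndim = x.size
    rng = np.random.default_rng(settings.seed)
    lp = logpdf(x)
    if not np.isfinite(lp):
        raise ValueError("initial point has zero density")

    keep_samples, keep_lp = [], []
    n_acc_post = n_post = 0
    n_acc_win = 0
    burn_chain = np.empty((settings.burn_in, ndim))
    for step in range(settings.n_steps):
        prop = x + scales * rng.standard_normal(ndim)
        lp_prop = logpdf(prop)
        if np.log(rng.random()) < lp_prop - lp:
            x, lp = prop, lp_prop
            n_acc_win += 1
            if step >= settings.burn_in:
                n_acc_post += 1
        if step < settings.burn_in:
            burn_chain[step] = x
            if (step + 1) % settings.tune_interval == 0:
                rate = n_acc_win / settings.tune_interval
                lo, hi = settings.target_acceptance
                scales = scales * np.exp(rate - 0.5 * (lo + hi))
                # shape the proposal to the running chain spread
                if step + 1 >= 2 * settings.tune_interval:
                    spread = burn_chain[: step + 1].std(axis=0, ddof=1)
                    if (spread > 0).any():
                        rel = np.where(spread > 0, spread, scales)
                        scales = rel / rel.max() * scales.max()
                n_acc_win = 0
        else:
            n_post += 1
            if (step - settings.burn_in) % settings.thin == 0:
                keep_samples.append(x.copy())
                keep_lp.append(lp)

    acc_rate = n_acc_post / max(n_post, 1)
    if not 0.1 <= acc_rate <= 0.6:
        warnings.warn(
            f"post-burn-in acceptance rate {acc_rate:.3f} outside [0.1, 0.6]; "
            "consider adjusting proposal scales or chain length",
            RuntimeWarning,
        )
    return np.asarray(keep_samples), np.asarray(keep_lp), acc_rate


def mcmc_sample(data: Sequence[TemperatureSeries],
                fixed: FixedModel,
                init: Mapping[str, float] | ParamVectorW,
                settings: MCMCSettings = MCMCSettings(),
                label: str = "") -> PosteriorEnsemble:
    """Sample the posterior over the parameters named in ``init``.

    Thin wrapper binding :func:`metropolis_hastings` to
    :func:`log_posterior_named`; reproducible for a fixed seed.
    """
    if isinstance(init, ParamVectorW):
        init = init.as_dict()
    names = tuple(init)
    x0 = np.array([init[k] for k in names], dtype=float)
    if not _in_support(dict(zip(names, x0))):
        raise ValueError("initial point outside the prior support")
    if settings.proposal_scales is not None:
        scales = np.array([settings.proposal_scales[k] for k in names], float)
    else:
        scales = 0.1 * np.abs(x0) + 0.01

    def logpdf(vec):
        return log_posterior_named(dict(zip(names, vec)), data, fixed)

    samples, log_post, acc_rate = metropolis_hastings(logpdf, x0, scales,
                                                      settings)
    return PosteriorEnsemble(
        names=names,
        samples=samples,
        log_post=log_post,
        acceptance_rate=acc_rate,
        seed=settings.seed,
        label=label,
    )


@dataclass(frozen=True)
class ZTestResult:
    parameter: str
    group_pair: tuple[str, str]
    z: float
    p_value: float
    significant: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def compare_groups(e1: PosteriorEnsemble, e2: PosteriorEnsemble,
                   parameter: str, alpha: float = 0.05) -> ZTestResult:
    """Two-sample z-test on ensemble means: z = (m1 - m2)/sqrt(se1^2 + se2^2)."""
    m1, m2 = e1.mean()[parameter], e2.mean()[parameter]
    se1, se2 = e1.se()[parameter], e2.se()[parameter]
    denom = float(np.hypot(se1, se2))
    if denom == 0.0:
        raise ZeroDivisionError("combined standard error is zero")
    z = (m1 - m2) / denom
    p = 2.0 * stats.norm.sf(abs(z))
    return ZTestResult(
        parameter=parameter,
        group_pair=(e1.label, e2.label),
        z=float(z),
        p_value=float(p),
        significant=bool(p < alpha),
    )


# ---------------------------------------------------------------------------
# I/O for group series


def write_series(path, series: TemperatureSeries) -> None:
    """Delimited text with columns time_min, mean_c, sd_c, n."""
    pd.DataFrame(
        {"time_min": series.times, "mean_c": series.mean,
         "sd_c": series.sd, "n": series.n}
    ).to_csv(path, index=False)


def read_series(path, sb_dose: float = 0.0,
                meth_dose: float = 0.0) -> TemperatureSeries:
    df = pd.read_csv(path)
    return TemperatureSeries(
        times=df["time_min"].to_numpy(float),
        mean=df["mean_c"].to_numpy(float),
        sd=df["sd_c"].to_numpy(float),
        n=int(df["n"].iloc[0]),
        sb_dose=sb_dose,
        meth_dose=meth_dose,
    )


def read_series_xlsx(path, sheet: str | int = 0, sb_dose: float = 0.0,
                     meth_dose: float = 0.0) -> TemperatureSeries:
    """Read a spreadsheet sheet laid out as time column + one column per animal.

    Group mean and SD are computed across the animal columns.  Matches the
    layout of deposited per-animal telemetry workbooks.
    """
    df = pd.read_excel(Path(path), sheet_name=sheet)
    times = df.iloc[:, 0].to_numpy(float)
    animals = df.iloc[:, 1:].to_numpy(float)
    return TemperatureSeries(
        times=times,
        mean=animals.mean(axis=1),
        sd=animals.std(axis=1, ddof=1),
        n=animals.shape[1],
        sb_dose=sb_dose,
        meth_dose=meth_dose,
    )
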