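"""Firing-rate circuit: Meth-sensitive nodes, medullary relay, SPN output.

Three Meth-sensitive populations — excitatory (Exc), inhibitory (Inhib) and
a high-dose-activated node (HD) — respond instantaneously to the blood Meth
concentration and, for Exc, to the injection-stress input, through a
sigmoid activation sigma(x) = (1 + tanh x)/2:

    P_Exc = sigma(w_S*S(t,-30) + w_S*S(t,0) + w_Exc*[M] + gamma_Exc)
    P_Inh = sigma(w_Inh*[M] + gamma_Inh)
    P_HD  = sigma(w_HD*[M] + gamma_HD)                       (base)
    P_HD  = sigma(w_HD*[M] + gamma_HD - w_Inh_HD*P_Inh)      (extended)

Excitatory and inhibitory drives compete at the medullary relay, and the
sympathetic premotor output adds the HD contribution:

    P_Med = w_Exc_Med*P_Exc - w_Inh_Med*P_Inh
    P_SPN = P_Med + w_HD_SPN*P_HD + gamma_SPN

The SPN drive (degC) forces the temperature ODE.  The ``gamma_hd`` variant
has identical dynamics to ``base``; it only changes which parameter is
treated as SB-dependent during inference (basal HD tone gamma_HD instead of
the Meth sensitivity w_HD).  The ``extended`` variant routes the inhibitory
tone onto HD through the Inhib population.  ``inhib_cap`` bounds the maximal
Inhib activity (hard ceiling) for inhibition-failure scenarios.

Baseline recentring: with the published constants the resting drive is about
-0.51 degC, which would place the resting temperature below T0.  By default
a constant offset is subtracted so that P_SPN = 0 at zero concentration and
zero stress (equivalent to recalibrating gamma_SPN); set
``raw_gamma_spn=True`` to use gamma_SPN verbatim.  The recentring offset is
computed with the cap released, so failure scenarios retain the tonic effect
of disinhibition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .pharmacokinetics import InjectionSchedule, PKParams, stress_input

__all__ = [
    "CircuitParams",
    "NodeActivities",
    "sigmoid",
    "node_activities",
    "spn_drive",
    "baseline_offset",
    "activation_curve",
    "half_activation",
    "VARIANTS",
]

VARIANTS = ("base", "gamma_hd", "extended")


def sigmoid(x):
    """sigma(x) = (1 + tanh x)/2: monotone, sigma(0) = 1/2, limits 0 and 1."""
    return 0.5 * (1.0 + np.tanh(x))


@dataclass(frozen=True)
class CircuitParams:
    """All circuit constants plus the SB-affected vector (w_S, w_Exc, w_Inh, w_HD).

    Sensitivities w_* are per mg/kg; projection weights and gamma_SPN are
    degC; the gamma_* offsets live on the concentration scale inside the
    sigmoids.  Only the four SB-affected entries (or gamma_HD under the
    ``gamma_hd`` variant) change between SB doses; the rest are fixed.
    """

    w_S: float = 1.2
    w_Exc: float = 0.85
    w_Inh: float = 0.66
    w_HD: float = 0.70
    gamma_Exc: float = -0.357
    gamma_Inh: float = -1.335
    gamma_HD: float = -3.69
    gamma_SPN: float = -3.35
    w_Exc_Med: float = 9.89
    w_Inh_Med: float = 6.38
    w_HD_SPN: float = 5.66
    variant: str = "base"
    w_Inh_HD: float = 5.0
    inhib_cap: float = 1.0
    raw_gamma_spn: bool = False

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )
        for name in ("w_Exc_Med", "w_Inh_Med", "w_HD_SPN", "w_Inh_HD"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.inhib_cap <= 1.0:
            raise ValueError("inhib_cap must lie in [0, 1]")


@dataclass(frozen=True)
class NodeActivities:
    """Node outputs: P_Exc/P_Inh/P_HD in [0, 1]; P_Med/P_SPN in degC."""

    P_Exc: np.ndarray | float
    P_Inh: np.ndarray | float
    P_HD: np.ndarray | float
    P_Med: np.ndarray | float
    P_SPN: np.ndarray | float


def _raw_activities(conc, stress_sum, params: CircuitParams, capped: bool = True):
    """Node activities from concentration and summed stress inputs."""
    p_exc = sigmoid(params.w_S * stress_sum + params.w_Exc * conc + params.gamma_Exc)
    p_inh = sigmoid(params.w_Inh * conc + params.gamma_Inh)
    if capped:
        p_inh = np.minimum(p_inh, params.inhib_cap)
    if params.variant == "extended":
        p_hd = sigmoid(
            params.w_HD * conc + params.gamma_HD - params.w_Inh_HD * p_inh
        )
    else:
        p_hd = sigmoid(params.w_HD * conc + params.gamma_HD)
    return p_exc, p_inh, p_hd


def baseline_offset(params: CircuitParams) -> float:
    """Resting SPN drive (degC) at zero concentration, zero stress, cap released.

    This is the constant subtracted when baseline recentring is active.
    """
    p_exc, p_inh, p_hd = _raw_activities(0.0, 0.0, params, capped=False)
    p_med = params.w_Exc_Med * p_exc - params.w_Inh_Med * p_inh
    return float(p_med + params.w_HD_SPN * p_hd + params.gamma_SPN)


def node_activities(t, conc, schedule: InjectionSchedule, params: CircuitParams,
                    pk: PKParams | None = None) -> NodeActivities:
    """Evaluate all node activities at time(s) ``t`` with concentration ``conc``.

    Stress inputs are computed from the schedule's injection times (one
    amplitude ``w_S`` per event, identical for both injections).
    """
    pk = pk or PKParams()
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be nonnegative")
    stress_sum = sum(stress_input(t, t0, pk.tau_s) for t0 in schedule.stress_times)
    p_exc, p_inh, p_hd = _raw_activities(conc, stress_sum, params)
    p_med = params.w_Exc_Med * p_exc - params.w_Inh_Med * p_inh
    p_spn = p_med + params.w_HD_SPN * p_hd + params.gamma_SPN
    if not params.raw_gamma_spn:
        p_spn = p_spn - baseline_offset(params)
    return NodeActivities(p_exc, p_inh, p_hd, p_med, p_spn)


def spn_drive(conc, stress_sum, params: CircuitParams):
    """SPN output drive (degC) from concentration and summed stress activity.

    Low-level entry point used by the temperature integrator; applies
    baseline recentring unless ``raw_gamma_spn`` is set.
    """
    p_exc, p_inh, p_hd = _raw_activities(conc, stress_sum, params)
    p_spn = (params.w_Exc_Med * p_exc - params.w_Inh_Med * p_inh
             + params.w_HD_SPN * p_hd + params.gamma_SPN)
    if not params.raw_gamma_spn:
        p_spn = p_spn - baseline_offset(params)
    return p_spn


def activation_curve(node: str, conc_grid, params: CircuitParams):
    """Node activity as a function of blood Meth concentration (stress = 0).

    ``node`` is one of ``Exc``, ``Inh``, ``HD``, ``Med``, ``SPN``.
    """
    conc_grid = np.asarray(conc_grid, dtype=float)
    if np.any(conc_grid < 0):
        raise ValueError("concentration grid must be nonnegative")
    p_exc, p_inh, p_hd = _raw_activities(conc_grid, 0.0, params)
    p_med = params.w_Exc_Med * p_exc - params.w_Inh_Med * p_inh
    p_spn = p_med + params.w_HD_SPN * p_hd + params.gamma_SPN
    if not params.raw_gamma_spn:
        p_spn = p_spn - baseline_offset(params)
    curves = {"Exc": p_exc, "Inh": p_inh, "HD": p_hd, "Med": p_med, "SPN": p_spn}
    try:
        return curves[node]
    except KeyError:
        raise ValueError(f"unknown node {node!r}; expected one of {tuple(curves)}")


def half_activation(node: str, params: CircuitParams) -> float:
    """Concentration at which a Meth-sensitive node reaches activity 1/2.

    Closed form -gamma/w of the sigmoid argument; for the extended variant's
    HD node the Inhib feed makes the threshold concentration-dependent and
    no closed form is returned.
    """
    pairs = {
        "Exc": (params.gamma_Exc, params.w_Exc),
        "Inh": (params.gamma_Inh, params.w_Inh),
        "HD": (params.gamma_HD, params.w_HD),
    }
    if node not in pairs:
        raise ValueError(f"unknown Meth-sensitive node {node!r}")
    if node == "HD" and params.variant == "extended":
        raise ValueError("extended-variant HD threshold has no closed form")
    gamma, w = pairs[node]
    if w <= 0:
        raise ValueError("half-activation undefined for nonpositive sensitivity")
    return -gamma / w


def with_W(params: CircuitParams, **w) -> CircuitParams:
    """Return a copy of ``params`` with SB-affected entries replaced."""
    return replace(params, **w)
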