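"""Activation mechanisms and their DCS contrast.

Three mechanisms convert neuronal activation into tissue dynamics visible to
diffuse correlation spectroscopy:

* ballistic neuronal cell-membrane motion (speed ~1 nm/ms, within ~100 ms of
  the action potential),
* the hemodynamic response — vessel dilation raising cerebral blood volume
  (rCBV = rd^2) and, by Poiseuille's law, blood flow (rCBF = rd^4), with the
  dilation onset delayed ~450 ms after neuronal activation,
* the vessel-wall movement itself (a ballistic phase contribution, shown to
  be negligible).

Every mechanism is reduced to the relative change of the fitted decay time,
C = (tau_c,baseline - tau_c,activated) / tau_c,baseline, evaluated in a
*paired* fashion on the same detected-photon ensemble so that Monte Carlo
sampling error cancels between the two states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .correlation import (
    GLOBAL,
    LOCAL,
    OUTSIDE,
    BallisticComponent,
    DiffusiveComponent,
    DynamicsSpec,
    G1Curve,
    decay_time_1e,
    default_tau_grid,
    extended_tau_grid,
    fit_tau_c,
    g1_from_records,
    NM_PER_MS,
)
from .mc_transport import PhotonRecordSet

__all__ = [
    "HemodynamicModel",
    "MeasurementWindow",
    "ContrastResult",
    "within_window_rate",
    "vessel_wall_speed",
    "paired_contrast",
    "contrast_cell_motion",
    "neuronal_only_g1",
    "neuronal_only_decay_time",
    "matched_diffusion_coefficient",
    "contrast_cell_motion_diffusive",
    "contrast_hemodynamic",
    "contrast_vessel_wall",
    "td_sweep",
]

DEFAULT_ALPHA_D = 1e-6  # mm^2/s, baseline blood flow index alpha*D
DEFAULT_ALPHA_RBC = 0.02  # baseline RBC scattering probability


@dataclass(frozen=True)
class HemodynamicModel:
    """Single-compartment neurovascular response.

    The relative vessel diameter follows
    rd(t) = 1 + delta_d * t^2 * exp(-t^2 / sigma_d^2)  (t in s, t=0 at the
    onset of vessel dilation), giving rCBV = rd^2 and rCBF = rd^4.  Both peak
    at t = sigma_d.  ``alpha_D0`` is the baseline blood flow index; the
    activated index is alpha_D0 * rCBF(td) because the scattering probability
    scales with volume and the diffusion coefficient with flow speed, and
    their product is driven by the volumetric flow.

    ``onset_delay`` (s) is the lag of vessel dilation behind neuronal
    activation; ``d0_um`` a nominal baseline vessel diameter used only for
    the wall-speed estimate.
    """

    delta_d: float = 0.07  # dimensionless amplitude
    sigma_d: float = 1.83  # s
    alpha_D0: float = DEFAULT_ALPHA_D  # mm^2/s
    alpha0: float = DEFAULT_ALPHA_RBC
    onset_delay: float = 0.45  # s
    d0_um: float = 20.0  # um

    def __post_init__(self) -> None:
        if self.sigma_d <= 0 or self.alpha_D0 < 0 or self.d0_um <= 0:
            raise ValueError("non-physical hemodynamic parameters")

    def rd(self, t):
        """Relative vessel diameter; rd(0) = 1."""
        t = np.asarray(t, dtype=float)
        return 1.0 + self.delta_d * t**2 * np.exp(-(t**2) / self.sigma_d**2)

    def rcbv(self, t):
        """Relative cerebral blood volume rd^2 (cylindrical vessels)."""
        return self.rd(t) ** 2

    def rcbf(self, t):
        """Relative cerebral blood flow rd^4 (Poiseuille, fixed pressure)."""
        return self.rd(t) ** 4

    def rd_prime(self, t):
        """d(rd)/dt in s^-1."""
        t = np.asarray(t, dtype=float)
        g = np.exp(-(t**2) / self.sigma_d**2)
        return self.delta_d * g * (2.0 * t - 2.0 * t**3 / self.sigma_d**2)

    def peak_time(self) -> float:
        """argmax of rCBF (== argmax rd == sigma_d), located by 1-D search."""
        res = minimize_scalar(
            lambda t: -self.rcbf(t),
            bounds=(0.0, 5.0 * self.sigma_d),
            method="bounded",
            options={"xatol": 1e-10},
        )
        return float(res.x)


@dataclass(frozen=True)
class MeasurementWindow:
    """Measurement starting td seconds after dilation onset, lasting T seconds."""

    td: float = 0.0
    T: float = 0.01

    def __post_init__(self) -> None:
        if self.td < 0 or self.T <= 0:
            raise ValueError("td must be >= 0 and T > 0")


@dataclass(frozen=True)
class ContrastResult:
    """Relative decay-time contrast C = delta(tau_c)/tau_c from paired fits."""

    contrast: float
    tau_c_baseline: float
    tau_c_activated: float
    scope: str
    mechanism: str


def within_window_rate(model: HemodynamicModel, window: MeasurementWindow) -> float:
    """Average rate of rCBF change across the window, R = (rCBF(td+T)-rCBF(td))/T."""
    return float((model.rcbf(window.td + window.T) - model.rcbf(window.td)) / window.T)


def vessel_wall_speed(model: HemodynamicModel, t: float) -> float:
    """Vessel-wall (radius) speed in nm/ms: (d0/2) * d(rd)/dt."""
    d0_mm = model.d0_um * 1e-3
    v_mm_s = 0.5 * d0_mm * float(model.rd_prime(t))
    return v_mm_s / NM_PER_MS


# ---------------------------------------------------------------------------
# Paired contrast machinery
# ---------------------------------------------------------------------------


def paired_contrast(
    records: PhotonRecordSet,
    baseline: DynamicsSpec,
    activated: DynamicsSpec,
    tau_grid: Optional[np.ndarray] = None,
    fit_window: float = 70e-6,
    scope: str = GLOBAL,
    mechanism: str = "custom",
) -> ContrastResult:
    """Fit tau_c for two dynamic states on the *same* photon ensemble."""
    if tau_grid is None:
        tau_grid = default_tau_grid(fit_window)
    g_base = g1_from_records(records, baseline, tau_grid)
    g_act = g1_from_records(records, activated, tau_grid)
    t_base = fit_tau_c(g_base, fit_window).tau_c
    t_act = fit_tau_c(g_act, fit_window).tau_c
    return ContrastResult(
        contrast=(t_base - t_act) / t_base,
        tau_c_baseline=t_base,
        tau_c_activated=t_act,
        scope=scope,
        mechanism=mechanism,
    )


def contrast_cell_motion(
    records: PhotonRecordSet,
    v_nm_per_ms: float = 1.0,
    alpha_neuronal: float = 1.0,
    scope: str = GLOBAL,
    alpha_D: float = DEFAULT_ALPHA_D,
) -> ContrastResult:
    """Contrast from ballistic neuronal membrane motion on top of baseline flow.

    alpha_neuronal = 1 is the best-case scenario (every scattering event in
    scope occurs at a neuron).
    """
    base = DynamicsSpec.baseline(alpha_D)
    act = DynamicsSpec(
        diffusive=base.diffusive,
        ballistic=(BallisticComponent(v_nm_per_ms, alpha_neuronal, scope),),
    )
    return paired_contrast(records, base, act, scope=scope, mechanism="cell_motion")


def neuronal_only_g1(
    records: PhotonRecordSet,
    v_nm_per_ms: float = 1.0,
    alpha_neuronal: float = 1.0,
    scope: str = GLOBAL,
    tau_grid: Optional[np.ndarray] = None,
) -> G1Curve:
    """g1 generated by neuronal cell motion alone (no blood dynamics)."""
    if tau_grid is None:
        tau_grid = extended_tau_grid()
    spec = DynamicsSpec(ballistic=(BallisticComponent(v_nm_per_ms, alpha_neuronal, scope),))
    return g1_from_records(records, spec, tau_grid)


def neuronal_only_decay_time(
    records: PhotonRecordSet,
    v_nm_per_ms: float = 1.0,
    tau_grid: Optional[np.ndarray] = None,
) -> dict:
    """Decay time of the neuronal-motion-only curve on an extended grid.

    Returns both the 1/e crossing and an exp(-tau/tau_c) fit over the full
    grid; the two definitions differ because the ensemble curve is not a
    single exponential.
    """
    curve = neuronal_only_g1(records, v_nm_per_ms, tau_grid=tau_grid)
    t_1e = decay_time_1e(curve)
    t_fit = fit_tau_c(curve, fit_window=float(curve.tau[-1])).tau_c
    return {"t_1e": t_1e, "t_fit": t_fit, "curve": curve}


def matched_diffusion_coefficient(
    records: PhotonRecordSet,
    target_decay_time: float,
    alpha: float = 1.0,
    scope: str = GLOBAL,
) -> float:
    """alpha*D (mm^2/s) whose diffusive-only curve has the given 1/e decay time."""

    from .correlation import FitError

    grid = np.concatenate([[0.0], np.geomspace(1e-7, 100.0 * target_decay_time, 400)])

    def t1e_of(log10_aD):
        spec = DynamicsSpec(diffusive=(DiffusiveComponent(10.0**log10_aD * alpha, scope),))
        curve = g1_from_records(records, spec, grid)
        try:
            return decay_time_1e(curve) - target_decay_time
        except FitError:
            # too slow to cross 1/e on this grid -> decay time above target
            return float(grid[-1])

    lg = brentq(t1e_of, -16.0, -2.0, xtol=1e-12)
    return float(10.0**lg * alpha)


def contrast_cell_motion_diffusive(
    records: PhotonRecordSet,
    target_decay_time: Optional[float] = None,
    scope: str = GLOBAL,
    alpha_D: float = DEFAULT_ALPHA_D,
) -> ContrastResult:
    """Contrast if neuronal motion were diffusive with a matched decay time.

    The hypothetical diffusion coefficient is chosen so the neuronal-only
    curve reaches 1/e at the same time as the ballistic case; because the
    mean-square displacement then grows as 6D*tau instead of v^2*tau^2, the
    early-tau (fit window) perturbation is orders of magnitude larger.
    """
    if target_decay_time is None:
        target_decay_time = neuronal_only_decay_time(records)["t_1e"]
    d_eq = matched_diffusion_coefficient(records, target_decay_time, alpha=1.0, scope=scope)
    base = DynamicsSpec.baseline(alpha_D)
    act = DynamicsSpec(
        diffusive=base.diffusive + (DiffusiveComponent(d_eq, scope),)
    )
    res = paired_contrast(records, base, act, scope=scope, mechanism="cell_motion_diffusive")
    return res


def contrast_hemodynamic(
    records: PhotonRecordSet,
    model: HemodynamicModel,
    window: MeasurementWindow,
    scope: str = GLOBAL,
    include_window_rate: Optional[bool] = None,
) -> ContrastResult:
    """Contrast from the blood volume/flow response at delay td.

    The activated state scales alpha_D by rCBF(td) — globally, or only for
    the activation-region component of the two-tissue decomposition.  The
    within-window linearization alpha_D*(1 + R_rCBF*tau) is off by default
    for td > 0 (orders of magnitude below the td effect) and on for td = 0,
    where it is the *only* effect.
    """
    if include_window_rate is None:
        include_window_rate = window.td == 0.0
    scale = float(model.rcbf(window.td))
    rate = within_window_rate(model, window) if include_window_rate else 0.0
    aD = model.alpha_D0
    base = DynamicsSpec.baseline(aD)
    if scope == GLOBAL:
        act = DynamicsSpec(
            diffusive=(DiffusiveComponent(aD * scale, GLOBAL, rate=rate),)
        )
    elif scope == LOCAL:
        act = DynamicsSpec.two_tissue(aD, aD * scale, rate_region=rate)
    else:
        raise ValueError("scope must be 'global' or 'local'")
    return paired_contrast(records, base, act, scope=scope, mechanism="hemodynamic")


def contrast_vessel_wall(
    records: PhotonRecordSet,
    model: HemodynamicModel,
    t: float,
    scope: str = GLOBAL,
) -> ContrastResult:
    """Contrast from the vessel-wall phase term alone (ballistic, alpha=alpha0).

    Evaluated at time t on the dilation time course; at the response peak the
    wall is momentarily stationary, so a rising-phase t probes the maximum
    effect.  This term is many orders of magnitude below the volume/flow
    effect and is ignored elsewhere.
    """
    v = abs(vessel_wall_speed(model, t))
    base = DynamicsSpec.baseline(model.alpha_D0)
    act = DynamicsSpec(
        diffusive=base.diffusive,
        ballistic=(BallisticComponent(v, model.alpha0, scope),),
    )
    return paired_contrast(records, base, act, scope=scope, mechanism="vessel_wall")


def td_sweep(
    records: PhotonRecordSet,
    model: HemodynamicModel,
    td_values: Optional[np.ndarray] = None,
    T: float = 0.01,
    scope: str = GLOBAL,
) -> tuple[np.ndarray, np.ndarray]:
    """Contrast as a function of measurement delay td (default 50 ms..2 s grid)."""
    if td_values is None:
        td_values = np.arange(1, 41) * 0.05
    td_values = np.asarray(td_values, dtype=float)
    out = np.empty_like(td_values)
    for i, td in enumerate(td_values):
        out[i] = contrast_hemodynamic(
            records, model, MeasurementWindow(td=float(td), T=T), scope=scope
        ).contrast
    return td_values, out
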