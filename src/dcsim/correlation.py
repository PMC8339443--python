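"""Field/intensity autocorrelation synthesis and decay-time estimation.

The field autocorrelation of multiply scattered light is built photon-by-photon
from the Monte Carlo tallies: each detected photon contributes

    g1_n(tau) = exp(-(1/3) * alpha * Y_n * k0^2 * <dr^2(tau)>) * exp(-mu_a L_n)

with <dr^2> = 6 D tau for diffusive scatterer motion (red blood cells) and
<dr^2> = v^2 tau^2 for ballistic motion (neuronal cell membranes, vessel
walls).  Every dynamics specification therefore reduces, per photon, to a
linear-plus-quadratic exponent a_n*tau + b_n*tau^2, which is what
:func:`g1_from_records` evaluates.  A two-tissue decomposition assigns
separate coefficients to momentum transfer accumulated inside the activation
region (Y2) and outside it (Y1 = Y - Y2).

The decay is summarized by a single time constant tau_c obtained from a
least-squares fit of exp(-tau/tau_c) over the early part of the curve (first
70 us by default, within the single-exponential validity window tau < tau_s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy.optimize import brentq

from .mc_transport import OpticalMedium, PhotonRecordSet

__all__ = [
    "GLOBAL",
    "LOCAL",
    "OUTSIDE",
    "DiffusiveComponent",
    "BallisticComponent",
    "DynamicsSpec",
    "G1Curve",
    "G2Curve",
    "DecayFit",
    "FitError",
    "g1_from_records",
    "g1_analytic_semiinf",
    "siegert",
    "fit_tau_c",
    "decay_time_1e",
    "tau_s_ratio",
    "default_tau_grid",
    "extended_tau_grid",
    "NM_PER_MS",
]

GLOBAL = "global"
LOCAL = "local"
OUTSIDE = "outside"

#: conversion factor from nm/ms (the natural unit for cell-membrane speeds)
#: to mm/s used internally.
NM_PER_MS = 1e-3  # 1 nm/ms = 1e-3 mm/s

DEFAULT_FIT_WINDOW_S = 70e-6
DEFAULT_BIN_TIME_S = 1e-6


def default_tau_grid(
    window: float = DEFAULT_FIT_WINDOW_S, bin_time: float = DEFAULT_BIN_TIME_S
) -> np.ndarray:
    """Linear tau grid 0..window with spacing ``bin_time`` (correlator bins)."""
    n = int(round(window / bin_time))
    return np.arange(n + 1) * bin_time


def extended_tau_grid(
    tau_max: float = 0.3, n: int = 600, tau_min: float = 1e-6
) -> np.ndarray:
    """Log-spaced grid (prepended with 0) for slowly decaying curves."""
    return np.concatenate([[0.0], np.geomspace(tau_min, tau_max, n)])


@dataclass(frozen=True)
class DiffusiveComponent:
    """Diffusive scatterer population: exponent 2 * alpha_D * k0^2 * Y * tau.

    ``alpha_D`` is the product of the scattering probability alpha and the
    effective diffusion coefficient D (mm^2/s) — the blood flow index.
    ``rate`` applies the within-window linearization alpha_D*(1 + rate*tau)
    used for measurements that start during a flow transient.
    """

    alpha_D: float
    scope: str = GLOBAL
    rate: float = 0.0  # s^-1

    def __post_init__(self) -> None:
        if self.alpha_D < 0:
            raise ValueError("alpha_D must be non-negative")
        if self.scope not in (GLOBAL, LOCAL, OUTSIDE):
            raise ValueError(f"unknown scope {self.scope!r}")


@dataclass(frozen=True)
class BallisticComponent:
    """Ballistic scatterer population: exponent (1/3)*alpha*k0^2*v^2*Y*tau^2."""

    v_nm_per_ms: float
    alpha: float = 1.0
    scope: str = GLOBAL

    def __post_init__(self) -> None:
        if self.v_nm_per_ms < 0:
            raise ValueError("speed must be non-negative")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("scattering probability must lie in [0, 1]")
        if self.scope not in (GLOBAL, LOCAL, OUTSIDE):
            raise ValueError(f"unknown scope {self.scope!r}")


@dataclass(frozen=True)
class DynamicsSpec:
    """Which scatterer populations move, and how.

    A baseline cerebral measurement is ``DynamicsSpec.baseline(alpha_D)``:
    one global diffusive blood component.  Activation states add ballistic
    components or re-scale the diffusive coefficient per scope.
    """

    diffusive: tuple[DiffusiveComponent, ...] = ()
    ballistic: tuple[BallisticComponent, ...] = ()

    @classmethod
    def baseline(cls, alpha_D: float = 1e-6) -> "DynamicsSpec":
        return cls(diffusive=(DiffusiveComponent(alpha_D, GLOBAL),))

    @classmethod
    def two_tissue(
        cls, alpha_D_outside: float, alpha_D_region: float, rate_region: float = 0.0
    ) -> "DynamicsSpec":
        """Separate blood dynamics outside vs inside the activation region."""
        return cls(
            diffusive=(
                DiffusiveComponent(alpha_D_outside, OUTSIDE),
                DiffusiveComponent(alpha_D_region, LOCAL, rate=rate_region),
            )
        )


@dataclass
class G1Curve:
    """Normalized field autocorrelation g1 on a tau grid."""

    tau: np.ndarray
    values: np.ndarray
    provenance: str = "mc"

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.tau.shape != self.values.shape:
            raise ValueError("tau and values must have the same shape")

    def to_tsv(self, path: str, metadata: Optional[dict] = None) -> None:
        _curve_to_tsv(path, "tau_s\tg1", self.tau, self.values, metadata)

    @classmethod
    def from_tsv(cls, path: str) -> "G1Curve":
        tau, vals = _curve_from_tsv(path)
        return cls(tau, vals, provenance="file")


@dataclass
class G2Curve:
    """Intensity autocorrelation g2 = 1 + beta*g1^2 (Siegert), possibly noisy."""

    tau: np.ndarray
    values: np.ndarray
    beta: float = 1.0

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.tau.shape != self.values.shape:
            raise ValueError("tau and values must have the same shape")

    def to_tsv(self, path: str, metadata: Optional[dict] = None) -> None:
        meta = dict(metadata or {})
        meta["beta"] = self.beta
        _curve_to_tsv(path, "tau_s\tg2", self.tau, self.values, meta)


@dataclass(frozen=True)
class DecayFit:
    """Result of the single-exponential decay-time fit."""

    tau_c: float
    fit_window: float
    residual_norm: float
    model: str  # "g1" or "g2"


class FitError(RuntimeError):
    """Raised when the decay-time fit cannot be performed (e.g. flat curve)."""


def _curve_to_tsv(path, colhdr, tau, values, metadata):
    import json

    with open(path, "w") as f:
        if metadata:
            f.write("# " + json.dumps(metadata) + "\n")
        f.write(f"# {colhdr}\n")
        for t, v in zip(tau, values):
            f.write(f"{t:.12g}\t{v:.17g}\n")


def _curve_from_tsv(path):
    data = np.loadtxt(path, comments="#", ndmin=2)
    return data[:, 0], data[:, 1]


# ---------------------------------------------------------------------------
# g1 synthesis
# ---------------------------------------------------------------------------


def _scope_Y(records: PhotonRecordSet, scope: str) -> np.ndarray:
    if scope == GLOBAL:
        return records.Y
    if scope == LOCAL:
        return records.Y2
    return records.Y - records.Y2


def g1_from_records(
    records: PhotonRecordSet,
    spec: DynamicsSpec,
    tau_grid: Optional[np.ndarray] = None,
    mu_a: Optional[float] = None,
) -> G1Curve:
    """Synthesize g1(tau) from photon tallies for a dynamics specification.

    Each photon contributes exp(-(a_n*tau + b_n*tau^2)) weighted by its
    survival factor exp(-mu_a*L_n); the curve is normalized to g1(0)=1
    (automatic, since every exponent vanishes at tau=0).
    """
    if records.n_detected == 0:
        raise ValueError("cannot synthesize g1 from an empty record set")
    if tau_grid is None:
        tau_grid = default_tau_grid()
    tau = np.asarray(tau_grid, dtype=float)
    if np.any(tau < 0):
        raise ValueError("correlation times must be non-negative")

    k02 = records.medium.k0**2
    w = records.weights(mu_a)

    a = np.zeros(records.n_detected)  # coefficient of tau
    b = np.zeros(records.n_detected)  # coefficient of tau^2
    for comp in spec.diffusive:
        Ys = _scope_Y(records, comp.scope)
        coeff = 2.0 * comp.alpha_D * k02  # (1/3)*k0^2*6D*alpha
        a = a + coeff * Ys
        if comp.rate != 0.0:
            b = b + coeff * comp.rate * Ys
    for comp in spec.ballistic:
        Ys = _scope_Y(records, comp.scope)
        v = comp.v_nm_per_ms * NM_PER_MS  # mm/s
        b = b + (comp.alpha * k02 * v * v / 3.0) * Ys

    expo = np.outer(a, tau) + np.outer(b, tau**2)
    vals = (w @ np.exp(-expo)) / w.sum()
    return G1Curve(tau, vals, provenance="mc")


def g1_analytic_semiinf(
    medium: OpticalMedium,
    rho: float,
    alpha_D: float,
    tau_grid: Optional[np.ndarray] = None,
) -> G1Curve:
    """Correlation-diffusion solution for a semi-infinite medium.

    g1(rho, tau) ~ exp(-K r1)/r1 - exp(-K r2)/r2 with
    K^2 = 3 mu_a mu_s' + 6 mu_s'^2 k0^2 alpha_D tau, r1 = (rho^2+z0^2)^1/2,
    r2 = (rho^2+(z0+2 zb)^2)^1/2; normalized to g1(0)=1.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    if alpha_D < 0:
        raise ValueError("alpha_D must be non-negative")
    if tau_grid is None:
        tau_grid = default_tau_grid()
    tau = np.asarray(tau_grid, dtype=float)
    if np.any(tau < 0):
        raise ValueError("correlation times must be non-negative")

    musp = medium.mu_s_prime
    k02 = medium.k0**2
    z0 = medium.z0
    zb = medium.zb
    r1 = math.sqrt(rho**2 + z0**2)
    r2 = math.sqrt(rho**2 + (z0 + 2 * zb) ** 2)

    def raw(t):
        K = np.sqrt(3.0 * medium.mu_a * musp + 6.0 * musp**2 * k02 * alpha_D * t)
        return np.exp(-K * r1) / r1 - np.exp(-K * r2) / r2

    vals = raw(tau) / raw(np.array(0.0))
    return G1Curve(tau, vals, provenance="analytic")


def siegert(g1: G1Curve, beta: float = 1.0) -> G2Curve:
    """Intensity autocorrelation via the Siegert relation g2 = 1 + beta*g1^2."""
    if not 0.0 < beta <= 1.0:
        raise ValueError("beta must lie in (0, 1]")
    return G2Curve(g1.tau, 1.0 + beta * g1.values**2, beta=beta)


# ---------------------------------------------------------------------------
# Decay-time estimation
# ---------------------------------------------------------------------------


def _fit_rate(tau: np.ndarray, y: np.ndarray, twofold: float, offset: float, amp: float):
    """Least-squares decay rate for y ~ offset + amp*exp(-twofold*theta*tau).

    One free parameter theta = 1/tau_c; solved by bracketing the stationarity
    condition of the sum of squares and bisecting to machine precision.
    """
    resid = y - offset

    def grad(theta):
        e = np.exp(-twofold * theta * tau)
        return float(np.sum((resid - amp * e) * tau * e))

    lo, hi = 1e-3, 1e3
    glo = grad(lo)
    if glo >= 0.0:
        # decay faster than 1 ms^-1 never bracketed from below -> widen down
        while lo > 1e-12 and grad(lo) >= 0.0:
            lo *= 1e-3
        glo = grad(lo)
        if glo >= 0.0:
            raise FitError("curve does not decay: no decay-rate bracket")
    ghi = grad(hi)
    while ghi <= 0.0:
        hi *= 10.0
        if hi > 1e13:
            raise FitError("no sign change for the decay-rate gradient")
        ghi = grad(hi)
    theta = brentq(grad, lo, hi, xtol=1e-30, rtol=1e-15, maxiter=300)
    e = np.exp(-twofold * theta * tau)
    rn = float(np.sqrt(np.sum((resid - amp * e) ** 2)))
    return theta, rn


def fit_tau_c(
    curve: Union[G1Curve, G2Curve],
    fit_window: float = DEFAULT_FIT_WINDOW_S,
) -> DecayFit:
    """Fit the decay time tau_c on tau <= fit_window.

    G1 input is fit with exp(-tau/tau_c); G2 input with 1 + beta*exp(-2tau/tau_c)
    (beta fixed at the curve's value).  Deterministic given the curve; a flat
    (non-decaying) curve raises :class:`FitError`.
    """
    mask = curve.tau <= fit_window * (1 + 1e-12)
    tau = curve.tau[mask]
    y = curve.values[mask]
    if tau.size < 3:
        raise FitError("fit window contains fewer than 3 samples")
    if isinstance(curve, G2Curve):
        theta, rn = _fit_rate(tau, y, 2.0, 1.0, curve.beta)
        model = "g2"
    else:
        theta, rn = _fit_rate(tau, y, 1.0, 0.0, 1.0)
        model = "g1"
    return DecayFit(tau_c=1.0 / theta, fit_window=fit_window, residual_norm=rn, model=model)


def decay_time_1e(curve: G1Curve) -> float:
    """First crossing of g1 below 1/e, by linear interpolation on the grid."""
    v = curve.values
    target = 1.0 / math.e
    below = np.nonzero(v < target)[0]
    if below.size == 0:
        raise FitError("curve does not decay below 1/e on this grid")
    i = below[0]
    if i == 0:
        raise FitError("curve starts below 1/e")
    t0, t1 = curve.tau[i - 1], curve.tau[i]
    v0, v1 = v[i - 1], v[i]
    return float(t0 + (v0 - target) / (v0 - v1) * (t1 - t0))


def tau_s_ratio(medium: OpticalMedium, rho: float) -> float:
    """Single-exponential validity ratio tau_s/tau_c.

    Computed as sqrt((3/4) mu_a mu_s' (rho^2 + (z0+zb)^2)); for the default
    cerebral parameter set (mu_a=0.01, mu_s'=1, rho=30) this evaluates to 2.6,
    so fitting exp(-tau/tau_c) over the first ~1.5 tau_c is well inside the
    validity window.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    z = medium.z0 + medium.zb
    return math.sqrt(0.75 * medium.mu_a * medium.mu_s_prime * (rho**2 + z**2))
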