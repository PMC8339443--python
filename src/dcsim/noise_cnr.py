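"""Analytical DCS noise model, noisy-g2 synthesis, and detectability analysis.

The correlator noise model gives the standard deviation of g2(tau)-1 at each
bin as a function of bin time Tb, measurement window T, coherence factor
beta, mean photon count per bin <n>, and decay rate Gamma = 1/tau_c:

    sigma(tau) = sqrt(Tb/T) * [ beta^2 * ((1+e^{-2 G Tb})(1+e^{-2 G tau})
                                 + 2 m (1-e^{-2 G Tb}) e^{-2 G tau}) / (1-e^{-2 G Tb})
                 + 2 <n>^-1 beta (1+e^{-2 G tau})
                 + <n>^-2 (1 + beta e^{-G tau}) ]^{1/2}

with m = tau/Tb the bin index.  Synthetic noisy g2 curves are generated by
adding independent zero-mean Gaussian perturbations of this magnitude to the
model curve g2-1 = beta*exp(-2*Gamma*tau); fitting each perturbed curve with
the exp(-tau/tau_c) form yields the noise-induced spread std(tau_c).
Averaging Nc independent channels reduces the noise to sigma/sqrt(Nc)
(central limit theorem), which is implemented by scaling sigma — equivalent
in distribution to averaging Nc synthetic channels and much cheaper.

Detectability: CNR = delta(tau_c)/std(tau_c) = C * SNR with C the relative
contrast and SNR = tau_c/std(tau_c); the channel count needed for CNR = 1 is
ceil((std_ratio/C)^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .correlation import G2Curve

__all__ = [
    "NoiseParams",
    "TauCDistribution",
    "DetectabilityResult",
    "sigma_g2",
    "generate_noisy_g2",
    "fit_noisy_g2_rates",
    "estimate_std_tau_c",
    "required_channels",
    "cnr",
    "earliest_detectable_delay",
]


@dataclass(frozen=True)
class NoiseParams:
    """Correlator noise parameters; Gamma = 1/tau_c in s^-1."""

    Tb: float = 1e-6  # bin time (s)
    T: float = 1e-2  # measurement window (s)
    beta: float = 1.0
    n_mean: float = 0.1  # photons per bin
    tau_c: float = 46e-6  # s

    def __post_init__(self) -> None:
        if self.Tb <= 0 or self.T < self.Tb:
            raise ValueError("need Tb > 0 and T >= Tb")
        if not 0.0 < self.beta <= 1.0:
            raise ValueError("beta must lie in (0, 1]")
        if self.n_mean <= 0 or self.tau_c <= 0:
            raise ValueError("n_mean and tau_c must be positive")

    @property
    def Gamma(self) -> float:
        return 1.0 / self.tau_c

    def bin_grid(self, fit_window: float = 70e-6) -> np.ndarray:
        """tau = m*Tb for m = 1..floor(window/Tb) (the correlator's bins)."""
        m_max = int(round(fit_window / self.Tb))
        return np.arange(1, m_max + 1) * self.Tb

    def model_g2_minus_1(self, tau: np.ndarray) -> np.ndarray:
        return self.beta * np.exp(-2.0 * self.Gamma * np.asarray(tau, dtype=float))


def sigma_g2(tau, params: NoiseParams) -> np.ndarray:
    """Standard deviation of g2(tau)-1 at correlation times tau = m*Tb, m >= 1."""
    tau = np.asarray(tau, dtype=float)
    m = tau / params.Tb
    m_round = np.round(m)
    if np.any(m_round < 1) or np.any(np.abs(m - m_round) > 1e-6 * np.maximum(m_round, 1)):
        raise ValueError("tau must be positive integer multiples of the bin time Tb")
    G = params.Gamma
    b = params.beta
    e_tb = math.exp(-2.0 * G * params.Tb)
    e_tau = np.exp(-2.0 * G * tau)
    speckle = b * b * ((1.0 + e_tb) * (1.0 + e_tau) + 2.0 * m_round * (1.0 - e_tb) * e_tau)
    speckle /= 1.0 - e_tb
    shot_cross = 2.0 / params.n_mean * b * (1.0 + e_tau)
    shot = (1.0 + b * np.exp(-G * tau)) / params.n_mean**2
    return np.sqrt(params.Tb / params.T) * np.sqrt(speckle + shot_cross + shot)


def generate_noisy_g2(
    params: NoiseParams,
    seed: int = 0,
    fit_window: float = 70e-6,
    nc: int = 1,
    noise_scale: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> G2Curve:
    """One synthetic noisy g2 curve on the bin grid.

    Independent Gaussian perturbations with std sigma(tau)/sqrt(nc) are added
    per bin; values may fall below 1 (no clipping).  ``noise_scale`` = 0
    returns the noiseless model curve.
    """
    if nc < 1:
        raise ValueError("nc must be >= 1")
    tau = params.bin_grid(fit_window)
    sig = sigma_g2(tau, params) * noise_scale / math.sqrt(nc)
    if rng is None:
        rng = np.random.default_rng(seed)
    vals = 1.0 + params.model_g2_minus_1(tau) + rng.standard_normal(tau.size) * sig
    return G2Curve(tau, vals, beta=params.beta)


@dataclass
class TauCDistribution:
    """Distribution of fitted decay times from an ensemble of noisy curves."""

    samples: np.ndarray
    nc: int
    n_requested: int
    n_failed: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.samples))

    @property
    def std(self) -> float:
        return float(np.std(self.samples, ddof=1)) if self.samples.size > 1 else 0.0

    @property
    def std_ratio(self) -> float:
        """std(tau_c)/mean(tau_c) — the single-channel noise floor on contrast."""
        return self.std / self.mean

    @property
    def discard_rate(self) -> float:
        return self.n_failed / self.n_requested if self.n_requested else 0.0


def fit_noisy_g2_rates(
    tau: np.ndarray, values: np.ndarray, beta: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized decay-rate fits for a batch of noisy g2 curves.

    ``values`` has shape (n_curves, n_bins).  Each curve is fit with
    1 + beta*exp(-2*theta*tau) (beta fixed, theta = 1/tau_c free) by bisecting
    the least-squares stationarity condition; curves whose gradient does not
    bracket a root (noise-dominated) are flagged as failed.
    Returns (theta, ok_mask).
    """
    y = values - 1.0  # (n, m)
    tau = np.asarray(tau, dtype=float)

    def grad(theta):
        e = np.exp(-2.0 * np.outer(theta, tau))  # (n, m)
        return ((y - beta * e) * (tau * e)).sum(axis=1)

    lo = np.full(y.shape[0], 1.0)
    hi = np.full(y.shape[0], 1e8)
    ok = (grad(lo) < 0.0) & (grad(hi) > 0.0)
    for _ in range(64):
        mid = 0.5 * (lo + hi)
        gm = grad(mid)
        high = gm > 0.0
        hi = np.where(high, mid, hi)
        lo = np.where(high, lo, mid)
    theta = 0.5 * (lo + hi)
    return theta, ok


def estimate_std_tau_c(
    params: NoiseParams,
    n_instances: int = 10_000,
    nc: int = 1,
    seed: int = 7,
    fit_window: float = 70e-6,
    noise_scale: float = 1.0,
) -> TauCDistribution:
    """Monte Carlo over noisy g2 curves: distribution of the fitted tau_c.

    The noise is scaled by 1/sqrt(nc) before generation to emulate averaging
    over nc independent channels.  Failed fits are discarded and counted.
    """
    if n_instances < 1:
        raise ValueError("n_instances must be >= 1")
    if nc < 1:
        raise ValueError("nc must be >= 1")
    tau = params.bin_grid(fit_window)
    sig = sigma_g2(tau, params) * noise_scale / math.sqrt(nc)
    rng = np.random.default_rng(seed)
    model = 1.0 + params.model_g2_minus_1(tau)
    values = model[None, :] + rng.standard_normal((n_instances, tau.size)) * sig[None, :]
    if noise_scale == 0.0:
        theta = np.full(n_instances, params.Gamma)
        ok = np.ones(n_instances, dtype=bool)
    else:
        theta, ok = fit_noisy_g2_rates(tau, values, params.beta)
    samples = 1.0 / theta[ok]
    return TauCDistribution(
        samples=samples,
        nc=nc,
        n_requested=n_instances,
        n_failed=int(n_instances - ok.sum()),
    )


def required_channels(contrast: float, std_ratio: float) -> int:
    """Smallest channel count with CNR >= 1: ceil((std_ratio/contrast)^2)."""
    if contrast <= 0:
        raise ValueError("contrast must be positive")
    if std_ratio <= 0:
        raise ValueError("std_ratio must be positive")
    return int(math.ceil((std_ratio / contrast) ** 2))


def cnr(contrast: float, std_ratio: float, nc: int = 1) -> float:
    """Contrast-to-noise ratio C*sqrt(Nc)/std_ratio."""
    return contrast * math.sqrt(nc) / std_ratio


@dataclass(frozen=True)
class DetectabilityResult:
    """Earliest detectable measurement delay for a given system SNR."""

    td: float  # s, after vessel-dilation onset
    t_after_activation: float  # s, after neuronal-activation onset
    contrast_at_td: float
    threshold: float


def earliest_detectable_delay(
    td_grid: Sequence[float],
    contrasts: Sequence[float],
    snr: float,
    onset_delay: float = 0.45,
) -> DetectabilityResult:
    """First delay on the grid where the contrast exceeds the noise floor 1/SNR."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    td_grid = np.asarray(td_grid, dtype=float)
    contrasts = np.asarray(contrasts, dtype=float)
    thresh = 1.0 / snr
    hits = np.nonzero(contrasts >= thresh)[0]
    if hits.size == 0:
        raise ValueError("activation is not detectable anywhere on this td grid")
    i = hits[0]
    return DetectabilityResult(
        td=float(td_grid[i]),
        t_after_activation=float(td_grid[i] + onset_delay),
        contrast_at_td=float(contrasts[i]),
        threshold=thresh,
    )
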