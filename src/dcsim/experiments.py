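"""Orchestration layer: named end-to-end experiments emitted as tables.

Each experiment reproduces one quantitative scenario of the study — baseline
calibration, hemodynamic peak contrast, cell-motion contrast, fast-onset
hemodynamics, the detectability sweep, the ballistic-vs-diffusive comparison,
and the noise chain — and returns machine-readable rows (list of dicts).
Outputs are deterministic for a fixed configuration and seed; TSV emission
carries the resolved configuration and its hash in `#` header lines.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .activation_models import (
    HemodynamicModel,
    MeasurementWindow,
    contrast_cell_motion,
    contrast_cell_motion_diffusive,
    contrast_hemodynamic,
    neuronal_only_decay_time,
    td_sweep,
)
from .correlation import (
    DynamicsSpec,
    default_tau_grid,
    fit_tau_c,
    g1_analytic_semiinf,
    g1_from_records,
    tau_s_ratio,
)
from .mc_transport import (
    ActivationRegion,
    DetectionGeometry,
    OpticalMedium,
    PhotonRecordSet,
    run_mc,
    save_records,
)
from .noise_cnr import (
    NoiseParams,
    earliest_detectable_delay,
    estimate_std_tau_c,
    required_channels,
)

__all__ = ["ExperimentConfig", "make_fixtures", "run_experiment", "write_table", "EXPERIMENTS"]

log = logging.getLogger("dcsim")

EXPERIMENTS = ("fig2", "fig7", "fig8", "fig9", "fig10", "fig11", "noise")


@dataclass(frozen=True)
class ExperimentConfig:
    """Fully resolved parameters for one experiment run."""

    experiment: str
    n_photons: int = 1_000_000
    seed: int = 1
    mc_seed: Optional[int] = None
    noise_seed: Optional[int] = None
    mu_s_prime: float = 1.0
    mu_a: float = 0.01
    wavelength_nm: float = 800.0
    rho: float = 30.0
    det_radius: float = 2.0
    alpha_D: float = 1e-6
    v_nm_per_ms: float = 1.0
    delta_d: float = 0.07
    sigma_d: float = 1.83
    snr: float = 300.0
    n_instances: int = 10_000
    beta: float = 1.0
    n_mean: float = 0.1
    Tb: float = 1e-6
    T: float = 1e-2
    tau_c_noise: float = 46e-6

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; choose from {EXPERIMENTS}"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(**d)

    def resolved(self) -> dict:
        d = asdict(self)
        d["mc_seed"] = self.mc_seed if self.mc_seed is not None else self.seed
        d["noise_seed"] = self.noise_seed if self.noise_seed is not None else self.seed + 1
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def medium(self) -> OpticalMedium:
        return OpticalMedium(self.mu_s_prime, self.mu_a, self.wavelength_nm)

    def geometry(self) -> DetectionGeometry:
        return DetectionGeometry(self.rho, self.det_radius)

    def hemodynamics(self) -> HemodynamicModel:
        return HemodynamicModel(
            delta_d=self.delta_d, sigma_d=self.sigma_d, alpha_D0=self.alpha_D
        )

    def noise_params(self) -> NoiseParams:
        return NoiseParams(self.Tb, self.T, self.beta, self.n_mean, self.tau_c_noise)


def make_fixtures(
    seed: int = 1,
    n_photons: int = 1_000_000,
    out_dir: str = "fixtures",
    config: Optional[ExperimentConfig] = None,
) -> dict[str, Path]:
    """Run a small seeded MC and cache the photon records (HDF5 + TSV).

    The cached record set carries the default cerebral parameter set
    (rho=30 mm, mu_s'=1 mm^-1, mu_a=0.01 mm^-1, lambda=800 nm) and the local
    activation region, so all downstream analyses can run without re-tracing.
    """
    cfg = config or ExperimentConfig("fig2", n_photons=n_photons, seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    rec = run_mc(cfg.medium(), cfg.geometry(), ActivationRegion(), n_photons, seed)
    log.info(
        "fixture MC: %d launched, %d detected in %.1f s",
        n_photons,
        rec.n_detected,
        time.perf_counter() - t0,
    )
    paths = {}
    for ext in ("h5", "tsv"):
        p = out / f"records_seed{seed}_n{n_photons}.{ext}"
        save_records(rec, str(p))
        paths[ext] = p
    return paths


def _get_records(cfg: ExperimentConfig, records: Optional[PhotonRecordSet]) -> PhotonRecordSet:
    if records is not None:
        return records
    mc_seed = cfg.mc_seed if cfg.mc_seed is not None else cfg.seed
    t0 = time.perf_counter()
    rec = run_mc(cfg.medium(), cfg.geometry(), ActivationRegion(), cfg.n_photons, mc_seed)
    log.info(
        "MC: %d launched, %d detected, %.1f s",
        cfg.n_photons,
        rec.n_detected,
        time.perf_counter() - t0,
    )
    return rec


def run_experiment(
    cfg: ExperimentConfig, records: Optional[PhotonRecordSet] = None
) -> list[dict]:
    """Run one named experiment; returns rows of (quantity, scope, value, ...)."""
    name = cfg.experiment
    rows: list[dict] = []

    if name == "fig2":
        rec = _get_records(cfg, records)
        grid = default_tau_grid()
        g_mc = g1_from_records(rec, DynamicsSpec.baseline(cfg.alpha_D), grid)
        g_an = g1_analytic_semiinf(cfg.medium(), cfg.rho, cfg.alpha_D, grid)
        tc_mc = fit_tau_c(g_mc).tau_c
        tc_an = fit_tau_c(g_an).tau_c
        cmp_mask = grid <= 3 * tc_mc
        rows += [
            {"quantity": "tau_c_mc_us", "value": tc_mc * 1e6},
            {"quantity": "tau_c_analytic_us", "value": tc_an * 1e6},
            {"quantity": "max_abs_dg1", "value": float(np.max(np.abs(g_mc.values - g_an.values)[cmp_mask]))},
            {"quantity": "tau_s_over_tau_c", "value": tau_s_ratio(cfg.medium(), cfg.rho)},
            {"quantity": "n_detected", "value": rec.n_detected},
        ]

    elif name == "fig7":
        rec = _get_records(cfg, records)
        model = cfg.hemodynamics()
        peak = model.peak_time()
        std_ratio = estimate_std_tau_c(
            cfg.noise_params(),
            n_instances=cfg.n_instances,
            seed=cfg.noise_seed if cfg.noise_seed is not None else cfg.seed + 1,
        ).std_ratio
        for scope in ("global", "local"):
            res = contrast_hemodynamic(
                rec, model, MeasurementWindow(td=peak, T=cfg.T), scope=scope
            )
            rows.append(
                {
                    "quantity": "hemodynamic_peak_contrast",
                    "scope": scope,
                    "td_s": peak,
                    "contrast": res.contrast,
                    "tau_c_baseline_us": res.tau_c_baseline * 1e6,
                    "tau_c_activated_us": res.tau_c_activated * 1e6,
                    "nc_required": required_channels(res.contrast, std_ratio),
                }
            )

    elif name == "fig8":
        rec = _get_records(cfg, records)
        std_ratio = estimate_std_tau_c(
            cfg.noise_params(),
            n_instances=cfg.n_instances,
            seed=cfg.noise_seed if cfg.noise_seed is not None else cfg.seed + 1,
        ).std_ratio
        for scope in ("global", "local"):
            res = contrast_cell_motion(
                rec, cfg.v_nm_per_ms, alpha_neuronal=1.0, scope=scope, alpha_D=cfg.alpha_D
            )
            rows.append(
                {
                    "quantity": "cell_motion_contrast",
                    "scope": scope,
                    "contrast": res.contrast,
                    "tau_c_baseline_us": res.tau_c_baseline * 1e6,
                    "tau_c_activated_us": res.tau_c_activated * 1e6,
                    "nc_required": required_channels(res.contrast, std_ratio),
                }
            )

    elif name == "fig9":
        rec = _get_records(cfg, records)
        model = cfg.hemodynamics()
        for scope in ("global", "local"):
            for T in (0.01, 0.1):
                res = contrast_hemodynamic(
                    rec, model, MeasurementWindow(td=0.0, T=T), scope=scope
                )
                rows.append(
                    {
                        "quantity": "fast_hemodynamic_contrast",
                        "scope": scope,
                        "T_s": T,
                        "contrast": res.contrast,
                    }
                )

    elif name == "fig10":
        rec = _get_records(cfg, records)
        model = cfg.hemodynamics()
        std_ratio = estimate_std_tau_c(
            cfg.noise_params(),
            n_instances=cfg.n_instances,
            seed=cfg.noise_seed if cfg.noise_seed is not None else cfg.seed + 1,
        ).std_ratio
        for scope in ("global", "local"):
            td, C = td_sweep(rec, model, T=cfg.T, scope=scope)
            for t, c in zip(td, C):
                rows.append(
                    {
                        "quantity": "td_sweep",
                        "scope": scope,
                        "td_s": float(t),
                        "contrast": float(c),
                        "nc_required": required_channels(float(c), std_ratio) if c > 0 else -1,
                    }
                )
            try:
                det = earliest_detectable_delay(td, C, cfg.snr, model.onset_delay)
                rows.append(
                    {
                        "quantity": "earliest_detectable_td",
                        "scope": scope,
                        "td_s": det.td,
                        "t_after_activation_s": det.t_after_activation,
                        "contrast": det.contrast_at_td,
                    }
                )
            except ValueError:
                rows.append(
                    {"quantity": "earliest_detectable_td", "scope": scope, "td_s": -1.0}
                )

    elif name == "fig11":
        rec = _get_records(cfg, records)
        grid = default_tau_grid()
        tc_base = fit_tau_c(g1_from_records(rec, DynamicsSpec.baseline(cfg.alpha_D), grid)).tau_c
        dec = neuronal_only_decay_time(rec, cfg.v_nm_per_ms)
        res_diff = contrast_cell_motion_diffusive(rec, target_decay_time=dec["t_1e"], alpha_D=cfg.alpha_D)
        res_ball = contrast_cell_motion(rec, cfg.v_nm_per_ms, alpha_D=cfg.alpha_D)
        rows += [
            {"quantity": "tau_c_baseline_us", "value": tc_base * 1e6},
            {"quantity": "neuronal_decay_1e_ms", "value": dec["t_1e"] * 1e3},
            {"quantity": "neuronal_decay_fit_ms", "value": dec["t_fit"] * 1e3},
            {"quantity": "decay_time_ratio", "value": dec["t_1e"] / tc_base},
            {"quantity": "contrast_ballistic", "value": res_ball.contrast},
            {"quantity": "contrast_diffusive_equivalent", "value": res_diff.contrast},
        ]

    elif name == "noise":
        params = cfg.noise_params()
        seed = cfg.noise_seed if cfg.noise_seed is not None else cfg.seed + 1
        for nc in (1, 4, 16, 64):
            dist = estimate_std_tau_c(params, n_instances=cfg.n_instances, nc=nc, seed=seed + nc)
            rows.append(
                {
                    "quantity": "std_tau_c",
                    "nc": nc,
                    "mean_tau_c_us": dist.mean * 1e6,
                    "std_tau_c_us": dist.std * 1e6,
                    "std_ratio": dist.std_ratio,
                    "discard_rate": dist.discard_rate,
                }
            )

    return rows


def write_table(rows: list[dict], path: str, cfg: Optional[ExperimentConfig] = None) -> None:
    """Emit rows as a TSV table with resolved-config provenance headers."""
    keys: list[str] = []
    for row in rows:
        for k in row:
            if k not in keys:
                keys.append(k)
    with open(path, "w") as f:
        if cfg is not None:
            f.write("# config: " + json.dumps(cfg.resolved(), sort_keys=True) + "\n")
            f.write(f"# config_hash: {cfg.config_hash()}\n")
        f.write("\t".join(keys) + "\n")
        for row in rows:
            f.write("\t".join(_fmt(row.get(k, "")) for k in keys) + "\n")


def _fmt(v) -> str:
    if isinstance(v, float):
        return format(v, ".10g")
    return str(v)
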