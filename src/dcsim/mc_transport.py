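"""Photon-migration Monte Carlo in a semi-infinite dynamic scattering medium.

A pencil beam enters a homogeneous half-space (z > 0) at the origin, directed
into the medium.  Photons random-walk with exponentially distributed free
paths (mean 1/mu_s) and isotropic scattering (g = 0, so mu_s == mu_s_prime).
Absorption is *not* applied during transport; each detected photon instead
carries its total pathlength L so that the correlation layer can weight it by
exp(-mu_a * L) afterwards.  At every scattering event the dimensionless
momentum transfer q^2 / 2 k0^2 = 1 - cos(theta) is accumulated into Y; the
same tallies restricted to a localized activation region give (L2, Y2).

Photons hitting the surface undergo unpolarized Fresnel reflection (internal
relative index ``n_rel``); transmitted photons exiting through a detector disk
of radius ``r`` centred a distance ``rho`` from the source are recorded, all
exit angles accepted.  Transport is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

__all__ = [
    "OpticalMedium",
    "DetectionGeometry",
    "ActivationRegion",
    "PhotonRecordSet",
    "run_mc",
    "save_records",
    "load_records",
    "RecordFormatError",
    "diffusion_reflectance",
    "disk_integrated_reflectance",
    "effective_boundary_parameter",
    "n_rel_for_boundary_parameter",
    "sample_scattering_deflections",
    "DEFAULT_N_REL",
    "DEFAULT_MAX_PATHLENGTH_MM",
]

FORMAT_VERSION = 1

# Relative refractive index whose Fresnel-averaged effective reflectance gives
# an extrapolated-boundary parameter A ~= 2.5, matching zb = (5/3)/mu_s' in the
# correlation-diffusion benchmark.  See n_rel_for_boundary_parameter().
DEFAULT_N_REL = 1.3274

# Fixed transport cutoff.  Chosen so the neglected survival weight
# exp(-mu_a * L) is below 1e-6 at the default mu_a = 0.01 mm^-1; kept
# independent of mu_a so that transport records do not depend on absorption.
DEFAULT_MAX_PATHLENGTH_MM = 1400.0

_CHUNK = 1_000_000  # photons per kernel call; fixed so results are chunk-stable


@dataclass(frozen=True)
class OpticalMedium:
    """Homogeneous semi-infinite tissue optical properties.

    Parameters
    ----------
    mu_s_prime : float
        Reduced scattering coefficient (mm^-1).  With isotropic scattering the
        scattering coefficient equals ``mu_s_prime``.
    mu_a : float
        Absorption coefficient (mm^-1), applied post hoc as exp(-mu_a L).
    wavelength_nm : float
        Vacuum wavelength in nm; the wavenumber k0 = 2*pi/lambda (mm^-1).
    n_rel : float
        Relative refractive index medium/outside at the surface.
    """

    mu_s_prime: float = 1.0
    mu_a: float = 0.01
    wavelength_nm: float = 800.0
    n_rel: float = DEFAULT_N_REL

    def __post_init__(self) -> None:
        if self.mu_s_prime <= 0:
            raise ValueError("mu_s_prime must be positive")
        if self.mu_a < 0:
            raise ValueError("mu_a must be non-negative")
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        if self.n_rel < 1.0:
            raise ValueError("n_rel below 1 not supported")

    @property
    def k0(self) -> float:
        """Wavenumber in mm^-1."""
        return 2.0 * math.pi / (self.wavelength_nm * 1e-6)

    @property
    def z0(self) -> float:
        """Depth of the effective isotropic source, 1/mu_s' (mm)."""
        return 1.0 / self.mu_s_prime

    @property
    def zb(self) -> float:
        """Extrapolated boundary distance (5/3)/mu_s' (mm), i.e. A = 2.5."""
        return (5.0 / 3.0) / self.mu_s_prime


@dataclass(frozen=True)
class DetectionGeometry:
    """Source-detector layout on the surface z = 0.

    The source is at the origin; the detector is a disk of radius ``radius``
    centred at (rho, 0, 0).  All exit angles are accepted (NA = 1).
    """

    rho: float = 30.0
    radius: float = 2.0

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.radius <= 0:
            raise ValueError("rho and radius must be positive")


@dataclass(frozen=True)
class ActivationRegion:
    """Axis-aligned box inside the medium where local tallies accumulate."""

    x: tuple[float, float] = (10.0, 20.0)
    y: tuple[float, float] = (-5.0, 5.0)
    z: tuple[float, float] = (13.0, 17.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.x, self.y, self.z):
            if not hi > lo:
                raise ValueError("region extents must be positive")
        if self.z[0] < 0:
            raise ValueError("region must lie inside the medium (z >= 0)")

    @classmethod
    def centered(
        cls,
        center: tuple[float, float, float] = (15.0, 0.0, 15.0),
        size: tuple[float, float, float] = (10.0, 10.0, 4.0),
    ) -> "ActivationRegion":
        cx, cy, cz = center
        sx, sy, sz = size
        return cls(
            x=(cx - sx / 2, cx + sx / 2),
            y=(cy - sy / 2, cy + sy / 2),
            z=(cz - sz / 2, cz + sz / 2),
        )

    @classmethod
    def whole_medium(cls, extent: float = 1e9) -> "ActivationRegion":
        """Degenerate region covering the entire half-space (forces L2=L, Y2=Y)."""
        return cls(x=(-extent, extent), y=(-extent, extent), z=(0.0, extent))


@dataclass
class PhotonRecordSet:
    """Tallies for every detected photon plus full provenance metadata.

    Attributes
    ----------
    L, Y : ndarray
        Total pathlength (mm) and accumulated dimensionless momentum transfer.
    L2, Y2 : ndarray
        The same tallies restricted to the activation region.
    """

    L: np.ndarray
    Y: np.ndarray
    L2: np.ndarray
    Y2: np.ndarray
    medium: OpticalMedium
    geometry: DetectionGeometry
    region: ActivationRegion
    n_launched: int
    seed: int
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.L)
        if not (len(self.Y) == len(self.L2) == len(self.Y2) == n):
            raise ValueError("tally arrays must have equal length")

    def __len__(self) -> int:
        return len(self.L)

    @property
    def n_detected(self) -> int:
        return len(self.L)

    @property
    def detected_fraction(self) -> float:
        return self.n_detected / self.n_launched if self.n_launched else 0.0

    def weights(self, mu_a: Optional[float] = None) -> np.ndarray:
        """Survival weights exp(-mu_a L); defaults to the medium's mu_a."""
        if mu_a is None:
            mu_a = self.medium.mu_a
        return np.exp(-mu_a * self.L)

    def metadata_dict(self) -> dict:
        return {
            "format_version": FORMAT_VERSION,
            "medium": {
                "mu_s_prime": self.medium.mu_s_prime,
                "mu_a": self.medium.mu_a,
                "wavelength_nm": self.medium.wavelength_nm,
                "n_rel": self.medium.n_rel,
            },
            "geometry": {"rho": self.geometry.rho, "radius": self.geometry.radius},
            "region": {
                "x": list(self.region.x),
                "y": list(self.region.y),
                "z": list(self.region.z),
            },
            "n_launched": self.n_launched,
            "n_detected": self.n_detected,
            "seed": self.seed,
            "extra": self.extra,
        }

    @classmethod
    def from_arrays_and_metadata(cls, data: np.ndarray, meta: dict) -> "PhotonRecordSet":
        if meta.get("format_version") != FORMAT_VERSION:
            raise RecordFormatError(
                f"unsupported record format version {meta.get('format_version')!r}"
            )
        m = meta["medium"]
        g = meta["geometry"]
        r = meta["region"]
        return cls(
            L=np.ascontiguousarray(data[:, 0]),
            Y=np.ascontiguousarray(data[:, 1]),
            L2=np.ascontiguousarray(data[:, 2]),
            Y2=np.ascontiguousarray(data[:, 3]),
            medium=OpticalMedium(m["mu_s_prime"], m["mu_a"], m["wavelength_nm"], m["n_rel"]),
            geometry=DetectionGeometry(g["rho"], g["radius"]),
            region=ActivationRegion(tuple(r["x"]), tuple(r["y"]), tuple(r["z"])),
            n_launched=int(meta["n_launched"]),
            seed=int(meta["seed"]),
            extra=dict(meta.get("extra", {})),
        )


class RecordFormatError(RuntimeError):
    """Raised when a photon-record file is corrupted or of an unknown version."""


# ---------------------------------------------------------------------------
# Compiled kernel
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always", fastmath=True)
def _fresnel_unpolarized(ci: float, n_rel: float) -> float:
    """Unpolarized Fresnel reflectance, internal incidence cosine ci, n_in/n_out=n_rel."""
    si2 = 1.0 - ci * ci
    st2 = n_rel * n_rel * si2
    if st2 >= 1.0:
        return 1.0  # total internal reflection
    ct = math.sqrt(1.0 - st2)
    rs = (n_rel * ci - ct) / (n_rel * ci + ct)
    rp = (ci - n_rel * ct) / (ci + n_rel * ct)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, inline="always", fastmath=True)
def _segment_in_box(
    x, y, z, ux, uy, uz, s, bx0, bx1, by0, by1, bz0, bz1
):
    """Length of the segment p -> p + u*s lying inside the axis-aligned box."""
    tmin = 0.0
    tmax = s
    # x slab
    if ux == 0.0:
        if x < bx0 or x > bx1:
            return 0.0
    else:
        t1 = (bx0 - x) / ux
        t2 = (bx1 - x) / ux
        if t1 > t2:
            t1, t2 = t2, t1
        if t1 > tmin:
            tmin = t1
        if t2 < tmax:
            tmax = t2
    # y slab
    if uy == 0.0:
        if y < by0 or y > by1:
            return 0.0
    else:
        t1 = (by0 - y) / uy
        t2 = (by1 - y) / uy
        if t1 > t2:
            t1, t2 = t2, t1
        if t1 > tmin:
            tmin = t1
        if t2 < tmax:
            tmax = t2
    # z slab
    if uz == 0.0:
        if z < bz0 or z > bz1:
            return 0.0
    else:
        t1 = (bz0 - z) / uz
        t2 = (bz1 - z) / uz
        if t1 > t2:
            t1, t2 = t2, t1
        if t1 > tmin:
            tmin = t1
        if t2 < tmax:
            tmax = t2
    if tmax > tmin:
        return tmax - tmin
    return 0.0


@njit(cache=True, fastmath=True)
def _mc_kernel(
    n_photons,
    mu_s,
    n_rel,
    rho,
    det_r,
    bx0,
    bx1,
    by0,
    by1,
    bz0,
    bz1,
    l_max,
    seed,
    out,
):
    """Trace n_photons; write detected tallies (L, Y, L2, Y2) into ``out``.

    Returns the number of detected photons (may exceed out.shape[0], in which
    case the caller must re-run with a larger buffer; the RNG stream is a pure
    function of the seed so a re-run is identical).

    Photons whose *minimum possible* remaining path to the detector disk
    exceeds the pathlength budget are terminated early: they can never be
    recorded, and a surface exit outside the detector terminates a photon
    anyway, so the pruning is exact.
    """
    np.random.seed(seed)
    count = 0
    cap = out.shape[0]
    det_r2 = det_r * det_r
    for _ in range(n_photons):
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        L = 0.0
        Y = 0.0
        L2 = 0.0
        Y2 = 0.0
        alive = True
        while alive:
            s = -math.log(np.random.random()) / mu_s
            # a flight may touch the surface at most once before re-entering
            while True:
                if uz < 0.0:
                    sb = -z / uz
                    if sb <= s:
                        L += sb
                        # division-free reject before the full slab clip
                        x1 = x + ux * sb
                        y1 = y + uy * sb
                        if not (
                            (z < bz0)  # endpoint z == 0 < bz0 always
                            or (x < bx0 and x1 < bx0)
                            or (x > bx1 and x1 > bx1)
                            or (y < by0 and y1 < by0)
                            or (y > by1 and y1 > by1)
                        ):
                            L2 += _segment_in_box(
                                x, y, z, ux, uy, uz, sb, bx0, bx1, by0, by1, bz0, bz1
                            )
                        x = x1
                        y = y1
                        z = 0.0
                        if np.random.random() < _fresnel_unpolarized(-uz, n_rel):
                            uz = -uz
                            s -= sb
                            continue
                        dx = x - rho
                        if dx * dx + y * y <= det_r2:
                            if count < cap:
                                out[count, 0] = L
                                out[count, 1] = Y
                                out[count, 2] = L2
                                out[count, 3] = Y2
                            count += 1
                        alive = False
                        break
                L += s
                x1 = x + ux * s
                y1 = y + uy * s
                z1 = z + uz * s
                if not (
                    (z < bz0 and z1 < bz0)
                    or (z > bz1 and z1 > bz1)
                    or (x < bx0 and x1 < bx0)
                    or (x > bx1 and x1 > bx1)
                    or (y < by0 and y1 < by0)
                    or (y > by1 and y1 > by1)
                ):
                    L2 += _segment_in_box(
                        x, y, z, ux, uy, uz, s, bx0, bx1, by0, by1, bz0, bz1
                    )
                x = x1
                y = y1
                z = z1
                break
            if not alive:
                break
            # exact pruning: min distance from (x,y,z) to the detector disk
            rem = l_max - L
            if rem <= 0.0:
                break
            dx = x - rho
            rr = dx * dx + y * y
            if rr > det_r2:
                ex = math.sqrt(rr) - det_r
                if ex * ex + z * z > rem * rem:
                    break
            elif z > rem:
                break
            # isotropic scattering via Marsaglia's method
            while True:
                a = 2.0 * np.random.random() - 1.0
                b = 2.0 * np.random.random() - 1.0
                q = a * a + b * b
                if q < 1.0:
                    break
            root = 2.0 * math.sqrt(1.0 - q)
            nx = a * root
            ny = b * root
            nz = 1.0 - 2.0 * q
            dY = 1.0 - (ux * nx + uy * ny + uz * nz)
            Y += dY
            if bx0 <= x <= bx1 and by0 <= y <= by1 and bz0 <= z <= bz1:
                Y2 += dY
            ux = nx
            uy = ny
            uz = nz
    return count


@njit(cache=True, fastmath=True)
def _deflection_kernel(n, seed, out):
    """Sample 1 - cos(theta) deflections exactly as the transport kernel does."""
    np.random.seed(seed)
    ux = 0.0
    uy = 0.0
    uz = 1.0
    for i in range(n):
        while True:
            a = 2.0 * np.random.random() - 1.0
            b = 2.0 * np.random.random() - 1.0
            q = a * a + b * b
            if q < 1.0:
                break
        root = 2.0 * math.sqrt(1.0 - q)
        nx = a * root
        ny = b * root
        nz = 1.0 - 2.0 * q
        out[i] = 1.0 - (ux * nx + uy * ny + uz * nz)
        ux = nx
        uy = ny
        uz = nz


def sample_scattering_deflections(n: int, seed: int = 0) -> np.ndarray:
    """Per-event momentum-transfer increments q^2/2k0^2 = 1-cos(theta).

    Uses the same direction sampler as the transport kernel along a chain of
    scattering events; for isotropic scattering the analytic mean is exactly 1.
    """
    out = np.empty(n, dtype=np.float64)
    _deflection_kernel(n, seed, out)
    return out


def _chunk_seed(seed: int, chunk: int) -> int:
    return (seed + 1_000_003 * (chunk + 1)) % 2_147_483_647


def run_mc(
    medium: OpticalMedium,
    geometry: DetectionGeometry,
    region: Optional[ActivationRegion] = None,
    n_photons: int = 1_000_000,
    seed: int = 1,
    max_pathlength: float = DEFAULT_MAX_PATHLENGTH_MM,
) -> PhotonRecordSet:
    """Run the transport Monte Carlo and return per-detected-photon tallies.

    Absorption is handled post hoc (records are independent of ``medium.mu_a``
    except through metadata).  ``n_photons == 0`` yields a valid empty set.
    Photons are traced in fixed chunks of 10^6 with per-chunk seeds derived
    from ``seed``, so output is reproducible and independent of buffer sizes.
    """
    if region is None:
        region = ActivationRegion()
    if n_photons < 0:
        raise ValueError("n_photons must be non-negative")
    if max_pathlength <= 0:
        raise ValueError("max_pathlength must be positive")

    mu_s = medium.mu_s_prime  # g = 0
    chunks = []
    remaining = int(n_photons)
    chunk_idx = 0
    while remaining > 0:
        n_chunk = min(_CHUNK, remaining)
        cap = max(1024, int(n_chunk * 3e-4) + 256)
        cseed = _chunk_seed(seed, chunk_idx)
        while True:
            buf = np.empty((cap, 4), dtype=np.float64)
            n_det = _mc_kernel(
                n_chunk,
                mu_s,
                medium.n_rel,
                geometry.rho,
                geometry.radius,
                region.x[0],
                region.x[1],
                region.y[0],
                region.y[1],
                region.z[0],
                region.z[1],
                max_pathlength,
                cseed,
                buf,
            )
            if n_det <= cap:
                break
            cap = n_det + 64  # identical RNG stream; re-run losslessly
        chunks.append(buf[:n_det].copy())
        remaining -= n_chunk
        chunk_idx += 1

    if chunks:
        data = np.concatenate(chunks, axis=0)
    else:
        data = np.empty((0, 4), dtype=np.float64)
    return PhotonRecordSet(
        L=np.ascontiguousarray(data[:, 0]),
        Y=np.ascontiguousarray(data[:, 1]),
        L2=np.ascontiguousarray(data[:, 2]),
        Y2=np.ascontiguousarray(data[:, 3]),
        medium=medium,
        geometry=geometry,
        region=region,
        n_launched=int(n_photons),
        seed=int(seed),
        extra={"max_pathlength_mm": max_pathlength},
    )


# ---------------------------------------------------------------------------
# Persistence: HDF5 container and a plain TSV dialect
# ---------------------------------------------------------------------------


def save_records(records: PhotonRecordSet, path: str) -> None:
    """Save a record set; format chosen by extension (.h5/.hdf5 or .tsv/.txt)."""
    path = str(path)
    data = np.column_stack([records.L, records.Y, records.L2, records.Y2])
    meta = records.metadata_dict()
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "w") as f:
            dset = f.create_dataset(
                "records", data=data, compression="gzip", compression_opts=4
            )
            dset.attrs["columns"] = "L Y L2 Y2"
            f.attrs["dcsim_metadata"] = json.dumps(meta)
            f.attrs["format_version"] = FORMAT_VERSION
    else:
        with open(path, "w") as f:
            f.write(f"# dcsim photon records v{FORMAT_VERSION}\n")
            f.write("# " + json.dumps(meta) + "\n")
            f.write("# L\tY\tL2\tY2\n")
            for row in data:
                f.write(
                    "\t".join(format(v, ".17g") for v in row) + "\n"
                )


def load_records(path: str) -> PhotonRecordSet:
    """Load a record set saved by :func:`save_records`."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        try:
            with h5py.File(path, "r") as f:
                meta = json.loads(f.attrs["dcsim_metadata"])
                data = np.asarray(f["records"], dtype=np.float64)
        except (OSError, KeyError, json.JSONDecodeError) as exc:
            raise RecordFormatError(f"cannot read record file {path!r}: {exc}") from exc
    else:
        try:
            with open(path) as f:
                header = f.readline()
                if not header.startswith(f"# dcsim photon records v{FORMAT_VERSION}"):
                    raise RecordFormatError(
                        f"unrecognized record header in {path!r}: {header!r}"
                    )
                meta_line = f.readline()
                if not meta_line.startswith("# "):
                    raise RecordFormatError(f"missing metadata line in {path!r}")
                meta = json.loads(meta_line[2:])
                cols = f.readline()
                if "L\tY\tL2\tY2" not in cols:
                    raise RecordFormatError(f"missing column header in {path!r}")
                body = f.read().strip()
                if body:
                    data = np.loadtxt(body.splitlines(), dtype=np.float64, ndmin=2)
                else:
                    data = np.empty((0, 4), dtype=np.float64)
        except RecordFormatError:
            raise
        except (OSError, ValueError, json.JSONDecodeError) as exc:
            raise RecordFormatError(f"cannot read record file {path!r}: {exc}") from exc
    if data.ndim != 2 or data.shape[1] != 4:
        raise RecordFormatError(f"record table in {path!r} is not 4 columns")
    rec = PhotonRecordSet.from_arrays_and_metadata(data, meta)
    if rec.n_detected != meta.get("n_detected"):
        raise RecordFormatError(
            f"record count mismatch in {path!r}: "
            f"{rec.n_detected} rows vs metadata {meta.get('n_detected')}"
        )
    return rec


# ---------------------------------------------------------------------------
# Diffusion-theory benchmarks
# ---------------------------------------------------------------------------


def diffusion_reflectance(medium: OpticalMedium, rho: np.ndarray | float) -> np.ndarray:
    """Steady-state spatially resolved diffuse reflectance R(rho) (mm^-2).

    Two-source extrapolated-boundary solution for a semi-infinite medium with
    z0 = 1/mu_s' and zb = (5/3)/mu_s'; serves as the independent check on the
    absorption-weighted detected fraction of the Monte Carlo.
    """
    rho = np.asarray(rho, dtype=float)
    mu_eff = math.sqrt(3.0 * medium.mu_a * medium.mu_s_prime)
    z0 = medium.z0
    zb = medium.zb
    r1 = np.sqrt(rho**2 + z0**2)
    r2 = np.sqrt(rho**2 + (z0 + 2 * zb) ** 2)
    term1 = z0 * (mu_eff + 1.0 / r1) * np.exp(-mu_eff * r1) / r1**2
    term2 = (z0 + 2 * zb) * (mu_eff + 1.0 / r2) * np.exp(-mu_eff * r2) / r2**2
    return (term1 + term2) / (4.0 * math.pi)


def disk_integrated_reflectance(
    medium: OpticalMedium, geometry: DetectionGeometry, n_quad: int = 64
) -> float:
    """R(rho) integrated over the detector disk (dimensionless fraction)."""
    from scipy.integrate import fixed_quad

    rho0, a = geometry.rho, geometry.radius

    def integrand(r):
        r = np.atleast_1d(r)
        # average over the azimuth of the disk at offset r from its centre
        th = np.linspace(0.0, math.pi, 181)
        vals = np.empty_like(r)
        for i, ri in enumerate(r):
            d = np.sqrt(rho0**2 + ri**2 + 2 * rho0 * ri * np.cos(th))
            vals[i] = np.trapezoid(diffusion_reflectance(medium, d), th) / math.pi
        return 2.0 * math.pi * r * vals

    val, _ = fixed_quad(integrand, 0.0, a, n=n_quad)
    return float(val)


def effective_boundary_parameter(n_rel: float) -> float:
    """Extrapolation parameter A = (1+R_eff)/(1-R_eff) for a given n_rel.

    R_eff combines the fluence- and flux-weighted Fresnel integrals
    (R_phi = int 2 mu R(mu) dmu, R_j = int 3 mu^2 R(mu) dmu).
    """
    from scipy.integrate import quad

    def rf(mu):
        return _fresnel_unpolarized.py_func(mu, n_rel)

    r_phi, _ = quad(lambda m: 2.0 * m * rf(m), 0.0, 1.0, limit=200)
    r_j, _ = quad(lambda m: 3.0 * m * m * rf(m), 0.0, 1.0, limit=200)
    r_eff = (r_phi + r_j) / (2.0 - r_phi + r_j)
    return (1.0 + r_eff) / (1.0 - r_eff)


def n_rel_for_boundary_parameter(A: float = 2.5) -> float:
    """Relative index whose effective extrapolation parameter equals ``A``."""
    from scipy.optimize import brentq

    return float(brentq(lambda n: effective_boundary_parameter(n) - A, 1.0001, 2.0))
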