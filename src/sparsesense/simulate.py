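"""Synthetic multi-coil Cartesian acquisition.

Everything needed to exercise the reconstruction solvers without scanner
data: piecewise-smooth phantoms, smooth complex coil-sensitivity maps,
variable-density undersampling masks, and the noisy forward model
``y_j = mask * F(S_j * x) + mask * noise`` with the centered orthonormal
2-D DFT.  Every generator is a pure function of its arguments, seed
included.

Datasets round-trip through an HDF5 container with datasets ``/kspace``,
``/sens``, ``/mask`` and optional ``/reference``, plus root attributes
``seed``, ``factor``, ``snr_db`` (NaN when noiseless) and ``dc_centered``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .exceptions import ConfigurationError, DataError, FormatError
from .operators import fft2c
from .metrics import sos_combine

__all__ = [
    "Dataset",
    "make_phantom",
    "make_sensitivities",
    "make_mask",
    "simulate_kspace",
    "make_dataset",
    "write_dataset",
    "read_dataset",
]

# Modified Shepp-Logan ellipse table (value, a, b, x0, y0, angle_deg) on the
# unit square [-1, 1]^2; the ten-ellipse head phantom with intensities in [0, 1].
_SHEPP_LOGAN = [
    (1.0, 0.69, 0.92, 0.0, 0.0, 0.0),
    (-0.8, 0.6624, 0.8740, 0.0, -0.0184, 0.0),
    (-0.2, 0.1100, 0.3100, 0.22, 0.0, -18.0),
    (-0.2, 0.1600, 0.4100, -0.22, 0.0, 18.0),
    (0.1, 0.2100, 0.2500, 0.0, 0.35, 0.0),
    (0.1, 0.0460, 0.0460, 0.0, 0.1, 0.0),
    (0.1, 0.0460, 0.0460, 0.0, -0.1, 0.0),
    (0.1, 0.0460, 0.0230, -0.08, -0.605, 0.0),
    (0.1, 0.0230, 0.0230, 0.0, -0.606, 0.0),
    (0.1, 0.0230, 0.0460, 0.06, -0.605, 0.0),
]


@dataclass
class Dataset:
    """A complete synthetic acquisition: k-space, maps, mask, SoS reference."""

    kspace: np.ndarray  # (k, ny, nx) complex, zero off-mask
    sens: np.ndarray  # (k, ny, nx) complex
    mask: np.ndarray  # (ny, nx) uint8
    reference: np.ndarray | None = None  # (ny, nx) real SoS image
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        k, ny, nx = self.kspace.shape
        if self.sens.shape != (k, ny, nx):
            raise DataError("sens shape inconsistent with kspace")
        if self.mask.shape != (ny, nx):
            raise DataError("mask shape inconsistent with kspace")
        if self.reference is not None and self.reference.shape != (ny, nx):
            raise DataError("reference shape inconsistent with kspace")

    @property
    def shape(self) -> tuple[int, int]:
        return self.kspace.shape[1:]

    @property
    def ncoils(self) -> int:
        return self.kspace.shape[0]


def _grids(ny: int, nx: int):
    yy = np.linspace(-1.0, 1.0, ny, endpoint=False) + 1.0 / ny
    xx = np.linspace(-1.0, 1.0, nx, endpoint=False) + 1.0 / nx
    return np.meshgrid(yy, xx, indexing="ij")


def make_phantom(ny: int, nx: int, kind: str = "shepp_logan", seed: int = 0,
                 phase: bool = False) -> np.ndarray:
    """Piecewise-smooth test image with magnitude in [0, 1].

    ``shepp_logan`` rasterizes the standard ten-ellipse head phantom (purely
    real); ``blocks`` paints random overwriting rectangles (piecewise
    constant); ``smooth_bumps`` sums random Gaussian bumps.  With
    ``phase=True`` a smooth synthetic phase ramp is applied (off by default
    so the truth stays real and its total variation small).
    """
    if ny < 8 or nx < 8:
        raise ConfigurationError("phantom grid must be at least 8x8")
    rng = np.random.default_rng(seed)
    if kind == "shepp_logan":
        Y, X = _grids(ny, nx)
        img = np.zeros((ny, nx))
        for val, a, b, x0, y0, ang in _SHEPP_LOGAN:
            t = np.deg2rad(ang)
            xr = (X - x0) * np.cos(t) + (Y - y0) * np.sin(t)
            yr = -(X - x0) * np.sin(t) + (Y - y0) * np.cos(t)
            img[(xr / a) ** 2 + (yr / b) ** 2 <= 1.0] += val
        img = np.clip(img, 0.0, 1.0)
    elif kind == "blocks":
        nblocks = 6
        img = np.zeros((ny, nx))
        vals = rng.uniform(0.2, 1.0, size=nblocks)
        for v in vals:
            y0, y1 = np.sort(rng.integers(0, ny, size=2))
            x0, x1 = np.sort(rng.integers(0, nx, size=2))
            img[y0:y1 + 1, x0:x1 + 1] = v  # overwrite, keeping values discrete
        img = img / max(img.max(), 1e-12)
    elif kind == "smooth_bumps":
        Y, X = _grids(ny, nx)
        img = np.zeros((ny, nx))
        for _ in range(5):
            cy, cx = rng.uniform(-0.6, 0.6, size=2)
            s = rng.uniform(0.15, 0.4)
            img += rng.uniform(0.3, 1.0) * np.exp(-((Y - cy) ** 2 + (X - cx) ** 2) / (2 * s**2))
        img = img / img.max()
    else:
        raise ConfigurationError(f"unknown phantom kind {kind!r}")
    out = img.astype(complex)
    if phase:
        Y, X = _grids(ny, nx)
        out = out * np.exp(1j * np.pi * (0.3 * X + 0.2 * Y + 0.4 * X * Y))
    return out


def make_sensitivities(ny: int, nx: int, k: int, model: str = "gaussian_lobes",
                       normalize: bool = True, seed: int = 0) -> np.ndarray:
    """Smooth complex coil maps with centers spread around the field of view.

    ``gaussian_lobes`` places a broad Gaussian magnitude lobe per coil on a
    circle around the FOV with a smooth linear phase; ``polynomial`` uses
    low-order complex polynomials in the image coordinates.  With
    ``normalize=True`` the maps are scaled so ``sum_j |S_j|^2 = 1`` at every
    pixel, which makes the SoS reference exactly ``|x|`` and bounds the
    encoding operator norm by 1.
    """
    if k < 1:
        raise ConfigurationError("need at least one coil")
    rng = np.random.default_rng(seed)
    Y, X = _grids(ny, nx)
    maps = np.empty((k, ny, nx), dtype=complex)
    if model == "gaussian_lobes":
        # surface-coil-like lobes: centers on a circle just outside the FOV,
        # penetration depth about half the FOV (keeps the array well conditioned)
        angles = 2 * np.pi * np.arange(k) / k + rng.uniform(0, 2 * np.pi)
        for j in range(k):
            cy, cx = 1.1 * np.sin(angles[j]), 1.1 * np.cos(angles[j])
            width = 0.55 * (1.0 + 0.1 * rng.standard_normal())
            mag = np.exp(-((Y - cy) ** 2 + (X - cx) ** 2) / (2 * width**2))
            py, px = rng.uniform(-0.5, 0.5, size=2)
            maps[j] = mag * np.exp(1j * np.pi * (py * Y + px * X))
    elif model == "polynomial":
        for j in range(k):
            c = rng.standard_normal(4) + 1j * rng.standard_normal(4)
            maps[j] = 1.0 + 0.5 * (c[0] + c[1] * X + c[2] * Y + c[3] * X * Y)
    else:
        raise ConfigurationError(f"unknown sensitivity model {model!r}")
    if normalize:
        sos = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
        maps = maps / np.maximum(sos, 1e-300)[None, :, :]
    return maps


def make_mask(ny: int, nx: int, factor: float = 4.0,
              scheme: str = "variable_density_2d", seed: int = 0) -> np.ndarray:
    """Variable-density random undersampling pattern, DC always sampled.

    The inclusion probability decays with k-space radius as
    ``(1 + r/r0)^(-2)``; the exact sample count ``round(ny*nx/factor)``
    (``round(ny/factor)`` full rows for the lines scheme) is hit by keeping
    the top-scoring draws.  ``factor=1`` gives full sampling.
    """
    if factor < 1:
        raise ConfigurationError("undersampling factor must be >= 1")
    if factor > ny * nx:
        raise ConfigurationError("undersampling factor exceeds grid size")
    rng = np.random.default_rng(seed)
    cy, cx = ny // 2, nx // 2
    mask = np.zeros((ny, nx), dtype=np.uint8)
    if scheme == "variable_density_2d":
        n_keep = int(round(ny * nx / factor))
        Y, X = np.meshgrid(np.arange(ny) - cy, np.arange(nx) - cx, indexing="ij")
        r = np.hypot(Y, X)
        r0 = max(ny, nx) / 4.0
        p = (1.0 + r / r0) ** -2
        u = rng.random((ny, nx))
        score = (u / p).ravel()
        score[cy * nx + cx] = -np.inf  # DC forced on
        keep = np.argsort(score, kind="stable")[:n_keep]
        mask.ravel()[keep] = 1
    elif scheme == "variable_density_lines":
        n_keep = int(round(ny / factor))
        r = np.abs(np.arange(ny) - cy)
        r0 = ny / 4.0
        p = (1.0 + r / r0) ** -2
        score = rng.random(ny) / p
        score[cy] = -np.inf  # DC row forced on
        rows = np.argsort(score, kind="stable")[:max(n_keep, 1)]
        mask[rows, :] = 1
    else:
        raise ConfigurationError(f"unknown mask scheme {scheme!r}")
    return mask


def simulate_kspace(x: np.ndarray, sens: np.ndarray, mask: np.ndarray,
                    snr_db: float | None = None, seed: int = 0) -> np.ndarray:
    """Forward model ``y_j = mask * F(S_j x) + mask * noise``.

    The complex Gaussian noise variance is calibrated on the sampled
    locations so that ``10 log10(||signal||^2 / E||noise||^2) = snr_db``;
    ``snr_db=None`` returns exact data.  Unsampled entries are exactly zero.
    """
    x = np.asarray(x, dtype=complex)
    sens = np.asarray(sens, dtype=complex)
    if sens.ndim != 3 or sens.shape[1:] != x.shape:
        raise DataError("sensitivity maps inconsistent with image shape")
    if mask.shape != x.shape:
        raise DataError("mask inconsistent with image shape")
    m = np.asarray(mask).astype(float)
    y = m * fft2c(sens * x[None, :, :])
    if snr_db is not None:
        rng = np.random.default_rng(seed)
        n_sampled = int(m.sum()) * sens.shape[0]
        signal_energy = float(np.sum(np.abs(y) ** 2))
        sigma2 = signal_energy / (n_sampled * 10.0 ** (snr_db / 10.0))
        noise = rng.standard_normal(y.shape) + 1j * rng.standard_normal(y.shape)
        y = y + m * np.sqrt(sigma2 / 2.0) * noise
    return y


def make_dataset(ny: int = 128, nx: int = 128, ncoils: int = 8,
                 factor: float = 4.0, snr_db: float | None = 30.0,
                 phantom: str = "shepp_logan", scheme: str = "variable_density_2d",
                 sens_model: str = "gaussian_lobes", normalize: bool = True,
                 amplitude: float = 255.0, seed: int = 0) -> Dataset:
    """End-to-end synthetic study: phantom -> maps -> mask -> noisy k-space.

    The SoS reference is computed from the *fully sampled, noiseless* coil
    images, mirroring how fully acquired data serve as ground truth before
    artificial undersampling.  The phantom (unit magnitude) is scaled by
    ``amplitude`` (default 255, the 8-bit image convention on which the
    standard data weight lam=1e3, the stopping tolerance and the PSNR peak
    constant are all calibrated).  Sub-seeds for the independent random
    stages are derived deterministically from ``seed``.
    """
    ss = np.random.SeedSequence(seed).generate_state(4) % (2**31)
    x = amplitude * make_phantom(ny, nx, phantom, int(ss[0]))
    sens = make_sensitivities(ny, nx, ncoils, sens_model, normalize, int(ss[1]))
    mask = make_mask(ny, nx, factor, scheme, int(ss[2]))
    kspace = simulate_kspace(x, sens, mask, snr_db, int(ss[3]))
    reference = sos_combine(sens * x[None, :, :])
    meta = {"seed": int(seed), "factor": float(factor), "amplitude": float(amplitude),
            "snr_db": float("nan") if snr_db is None else float(snr_db)}
    return Dataset(kspace=kspace, sens=sens, mask=mask, reference=reference, meta=meta)


def write_dataset(ds: Dataset, path) -> None:
    """Write the HDF5 container (complex arrays as compound (re, im) float64)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=ds.kspace.astype(np.complex128))
        f.create_dataset("sens", data=ds.sens.astype(np.complex128))
        f.create_dataset("mask", data=ds.mask.astype(np.uint8))
        if ds.reference is not None:
            f.create_dataset("reference", data=np.asarray(ds.reference, dtype=np.float64))
        f.attrs["seed"] = int(ds.meta.get("seed", 0))
        f.attrs["factor"] = float(ds.meta.get("factor", float("nan")))
        f.attrs["snr_db"] = float(ds.meta.get("snr_db", float("nan")))
        f.attrs["dc_centered"] = 1


def read_dataset(path) -> Dataset:
    """Read the HDF5 container; missing fields raise :class:`FormatError`."""
    with h5py.File(path, "r") as f:
        for name in ("kspace", "sens", "mask"):
            if name not in f:
                raise FormatError(f"dataset container {path!s} is missing /{name}")
        kspace = np.asarray(f["kspace"], dtype=np.complex128)
        sens = np.asarray(f["sens"], dtype=np.complex128)
        mask = np.asarray(f["mask"], dtype=np.uint8)
        reference = np.asarray(f["reference"], dtype=np.float64) if "reference" in f else None
        meta = {"seed": int(f.attrs.get("seed", 0)),
                "factor": float(f.attrs.get("factor", float("nan"))),
                "snr_db": float(f.attrs.get("snr_db", float("nan")))}
    return Dataset(kspace=kspace, sens=sens, mask=mask, reference=reference, meta=meta)
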