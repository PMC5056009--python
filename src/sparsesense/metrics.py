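"""Reference construction and reconstruction quality metrics.

The ground-truth image is the square-root sum-of-squares (SoS) combination
of the fully sampled coil images.  Both metrics compare magnitude images:
relative error ``||x - ref||_2 / ||ref||_2`` and PSNR with the reference
magnitude pre-scaled to [0, 255] (and the same scale applied to the
reconstruction).  Two PSNR conventions are shipped: ``as_printed`` uses
``20 log10(255 / ||x - ref||_2^2)`` (squared 2-norm in the denominator) and
``standard`` uses the conventional RMSE denominator; neither is silently
preferred because published definitions differ on exactly this point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError

__all__ = ["sos_combine", "relative_error", "psnr", "ReconReport"]


def sos_combine(coil_images: np.ndarray) -> np.ndarray:
    """Pixelwise ``sqrt(sum_j |img_j|^2)`` over a (k, ny, nx) stack."""
    coil_images = np.asarray(coil_images)
    if coil_images.ndim != 3 or coil_images.shape[0] < 1:
        raise DataError("expected a non-empty (k, ny, nx) stack of coil images")
    return np.sqrt(np.sum(np.abs(coil_images) ** 2, axis=0))


def relative_error(x: np.ndarray, ref: np.ndarray) -> float:
    """``||x - ref||_2 / ||ref||_2`` over magnitude images."""
    a = np.abs(np.asarray(x))
    b = np.abs(np.asarray(ref))
    denom = np.linalg.norm(b)
    if denom == 0:
        raise ConfigurationError("relative error undefined for a zero reference")
    return float(np.linalg.norm(a - b) / denom)


def psnr(x: np.ndarray, ref: np.ndarray, formula: str = "as_printed") -> float:
    """Peak signal-to-noise ratio in dB after scaling the reference to [0, 255].

    ``as_printed``: ``20 log10(255 / ||x - ref||_2^2)``;
    ``standard``:  ``20 log10(255 / RMSE)``.
    Exact match returns ``inf``.
    """
    if formula not in ("as_printed", "standard"):
        raise ConfigurationError(f"unknown PSNR formula {formula!r}")
    a = np.abs(np.asarray(x, dtype=float) if not np.iscomplexobj(x) else np.asarray(x))
    b = np.abs(np.asarray(ref, dtype=float) if not np.iscomplexobj(ref) else np.asarray(ref))
    peak = b.max()
    if peak == 0:
        raise ConfigurationError("PSNR undefined for a zero reference")
    scale = 255.0 / peak
    err = float(np.linalg.norm(scale * a - scale * b))
    if err == 0:
        return float("inf")
    if formula == "as_printed":
        return float(20.0 * np.log10(255.0 / err**2))
    rmse = err / np.sqrt(a.size)
    return float(20.0 * np.log10(255.0 / rmse))


@dataclass
class ReconReport:
    """Per-run record: final metrics, per-iteration traces, parameter echo."""

    algo: str
    iterations: int
    converged: bool
    objective: float
    relative_change: float
    elapsed_seconds: float
    psnr: float | None = None
    relative_error: float | None = None
    params: dict = field(default_factory=dict)
    traces: pd.DataFrame | None = None

    def to_csv(self, path) -> None:
        """Write the iteration traces as CSV."""
        if self.traces is None:
            raise ConfigurationError("report has no traces to write")
        self.traces.to_csv(path, index=False)

    def to_dict(self) -> dict:
        d = {
            "algo": self.algo,
            "iterations": self.iterations,
            "converged": self.converged,
            "objective": self.objective,
            "relative_change": self.relative_change,
            "elapsed_seconds": self.elapsed_seconds,
            "psnr": self.psnr,
            "relative_error": self.relative_error,
            "params": dict(self.params),
        }
        return d
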