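"""Model/Results interface over the reconstruction machinery.

``SparseSenseModel`` bundles the measured multi-coil k-space, coil maps,
sampling mask and regularisation choice; ``fit`` runs one of the solvers
and returns a ``ReconResults`` carrying the reconstructed image, the
convergence traces, quality metrics against the reference, and a text
``summary()``.

Example
-------
>>> from sparsesense import make_dataset, SparseSenseModel
>>> ds = make_dataset(ny=64, nx=64, ncoils=4, factor=4, snr_db=30, seed=0)
>>> model = SparseSenseModel.from_dataset(ds, lam=1e3)
>>> res = model.fit(method="fboss", gamma=1.0)
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

import json

import numpy as np

from .exceptions import ConfigurationError
from .metrics import ReconReport, psnr as psnr_metric, relative_error
from .operators import FiniteDifference, SenseOperator
from .simulate import Dataset, read_dataset
from . import solvers as _solvers

__all__ = ["SparseSenseModel", "ReconResults"]


class SparseSenseModel:
    """Sparsity-regularised SENSE reconstruction model.

    Parameters
    ----------
    kspace : ndarray (k, ny, nx), complex
        Measured (zero-filled) multi-coil k-space, DC-centered.
    sens : ndarray (k, ny, nx), complex
        Coil sensitivity maps.
    mask : ndarray (ny, nx)
        Binary sampling pattern.
    lam : float
        Data-consistency weight (default 1e3); larger values trust the
        measured samples more relative to the sparsity prior.
    reg : {"tv", "tgv2"}
        Sparsifying transform.
    boundary : {"periodic", "neumann"}
        Finite-difference boundary rule.
    reference : ndarray (ny, nx), optional
        Ground-truth magnitude image (e.g. the SoS combination of fully
        sampled coil images) used for PSNR / relative-error reporting.
    """

    def __init__(self, kspace, sens, mask, *, lam: float = 1.0e3,
                 reg: str = "tv", boundary: str = "periodic", reference=None):
        self.A = SenseOperator(sens, mask)
        self.D = FiniteDifference(reg, boundary)
        self.y = np.asarray(kspace, dtype=complex)
        self.problem = _solvers.ReconProblem(A=self.A, D=self.D, y=self.y, lam=lam)
        self.reference = None if reference is None else np.asarray(reference, dtype=float)

    @classmethod
    def from_dataset(cls, ds: Dataset, **kwargs) -> "SparseSenseModel":
        kwargs.setdefault("reference", ds.reference)
        return cls(ds.kspace, ds.sens, ds.mask, **kwargs)

    @classmethod
    def from_file(cls, path, **kwargs) -> "SparseSenseModel":
        return cls.from_dataset(read_dataset(path), **kwargs)

    @property
    def zero_filled(self) -> np.ndarray:
        """The adjoint reconstruction ``A^H y`` (also the default start)."""
        return self.A.adjoint(self.y)

    def objective(self, x: np.ndarray) -> float:
        return _solvers.objective(self.problem, x)

    def fit(self, method: str = "fboss", *, gamma: float = 1.0,
            delta0: float = 1.0, eps: float = 5.0e-5, max_iter: int = 500,
            stepsize_mode: str = "bb", x_update_rule: str = "inverse_product",
            rho: float = 0.5, bos_delta: float = 1.0, alpha: float = 1.0e2,
            x0=None) -> "ReconResults":
        """Run a solver to the relative-change stopping rule and wrap the result."""
        params = _solvers.SolverParams(
            gamma=gamma, delta0=delta0, eps=eps, max_iter=max_iter,
            stepsize_mode=stepsize_mode, x_update_rule=x_update_rule)
        x, state, report = _solvers.run_solver(
            self.problem, params, algo=method,
            bos=_solvers.BOSParams(rho=rho, delta=bos_delta),
            am=_solvers.AMParams(alpha=alpha),
            x0=x0, reference=self.reference)
        return ReconResults(self, x, state, report)


class ReconResults:
    """Result of one reconstruction: image, traces, metrics, summary."""

    def __init__(self, model: SparseSenseModel, image: np.ndarray,
                 state: "_solvers.SolverState", report: ReconReport):
        self.model = model
        self.image = image
        self.state = state
        self.report = report

    # -- convenience accessors -------------------------------------------------
    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.image)

    @property
    def n_iter(self) -> int:
        return self.report.iterations

    @property
    def converged(self) -> bool:
        return self.report.converged

    @property
    def objective(self) -> float:
        return self.report.objective

    @property
    def psnr(self) -> float | None:
        return self.report.psnr

    @property
    def relative_error(self) -> float | None:
        return self.report.relative_error

    @property
    def traces(self):
        return self.report.traces

    def error_image(self) -> np.ndarray:
        """``| |x| - reference |`` — the absolute-error map against the reference."""
        if self.model.reference is None:
            raise ConfigurationError("no reference image attached to the model")
        return np.abs(self.magnitude - self.model.reference)

    # -- reporting -------------------------------------------------------------
    def summary(self) -> str:
        r = self.report
        ny, nx = self.image.shape
        lines = [
            "SparseSENSE reconstruction results",
            "=" * 44,
            f"{'method':<22}{r.algo}",
            f"{'grid':<22}{ny} x {nx}",
            f"{'coils':<22}{self.model.A.ncoils}",
            f"{'regulariser':<22}{self.model.D.kind} ({self.model.D.boundary})",
            f"{'lam':<22}{self.model.problem.lam:g}",
            f"{'gamma':<22}{r.params.get('gamma', float('nan')):g}",
            f"{'iterations':<22}{r.iterations}",
            f"{'converged':<22}{r.converged}",
            f"{'final objective':<22}{r.objective:.6g}",
            f"{'final rel. change':<22}{r.relative_change:.3e}",
            f"{'elapsed seconds':<22}{r.elapsed_seconds:.3f}",
        ]
        if r.relative_error is not None:
            lines.append(f"{'relative error':<22}{r.relative_error:.4e}")
        if r.psnr is not None:
            lines.append(f"{'PSNR (dB)':<22}{r.psnr:.2f}")
        lines.append("=" * 44)
        return "\n".join(lines)

    def save_report(self, outdir) -> None:
        """Write trace CSV and parameter/metric JSON sidecar into ``outdir``."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.report.to_csv(outdir / "trace.csv")
        with open(outdir / "report.json", "w") as f:
            json.dump(self.report.to_dict(), f, indent=2, default=float)

    def plot_convergence(self, ax=None):
        """Objective and relative change versus iteration (log scale)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.report.traces
        ax.semilogy(t["iteration"], t["relative_change"], label="relative change")
        ax2 = ax.twinx()
        ax2.plot(t["iteration"], t["objective"], color="C1", label="objective")
        ax.set_xlabel("iteration")
        ax.set_ylabel("relative change")
        ax2.set_ylabel("objective")
        ax.legend(loc="upper right")
        return ax
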