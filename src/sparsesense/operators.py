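"""Linear operators of the SparseSENSE model.

The encoding operator ``A = [F_p S_1; ...; F_p S_k]`` maps an image to
undersampled multi-coil k-space: each coil image ``S_j * x`` is Fourier
transformed with the centered orthonormal 2-D DFT and restricted to the
sampled locations.  The sparsifying operator ``D`` is either the discrete
gradient (isotropic TV, 2 components) or a special second-order TGV built
from second-order finite differences (3 unique tensor components, the
symmetrised cross term carrying multiplicity 2).

All arrays follow the DC-centered k-space convention: the zero-frequency
coefficient sits at grid index ``(ny//2, nx//2)``.  FFT-layout shifts are
internal to :func:`fft2c` / :func:`ifft2c`.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ConfigurationError, DataError

__all__ = [
    "fft2c",
    "ifft2c",
    "SenseOperator",
    "FiniteDifference",
    "group_magnitude",
    "spectral_norm",
]


def fft2c(x: np.ndarray) -> np.ndarray:
    """Centered orthonormal 2-D DFT over the last two axes."""
    axes = (-2, -1)
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def ifft2c(y: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft2c` (also orthonormal, DC-centered)."""
    axes = (-2, -1)
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(y, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


class SenseOperator:
    """SENSE encoding operator built from sensitivity maps and a sampling mask.

    Parameters
    ----------
    sens : ndarray, shape (k, ny, nx), complex
        Coil sensitivity maps ``S_j``, applied pointwise.
    mask : ndarray, shape (ny, nx)
        Binary k-space sampling pattern (DC-centered); cast to float.
    """

    def __init__(self, sens: np.ndarray, mask: np.ndarray):
        sens = np.asarray(sens, dtype=complex)
        mask = np.asarray(mask)
        if sens.ndim != 3:
            raise DataError(f"sens must be (k, ny, nx), got shape {sens.shape}")
        if mask.shape != sens.shape[1:]:
            raise DataError(
                f"mask shape {mask.shape} does not match sens grid {sens.shape[1:]}"
            )
        self.sens = sens
        self.mask = mask.astype(float)
        self.ncoils, self.ny, self.nx = sens.shape

    @property
    def in_shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    def apply(self, x: np.ndarray) -> np.ndarray:
        """``(Ax)_j = mask * fft2c(S_j * x)``; zeros off-mask."""
        x = np.asarray(x)
        if x.shape != (self.ny, self.nx):
            raise DataError(f"image shape {x.shape}, expected {(self.ny, self.nx)}")
        return self.mask * fft2c(self.sens * x[None, :, :])

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        """``A^H y = sum_j conj(S_j) * ifft2c(mask * y_j)``."""
        y = np.asarray(y)
        if y.shape != self.sens.shape:
            raise DataError(f"k-space shape {y.shape}, expected {self.sens.shape}")
        return np.sum(np.conj(self.sens) * ifft2c(self.mask * y), axis=0)

    def normal(self, x: np.ndarray) -> np.ndarray:
        """``A^H A x`` — used by power iteration and diagnostics."""
        return self.adjoint(self.apply(x))


def _fwd_diff(x: np.ndarray, axis: int, boundary: str) -> np.ndarray:
    if boundary == "periodic":
        return np.roll(x, -1, axis=axis) - x
    # neumann: replicate edge, so the last difference along `axis` is zero
    out = np.zeros_like(x)
    head = [slice(None)] * x.ndim
    tail = [slice(None)] * x.ndim
    head[axis] = slice(None, -1)
    tail[axis] = slice(1, None)
    out[tuple(head)] = x[tuple(tail)] - x[tuple(head)]
    return out


def _fwd_diff_adjoint(g: np.ndarray, axis: int, boundary: str) -> np.ndarray:
    if boundary == "periodic":
        return np.roll(g, 1, axis=axis) - g
    # zero the (structurally unused) last slice, then negative backward diff
    gt = g.copy()
    last = [slice(None)] * g.ndim
    last[axis] = slice(-1, None)
    gt[tuple(last)] = 0
    out = -gt
    head = [slice(None)] * g.ndim
    tail = [slice(None)] * g.ndim
    head[axis] = slice(None, -1)
    tail[axis] = slice(1, None)
    out[tuple(tail)] += gt[tuple(head)]
    return out


class FiniteDifference:
    """TV or second-order-TGV sparsifying operator ``D`` with exact adjoint.

    ``kind='tv'`` produces the 2-component forward-difference gradient
    (vertical, horizontal).  ``kind='tgv2'`` produces the 3 unique components
    of the symmetric second-derivative tensor ``(D11 x, D22 x,
    (D12 x + D21 x)/2)``, built from forward-forward second differences; the
    cross component carries multiplicity weight 2 so that the weighted group
    magnitude equals the pointwise Frobenius norm of the full 2x2 tensor.

    The adjoint is exact under the weighted inner product
    ``<u, v>_w = sum_c w_c sum_pixels u_c conj(v_c)``.
    """

    KINDS = ("tv", "tgv2")
    BOUNDARIES = ("periodic", "neumann")

    def __init__(self, kind: str = "tv", boundary: str = "periodic"):
        if kind not in self.KINDS:
            raise ConfigurationError(f"unknown sparsifying kind {kind!r}")
        if boundary not in self.BOUNDARIES:
            raise ConfigurationError(f"unknown boundary rule {boundary!r}")
        self.kind = kind
        self.boundary = boundary
        self.nfields = 2 if kind == "tv" else 3
        self.weights = (1.0, 1.0) if kind == "tv" else (1.0, 1.0, 2.0)

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Return the gradient field, shape ``(g, ny, nx)``."""
        x = np.asarray(x)
        b = self.boundary
        if self.kind == "tv":
            return np.stack([_fwd_diff(x, 0, b), _fwd_diff(x, 1, b)])
        d1 = _fwd_diff(x, 0, b)
        d2 = _fwd_diff(x, 1, b)
        d11 = _fwd_diff(d1, 0, b)
        d22 = _fwd_diff(d2, 1, b)
        cross = 0.5 * (_fwd_diff(d2, 0, b) + _fwd_diff(d1, 1, b))
        return np.stack([d11, d22, cross])

    def adjoint(self, g: np.ndarray) -> np.ndarray:
        """Adjoint ``D^T g`` under the weighted inner product."""
        g = np.asarray(g)
        if g.shape[0] != self.nfields:
            raise DataError(
                f"gradient field has {g.shape[0]} components, "
                f"{self.kind} expects {self.nfields}"
            )
        b = self.boundary
        if self.kind == "tv":
            return _fwd_diff_adjoint(g[0], 0, b) + _fwd_diff_adjoint(g[1], 1, b)
        # weights (1, 1, 2): the cross component contributes twice
        a11 = _fwd_diff_adjoint(_fwd_diff_adjoint(g[0], 0, b), 0, b)
        a22 = _fwd_diff_adjoint(_fwd_diff_adjoint(g[1], 1, b), 1, b)
        across = _fwd_diff_adjoint(_fwd_diff_adjoint(g[2], 0, b), 1, b) + _fwd_diff_adjoint(
            _fwd_diff_adjoint(g[2], 1, b), 0, b
        )
        return a11 + a22 + across

    def laplacian_symbol(self, ny: int, nx: int) -> np.ndarray:
        """DFT symbol of ``D^T D`` for tv/periodic, in standard FFT layout.

        ``L(u, v) = 4 sin^2(pi u / ny) + 4 sin^2(pi v / nx)`` — the periodic
        Laplacian, which lets the BOS x-solve be performed by FFT.
        """
        if self.kind != "tv" or self.boundary != "periodic":
            raise ConfigurationError(
                "D^T D is FFT-diagonalizable only for kind='tv', boundary='periodic'"
            )
        u = np.arange(ny)[:, None]
        v = np.arange(nx)[None, :]
        return 4 * np.sin(np.pi * u / ny) ** 2 + 4 * np.sin(np.pi * v / nx) ** 2


def group_magnitude(v: np.ndarray, weights=None) -> np.ndarray:
    """Pointwise weighted group magnitude ``sqrt(sum_c w_c |v_c|^2)``."""
    v = np.asarray(v)
    if weights is None:
        weights = np.ones(v.shape[0])
    w = np.asarray(weights, dtype=float).reshape((-1,) + (1,) * (v.ndim - 1))
    return np.sqrt(np.sum(w * np.abs(v) ** 2, axis=0))


def spectral_norm(op, shape=None, iters: int = 50, seed: int = 0) -> float:
    """Power-iteration estimate of the largest eigenvalue of ``op^H op``.

    For the SENSE operator with normalised sensitivities this is at most 1
    (the DFT is unitary and the mask a projection); the value bounds the
    Barzilai-Borwein stepsizes and sets the safe constant stepsize.

    Parameters
    ----------
    op : object with ``apply`` and ``adjoint`` methods
        The linear operator; ``shape`` may be omitted when the operator
        exposes ``in_shape``.
    iters : int
        Number of power iterations (estimate is nondecreasing in ``iters``
        up to round-off).
    seed : int
        Seed for the random complex starting vector.
    """
    if iters < 1:
        raise ConfigurationError("iters must be >= 1")
    if shape is None:
        shape = op.in_shape
    rng = np.random.default_rng(seed)
    b = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    est = 0.0
    for _ in range(iters):
        nb = op.adjoint(op.apply(b))
        norm = np.linalg.norm(nb)
        if norm == 0.0:
            return 0.0
        est = float(np.real(np.vdot(b, nb)) / np.real(np.vdot(b, b)))
        b = nb / norm
    return est
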