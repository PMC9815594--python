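"""Total-variation compressed sensing by split Bregman, plus zero filling.

The reconstruction solves

    min_u  TV(u) + (mu / 2) ||F_mask u - f||_2^2

with isotropic TV under periodic boundary conditions, where ``F_mask``
restricts the 2-D Fourier transform to the sampled PE lines.  Splitting
``d = grad u`` gives the split-Bregman iteration: the ``u`` subproblem is
solved in closed form in the Fourier domain (both the sampling operator and
the finite-difference Laplacian are diagonalized by the FFT), the ``d``
subproblem by isotropic soft shrinkage, and the Bregman variables are
updated once per outer iteration.

Internally the solver works with the unitary centered FFT so the image and
data terms share the pixel-intensity scale; inputs and outputs use the
package-wide unnormalized-forward convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, SolverError
from .fourier import ifft2c
from .phantoms import ReferenceImage, normalize


@dataclass
class ReconParams:
    """Solver weights and iteration controls.

    ``mu`` weighs data fidelity against the (unit-weight) TV term; ``lam``
    is the splitting weight of the ``d = grad u`` constraint.  Not taken
    from any acquisition protocol — tuned on phantoms (see docs).
    """

    mu: float = 50.0
    lam: float = 1.0
    n_outer: int = 30
    n_inner: int = 2
    tol: float = 1e-5

    def __post_init__(self):
        if self.mu <= 0 or self.lam <= 0:
            raise ConfigurationError("mu and lam must be positive")
        if self.n_outer < 1 or self.n_inner < 1:
            raise ConfigurationError("iteration counts must be >= 1")
        if self.tol < 0:
            raise ConfigurationError("tol must be >= 0")


def _grad(u):
    return np.roll(u, -1, axis=0) - u, np.roll(u, -1, axis=1) - u


def _div(px, py):
    # negative adjoint of _grad
    return px - np.roll(px, 1, axis=0) + py - np.roll(py, 1, axis=1)


def _fft2c_unitary(x):
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(x), norm="ortho"))


def _ifft2c_unitary(k):
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(k), norm="ortho"))


def _check_mask(k_data, mask):
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 1 or mask.size != k_data.shape[1]:
        raise ConfigurationError("mask must be one boolean per PE line")
    if mask.sum() < 4:
        raise ConfigurationError("mask must select at least 4 PE lines")
    return mask


def tv_objective(u, f, mask_cols, mu):
    """The objective TV(u) + (mu/2)||F_mask u - f||^2 (unitary-FFT scale)."""
    gx, gy = _grad(u)
    tv = np.sum(np.sqrt(np.abs(gx) ** 2 + np.abs(gy) ** 2))
    resid = (_fft2c_unitary(u) - f) * mask_cols
    return float(tv + 0.5 * mu * np.sum(np.abs(resid) ** 2))


def split_bregman_cs(
    k_data: np.ndarray,
    mask: np.ndarray,
    params: ReconParams | None = None,
    full_output: bool = False,
):
    """Reconstruct an image from the retained PE lines.

    Parameters
    ----------
    k_data
        Complex k-space (readout x PE) in the package's centered,
        unnormalized-forward convention.  Unsampled columns are ignored.
    mask
        Boolean per-PE-line sampling mask.
    full_output
        Also return a dict with per-outer-iteration objective values and
        relative changes.
    """
    if params is None:
        params = ReconParams()
    k_data = np.asarray(k_data, dtype=complex)
    mask = _check_mask(k_data, mask)
    num_r, num_pe = k_data.shape
    mask_cols = np.broadcast_to(mask, (num_r, num_pe)).astype(float)
    f = k_data / np.sqrt(num_r * num_pe) * mask_cols  # unitary scale

    wy = 2.0 - 2.0 * np.cos(2.0 * np.pi * np.fft.fftfreq(num_r))
    wx = 2.0 - 2.0 * np.cos(2.0 * np.pi * np.fft.fftfreq(num_pe))
    lap = np.fft.fftshift(wy)[:, None] + np.fft.fftshift(wx)[None, :]
    denom = params.mu * mask_cols + params.lam * lap
    denom[denom == 0.0] = 1.0  # DC on an unsampled line: keep it at zero

    u = _ifft2c_unitary(f)
    dx = dy = bx = by = np.zeros_like(u)
    objectives, rel_changes = [], []
    for _ in range(params.n_outer):
        u_prev = u
        for _ in range(params.n_inner):
            rhs = params.mu * f + params.lam * _fft2c_unitary(_div(dx - bx, dy - by) * -1.0)
            u = _ifft2c_unitary(rhs / denom)
            gx, gy = _grad(u)
            sx, sy = gx + bx, gy + by
            s = np.sqrt(np.abs(sx) ** 2 + np.abs(sy) ** 2)
            shrink = np.maximum(s - 1.0 / params.lam, 0.0) / np.where(s > 0, s, 1.0)
            dx, dy = shrink * sx, shrink * sy
        bx = bx + gx - dx
        by = by + gy - dy
        if not np.all(np.isfinite(u)):
            raise SolverError("split-Bregman iterate became non-finite")
        objectives.append(tv_objective(u, f, mask_cols, params.mu))
        change = np.linalg.norm(u - u_prev) / max(np.linalg.norm(u_prev), 1e-30)
        rel_changes.append(float(change))
        if change < params.tol:
            break
    image = ReferenceImage(normalize(np.abs(u)))
    if full_output:
        return image, {"objective": np.array(objectives), "rel_change": np.array(rel_changes)}
    return image


def zero_fill(k_data: np.ndarray, mask: np.ndarray) -> ReferenceImage:
    """Inverse FFT with unsampled PE lines set to zero (naive baseline)."""
    k_data = np.asarray(k_data, dtype=complex)
    mask = _check_mask(k_data, mask)
    k = k_data * mask[None, :]
    return ReferenceImage(normalize(np.abs(ifft2c(k))))
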