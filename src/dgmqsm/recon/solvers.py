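"""Shared linear operators for the TV-regularized dipole inversions.

The inversions solve normal equations of the form

    [P C_D' W C_D P + lambda P G' U G P] y = rhs

where ``C_D`` is circular convolution with the dipole kernel (self-adjoint,
real symmetric in k-space), ``G`` the forward-difference gradient with
periodic wrap, ``U`` the IRLS weights of the epsilon-smoothed edge-masked
TV term, and ``P`` the diagonal two-level preconditioner.  Conjugate
gradients (scipy) are accelerated by a circulant approximation of the
normal operator: spatially averaged weights make the operator diagonal in
k-space, ``abar D(k)^2 + lambda sum_a ubar_a s_a(k)``, which captures both
the dipole cone and the gradient Laplacian and is inverted exactly per CG
iteration.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse.linalg import LinearOperator, cg


def conv_kernel(vol: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Circular convolution with a real k-space kernel (self-adjoint)."""
    return np.fft.ifftn(kernel * np.fft.fftn(vol)).real


def gradient(vol: np.ndarray) -> np.ndarray:
    """Forward differences along each axis with periodic wrap, shape (3, ...)."""
    return np.stack([np.roll(vol, -1, axis=ax) - vol for ax in range(3)])


def divergence(g: np.ndarray) -> np.ndarray:
    """Negative adjoint of :func:`gradient` (periodic)."""
    out = np.zeros(g.shape[1:])
    for ax in range(3):
        out += g[ax] - np.roll(g[ax], 1, axis=ax)
    return out


def tv_value(chi: np.ndarray, edge_weights: np.ndarray, eps: float) -> float:
    """Edge-masked, epsilon-smoothed total variation of ``chi``."""
    g = gradient(chi)
    return float(np.sum(edge_weights * np.sqrt(g**2 + eps**2)))


def irls_weights(chi: np.ndarray, edge_weights: np.ndarray, eps: float) -> np.ndarray:
    """Majorizer weights ``M / sqrt(grad^2 + eps^2)`` of the smoothed TV."""
    g = gradient(chi)
    return edge_weights / np.sqrt(g**2 + eps**2)


def _gradient_symbols(shape: tuple[int, ...]) -> list[np.ndarray]:
    """Eigenvalue symbols ``s_a(k) = 4 sin^2(pi k_a)`` of each G_a' G_a."""
    out = []
    for ax, m in enumerate(shape):
        s = 4.0 * np.sin(np.pi * np.fft.fftfreq(m)) ** 2
        sh = [1, 1, 1]
        sh[ax] = m
        out.append(s.reshape(sh))
    return out


def _circulant_symbol(
    fidelity_weight: np.ndarray,
    kernel: np.ndarray,
    u_tv: np.ndarray | None,
    lambda_tv: float,
) -> np.ndarray:
    """k-space symbol of the normal operator with spatially averaged weights.

    The preconditioner applied to ``P A P`` is ``P^-1 Circ^-1 P^-1`` — the
    exact inverse of the circulant approximation ``P Circ P`` — so the
    two-level preconditioner P does not degrade the circulant fit.
    """
    sym = float(np.mean(fidelity_weight)) * kernel**2
    if u_tv is not None:
        for ax, s in enumerate(_gradient_symbols(kernel.shape)):
            sym = sym + lambda_tv * float(np.mean(u_tv[ax])) * s
    return sym + 1e-8 * float(sym.max())


def solve_normal_equations(
    fidelity_weight: np.ndarray,
    kernel: np.ndarray,
    u_tv: np.ndarray,
    lambda_tv: float,
    precond: np.ndarray,
    rhs: np.ndarray,
    cg_iters: int,
    x0: np.ndarray | None = None,
) -> np.ndarray:
    """Circulant-preconditioned CG solve of the normal equations.

    ``fidelity_weight`` is the voxelwise weight of the squared fidelity term
    applied between the two kernel convolutions.  Returns y (not P y).
    """
    shape = rhs.shape
    n = rhs.size
    inv_sym = 1.0 / _circulant_symbol(fidelity_weight, kernel, u_tv, lambda_tv)

    def matvec(yflat: np.ndarray) -> np.ndarray:
        y = yflat.reshape(shape)
        chi = precond * y
        out = precond * conv_kernel(fidelity_weight * conv_kernel(chi, kernel), kernel)
        out -= lambda_tv * precond * divergence(u_tv * gradient(chi))
        return out.ravel()

    def apply_precond(rflat: np.ndarray) -> np.ndarray:
        r = rflat.reshape(shape) / precond
        return (np.fft.ifftn(inv_sym * np.fft.fftn(r)).real / precond).ravel()

    op = LinearOperator((n, n), matvec=matvec, dtype=float)
    m_op = LinearOperator((n, n), matvec=apply_precond, dtype=float)
    y, _ = cg(
        op,
        rhs.ravel(),
        x0=None if x0 is None else x0.ravel(),
        rtol=1e-14,
        maxiter=cg_iters,
        M=m_op,
    )
    return y.reshape(shape)


def tikhonov_dipole_solve(
    fidelity_weight: np.ndarray,
    kernel: np.ndarray,
    target: np.ndarray,
    precond: np.ndarray,
    cg_iters: int = 60,
    delta: float = 1e-6,
) -> np.ndarray:
    """Warm-start stage: minimize ``||w (target - D * P y)||^2 + delta ||y||^2``.

    A nearly unregularized weighted inversion whose solution seeds the IRLS
    TV iterations away from the flat start (where the l1 majorizer is at its
    stiffest).  Returns y.
    """
    shape = target.shape
    n = target.size
    inv_sym = 1.0 / (float(np.mean(fidelity_weight)) * kernel**2 + delta)

    def matvec(yflat: np.ndarray) -> np.ndarray:
        y = yflat.reshape(shape)
        out = precond * conv_kernel(
            fidelity_weight * conv_kernel(precond * y, kernel), kernel
        )
        return out.ravel() + delta * yflat

    def apply_precond(rflat: np.ndarray) -> np.ndarray:
        r = rflat.reshape(shape) / precond
        return (np.fft.ifftn(inv_sym * np.fft.fftn(r)).real / precond).ravel()

    op = LinearOperator((n, n), matvec=matvec, dtype=float)
    m_op = LinearOperator((n, n), matvec=apply_precond, dtype=float)
    rhs = precond * conv_kernel(fidelity_weight * target, kernel)
    y, _ = cg(op, rhs.ravel(), rtol=1e-14, maxiter=cg_iters, M=m_op)
    return y.reshape(shape)
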