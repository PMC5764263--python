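"""Shared integrator for bilinear state-space dynamics.

The system is ``dx/dt = (A + sum_j u_j(t) B_j) x + C u_drive(t)`` with all
inputs piecewise-constant on the sampling grid (zero-order hold).  Two schemes
are provided: exact ZOH propagation via matrix exponentials (cached per unique
modulatory-input combination, exact for step inputs) and forward Euler (first
order, used for convergence checks).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

# beyond this many distinct modulatory-input combinations expm caching loses
# to plain Euler at a refined grid
_MAX_COMBOS = 64


def _stack_mods(u_mods, n: int) -> np.ndarray:
    if not u_mods:
        return np.zeros((0, n))
    out = np.vstack([np.asarray(u, dtype=float) for u in u_mods])
    if out.shape[1] != n:
        raise ValueError("modulatory inputs must share the driving-input grid")
    return out


def trajectory(A, B_list, C, u_drive, u_mods, dt, method="zoh") -> np.ndarray:
    """Integrate from x(0)=0; returns states sampled on the input grid (d, n)."""
    A = np.asarray(A, dtype=float)
    C = np.asarray(C, dtype=float)
    u_drive = np.asarray(u_drive, dtype=float)
    n = u_drive.shape[0]
    d = A.shape[0]
    U = _stack_mods(u_mods, n)
    B = np.asarray(B_list, dtype=float).reshape(len(u_mods), d, d) if u_mods else np.zeros((0, d, d))

    out = trajectory_batch(A[None], B[None], C[None], u_drive, U, dt, method=method)
    return out[0]


def trajectory_batch(A_b, B_b, C_b, u_drive, u_mods, dt, method="zoh") -> np.ndarray:
    """Integrate a batch of P parameter sets under shared inputs -> (P, d, n).

    ``A_b``: (P, d, d); ``B_b``: (P, m, d, d); ``C_b``: (P, d);
    ``u_mods``: (m, n) stacked modulatory inputs.
    """
    A_b = np.asarray(A_b, dtype=float)
    B_b = np.asarray(B_b, dtype=float)
    C_b = np.asarray(C_b, dtype=float)
    u_drive = np.asarray(u_drive, dtype=float)
    U = np.asarray(u_mods, dtype=float)
    P, d, _ = A_b.shape
    n = u_drive.shape[0]

    if method == "euler":
        x = np.zeros((P, d))
        out = np.empty((P, d, n))
        for k in range(n):
            out[:, :, k] = x
            M = A_b + np.einsum("m,pmij->pij", U[:, k], B_b) if U.size else A_b
            x = x + dt * (np.einsum("pij,pj->pi", M, x) + C_b * u_drive[k])
        return out
    if method != "zoh":
        raise ValueError(f"unknown integration method {method!r}")

    # unique modulatory combinations -> cached (Phi, psi) per batch element
    if U.size:
        combos, idx = np.unique(U.T, axis=0, return_inverse=True)
    else:
        combos, idx = np.zeros((1, 0)), np.zeros(n, dtype=int)
    if len(combos) > _MAX_COMBOS:
        # inputs too irregular for caching; refine Euler instead
        refine = 8
        u_d = np.repeat(u_drive, refine)
        u_m = np.repeat(U, refine, axis=1)
        fine = trajectory_batch(A_b, B_b, C_b, u_d, u_m, dt / refine, method="euler")
        return fine[:, :, ::refine]

    n_c = len(combos)
    Phi = np.empty((n_c, P, d, d))
    psi = np.empty((n_c, P, d))
    aug = np.zeros((d + 1, d + 1))
    for c, u in enumerate(combos):
        for p in range(P):
            M = A_b[p] + np.einsum("m,mij->ij", u, B_b[p]) if u.size else A_b[p]
            aug[:d, :d] = M * dt
            aug[:d, d] = C_b[p] * dt
            E = expm(aug)
            Phi[c, p] = E[:d, :d]
            psi[c, p] = E[:d, d]

    x = np.zeros((P, d))
    out = np.empty((P, d, n))
    for k in range(n):
        out[:, :, k] = x
        c = idx[k]
        x = np.einsum("pij,pj->pi", Phi[c], x) + psi[c] * u_drive[k]
    return out
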