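"""Numba-compiled inner kernels of the semi-implicit spectral stepper.

These fuse the per-cell real-space arithmetic (regularised bulk potentials
and mass-action sources) and the per-mode spectral update into single
loops; they implement exactly the formulas of :mod:`llps_gsa.model` and
are cross-checked against them in the test suite.
"""

from __future__ import annotations

import numba
import numpy as np

from .model import LOG_CLAMP

_LOG_DELTA = float(np.log(LOG_CLAMP))


@numba.njit(cache=True, fastmath=True)
def bulk_and_reactions(K1, K2, P, R1, R2,
                       a1, a2, a3, a4, A, chi12, chiS, out):
    """Fill ``out`` (4, nx, ny) with mu_bulk(K1), mu_bulk(K2), f1, f2."""
    d = LOG_CLAMP
    nx, ny = K1.shape
    for i in range(nx):
        for j in range(ny):
            k1 = K1[i, j]
            k2 = K2[i, j]
            S = 1.0 - k1 - k2
            lk1 = np.log(k1) if k1 > d else _LOG_DELTA + (k1 - d) / d
            lk2 = np.log(k2) if k2 > d else _LOG_DELTA + (k2 - d) / d
            lS = np.log(S) if S > d else _LOG_DELTA + (S - d) / d
            common = chiS * (1.0 - 2.0 * k1 - 2.0 * k2)
            out[0, i, j] = A * (lk1 - lS + chi12 * k2 + common)
            out[1, i, j] = A * (lk2 - lS + chi12 * k1 + common)
            out[2, i, j] = a1 * P[i, j] * R1[i, j] - a2 * k1
            out[3, i, j] = a3 * P[i, j] * R2[i, j] - a4 * k2


@numba.njit(cache=True, fastmath=True)
def update_hats(H, B, K2w, denoms, lam1M, lam2M, s, dt):
    """Semi-implicit spectral update, in place on the five transforms ``H``.

    ``B`` holds the transforms of (mu_bulk1, mu_bulk2, f1, f2); ``denoms``
    the five precomputed implicit denominators; ``lam1M``/``lam2M`` the
    mobility-scaled complex diffusivities and ``s`` the stabilisation
    shift.
    """
    _, nx, ny = H.shape
    for i in range(nx):
        for j in range(ny):
            k2w = K2w[i, j]
            f1 = B[2, i, j]
            f2 = B[3, i, j]
            H[0, i, j] = (H[0, i, j]
                          - dt * lam1M * k2w * (B[0, i, j] - s * H[0, i, j])
                          + dt * f1) / denoms[0, i, j]
            H[1, i, j] = (H[1, i, j]
                          - dt * lam2M * k2w * (B[1, i, j] - s * H[1, i, j])
                          + dt * f2) / denoms[1, i, j]
            H[2, i, j] = (H[2, i, j] + dt * (-f1 - f2)) / denoms[2, i, j]
            H[3, i, j] = (H[3, i, j] - dt * f1) / denoms[3, i, j]
            H[4, i, j] = (H[4, i, j] - dt * f2) / denoms[4, i, j]
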