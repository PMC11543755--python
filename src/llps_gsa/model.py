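"""Phase-field model of two RNA species competing for one protein partner.

Five volume-fraction fields live on a 2-D periodic grid: free protein ``P``,
free RNAs ``R1`` and ``R2``, and the two protein-RNA complexes ``K1`` and
``K2``.  Complexes form by mass action (``P + R1 <-> K1`` at rates ``a1/a2``,
``P + R2 <-> K2`` at rates ``a3/a4``) and demix from the passive solvent
``S = 1 - K1 - K2`` under a Flory-Huggins free energy

    F = \\int (eps^2/2)(|grad K1|^2 + |grad K2|^2)
         + A (K1 ln K1 + K2 ln K2 + S ln S
              + chi_12 K1 K2 + chi_S K1 S + chi_S K2 S) dx

driving conserved Cahn-Hilliard dynamics for the complexes, while the free
species diffuse Fickian-ly.  The mobility prefactor is the constant 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields, replace
from functools import lru_cache

import numpy as np

__all__ = [
    "LOG_CLAMP",
    "ModelParameters",
    "FieldState",
    "solvent_field",
    "free_energy",
    "chemical_potentials",
    "reaction_terms",
]

#: Regularisation scale of the logarithmic entropy.  Below LOG_CLAMP the
#: logarithm is continued linearly (a C^1 extension), so the entropic
#: potential stays monotone-restoring -- fields are still driven back
#: towards positive values -- while its stiffness is bounded by
#: f'' <= A/LOG_CLAMP.  That bound is what lets the semi-implicit solver
#: hold a fixed stabilisation shift at a practical time step.  The value
#: sits near the dilute Flory-Huggins branch at the study's chi values.
#: Energy and chemical potentials use the same extension, so they remain an
#: exact discrete variational pair on both branches.
LOG_CLAMP = 0.02

#: Parameter sampling ranges for the sensitivity analyses (physical units).
SENSITIVITY_RANGES: dict[str, tuple[float, float]] = {
    "lambda_P": (0.0, 5.0),
    "lambda_R1": (0.0, 2.0),
    "lambda_R2": (0.0, 2.0),
    "lambda_K1": (0.0, 2.0),
    "lambda_K2": (0.0, 2.0),
    "a1": (0.5, 1.5),
    "a2": (0.0, 0.5),
    "a3": (0.5, 1.5),
    "a4": (0.0, 0.5),
}

#: Canonical ordering of the nine varied parameters.
VARIED_PARAMETERS = tuple(SENSITIVITY_RANGES)


@dataclass(frozen=True)
class ModelParameters:
    """Model rates and energies; defaults are the reported baseline values.

    Diffusion coefficients are in um^2/s, reaction rates in 1/s, the chi
    de-mixing energies and the scaling factor ``A`` are dimensionless.
    ``epsilon`` (um) sets the diffuse-interface width.  The default is two
    grid spacings of the 128x128 / 2.5 um reference grid, held fixed in
    physical units so that coarser working grids simulate the same
    dynamics; ``None`` resolves to two spacings of whatever grid is in
    use.
    """

    lambda_P: float = 3.75
    lambda_R1: float = 0.58
    lambda_R2: float = 0.145
    lambda_K1: float = 0.5
    lambda_K2: float = 0.139
    a1: float = 1.0
    a2: float = 0.01
    a3: float = 1.0
    a4: float = 0.01
    chi_S: float = 4.25
    chi_K1K2: float = 4.5
    A: float = 0.2
    epsilon: float | None = 2.0 * 2.5 / 128
    mobility: float = 1.0

    def __post_init__(self) -> None:
        for name in ("lambda_P", "lambda_R1", "lambda_R2", "lambda_K1", "lambda_K2"):
            if getattr(self, name) < 0:
                raise ValueError(f"diffusion coefficient {name} must be >= 0")
        if self.a1 <= 0 or self.a3 <= 0:
            raise ValueError("association rates a1, a3 must be > 0")
        if self.a2 < 0 or self.a4 < 0:
            raise ValueError("disassociation rates a2, a4 must be >= 0")
        if self.A <= 0:
            raise ValueError("free-energy scale A must be > 0")
        if self.epsilon is not None and self.epsilon <= 0:
            raise ValueError("interface width epsilon must be > 0")

    def resolve_epsilon(self, h: float) -> float:
        """Interface-width coefficient, defaulting to two grid spacings."""
        return 2.0 * h if self.epsilon is None else self.epsilon

    def with_values(self, **kwargs: float) -> "ModelParameters":
        return replace(self, **kwargs)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)
                if getattr(self, f.name) is not None}


@dataclass
class FieldState:
    """The five concentration fields on one shared periodic grid.

    Volume fractions are dimensionless; ``h`` is the grid spacing in um and
    ``time`` the model time in seconds.  Admissibility means every field in
    [0, 1) and K1 + K2 < 1 everywhere so the solvent fraction stays positive.
    """

    K1: np.ndarray
    K2: np.ndarray
    P: np.ndarray
    R1: np.ndarray
    R2: np.ndarray
    h: float
    time: float = 0.0

    def __post_init__(self) -> None:
        shape = self.K1.shape
        for name in ("K2", "P", "R1", "R2"):
            if getattr(self, name).shape != shape:
                raise ValueError("all five fields must share one grid")
        if self.h <= 0:
            raise ValueError("grid spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.K1.shape

    def fields(self) -> dict[str, np.ndarray]:
        return {"K1": self.K1, "K2": self.K2, "P": self.P,
                "R1": self.R1, "R2": self.R2}

    def validate(self, atol: float = 0.0) -> None:
        """Raise if any field leaves [0, 1) or the solvent fraction S <= 0."""
        for name, arr in self.fields().items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in field {name}")
            if arr.min() < -atol or arr.max() >= 1.0 + atol:
                raise ValueError(f"field {name} outside [0, 1)")
        if (self.K1 + self.K2).max() >= 1.0 + atol:
            raise ValueError("K1 + K2 >= 1 somewhere: solvent fraction S <= 0")

    def copy(self) -> "FieldState":
        return FieldState(self.K1.copy(), self.K2.copy(), self.P.copy(),
                          self.R1.copy(), self.R2.copy(), self.h, self.time)


def solvent_field(state: FieldState) -> np.ndarray:
    """Passive solvent fraction S = 1 - K1 - K2, pointwise.

    Raises ``ValueError`` if S <= 0 anywhere -- the incompressibility
    constraint failing is the signature of a solver blow-up.
    """
    S = 1.0 - state.K1 - state.K2
    if S.min() <= 0.0:
        raise ValueError("solvent fraction S <= 0: K1 + K2 reached 1")
    return S


def _safe_log(x: np.ndarray, delta: float = LOG_CLAMP) -> np.ndarray:
    """log(x) for x > delta, continued linearly below (C^1 at delta)."""
    x = np.asarray(x, dtype=float)
    return np.where(x > delta, np.log(np.maximum(x, delta)),
                    np.log(delta) + (x - delta) / delta)


def _entropy(x: np.ndarray, delta: float = LOG_CLAMP) -> np.ndarray:
    """x*log(x) with the quadratic continuation matching _safe_log, i.e.
    d/dx entropy(x) = _safe_log(x) + 1 on both branches."""
    x = np.asarray(x, dtype=float)
    above = x * np.log(np.maximum(x, delta))
    below = (delta * np.log(delta) + (np.log(delta) + 1.0) * (x - delta)
             + (x - delta) ** 2 / (2.0 * delta))
    return np.where(x > delta, above, below)


@lru_cache(maxsize=8)
def _wavenumbers(nx: int, ny: int, h: float):
    """Spectral wavenumbers for an nx-by-ny periodic grid (rfft2 layout)."""
    kx = 2.0 * np.pi * np.fft.fftfreq(nx, d=h)
    ky = 2.0 * np.pi * np.fft.rfftfreq(ny, d=h)
    KX = kx[:, None]
    KY = ky[None, :]
    return KX, KY, KX**2 + KY**2


def _grad_energy_spectral(f: np.ndarray, h: float) -> float:
    """Integral of |grad f|^2 over the periodic domain, evaluated in
    Fourier space with the same -k^2 symbol as :func:`laplacian`, so the
    discrete free energy and the chemical potentials are exactly adjoint
    pairs (including the Nyquist modes)."""
    nx, ny = f.shape
    _, _, K2 = _wavenumbers(nx, ny, h)
    fh = np.fft.rfft2(f)
    # rfft2 stores only half the spectrum: interior columns represent two
    # conjugate modes each
    w = np.full(fh.shape[1], 2.0)
    w[0] = 1.0
    if ny % 2 == 0:
        w[-1] = 1.0
    power = (np.abs(fh) ** 2 * K2 * w).sum() / (nx * ny)
    return float(power * h**2)


def _grad_sq_fd(f: np.ndarray, h: float) -> np.ndarray:
    fx = (np.roll(f, -1, axis=0) - np.roll(f, 1, axis=0)) / (2.0 * h)
    fy = (np.roll(f, -1, axis=1) - np.roll(f, 1, axis=1)) / (2.0 * h)
    return fx**2 + fy**2


def laplacian(f: np.ndarray, h: float, method: str = "spectral") -> np.ndarray:
    """Periodic Laplacian, spectral by default with a centred-difference
    fallback (the two agree to discretisation error on smooth fields)."""
    if method == "spectral":
        _, _, K2 = _wavenumbers(*f.shape, h)
        return np.fft.irfft2(-K2 * np.fft.rfft2(f), s=f.shape)
    if method == "fd":
        return (np.roll(f, 1, 0) + np.roll(f, -1, 0) + np.roll(f, 1, 1)
                + np.roll(f, -1, 1) - 4.0 * f) / h**2
    raise ValueError(f"unknown discretisation {method!r}")


def bulk_free_energy_density(K1: np.ndarray, K2: np.ndarray,
                             params: ModelParameters) -> np.ndarray:
    """Flory-Huggins bulk density A*(entropy + chi interaction terms)."""
    S = 1.0 - K1 - K2
    ent = _entropy(K1) + _entropy(K2) + _entropy(S)
    mix = (params.chi_K1K2 * K1 * K2
           + params.chi_S * K1 * S + params.chi_S * K2 * S)
    return params.A * (ent + mix)


def free_energy(state: FieldState, params: ModelParameters,
                method: str = "spectral") -> float:
    """Discretised free-energy functional, integrated over the domain.

    Gradient terms use the periodic spectral convention by default
    (``method='fd'`` switches to centred differences).
    """
    eps = params.resolve_epsilon(state.h)
    if method == "spectral":
        grad_term = 0.5 * eps**2 * (_grad_energy_spectral(state.K1, state.h)
                                    + _grad_energy_spectral(state.K2, state.h))
    elif method == "fd":
        grad_term = float(0.5 * eps**2
                          * (_grad_sq_fd(state.K1, state.h)
                             + _grad_sq_fd(state.K2, state.h)).sum()
                          * state.h**2)
    else:
        raise ValueError(f"unknown discretisation {method!r}")
    bulk = bulk_free_energy_density(state.K1, state.K2, params)
    F = grad_term + float(bulk.sum() * state.h**2)
    if not np.isfinite(F):
        raise FloatingPointError("free energy is non-finite")
    return F


def bulk_potentials(K1: np.ndarray, K2: np.ndarray,
                    params: ModelParameters) -> tuple[np.ndarray, np.ndarray]:
    """Bulk (non-gradient) part of the chemical potentials dF/dK1, dF/dK2."""
    S = 1.0 - K1 - K2
    logS = _safe_log(S)
    common = params.chi_S * (1.0 - 2.0 * K1 - 2.0 * K2)
    mu1 = params.A * (_safe_log(K1) - logS + params.chi_K1K2 * K2 + common)
    mu2 = params.A * (_safe_log(K2) - logS + params.chi_K1K2 * K1 + common)
    return mu1, mu2


def chemical_potentials(state: FieldState, params: ModelParameters,
                        method: str = "spectral") -> tuple[np.ndarray, np.ndarray]:
    """Variational derivatives (dF/dK1, dF/dK2) of the free energy.

    mu_K1 = -eps^2 lap(K1) + A [ln(K1/S) + chi_12 K2 + chi_S (1 - 2K1 - 2K2)]
    and symmetrically for K2.
    """
    eps = params.resolve_epsilon(state.h)
    b1, b2 = bulk_potentials(state.K1, state.K2, params)
    mu1 = -eps**2 * laplacian(state.K1, state.h, method) + b1
    mu2 = -eps**2 * laplacian(state.K2, state.h, method) + b2
    if not (np.all(np.isfinite(mu1)) and np.all(np.isfinite(mu2))):
        raise FloatingPointError("chemical potential is non-finite")
    return mu1, mu2


def reaction_terms(state: FieldState, params: ModelParameters
                   ) -> dict[str, np.ndarray]:
    """Mass-action sources (1/s) for all five fields.

    K1 forms at rate a1*P*R1 and dissolves at a2*K1; K2 at a3*P*R2 / a4*K2.
    The protein and RNA sources are the exact negatives, so P+K1+K2, R1+K1
    and R2+K2 are pointwise conserved by the kinetics.
    """
    f1 = params.a1 * state.P * state.R1 - params.a2 * state.K1
    f2 = params.a3 * state.P * state.R2 - params.a4 * state.K2
    return {"K1": f1, "K2": f2, "P": -f1 - f2, "R1": -f1, "R2": -f2}
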