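"""Synthetic ground-truth inputs for testing the QoI and sensitivity stages.

Everything downstream of the PDE solver can be exercised without solving a
PDE: droplet fields are painted directly as tanh-profiled disks with a known
census, trajectories are assembled from such fields so the separation
detector's ceiling/cap paths are reachable, and cheap surrogate QoI
functions with closed-form (or brute-force quadrature) Sobol' indices stand
in for the expensive simulation QoIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import FieldState, ModelParameters
from .simulate import GridSpec, InitialConditionSpec, Trajectory

__all__ = [
    "Disk",
    "DropletFixtureSpec",
    "SurrogateSpec",
    "make_droplet_field",
    "make_fixture_trajectory",
    "surrogate_qoi",
]


@dataclass(frozen=True)
class Disk:
    """One synthetic droplet: centre (cells), radius (cells), species."""

    cx: float
    cy: float
    radius: float
    species: str = "K1"
    plateau: float = 0.8

    def __post_init__(self):
        if self.species not in ("K1", "K2"):
            raise ValueError("species must be 'K1' or 'K2'")
        if self.radius <= 0 or not 0 < self.plateau < 1:
            raise ValueError("invalid disk geometry")


@dataclass(frozen=True)
class DropletFixtureSpec:
    """Synthetic droplet-field image with an exact census."""

    shape: tuple[int, int] = (64, 64)
    disks: tuple[Disk, ...] = ()
    background: float = 0.05
    interface_width: float = 1.0     # cells; tanh profile half-width
    noise_amplitude: float = 0.0
    seed: int = 0
    h: float = 10.0 / 64

    def __post_init__(self):
        for d in self.disks:
            if d.plateau <= self.background:
                raise ValueError("disk plateau must exceed the background")


@dataclass(frozen=True)
class SurrogateSpec:
    """Analytic stand-in QoI with exactly known sensitivity indices."""

    family: str = "linear"
    dimension: int = 3
    coefficients: tuple[float, ...] | None = None
    a: float = 7.0       # Ishigami parameters
    b: float = 0.1
    cap: float = 10.0    # capped-step family

    def __post_init__(self):
        if self.family not in ("linear", "product", "ishigami", "capped-step"):
            raise ValueError(f"unknown surrogate family {self.family!r}")


def _periodic_distance(shape: tuple[int, int], cx: float, cy: float
                       ) -> np.ndarray:
    nx, ny = shape
    ix = np.arange(nx)[:, None]
    iy = np.arange(ny)[None, :]
    dx = np.minimum(np.abs(ix - cx), nx - np.abs(ix - cx))
    dy = np.minimum(np.abs(iy - cy), ny - np.abs(iy - cy))
    return np.sqrt(dx**2 + dy**2)


def make_droplet_field(spec: DropletFixtureSpec
                       ) -> tuple[FieldState, dict]:
    """Paint the disks and return the field plus its exact ground truth.

    Ground truth: total droplet count, per-disk species tags and the
    analytic K1 count fraction.  Overlapping disks of different species are
    rejected (their census would be ambiguous).
    """
    nx, ny = spec.shape
    half_bg = spec.background / 2.0
    K1 = np.full(spec.shape, half_bg)
    K2 = np.full(spec.shape, half_bg)
    ownership = np.zeros(spec.shape, dtype=int)   # 0 none, 1 K1, 2 K2
    for d in spec.disks:
        dist = _periodic_distance(spec.shape, d.cx, d.cy)
        profile = 0.5 * (1.0 - np.tanh((dist - d.radius)
                                       / spec.interface_width))
        inside = dist <= d.radius + 2.0 * spec.interface_width
        tag = 1 if d.species == "K1" else 2
        clash = inside & (ownership != 0) & (ownership != tag)
        if clash.any():
            raise ValueError("overlapping disks of different species: "
                             "ground truth would be ambiguous")
        ownership[inside] = tag
        target = K1 if d.species == "K1" else K2
        np.maximum(target, half_bg + (d.plateau - half_bg) * profile,
                   out=target)
    if spec.noise_amplitude:
        rng = np.random.default_rng(spec.seed)
        for f in (K1, K2):
            f += rng.uniform(-spec.noise_amplitude, spec.noise_amplitude,
                             size=spec.shape)
            np.clip(f, 1e-6, None, out=f)

    rest = np.clip(1.0 - K1 - K2, 1e-3, None)
    state = FieldState(K1=K1, K2=K2, P=rest / 2.0, R1=rest / 4.0,
                       R2=rest / 4.0, h=spec.h, time=0.0)
    n = len(spec.disks)
    n_k1 = sum(d.species == "K1" for d in spec.disks)
    truth = {
        "n_droplets": n,
        "n_k1_droplets": n_k1,
        "species": tuple(d.species for d in spec.disks),
        "areas": tuple(int(np.pi * d.radius**2 + 0.5) for d in spec.disks),
        "k1_fraction": n_k1 / n if n else None,
    }
    return state, truth


def make_fixture_trajectory(separation_second: float | None,
                            spec: DropletFixtureSpec,
                            t_cap: float = 10.0) -> Trajectory:
    """Trajectory that is well mixed before ``separation_second`` and shows
    the spec's droplet field from that second onward.

    ``separation_second=None`` never separates, exercising the cap path.
    """
    mixed_spec = DropletFixtureSpec(shape=spec.shape, disks=(),
                                    background=spec.background, h=spec.h)
    mixed, _ = make_droplet_field(mixed_spec)
    separated, _ = make_droplet_field(spec)
    snapshots = []
    for t in range(int(t_cap) + 1):
        src = mixed if (separation_second is None
                        or t < separation_second) else separated
        snap = src.copy()
        snap.time = float(t)
        snapshots.append(snap)
    return Trajectory(snapshots, ModelParameters(), None, t_cap,
                      meta={"fixture": True,
                            "separation_second": separation_second})


# ---------------------------------------------------------------------------
# surrogate QoI functions with known variance decompositions


def _ishigami_indices(a: float, b: float) -> dict:
    V1 = b * np.pi**4 / 5 + b**2 * np.pi**8 / 50 + 0.5
    V2 = a**2 / 8.0
    V13 = b**2 * np.pi**8 * (1.0 / 18 - 1.0 / 50)
    V = V1 + V2 + V13
    S1 = np.array([V1 / V, V2 / V, 0.0])
    ST = np.array([(V1 + V13) / V, V2 / V, V13 / V])
    S2 = np.full((3, 3), 0.0)
    S2[0, 2] = S2[2, 0] = V13 / V
    np.fill_diagonal(S2, np.nan)
    return {"S1": S1, "ST": ST, "S2": S2, "variance": V}


def _capped_step_indices(cap: float, m: int = 2000) -> dict:
    """Brute-force midpoint-quadrature decomposition of the 2-D capped-step
    surrogate (exact up to quadrature error; the function is bounded)."""
    u = (np.arange(m) + 0.5) / m
    X1, X2 = np.meshgrid(u, u, indexing="ij")
    Y = _capped_step_eval(X1, X2, cap)
    V = Y.var()
    E1 = Y.mean(axis=1)          # E[Y | X1]
    E2 = Y.mean(axis=0)
    S1 = np.array([E1.var() / V, E2.var() / V])
    # two inputs: everything not first order is the pair interaction
    S2 = np.full((2, 2), np.nan)
    S2[0, 1] = S2[1, 0] = 1.0 - S1[0] - S1[1]
    ST = np.array([1.0 - S1[1], 1.0 - S1[0]])
    return {"S1": S1, "ST": ST, "S2": S2, "variance": V}


def _capped_step_eval(X1, X2, cap):
    """Whole-second separation-time mimic: a smooth rate map pushed through
    a ceiling and a cap, reproducing the discrete, clustered QoI geometry."""
    rate = 0.35 * X1 + 0.65 * X1 * X2 + 0.05
    return np.minimum(np.ceil(1.0 / rate), cap)


def surrogate_qoi(spec: SurrogateSpec):
    """Return (evaluator on the unit cube, analytic index dictionary).

    Families: ``linear`` (sum of c_i X_i, additive), ``product``
    (X1*X2 on zero-mean uniforms, purely interactive), ``ishigami``
    (the standard three-parameter benchmark), and ``capped-step``
    (discontinuous, mimicking the capped/sentinel simulation QoIs).
    """
    if spec.family == "linear":
        c = np.array(spec.coefficients
                     if spec.coefficients is not None
                     else np.ones(spec.dimension))
        Vi = c**2 / 12.0
        V = Vi.sum()
        S1 = Vi / V
        S2 = np.zeros((c.size, c.size))
        np.fill_diagonal(S2, np.nan)
        indices = {"S1": S1, "ST": S1.copy(), "S2": S2, "variance": V}

        def f(x):
            return float(np.dot(c, np.asarray(x)))

    elif spec.family == "product":
        S2 = np.full((2, 2), np.nan)
        S2[0, 1] = S2[1, 0] = 1.0
        indices = {"S1": np.zeros(2), "ST": np.ones(2), "S2": S2,
                   "variance": 1.0 / 9.0}

        def f(x):
            z = 2.0 * np.asarray(x) - 1.0
            return float(z[0] * z[1])

    elif spec.family == "ishigami":
        a, b = spec.a, spec.b
        indices = _ishigami_indices(a, b)

        def f(x):
            z = np.pi * (2.0 * np.asarray(x) - 1.0)
            return float(np.sin(z[0]) + a * np.sin(z[1])**2
                         + b * z[2]**4 * np.sin(z[0]))

    else:  # capped-step
        indices = _capped_step_indices(spec.cap)

        def f(x):
            x = np.asarray(x)
            return float(_capped_step_eval(x[0], x[1], spec.cap))

    return f, indices
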