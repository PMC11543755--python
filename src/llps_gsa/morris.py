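"""Morris elementary-effects screening with a tiny fixed step.

Each of ``r`` base points is drawn i.i.d. uniform on the unit hypercube;
every coordinate is then perturbed one at a time by a fixed step delta
(reflected to -delta at the upper boundary) and the finite-difference slope
of the quantity of interest along that coordinate is the elementary effect.
mu* (mean absolute effect) ranks parameter importance; sigma (spread of the
signed effects) flags nonlinearity and interaction.  The design costs
r * (p + 1) evaluations because each base evaluation is shared by all p
perturbations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import SENSITIVITY_RANGES

__all__ = [
    "MorrisDesign",
    "MorrisResult",
    "sample_base_points",
    "elementary_effects",
    "morris_stats",
    "screen",
]


@dataclass(frozen=True)
class MorrisDesign:
    """Screening design: parameter ranges, unit-cube step, sample count."""

    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(SENSITIVITY_RANGES))
    delta: float = 0.001
    r: int = 1000
    seed: int = 0
    # number of levels the range is notionally divided into; metadata only,
    # sampling uses the continuous uniform measure with the fixed delta.
    levels: int | None = None

    def __post_init__(self):
        if not 0.0 < self.delta < 1.0:
            raise ValueError("delta must lie in (0, 1)")
        if self.r < 2:
            raise ValueError("need at least r=2 base samples")
        for name, (lo, hi) in self.ranges.items():
            if hi <= lo:
                raise ValueError(f"empty range for {name}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.ranges)

    @property
    def p(self) -> int:
        return len(self.ranges)

    def scale(self, X: np.ndarray) -> np.ndarray:
        """Map unit-cube points to physical parameter values."""
        lo = np.array([r[0] for r in self.ranges.values()])
        hi = np.array([r[1] for r in self.ranges.values()])
        return lo + np.asarray(X) * (hi - lo)


@dataclass
class MorrisResult:
    """Per-parameter screening statistics plus the raw effects for audit."""

    names: tuple[str, ...]
    mu_star: np.ndarray
    sigma: np.ndarray              # about the signed-EE mean (default)
    sigma_as_printed: np.ndarray   # deviations taken about mu*
    effects: np.ndarray            # r x p signed elementary effects
    qoi: str = ""
    ratio: str = ""

    def __post_init__(self):
        if not (len(self.names) == self.mu_star.size == self.sigma.size):
            raise ValueError("inconsistent result lengths")
        if not (np.all(np.isfinite(self.mu_star))
                and np.all(np.isfinite(self.sigma))):
            raise ValueError("non-finite Morris statistics")


def sample_base_points(design: MorrisDesign
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Draw the r base points and their signed unit-cube steps.

    Steps are +delta except where that would leave the cube, in which case
    the reflected step -delta is used; both the base and perturbed points
    therefore always stay inside [0, 1].
    """
    rng = np.random.default_rng(design.seed)
    X = rng.uniform(size=(design.r, design.p))
    steps = np.where(X + design.delta <= 1.0, design.delta, -design.delta)
    return X, steps


def elementary_effects(f, design: MorrisDesign,
                       base: tuple[np.ndarray, np.ndarray] | None = None
                       ) -> np.ndarray:
    """r x p matrix of elementary effects of ``f`` over the design.

    ``f`` maps a physical parameter vector (ordered as ``design.names``) to
    a scalar QoI.  Effects are slopes on the unit-scaled space:
    EE_j = [Y(x + step_j e_j) - Y(x)] / step_j, so a reflected step keeps
    the sign convention of a forward difference.
    """
    X, steps = sample_base_points(design) if base is None else base
    EE = np.empty_like(X)
    for i in range(design.r):
        x = X[i]
        try:
            y0 = float(f(design.scale(x)))
            for j in range(design.p):
                xp = x.copy()
                xp[j] += steps[i, j]
                EE[i, j] = (float(f(design.scale(xp))) - y0) / steps[i, j]
        except Exception as err:
            raise RuntimeError(
                f"QoI evaluation failed at base sample {i}, "
                f"x={design.scale(x)!r}") from err
    return EE


def morris_stats(effects: np.ndarray, names, qoi: str = "",
                 ratio: str = "") -> MorrisResult:
    """mu* and sigma from the elementary-effect samples.

    mu*_j = mean |EE_j|.  Two sigma conventions are computed: the standard
    sample standard deviation about the signed mean, and an "as printed"
    variant whose deviations are taken about mu* itself; both use the
    1/(r-1) normalisation.
    """
    effects = np.asarray(effects, dtype=float)
    if effects.ndim != 2 or effects.shape[0] < 2:
        raise ValueError("need a 2-D effects matrix with >= 2 samples")
    r = effects.shape[0]
    mu_star = np.abs(effects).mean(axis=0)
    sigma = effects.std(axis=0, ddof=1)
    sigma_printed = np.sqrt(((effects - mu_star) ** 2).sum(axis=0) / (r - 1))
    return MorrisResult(tuple(names), mu_star, sigma, sigma_printed,
                        effects, qoi=qoi, ratio=ratio)


def screen(result: MorrisResult, rule: str = "threshold",
           alpha: float = 0.4) -> list[str]:
    """Partition parameters into retained (influential) and freezable sets.

    ``rule='threshold'`` keeps parameter j iff mu*_j >= alpha * max mu*;
    ``rule='largest-gap'`` splits the sorted mu* at the largest ratio
    between consecutive values and keeps everything above the gap.
    """
    mu = result.mu_star
    if rule == "threshold":
        keep = mu >= alpha * mu.max()
    elif rule == "largest-gap":
        order = np.argsort(mu)[::-1]
        sorted_mu = mu[order]
        if np.allclose(sorted_mu, sorted_mu[0]):
            keep = np.ones_like(mu, dtype=bool)
        else:
            with np.errstate(divide="ignore"):
                ratios = sorted_mu[:-1] / np.maximum(sorted_mu[1:], 1e-300)
            cut = int(np.argmax(ratios)) + 1
            keep = np.zeros_like(mu, dtype=bool)
            keep[order[:cut]] = True
    else:
        raise ValueError("rule must be 'threshold' or 'largest-gap'")
    return [n for n, k in zip(result.names, keep) if k]
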