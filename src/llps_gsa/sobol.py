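"""Saltelli-sampled Sobol' variance decomposition with convergence doubling.

Two base matrices A and B are drawn from a scrambled low-discrepancy
sequence; cross matrices AB^(i) (columns of A with column i from B) and,
when second-order indices are requested, BA^(i) complete the design.  The
evaluation budget is n(p+2) without second order and n(2p+2) with it.

Estimators follow the conventions of the standard Saltelli toolchain:
the Saltelli-2010 form for first-order indices, the Jansen form for total
order, and the closed Saltelli-2002 pair estimator for second order.
Convergence is assessed by doubling n until the total-order indices change
by less than a relative threshold between consecutive doublings; the
sequence property that a 2n-point draw extends the n-point draw lets every
earlier evaluation be reused.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import qmc

__all__ = [
    "SobolDesign",
    "SaltelliSample",
    "SobolResult",
    "ConvergenceError",
    "saltelli_sample",
    "estimate_first_order",
    "estimate_total_order",
    "estimate_second_order",
    "sobol_indices",
    "converge",
]


@dataclass(frozen=True)
class SobolDesign:
    """Sampling design over the (possibly screened) parameter space."""

    ranges: dict[str, tuple[float, float]]
    n: int = 128
    second_order: bool = False
    seed: int = 0
    scramble: bool = True

    def __post_init__(self):
        if self.n < 2 or self.n & (self.n - 1):
            raise ValueError("n must be a power of two")
        if not self.ranges:
            raise ValueError("need at least one varied parameter")
        for name, (lo, hi) in self.ranges.items():
            if hi <= lo:
                raise ValueError(f"empty range for {name}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.ranges)

    @property
    def p(self) -> int:
        return len(self.ranges)

    @property
    def n_evaluations(self) -> int:
        return self.n * (2 * self.p + 2 if self.second_order else self.p + 2)

    def scale(self, U: np.ndarray) -> np.ndarray:
        lo = np.array([r[0] for r in self.ranges.values()])
        hi = np.array([r[1] for r in self.ranges.values()])
        return lo + np.asarray(U) * (hi - lo)


@dataclass
class SaltelliSample:
    """Evaluation matrix plus the block bookkeeping needed by estimators."""

    design: SobolDesign
    rows: np.ndarray        # k x p physical-unit evaluation points
    unit_rows: np.ndarray   # same points on the unit cube (cache keys)

    @property
    def n(self) -> int:
        return self.design.n

    def blocks(self, Y: np.ndarray):
        """Split an output vector into (fA, fB, fAB[p x n], fBA or None)."""
        n, p = self.design.n, self.design.p
        Y = np.asarray(Y, dtype=float)
        if Y.size != self.design.n_evaluations:
            raise ValueError("output length does not match the design")
        fA, fB = Y[:n], Y[n:2 * n]
        fAB = Y[2 * n:2 * n + p * n].reshape(p, n)
        fBA = None
        if self.design.second_order:
            fBA = Y[2 * n + p * n:].reshape(p, n)
        return fA, fB, fAB, fBA


@dataclass
class SobolResult:
    """First/total/pairwise indices with estimator metadata."""

    names: tuple[str, ...]
    S1: np.ndarray
    ST: np.ndarray
    S2_raw: np.ndarray | None
    S2_clipped: np.ndarray | None
    n: int
    history: list[dict] = field(default_factory=list)

    def __post_init__(self):
        if not np.all(np.isfinite(self.ST)):
            raise ValueError("non-finite total-order indices")
        if self.S2_clipped is not None and np.nanmin(self.S2_clipped) < 0:
            raise ValueError("clipped S2 must be non-negative")

    @property
    def interaction_share(self) -> np.ndarray:
        """(ST - S1)/ST per parameter; the part of a parameter's total
        influence owed to interactions with other parameters."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.ST != 0, (self.ST - self.S1) / self.ST,
                            0.0)


class ConvergenceError(RuntimeError):
    """Doubling budget exhausted; carries the partial history."""

    def __init__(self, message: str, history: list[dict]):
        super().__init__(message)
        self.history = history


def saltelli_sample(design: SobolDesign) -> SaltelliSample:
    """Build the A / B / AB (and BA) evaluation matrix, deterministically.

    The base sequence is a scrambled Sobol' sequence in 2p dimensions; the
    first p coordinates form A, the last p form B.  Because sequential
    draws extend the sequence, designs at n and 2n with the same seed share
    their first-n rows, which ``converge`` exploits to reuse evaluations.
    """
    p, n = design.p, design.n
    eng = qmc.Sobol(d=2 * p, scramble=design.scramble, seed=design.seed)
    base = eng.random(n)
    A, B = base[:, :p], base[:, p:]
    blocks = [A, B]
    for i in range(p):
        AB = A.copy()
        AB[:, i] = B[:, i]
        blocks.append(AB)
    if design.second_order:
        for i in range(p):
            BA = B.copy()
            BA[:, i] = A[:, i]
            blocks.append(BA)
    unit_rows = np.vstack(blocks)
    return SaltelliSample(design, design.scale(unit_rows), unit_rows)


def _variance(fA: np.ndarray, fB: np.ndarray) -> float:
    V = float(np.var(np.concatenate([fA, fB])))
    if V == 0.0:
        raise ValueError("constant output: Sobol' indices are undefined")
    return V


def estimate_first_order(fA, fB, fAB) -> np.ndarray:
    """Saltelli-2010 first-order estimator; may be slightly negative by
    Monte-Carlo noise (reported raw)."""
    V = _variance(fA, fB)
    return np.array([np.mean(fB * (fABi - fA)) for fABi in fAB]) / V


def estimate_total_order(fA, fB, fAB) -> np.ndarray:
    """Jansen total-order estimator."""
    V = _variance(fA, fB)
    return np.array([0.5 * np.mean((fA - fABi) ** 2) for fABi in fAB]) / V


def estimate_second_order(fA, fB, fAB, fBA) -> np.ndarray:
    """Closed pairwise (Saltelli-2002) estimator; returns the raw p x p
    symmetric matrix with NaN on the diagonal."""
    if fBA is None:
        raise ValueError("second-order sampling (BA blocks) not available")
    V = _variance(fA, fB)
    S1 = estimate_first_order(fA, fB, fAB)
    p = len(fAB)
    S2 = np.full((p, p), np.nan)
    for j in range(p):
        for k in range(j + 1, p):
            Vjk = np.mean(fBA[j] * fAB[k] - fA * fB) / V
            S2[j, k] = S2[k, j] = Vjk - S1[j] - S1[k]
    return S2


def sobol_indices(Y: np.ndarray, sample: SaltelliSample,
                  history: list[dict] | None = None) -> SobolResult:
    """All indices for one evaluated sample; negative pairwise estimates are
    additionally reported clipped to zero, the raw values retained."""
    fA, fB, fAB, fBA = sample.blocks(Y)
    S1 = estimate_first_order(fA, fB, fAB)
    ST = estimate_total_order(fA, fB, fAB)
    S2 = S2c = None
    if sample.design.second_order:
        S2 = estimate_second_order(fA, fB, fAB, fBA)
        S2c = np.where(np.isnan(S2), np.nan, np.clip(S2, 0.0, None))
    return SobolResult(sample.design.names, S1, ST, S2, S2c,
                       n=sample.design.n, history=history or [])


def converge(f, design: SobolDesign, threshold: float = 0.1,
             abs_floor: float = 0.01, max_doublings: int = 8,
             cache: dict | None = None) -> SobolResult:
    """Double n until every total-order index changes by < ``threshold``
    relative between consecutive doublings.

    Parameters whose |ST| is below ``abs_floor`` are treated as converged to
    avoid dividing by a near-zero index.  Evaluations are cached on the
    unit-cube row, so each doubling only pays for the new rows.
    """
    cache = {} if cache is None else cache
    history: list[dict] = []
    prev_ST = None
    n = design.n
    for _ in range(max_doublings + 1):
        des = replace(design, n=n)
        sample = saltelli_sample(des)
        Y = np.empty(len(sample.rows))
        for i, (u, x) in enumerate(zip(sample.unit_rows, sample.rows)):
            key = u.tobytes()
            if key not in cache:
                cache[key] = float(f(x))
            Y[i] = cache[key]
        result = sobol_indices(Y, sample)
        history.append({"n": n, "n_evaluations": des.n_evaluations,
                        "S1": result.S1.tolist(), "ST": result.ST.tolist()})
        if prev_ST is not None:
            with np.errstate(divide="ignore", invalid="ignore"):
                rel = np.abs(result.ST - prev_ST) / np.abs(prev_ST)
            settled = (np.abs(result.ST) < abs_floor) | (rel < threshold)
            if np.all(settled):
                result.history = history
                return result
        prev_ST = result.ST
        n *= 2
    raise ConvergenceError(
        f"total-order indices did not converge within {max_doublings} "
        "doublings", history)
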