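"""Operational quantities of interest extracted from simulated trajectories.

Two scalars summarise a run: the whole-second time of phase separation
(first recorded second with at least one droplet) and the count fraction of
K1-type droplets at that instant.  Runs that never separate within the cap
time keep the cap as their time and carry the sentinel fraction 1.25 so
they remain distinguishable from genuinely K1- or K2-homogeneous fields.

A droplet is a connected component (8-connectivity, periodic wraparound) of
cells where the total complex K1 + K2 exceeds a threshold, with small
components discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .model import FieldState
from .simulate import Trajectory

__all__ = [
    "SENTINEL_FRACTION",
    "MORRIS_TIME_CAP",
    "SOBOL_TIME_CAP",
    "DropletStats",
    "QoIRecord",
    "label_droplets",
    "detect_separation",
    "k1_droplet_fraction",
    "qoi_record",
]

#: Composition placeholder for runs that never separate within the cap.
SENTINEL_FRACTION = 1.25
#: Separation-time cap used for the screening stage (seconds).
MORRIS_TIME_CAP = 1000.0
#: Separation-time cap used for the variance-based stage (seconds).
SOBOL_TIME_CAP = 10.0

DEFAULT_THETA = 0.5
DEFAULT_MIN_AREA = 4


@dataclass(frozen=True)
class DropletStats:
    """Census entry for one droplet."""

    label: int
    area: int            # cells
    mean_K1: float
    mean_K2: float

    @property
    def is_k1_type(self) -> bool:
        """Dominant-species classification; ties resolve to K1-type."""
        return self.mean_K1 >= self.mean_K2


@dataclass(frozen=True)
class QoIRecord:
    """Per-run QoI pair with the capping/sentinel conventions applied."""

    t_sep: float
    k1_fraction: float
    separated: bool
    n_droplets: int = 0
    n_k1_droplets: int = 0

    def __post_init__(self):
        if self.separated:
            if self.n_droplets < 1:
                raise ValueError("separated run must have >= 1 droplet")
        else:
            if self.k1_fraction != SENTINEL_FRACTION:
                raise ValueError("unseparated run must carry the sentinel "
                                 f"fraction {SENTINEL_FRACTION}")


def _merge_periodic(labels: np.ndarray, n: int) -> np.ndarray:
    """Union labels that touch across the periodic boundary (8-connectivity)."""
    parent = np.arange(n + 1)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(pairs_a, pairs_b):
        for a, b in zip(pairs_a, pairs_b):
            if a and b:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)

    for shift in (-1, 0, 1):
        union(labels[0, :], np.roll(labels[-1, :], shift))
        union(labels[:, 0], np.roll(labels[:, -1], shift))
    roots = np.array([find(i) for i in range(n + 1)])
    # compact to consecutive labels, background stays 0
    uniq = np.unique(roots[1:]) if n else np.array([], dtype=int)
    remap = np.zeros(n + 1, dtype=int)
    remap[uniq] = np.arange(1, uniq.size + 1)
    return remap[roots][labels]


def label_droplets(state: FieldState, theta: float = DEFAULT_THETA,
                   min_area: int = DEFAULT_MIN_AREA
                   ) -> tuple[np.ndarray, list[DropletStats]]:
    """Binarise on K1 + K2 >= theta and label periodic connected components.

    Components smaller than ``min_area`` cells are discarded.  Returns the
    label map (0 = background) and the per-droplet census.
    """
    if not 0.0 < theta < 1.0:
        raise ValueError("theta must lie in (0, 1)")
    mask = (state.K1 + state.K2) >= theta
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n:
        labels = _merge_periodic(labels, n)
        n = labels.max()
    stats: list[DropletStats] = []
    kept = np.zeros(n + 1, dtype=int)
    next_label = 1
    for lab in range(1, n + 1):
        sel = labels == lab
        area = int(sel.sum())
        if area < min_area:
            continue
        kept[lab] = next_label
        stats.append(DropletStats(
            label=next_label, area=area,
            mean_K1=float(state.K1[sel].mean()),
            mean_K2=float(state.K2[sel].mean()),
        ))
        next_label += 1
    return kept[labels], stats


def detect_separation(trajectory: Trajectory, theta: float = DEFAULT_THETA,
                      min_area: int = DEFAULT_MIN_AREA,
                      t_cap: float | None = None) -> tuple[float, bool]:
    """First recorded second with >= 1 droplet, or (t_cap, False).

    Whole-second recording implements the ceiling convention: a field that
    separates at a fractional time is reported at the next recorded second.
    """
    if t_cap is None:
        t_cap = trajectory.t_cap
    for snap in trajectory.snapshots:
        if snap.time > t_cap:
            break
        _, droplets = label_droplets(snap, theta, min_area)
        if droplets:
            return snap.time, True
    return float(t_cap), False


def k1_droplet_fraction(state: FieldState | None,
                        theta: float = DEFAULT_THETA,
                        min_area: int = DEFAULT_MIN_AREA,
                        separated: bool = True,
                        weight: str = "count") -> float:
    """Fraction of droplets classified K1-type by dominant mean species.

    ``weight='count'`` (default) counts droplets; ``'area'`` weights by
    droplet area.  For an unseparated run (``separated=False``) the sentinel
    1.25 is returned without touching the field.
    """
    if not separated:
        return SENTINEL_FRACTION
    _, droplets = label_droplets(state, theta, min_area)
    if not droplets:
        raise ValueError("no droplets found in a run flagged as separated")
    if weight == "count":
        return sum(d.is_k1_type for d in droplets) / len(droplets)
    if weight == "area":
        areas = np.array([d.area for d in droplets], dtype=float)
        k1 = np.array([d.is_k1_type for d in droplets], dtype=float)
        return float((areas * k1).sum() / areas.sum())
    raise ValueError("weight must be 'count' or 'area'")


def qoi_record(trajectory: Trajectory, theta: float = DEFAULT_THETA,
               min_area: int = DEFAULT_MIN_AREA,
               t_cap: float | None = None) -> QoIRecord:
    """Full QoI extraction for one trajectory, caps and sentinel included."""
    t_sep, separated = detect_separation(trajectory, theta, min_area, t_cap)
    if not separated:
        return QoIRecord(t_sep=t_sep, k1_fraction=SENTINEL_FRACTION,
                         separated=False)
    _, droplets = label_droplets(trajectory.at(t_sep), theta, min_area)
    n_k1 = sum(d.is_k1_type for d in droplets)
    return QoIRecord(t_sep=t_sep, k1_fraction=n_k1 / len(droplets),
                     separated=True, n_droplets=len(droplets),
                     n_k1_droplets=n_k1)
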