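"""End-to-end study orchestration: screen, freeze, decompose, summarise.

For each (QoI, RNA-ratio) cell the pipeline runs Morris screening over all
nine varied parameters, retains the influential set, freezes the rest at
their reported baseline values, runs the Saltelli/Sobol' stage over the
retained parameters, and summarises the per-run QoI distribution.  Separate
separation-time caps apply to the two stages (1000 s for screening, 10 s
for the variance stage), matching the conventions the QoIs are defined
under.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import ModelParameters, SENSITIVITY_RANGES, VARIED_PARAMETERS
from .morris import MorrisDesign, MorrisResult, elementary_effects, \
    morris_stats, screen
from .qoi import MORRIS_TIME_CAP, QoIRecord, SENTINEL_FRACTION, \
    SOBOL_TIME_CAP, qoi_record
from .simulate import GridSpec, InitialConditionSpec, simulate
from .sobol import SobolDesign, SobolResult, saltelli_sample, sobol_indices
from . import qoi as qoi_mod

__all__ = [
    "StudyConfig",
    "StudySummary",
    "SimulationQoI",
    "CANONICAL_SCENARIOS",
    "derive_seed",
    "summarize_distribution",
    "run_canonical_scenario",
    "run_study",
    "PRESETS",
]


def derive_seed(global_seed: int, module: str, key: str = "") -> int:
    """Stable per-run seed: a SHA-256 hash of (global seed, module, key)
    truncated below 2**31, so partial re-runs reproduce regardless of
    evaluation order."""
    digest = hashlib.sha256(f"{global_seed}:{module}:{key}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class DetectorConfig:
    theta: float = 0.5
    min_area: int = 4


@dataclass(frozen=True)
class StudyConfig:
    """Declarative description of one full study; YAML round-trippable."""

    grid_nx: int = 64
    grid_length: float = 2.5
    dt: float = 5e-4
    noise_amplitude: float = 0.45
    P0: float = 0.5
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    morris_r: int = 1000
    morris_delta: float = 0.001
    sobol_n: int = 128
    sobol_second_order: bool = False
    ratios: tuple[str, ...] = ("1:1", "2:1", "3:1")
    qois: tuple[str, ...] = ("time", "fraction")
    morris_tcap: float = MORRIS_TIME_CAP
    sobol_tcap: float = SOBOL_TIME_CAP
    screen_alpha: float = 0.4
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self):
        if self.morris_tcap <= 0 or self.sobol_tcap <= 0:
            raise ValueError("time caps must be positive")
        for r in self.ratios:
            if r not in ("1:1", "2:1", "3:1"):
                raise ValueError(f"unknown ratio {r!r}")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(nx=self.grid_nx, length=self.grid_length)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        det = raw.pop("detector", {})
        raw["detector"] = DetectorConfig(**det)
        for key in ("ratios", "qois"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


#: Reduced-scale presets; "full" matches the published study scale.
PRESETS: dict[str, dict] = {
    "smoke": dict(grid_nx=32, grid_length=0.625, morris_r=4, sobol_n=4,
                  morris_tcap=20.0),
    "desk": dict(grid_nx=64, morris_r=16, sobol_n=16, morris_tcap=60.0),
    "full": dict(grid_nx=128, morris_r=1000, sobol_n=1024),
}


class SimulationQoI:
    """Maps a parameter vector to the two simulation QoIs, with caching.

    One PDE run per distinct vector serves both the separation-time and the
    K1-fraction evaluators.  The initial-condition seed for each run is
    derived from the study seed and the vector itself, so results do not
    depend on evaluation order.
    """

    def __init__(self, names, ratio: str = "1:1",
                 base_params: ModelParameters | None = None,
                 grid: GridSpec | None = None,
                 t_cap: float = SOBOL_TIME_CAP,
                 detector: DetectorConfig | None = None,
                 dt: float = 5e-4, P0: float = 0.5,
                 noise_amplitude: float = 0.45, seed: int = 0):
        self.names = tuple(names)
        self.ratio = ratio
        self.base_params = base_params or ModelParameters()
        self.grid = grid or GridSpec(nx=64)
        self.t_cap = t_cap
        self.detector = detector or DetectorConfig()
        self.dt = dt
        self.P0 = P0
        self.noise_amplitude = noise_amplitude
        self.seed = seed
        self._cache: dict[bytes, QoIRecord] = {}
        self.n_simulations = 0

    def record(self, x) -> QoIRecord:
        x = np.asarray(x, dtype=float)
        key = np.round(x, 12).tobytes()
        if key not in self._cache:
            self._cache[key] = self._run(x, key)
        return self._cache[key]

    def _run(self, x, key: bytes) -> QoIRecord:
        params = self.base_params.with_values(
            **dict(zip(self.names, x.tolist())))
        ic = InitialConditionSpec(
            ratio=self.ratio, P0=self.P0,
            noise_amplitude=self.noise_amplitude,
            seed=derive_seed(self.seed, "ic", key.hex()))
        det = self.detector

        def separated(snap):
            _, droplets = qoi_mod.label_droplets(snap, det.theta,
                                                 det.min_area)
            return bool(droplets)

        traj = simulate(params, ic, self.grid, t_cap=self.t_cap,
                        dt=self.dt, stop_when=separated)
        self.n_simulations += 1
        return qoi_record(traj, det.theta, det.min_area, self.t_cap)

    def evaluator(self, qoi: str):
        """Scalar evaluator for one QoI ('time' or 'fraction')."""
        if qoi not in ("time", "fraction"):
            raise ValueError("qoi must be 'time' or 'fraction'")

        def f(x):
            rec = self.record(x)
            return rec.t_sep if qoi == "time" else rec.k1_fraction

        return f

    def records(self) -> list[QoIRecord]:
        return list(self._cache.values())


def summarize_distribution(records: list[QoIRecord], qoi: str = "time",
                           t_cap: float = SOBOL_TIME_CAP) -> dict:
    """Median, quartiles (linear interpolation) and percent capped.

    Capped runs enter the statistics at their cap/sentinel value, exactly
    as they are plotted in the distribution summaries.
    """
    if not records:
        raise ValueError("need at least one QoI record")
    if qoi == "time":
        values = np.array([r.t_sep for r in records], dtype=float)
    elif qoi == "fraction":
        values = np.array([r.k1_fraction for r in records], dtype=float)
    else:
        raise ValueError("qoi must be 'time' or 'fraction'")
    capped = np.array([not r.separated for r in records])
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3),
            "percent_capped": float(100.0 * capped.mean()),
            "n": len(records)}


#: The four canonical binding-dynamics scenarios: (a2, a3) overrides with
#: every other parameter at its reported value, 1:1 RNA ratio.
CANONICAL_SCENARIOS: dict[str, tuple[float, float]] = {
    "A": (0.01, 0.25),
    "B": (1.0, 0.25),
    "C": (0.01, 1.0),
    "D": (1.0, 1.0),
}


def run_canonical_scenario(scenario: str, grid: GridSpec | None = None,
                   seed: int = 0, dt: float = 5e-4,
                   detector: DetectorConfig | None = None,
                   t_cap: float = 30.0, noise_amplitude: float = 0.45):
    """Run one canonical scenario and return (trajectory, QoI record)."""
    if scenario not in CANONICAL_SCENARIOS:
        raise ValueError(f"scenario must be one of {sorted(CANONICAL_SCENARIOS)}")
    a2, a3 = CANONICAL_SCENARIOS[scenario]
    params = ModelParameters(a2=a2, a3=a3)
    grid = grid or GridSpec(nx=128)
    det = detector or DetectorConfig()
    ic = InitialConditionSpec(ratio="1:1", noise_amplitude=noise_amplitude,
                              seed=seed)

    def separated(snap):
        _, droplets = qoi_mod.label_droplets(snap, det.theta, det.min_area)
        return bool(droplets)

    traj = simulate(params, ic, grid, t_cap=t_cap, dt=dt,
                    stop_when=separated)
    return traj, qoi_record(traj, det.theta, det.min_area, t_cap)


@dataclass
class CellResult:
    qoi: str
    ratio: str
    morris: MorrisResult
    retained: list[str]
    sobol: SobolResult
    distribution: dict
    n_morris_simulations: int
    n_sobol_simulations: int


@dataclass
class StudySummary:
    config: StudyConfig
    cells: dict[tuple[str, str], CellResult]

    def cell(self, qoi: str, ratio: str) -> CellResult:
        return self.cells[(qoi, ratio)]


def _frozen_params(retained) -> ModelParameters:
    # screened-out parameters stay at the reported baseline by construction
    return ModelParameters()


def run_study(config: StudyConfig) -> StudySummary:
    """Run the full screening -> freezing -> Sobol' pipeline per cell."""
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")
    cells: dict[tuple[str, str], CellResult] = {}
    for ratio in config.ratios:
        # one screening simulation cache serves both QoIs for this ratio
        morris_sim = SimulationQoI(
            VARIED_PARAMETERS, ratio=ratio, grid=config.grid,
            t_cap=config.morris_tcap, detector=config.detector,
            dt=config.dt, P0=config.P0,
            noise_amplitude=config.noise_amplitude,
            seed=derive_seed(config.seed, "morris", ratio))
        mdesign = MorrisDesign(delta=config.morris_delta, r=config.morris_r,
                               seed=derive_seed(config.seed, "morris-design",
                                                ratio))
        base = None
        for qoi in config.qois:
            from .morris import sample_base_points
            if base is None:
                base = sample_base_points(mdesign)
            effects = elementary_effects(morris_sim.evaluator(qoi),
                                         mdesign, base=base)
            mres = morris_stats(effects, mdesign.names, qoi=qoi, ratio=ratio)
            retained = screen(mres, alpha=config.screen_alpha)
            n_morris = morris_sim.n_simulations

            sobol_sim = SimulationQoI(
                retained, ratio=ratio, grid=config.grid,
                t_cap=config.sobol_tcap, detector=config.detector,
                dt=config.dt, P0=config.P0,
                noise_amplitude=config.noise_amplitude,
                seed=derive_seed(config.seed, "sobol", f"{qoi}:{ratio}"))
            sdesign = SobolDesign(
                ranges={k: SENSITIVITY_RANGES[k] for k in retained},
                n=config.sobol_n, second_order=config.sobol_second_order,
                seed=derive_seed(config.seed, "sobol-design",
                                 f"{qoi}:{ratio}"))
            sample = saltelli_sample(sdesign)
            f = sobol_sim.evaluator(qoi)
            Y = np.array([f(x) for x in sample.rows])
            sres = sobol_indices(Y, sample)
            dist = summarize_distribution(
                [sobol_sim.record(x) for x in sample.rows], qoi=qoi,
                t_cap=config.sobol_tcap)
            cell = CellResult(qoi, ratio, mres, retained, sres, dist,
                              n_morris, sobol_sim.n_simulations)
            cells[(qoi, ratio)] = cell
            if outdir:
                _write_cell(outdir, cell, sobol_sim)
    summary = StudySummary(config, cells)
    if outdir:
        _write_summary(outdir, summary)
    return summary


def _write_cell(outdir: Path, cell: CellResult, sim: SimulationQoI) -> None:
    tag = f"{cell.qoi}_{cell.ratio.replace(':', 'to')}"
    pd.DataFrame({
        "parameter": cell.morris.names,
        "mu_star": cell.morris.mu_star,
        "sigma": cell.morris.sigma,
        "sigma_as_printed": cell.morris.sigma_as_printed,
    }).to_csv(outdir / f"morris_{tag}.csv", index=False)
    pd.DataFrame({
        "parameter": cell.sobol.names,
        "S1": cell.sobol.S1,
        "ST": cell.sobol.ST,
    }).to_csv(outdir / f"sobol_{tag}.csv", index=False)
    if cell.sobol.S2_raw is not None:
        rows = []
        names = cell.sobol.names
        for j in range(len(names)):
            for k in range(j + 1, len(names)):
                rows.append({"pi": names[j], "pj": names[k],
                             "S2_raw": cell.sobol.S2_raw[j, k],
                             "S2_clipped": cell.sobol.S2_clipped[j, k]})
        pd.DataFrame(rows).to_csv(outdir / f"sobol_s2_{tag}.csv", index=False)
    recs = sim.records()
    pd.DataFrame({
        "t_sep": [r.t_sep for r in recs],
        "k1_fraction": [r.k1_fraction for r in recs],
        "separated": [r.separated for r in recs],
        "n_droplets": [r.n_droplets for r in recs],
    }).to_csv(outdir / f"qoi_table_{tag}.csv", index=False)


def _write_summary(outdir: Path, summary: StudySummary) -> None:
    payload = {}
    for (qoi, ratio), cell in summary.cells.items():
        payload[f"{qoi}|{ratio}"] = {
            "retained": cell.retained,
            "distribution": cell.distribution,
            "S1": dict(zip(cell.sobol.names, cell.sobol.S1.tolist())),
            "ST": dict(zip(cell.sobol.names, cell.sobol.ST.tolist())),
            "n_morris_simulations": cell.n_morris_simulations,
            "n_sobol_simulations": cell.n_sobol_simulations,
        }
    (outdir / "summary.json").write_text(json.dumps(payload, indent=2))
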