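"""JSON run configuration, validation, and the simulation pipeline.

A run is fully described by one JSON document (kinetics, grid, solver,
stimulus, analysis blocks).  ``run_pipeline`` executes it end to end and
writes plain-text artifacts — resolved config, steady-state report, TSV
snapshots with JSON sidecars, trace CSV, velocity estimate and outcome —
so a completed run can be re-analyzed or reproduced byte-for-byte from its
saved config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field as PField, ValidationError, model_validator

from . import solver as solver_mod
from .front_analysis import classify_outcome, estimate_velocity, track_front
from .kinetics import DimensionalParams, KineticParams, nondimensionalize, steady_states
from .solver import Field, GridSpec, SolverConfig, StabilityError, simulate, stability_limit
from .stimulation import StimulusSpec, make_initial_field

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "run_pipeline",
    "analyze_run",
    "write_snapshot",
    "read_snapshot",
]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class KineticsBlock(_Block):
    """Either the nondimensional set (a, b, d) or the dimensional set
    (alpha, beta, gamma, K_M, D, L) — supplying both is ambiguous."""

    a: float | None = None
    b: float | None = None
    d: float | None = None
    n: int = 2
    alpha: float | None = None
    beta: float | None = None
    gamma: float | None = None
    K_M: float | None = None
    D: float | None = None
    L: float = 1.0

    @model_validator(mode="after")
    def _one_parameter_set(self) -> "KineticsBlock":
        nondim = [self.a, self.b, self.d]
        dim = [self.alpha, self.beta, self.gamma, self.K_M, self.D]
        has_nondim = any(v is not None for v in nondim)
        has_dim = any(v is not None for v in dim)
        if has_nondim and has_dim:
            raise ValueError(
                "kinetics: supply either nondimensional (a, b, d) or dimensional "
                "(alpha, beta, gamma, K_M, D) parameters, not both"
            )
        if has_nondim:
            if self.a is None or self.b is None:
                raise ValueError("kinetics: both a and b are required")
        elif has_dim:
            missing = [k for k, v in zip(("alpha", "beta", "gamma", "K_M", "D"), dim) if v is None]
            if missing:
                raise ValueError(f"kinetics: missing dimensional parameter(s) {missing}")
        else:
            raise ValueError("kinetics: no parameters supplied")
        return self

    def to_params(self) -> KineticParams:
        if self.a is not None:
            return KineticParams(a=self.a, b=self.b, n=self.n, d=self.d or 0.0)
        dp = DimensionalParams(
            alpha=self.alpha, beta=self.beta, gamma=self.gamma,
            K_M=self.K_M, D=self.D, n=self.n, L=self.L,
        )
        return nondimensionalize(dp)


class GridBlock(_Block):
    nx: int = 200
    ny: int = 200
    dx: float = 1.0
    dy: float = 1.0

    def to_grid(self) -> GridSpec:
        return GridSpec(nx=self.nx, ny=self.ny, dx=self.dx, dy=self.dy)


class SolverBlock(_Block):
    dt: float = 0.05
    t_end: float = 300.0
    snapshot_interval: float = 5.0
    stability_safety: float = 0.9

    def to_config(self) -> SolverConfig:
        return SolverConfig(
            dt=self.dt,
            t_end=self.t_end,
            snapshot_interval=self.snapshot_interval,
            stability_safety=self.stability_safety,
        )


class StimulusBlock(_Block):
    centers: list[tuple[float, float]] | None = None  # default: grid center
    amplitude: float = 1.0
    sigma: float = 3.0
    background: float | None = None

    def to_spec(self, grid: GridSpec) -> StimulusSpec:
        centers = self.centers
        if centers is None:
            centers = [(grid.nx / 2.0, grid.ny / 2.0 if grid.ny > 1 else 0.0)]
        return StimulusSpec(
            centers=tuple(tuple(c) for c in centers),
            amplitude=self.amplitude,
            sigma=self.sigma,
            background=self.background,
        )


class AnalysisBlock(_Block):
    row: int | None = None            # default: middle row
    threshold: float | None = None    # default: S_T
    fit_window: tuple[float, float] | None = None
    expected_outcome: str | None = None


class RunConfig(_Block):
    kinetics: KineticsBlock
    grid: GridBlock = PField(default_factory=GridBlock)
    solver: SolverBlock = PField(default_factory=SolverBlock)
    stimulus: StimulusBlock = PField(default_factory=StimulusBlock)
    analysis: AnalysisBlock = PField(default_factory=AnalysisBlock)
    output_dir: str = "runs/latest"


def load_config(path: str | Path) -> RunConfig:
    """Load, schema-validate and consistency-check a JSON run config.

    Unknown keys are rejected; dt is checked against the Von Neumann
    stability limit for the configured kinetics and grid, with the limit
    cited in the error message.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{path} is not valid JSON: {exc}") from exc
    try:
        cfg = RunConfig.model_validate(raw)
    except ValidationError as exc:
        locs = "; ".join(
            "/".join(str(p) for p in err["loc"]) + ": " + err["msg"] for err in exc.errors()
        )
        raise ConfigError(f"invalid config {path}: {locs}") from exc
    _check_stability(cfg)
    return cfg


def _check_stability(cfg: RunConfig) -> None:
    p = cfg.kinetics.to_params()
    g = cfg.grid.to_grid()
    limit = stability_limit(p, g)
    allowed = cfg.solver.stability_safety * limit
    if cfg.solver.dt > allowed:
        raise ConfigError(
            f"solver/dt: dt={cfg.solver.dt} exceeds the allowed "
            f"{cfg.solver.stability_safety} x Von Neumann limit "
            f"({limit:.6g}); use dt <= {allowed:.6g}"
        )


def write_snapshot(directory: Path, index: int, q: np.ndarray, t: float, meta: dict) -> None:
    """TSV matrix (one line per grid row) plus a JSON sidecar with t/meta."""
    base = directory / f"snapshot_{index:04d}"
    np.savetxt(base.with_suffix(".tsv"), np.atleast_2d(q), delimiter="\t", fmt="%.17g")
    sidecar = {"t": t, "index": index, **meta}
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_snapshot(directory: Path, index: int) -> tuple[np.ndarray, float]:
    base = Path(directory) / f"snapshot_{index:04d}"
    q = np.atleast_2d(np.loadtxt(base.with_suffix(".tsv"), delimiter="\t"))
    meta = json.loads(base.with_suffix(".json").read_text())
    return q, float(meta["t"])


def _config_hash(resolved: dict) -> str:
    return hashlib.sha256(json.dumps(resolved, sort_keys=True).encode()).hexdigest()


def run_pipeline(cfg: RunConfig, output_dir: str | Path | None = None) -> Path:
    """Execute a configured run and write all artifacts to the run directory.

    Writes resolved_config.json (with its hash), steady_states.json,
    snapshot_*.tsv/.json, trace.csv, velocity.json and outcome.json plus a
    run.log including the stability margin.  On a stability failure the
    partial outputs are retained alongside a FAILED marker, and the error is
    re-raised.
    """
    out = Path(output_dir if output_dir is not None else cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("erythemawave")
    root.addHandler(log_handler)
    root.setLevel(logging.INFO)
    try:
        resolved = cfg.model_dump(mode="json")
        resolved["config_sha256"] = _config_hash(resolved)
        (out / "resolved_config.json").write_text(json.dumps(resolved, indent=1, sort_keys=True))

        p = cfg.kinetics.to_params()
        g = cfg.grid.to_grid()
        ss = steady_states(p)
        (out / "steady_states.json").write_text(
            json.dumps(
                {
                    "roots": list(ss.roots),
                    "stabilities": list(ss.stabilities),
                    "bistable": ss.bistable,
                },
                indent=1,
            )
        )
        f0 = make_initial_field(g, ss, cfg.stimulus.to_spec(g))
        scfg = cfg.solver.to_config()
        logger.info("starting run in %s (hash %s)", out, resolved["config_sha256"][:12])
        try:
            result = simulate(f0, p, scfg)
        except StabilityError as exc:
            (out / "FAILED.txt").write_text(str(exc) + "\n")
            if exc.partial_result is not None:
                _write_outputs(out, exc.partial_result, cfg, p, ss)
            raise
        run_meta = {"grid": {"nx": g.nx, "ny": g.ny, "dx": g.dx, "dy": g.dy}}
        for i, (t, q) in enumerate(zip(result.times, result.snapshots)):
            write_snapshot(out, i, q, float(t), run_meta)
        _write_outputs(out, result, cfg, p, ss)
        return out
    finally:
        root.removeHandler(log_handler)
        log_handler.close()


def _write_outputs(out: Path, result, cfg: RunConfig, p: KineticParams, ss) -> None:
    threshold = cfg.analysis.threshold
    if threshold is None:
        if not ss.bistable:
            raise ConfigError(
                "analysis/threshold: monostable kinetics have no S_T; "
                "set an explicit threshold"
            )
        threshold = ss.S_T
    row = cfg.analysis.row if cfg.analysis.row is not None else result.grid.ny // 2
    trace = track_front(result, threshold=threshold, row=row)
    trace.to_dataframe().to_csv(out / "trace.csv", index=False)
    outcome = classify_outcome(trace)
    vel: dict = {"outcome": outcome, "threshold": threshold, "row": row}
    try:
        est = estimate_velocity(trace, window=cfg.analysis.fit_window)
        vel.update(
            v=est.v, intercept=est.intercept, r_squared=est.r_squared, window=list(est.window)
        )
    except ValueError as exc:
        vel.update(velocity_error=str(exc))
    (out / "velocity.json").write_text(json.dumps(vel, indent=1, sort_keys=True))
    (out / "outcome.json").write_text(
        json.dumps(
            {
                "outcome": outcome,
                "expected_outcome": cfg.analysis.expected_outcome,
                "matches_expected": (
                    None
                    if cfg.analysis.expected_outcome is None
                    else outcome == cfg.analysis.expected_outcome
                ),
                "stability_margin": result.stability_margin,
            },
            indent=1,
        )
    )


def analyze_run(run_dir: str | Path) -> dict:
    """Recompute trace, velocity and outcome from a run directory's snapshots.

    Reads resolved_config.json and the stored snapshots, rebuilds the
    trajectory, and rewrites trace.csv / velocity.json / outcome.json; the
    recomputation is deterministic, so re-analysis of an intact run
    reproduces identical files.
    """
    run_dir = Path(run_dir)
    cfg = RunConfig.model_validate(
        {
            k: v
            for k, v in json.loads((run_dir / "resolved_config.json").read_text()).items()
            if k != "config_sha256"
        }
    )
    g = cfg.grid.to_grid()
    p = cfg.kinetics.to_params()
    ss = steady_states(p)
    indices = sorted(
        int(f.stem.split("_")[1]) for f in run_dir.glob("snapshot_*.tsv")
    )
    times, snaps = [], []
    for i in indices:
        q, t = read_snapshot(run_dir, i)
        times.append(t)
        snaps.append(q)
    # preserve the recorded stability margin so re-analysis is a no-op
    margin = float("nan")
    outcome_file = run_dir / "outcome.json"
    if outcome_file.exists():
        margin = json.loads(outcome_file.read_text()).get("stability_margin", float("nan"))
    result = solver_mod.SimulationResult(
        times=np.asarray(times),
        snapshots=snaps,
        final=Field(q=snaps[-1], grid=g, t=times[-1]),
        grid=g,
        stability_margin=margin,
    )
    _write_outputs(run_dir, result, cfg, p, ss)
    return json.loads((run_dir / "outcome.json").read_text())
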