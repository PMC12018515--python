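"""Run configuration and the end-to-end pipeline.

A :class:`RunConfig` collects every tunable of the toolkit with defaults
equal to the packaged reference parameters (right-insula ellipsoid,
reference E-I parameters, packaged connectivity matrix).  ``run_all``
executes geometry, somatotopy, dynamics and network stages, writes their
artifacts under one output directory and returns a JSON-serializable
summary; runs are deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, connectivity, dynamics, io, reference, somatotopy
from .geometry import EllipsoidModel, INSULA_SEMI_AXES, RIGHT_INSULA_CENTER

__all__ = ["RunConfig", "ConfigError", "load_config", "run_all"]

log = logging.getLogger("insulatk")


class ConfigError(ValueError):
    """Configuration parse or schema violation; message names the field."""


@dataclass(frozen=True)
class DynamicsConfig:
    a: float = 1.0
    b: float = 1.5
    c: float = 1.0
    d: float = -1.0
    x0: float = 1.0
    y0: float = 0.5
    t_span: tuple[float, float] = (0.0, 20.0)
    n_points: int = 1000


@dataclass(frozen=True)
class NetworkConfig:
    leak: float = 1.0
    drive: tuple[float, ...] | None = None
    ic: tuple[float, ...] | None = None
    t_span: tuple[float, float] = (0.0, 20.0)
    n_points: int = 1000
    matrix_csv: str | None = None  # defaults to the packaged matrix


@dataclass(frozen=True)
class SomatotopyConfig:
    n: int = 30
    sigma: float = 1.5


@dataclass(frozen=True)
class RunConfig:
    side: str = "right"
    center: tuple[float, float, float] | None = None
    semi_axes: tuple[float, float, float] = INSULA_SEMI_AXES
    voxel_size: float = 1.0
    mesh_nu: int = 60
    mesh_nv: int = 30
    dynamics: DynamicsConfig = field(default_factory=DynamicsConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    somatotopy: SomatotopyConfig = field(default_factory=SomatotopyConfig)
    seed: int = 42
    outdir: str = "insula_out"
    log_level: str = "INFO"

    def __post_init__(self):
        if self.side not in ("right", "left"):
            raise ConfigError(f"side must be 'right' or 'left', got {self.side!r}")

    def ellipsoid(self) -> EllipsoidModel:
        """The configured ellipsoid; an explicit center overrides side."""
        if self.center is not None:
            return EllipsoidModel(center=self.center, semi_axes=self.semi_axes)
        x0, y0, z0 = RIGHT_INSULA_CENTER
        if self.side == "left":
            x0 = -x0
        return EllipsoidModel(center=(x0, y0, z0), semi_axes=self.semi_axes)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def _build(cls, raw: dict, path: str):
    allowed = set(cls.__dataclass_fields__)
    unknown = set(raw) - allowed
    if unknown:
        key = sorted(unknown)[0]
        raise ConfigError(f"unknown configuration key {path}{key!r}")
    kwargs = {}
    for name, value in raw.items():
        if name in ("dynamics", "network", "somatotopy"):
            sub = {"dynamics": DynamicsConfig, "network": NetworkConfig, "somatotopy": SomatotopyConfig}[name]
            if not isinstance(value, dict):
                raise ConfigError(f"{path}{name} must be a mapping")
            kwargs[name] = _build(sub, value, f"{path}{name}.")
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration under {path or 'root'}: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and validate a JSON or YAML run configuration.

    Unknown keys are rejected with the offending field path; an empty
    file yields the full default configuration.
    """
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)  # YAML is a JSON superset
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"configuration root must be a mapping, got {type(raw).__name__}")
    return _build(RunConfig, raw, "")


def run_all(config: RunConfig, outdir=None) -> dict:
    """Execute all stages, write artifacts and return the summary.

    Stages: geometry (OBJ mesh, NIfTI mask, morphometric comparison),
    somatotopy (centroid, containment report, jittered-sample ANOVA),
    dynamics (trajectory CSV + analysis JSON), network (trajectory CSV,
    edge list, stability).  Any stage failure removes the partial
    outputs and raises with the stage name.  Containment is evaluated
    against the left-hemisphere mirror of the configured ellipsoid when
    needed, since the packaged coordinates are left-hemisphere.
    """
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    summary: dict = {
        "package": "insulatk",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
    }

    def _write(fn, path: Path, *args):
        fn(*args, path)
        written.append(path)

    stage = "geometry"
    try:
        ellipsoid = config.ellipsoid()
        mesh = ellipsoid.surface_mesh(config.mesh_nu, config.mesh_nv)
        _write(io.save_obj, out / "ellipsoid.obj", mesh)
        mask = ellipsoid.voxelize(config.voxel_size)
        _write(io.save_mask, out / f"insula_{config.side}.nii", mask)
        morpho = reference.compare_morphometrics(ellipsoid)
        morpho.to_csv(out / "morphometrics.csv", index=False, float_format=io.CSV_FLOAT_FORMAT)
        written.append(out / "morphometrics.csv")
        summary[stage] = {
            "extents_mm": list(ellipsoid.extents()),
            "volume_mm3": ellipsoid.volume(),
            "mask_voxels": mask.n_inside,
            "mask_volume_mm3": mask.volume(),
        }

        stage = "somatotopy"
        regions = somatotopy.packaged_regions()
        cen = somatotopy.centroid(regions)
        left = ellipsoid if ellipsoid.center[0] <= 0 else ellipsoid.mirror_lr()
        report = somatotopy.containment_report(left, regions)
        report.to_csv(out / "containment.csv", index=False, float_format=io.CSV_FLOAT_FORMAT)
        written.append(out / "containment.csv")
        samples = somatotopy.jitter_samples(
            regions, n=config.somatotopy.n, sigma=config.somatotopy.sigma, seed=config.seed
        )
        _write(io.save_samples_csv, out / "samples.csv", samples)
        anova = somatotopy.anova_all_axes(samples)
        summary[stage] = {
            "centroid_mm": [round(v, 2) for v in cen],
            "centroid_mm_full": list(cen),
            "anova": {
                ax: {"F": r.F, "p": r.p, "df": [r.df_between, r.df_within]}
                for ax, r in anova.items()
            },
        }

        stage = "dynamics"
        model = dynamics.LinearEIDynamics(
            a=config.dynamics.a, b=config.dynamics.b, c=config.dynamics.c,
            d=config.dynamics.d, x0=config.dynamics.x0, y0=config.dynamics.y0,
            t_span=tuple(config.dynamics.t_span), n_points=config.dynamics.n_points,
        )
        traj = dynamics.simulate(model)
        _write(io.save_trajectory_csv, out / "trajectory.csv", traj)
        fp = dynamics.classify(model)
        dyn_report = {
            "class": fp.kind.value,
            "stability": fp.stability.value,
            "eigenvalues": [{"re": ev.real, "im": ev.imag} for ev in fp.eigenvalues],
            "max_abs_activity": traj.max_abs(),
        }
        if fp.kind is dynamics.FixedPointKind.CENTER:
            dyn_report["period_s"] = dynamics.period(model)
            dyn_report["amplitude_bounds"] = list(dynamics.amplitude_bounds(model))
            dyn_report["conserved_form"] = list(dynamics.conserved_form(model))
        io.save_json(dyn_report, out / "dynamics_report.json")
        written.append(out / "dynamics_report.json")
        summary[stage] = dyn_report

        stage = "network"
        conn = (
            io.load_matrix_csv(config.network.matrix_csv)
            if config.network.matrix_csv
            else connectivity.packaged_matrix()
        )
        net = connectivity.simulate_network(
            conn,
            leak=config.network.leak,
            drive=config.network.drive,
            ic=config.network.ic,
            t_span=tuple(config.network.t_span),
            n_points=config.network.n_points,
        )
        _write(io.save_network_trajectory_csv, out / "network.csv", net)
        _write(io.save_edge_list_json, out / "edges.json", conn)
        stab = connectivity.stability_report(conn, config.network.leak)
        summary[stage] = {
            "labels": list(conn.labels),
            "stable": stab.stable,
            "marginal": stab.marginal,
            "max_real_eigenvalue": stab.max_real,
        }
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    io.save_json(summary, out / "summary.json")
    log.info("run_all complete: %d artifacts in %s (seed %d)", len(written) + 1, out, config.seed)
    return summary
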