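"""Pipeline orchestration: reproducible runs, provenance, and the benchmark.

``run_dynamics_pipeline`` chains PIV -> trajectory integration ->
MSD / Q / V_RMS on a stack (rendered from a simulation or loaded from
TIFF) and writes tidy CSV plus a JSON provenance record.
``run_jamming_benchmark`` is the end-to-end contrast at the heart of the
package: a low-motility ("control-like, late maturation") and a
high-motility ("disease-like") simulation are pushed through the full
pipeline and must land on opposite sides of the shape-index jamming
threshold, with concordant MSD / Q separation.

All randomness is funnelled through a single seed; stage-local seeds are
derived from it deterministically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .dynamics import DynamicsSummary, default_overlap_cutoff, summarize_dynamics
from .image import ImageStack
from .morphometry import (
    JAMMING_THRESHOLD,
    JammingCall,
    classify_jamming,
    shape_metrics,
)
from .piv import PIVConfig, fields_to_frame, multipass_piv
from .render import RenderConfig, render_frames, voronoi_masks
from .simulate import MonolayerTrajectory, SimulationConfig, simulate_monolayer

__all__ = [
    "RunConfig",
    "ProvenanceRecord",
    "BenchmarkReport",
    "BenchmarkError",
    "run_dynamics_pipeline",
    "run_jamming_benchmark",
    "BENCHMARK_LOW_MOTILITY",
    "BENCHMARK_HIGH_MOTILITY",
]

#: benchmark arm conditions: a caged, near-crystalline monolayer ...
BENCHMARK_LOW_MOTILITY = dict(v0=0.1, d_r=0.05, dt=0.5)
#: ... versus an actively flowing, structurally disordered one
BENCHMARK_HIGH_MOTILITY = dict(v0=4.0, d_r=0.1, dt=0.25)

#: morphometry masks are rasterised finer than the movie (cells ~100 px
#: across) so the Crofton perimeter is in its unbiased regime
BENCHMARK_MASK_RENDER = RenderConfig(pixel_size=0.25, image_shape=(1440, 1440))


class BenchmarkError(AssertionError):
    """The benchmark contrast did not hold."""


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    Either ``stack_path`` (a multi-page TIFF with calibration) or
    ``simulation`` must be given; the simulation seed is overridden by
    ``rng_seed`` so one named seed controls the whole run.
    """

    output_dir: str = "jamscope_run"
    rng_seed: int = 0
    stack_path: str | None = None
    pixel_size: float = 0.75488
    frame_interval: float = 5.0
    simulation: SimulationConfig | None = None
    render: RenderConfig = field(default_factory=RenderConfig)
    piv: PIVConfig = field(default_factory=PIVConfig)
    d_c: float | None = None
    origin_policy: str = "sliding"
    threshold: float = JAMMING_THRESHOLD

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, typ in (("simulation", SimulationConfig), ("render", RenderConfig), ("piv", PIVConfig)):
            if isinstance(raw.get(key), dict):
                sub = dict(raw[key])
                if typ is PIVConfig and "window_sizes" in sub:
                    sub["window_sizes"] = tuple(sub["window_sizes"])
                if typ is RenderConfig and "image_shape" in sub:
                    sub["image_shape"] = tuple(sub["image_shape"])
                raw[key] = typ(**sub)
        return cls(**raw)

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [conv(v) for v in obj]
            return obj

        return {
            f.name: conv(getattr(self, f.name)) for f in dataclasses.fields(self)
        }


@dataclass
class ProvenanceRecord:
    """What produced a set of outputs, sufficient to reproduce them."""

    config_hash: str
    software_version: str
    rng_seed: int
    input_checksums: dict
    timings_s: dict
    warnings: list

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _config_hash(cfg: RunConfig) -> str:
    canon = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def derive_seed(base: int, stage: str) -> int:
    """Deterministic stage-local seed below 2^31."""
    digest = hashlib.sha256(f"{base}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def _obtain_stack(cfg: RunConfig) -> tuple[ImageStack, MonolayerTrajectory | None, dict]:
    checksums: dict = {}
    if cfg.stack_path is not None:
        path = Path(cfg.stack_path)
        checksums[str(path)] = _sha256(path)
        return (
            ImageStack.load(path, cfg.frame_interval, cfg.pixel_size),
            None,
            checksums,
        )
    if cfg.simulation is None:
        raise ValueError("RunConfig needs either stack_path or simulation")
    sim_cfg = dataclasses.replace(cfg.simulation, rng_seed=derive_seed(cfg.rng_seed, "sim"))
    traj = simulate_monolayer(sim_cfg)
    return render_frames(traj, cfg.render), traj, checksums


def run_dynamics_pipeline(cfg: RunConfig) -> tuple[DynamicsSummary, ProvenanceRecord]:
    """PIV -> trajectories -> MSD / Q / V_RMS, written as CSV + provenance.

    Returns the summary and the provenance record; the output directory
    receives ``fields.csv``, ``dynamics.csv`` and ``provenance.json``.
    Low-quality PIV fields surface as recorded warnings (and a non-zero
    CLI exit status), not as errors.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict = {}
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        t0 = time.perf_counter()
        stack, _, checksums = _obtain_stack(cfg)
        timings["acquire"] = round(time.perf_counter() - t0, 3)

        t0 = time.perf_counter()
        fields = multipass_piv(stack, cfg.piv)
        timings["piv"] = round(time.perf_counter() - t0, 3)

        t0 = time.perf_counter()
        summary = summarize_dynamics(
            fields, d_c=cfg.d_c, origin_policy=cfg.origin_policy
        )
        timings["dynamics"] = round(time.perf_counter() - t0, 3)
    caught = [str(w.message) for w in wlist]

    fields_to_frame(fields).to_csv(out / "fields.csv", index=False)
    summary.to_frame().to_csv(out / "dynamics.csv", index=False)
    prov = ProvenanceRecord(
        config_hash=_config_hash(cfg),
        software_version=__version__,
        rng_seed=cfg.rng_seed,
        input_checksums=checksums,
        timings_s=timings,
        warnings=caught,
    )
    (out / "provenance.json").write_text(prov.to_json())
    (out / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
    return summary, prov


@dataclass
class BenchmarkArm:
    """One motility condition pushed through the whole pipeline."""

    name: str
    simulation: SimulationConfig
    summary: DynamicsSummary
    jamming: JammingCall

    @property
    def terminal_msd(self) -> float:
        return float(self.summary.msd[-1])

    @property
    def terminal_q(self) -> float:
        return float(self.summary.q_overlap[-1])


@dataclass
class BenchmarkReport:
    low: BenchmarkArm
    high: BenchmarkArm
    seed: int

    def to_dict(self) -> dict:
        def arm(a: BenchmarkArm) -> dict:
            return {
                "mean_q": a.jamming.mean_q,
                "state": a.jamming.state,
                "n_cells": a.jamming.n_cells,
                "terminal_msd_um2": a.terminal_msd,
                "terminal_q": a.terminal_q,
                "mean_vrms_um_min": float(np.nanmean(a.summary.vrms)),
            }

        return {"seed": self.seed, "low_motility": arm(self.low), "high_motility": arm(self.high)}


def _run_arm(
    name: str,
    sim_cfg: SimulationConfig,
    render_cfg: RenderConfig,
    piv_cfg: PIVConfig,
    threshold: float,
) -> BenchmarkArm:
    traj = simulate_monolayer(sim_cfg)
    stack = render_frames(traj, render_cfg)
    fields = multipass_piv(stack, piv_cfg)
    summary = summarize_dynamics(fields)
    mask = voronoi_masks(traj, sim_cfg.n_frames - 1, BENCHMARK_MASK_RENDER)
    table = shape_metrics(mask)
    call = classify_jamming(table, threshold)
    return BenchmarkArm(name=name, simulation=sim_cfg, summary=summary, jamming=call)


def run_jamming_benchmark(
    seed: int = 0,
    out_dir: str | None = None,
    n_frames: int = 41,
    threshold: float = JAMMING_THRESHOLD,
) -> BenchmarkReport:
    """Low- vs high-motility contrast through the complete pipeline.

    Both arms share geometry and rendering; only the motility parameters
    differ (see ``BENCHMARK_LOW_MOTILITY`` / ``BENCHMARK_HIGH_MOTILITY``).
    Raises :class:`BenchmarkError` unless the high-motility arm is called
    unjammed, the low-motility arm jammed, and the high arm has strictly
    larger terminal MSD and strictly lower terminal Q.
    """
    render_cfg = RenderConfig()
    piv_cfg = PIVConfig()
    arms = {}
    for name, params in (
        ("low", BENCHMARK_LOW_MOTILITY),
        ("high", BENCHMARK_HIGH_MOTILITY),
    ):
        sim_cfg = SimulationConfig(
            n_frames=n_frames, rng_seed=derive_seed(seed, f"benchmark-{name}"), **params
        )
        arms[name] = _run_arm(name, sim_cfg, render_cfg, piv_cfg, threshold)
    report = BenchmarkReport(low=arms["low"], high=arms["high"], seed=seed)

    if report.low.jamming.state != "jammed":
        raise BenchmarkError(
            f"low-motility arm called {report.low.jamming.state} "
            f"(mean q = {report.low.jamming.mean_q:.3f})"
        )
    if report.high.jamming.state != "unjammed":
        raise BenchmarkError(
            f"high-motility arm called {report.high.jamming.state} "
            f"(mean q = {report.high.jamming.mean_q:.3f})"
        )
    if not report.high.terminal_msd > report.low.terminal_msd:
        raise BenchmarkError("terminal MSD not separated between arms")
    if not report.high.terminal_q < report.low.terminal_q:
        raise BenchmarkError("terminal Q not separated between arms")

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "benchmark.json").write_text(json.dumps(report.to_dict(), indent=2))
        for arm in (report.low, report.high):
            arm.summary.to_frame().to_csv(out / f"dynamics_{arm.name}.csv", index=False)
    return report
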