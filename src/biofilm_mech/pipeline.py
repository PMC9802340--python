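"""Reproducible end-to-end pipeline: synth → track → piv → tfm → figures.

A :class:`PipelineConfig` (YAML-serializable) fully determines a run: every
tunable that affects a number in an output file appears in the serialized
config, and a :class:`RunManifest` records SHA-256 checksums of all numeric
outputs so that determinism is verifiable by re-running.  Outputs are flat
CSV + TIFF + JSON/HDF5 sidecars for spreadsheet/notebook audit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import boundary as bd
from . import piv as pv
from . import synthgen as sg
from . import traction as tr
from .stacks import ImageStack

__all__ = ["PipelineConfig", "RunManifest", "ConfigError", "run_pipeline", "render_figures"]

log = logging.getLogger(__name__)

ARTIFACT_VERSION = "0.1.0"


class ConfigError(ValueError):
    """Configuration invalid; raised before any computation starts."""


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
    )


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------
def _default_boundary() -> dict:
    return {"n_windows": 4, "dt_min": 20.0, "n_rays": 50}


def _default_piv() -> dict:
    return {"mode": "first_frame", "window_size": 32, "overlap": 0.5, "drift_roi": None}


def _default_tfm() -> dict:
    return {"enabled": True, "gprime_pa": None, "poisson": 0.5,
            "thickness_um": 1000.0, "reg": "auto", "finite_thickness": False,
            "whiskers": "minmax"}


@dataclass
class PipelineConfig:
    """Fully resolved run configuration.

    Inputs are either a ``synth`` block (scenario parameters for the
    generator) or paths to existing TIFF stacks with their calibration.
    Stage parameter dictionaries carry documented defaults; the resolved
    config is serialized next to the outputs.
    """

    output_dir: str
    seed: int = 0
    log_level: str = "INFO"
    synth: dict | None = None
    colony_tiff: str | None = None
    bead_tiff: str | None = None
    pixel_size: float | None = None
    frame_interval: float | None = None
    boundary: dict = field(default_factory=_default_boundary)
    piv: dict = field(default_factory=_default_piv)
    tfm: dict = field(default_factory=_default_tfm)
    figures: bool = True

    def __post_init__(self) -> None:
        self.boundary = {**_default_boundary(), **(self.boundary or {})}
        self.piv = {**_default_piv(), **(self.piv or {})}
        self.tfm = {**_default_tfm(), **(self.tfm or {})}

    # ------------------------------------------------------------ validation
    def validate(self) -> None:
        if self.synth is None:
            if self.colony_tiff is None and self.bead_tiff is None:
                raise ConfigError("config needs either a synth block or input TIFF paths")
            for p in (self.colony_tiff, self.bead_tiff):
                if p is not None and not Path(p).exists():
                    raise ConfigError(f"input stack not found: {p}")
        if self.tfm.get("enabled"):
            if not self.tfm.get("gprime_pa"):
                raise ConfigError("tfm enabled but substrate shear modulus (gprime_pa) missing")
        mode = self.piv.get("mode")
        if mode not in ("first_frame", "previous_frame"):
            raise ConfigError(f"piv mode must be first_frame|previous_frame, got {mode!r}")

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RunManifest:
    """Checksummed record of one pipeline run."""

    artifact_version: str
    config_hash: str
    checksums: dict
    warnings: list

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# --------------------------------------------------------------------------
# Stage helpers
# --------------------------------------------------------------------------
def _build_model(d: dict) -> sg.DisplacementModel:
    d = dict(d or {})
    hotspots = tuple(sg.Hotspot(**h) for h in d.pop("hotspots", []))
    ann = d.pop("edge_annulus", None)
    annulus = sg.EdgeAnnulus(**ann) if ann else None
    return sg.DisplacementModel(hotspots=hotspots, edge_annulus=annulus, **d)


def _synth_stage(cfg: PipelineConfig, out: Path) -> tuple[ImageStack | None, ImageStack | None]:
    colony_stack = bead_stack = None
    s = cfg.synth or {}
    if "colony" in s:
        scenario = sg.ColonyScenario(**{"seed": cfg.seed, **s["colony"]})
        colony_stack, truth = sg.generate_colony_stack(scenario)
        colony_stack.save(out / "colony.tif")
        truth.save(out / "colony_truth.h5")
    if "beads" in s:
        beads = sg.BeadScenario(**{"seed": cfg.seed + 1, **s["beads"]})
        model = _build_model(s.get("model", {}))
        n_frames = s.get("n_frames", 6)
        bead_stack, truth = sg.generate_bead_stack(beads, model, n_frames)
        bead_stack.save(out / "beads.tif")
        truth.save(out / "beads_truth.h5")
    with open(out / "scenario.json", "w") as fh:
        json.dump(s, fh, indent=2, sort_keys=True, default=str)
    return colony_stack, bead_stack


def _track_stage(cfg: PipelineConfig, stack: ImageStack, out: Path) -> list[bd.ColonyBoundary]:
    boundaries = bd.track_boundaries(stack)
    rows = []
    for b in boundaries:
        for i, (x, y) in enumerate(b.polyline):
            rows.append({"frame": b.frame, "point": i, "x_px": x, "y_px": y})
    pd.DataFrame(rows).to_csv(out / "boundaries.csv", index=False)
    arcs = pd.DataFrame([
        {"frame": b.frame, "cx_px": b.arc_center[0], "cy_px": b.arc_center[1],
         "radius_px": b.arc_radius, "residual_px": b.fit_residual}
        for b in boundaries
    ])
    arcs.to_csv(out / "arcs.csv", index=False)
    p = cfg.boundary
    records, summary = bd.expansion_curve(
        stack, n_windows=p["n_windows"], dt_min=p["dt_min"], n_rays=p["n_rays"],
        boundaries=boundaries,
    )
    records.to_csv(out / "expansion_records.csv", index=False)
    summary.to_csv(out / "expansion_summary.csv", index=False)
    return boundaries


def _piv_stage(cfg: PipelineConfig, stack: ImageStack, out: Path,
               warnings_sink: list) -> list[pv.DisplacementField]:
    p = cfg.piv
    fields = pv.accumulate_series(stack, mode=p["mode"], window_size=p["window_size"],
                                  overlap=p["overlap"])
    if p.get("drift_roi"):
        fields = [pv.drift_correct(f, tuple(p["drift_roi"])) for f in fields]
    for f in fields:
        if f.metadata.get("decorrelated"):
            warnings_sink.append(f"piv: frame {f.frame} decorrelated")
    pd.concat([f.to_frame() for f in fields]).to_csv(out / "displacements.csv", index=False)
    divs = [pv.divergence(f, window_min=stack.frame_interval) for f in fields]
    rows = []
    for d in divs:
        X, Y = np.meshgrid(d.x, d.y)
        rows.append(pd.DataFrame({
            "frame": d.frame, "x_um": X.ravel(), "y_um": Y.ravel(),
            "div": d.div.ravel(), "boundary_node": d.boundary.ravel(),
        }))
    pd.concat(rows).to_csv(out / "divergence.csv", index=False)
    return fields


def _tfm_stage(cfg: PipelineConfig, fields: list[pv.DisplacementField],
               stack: ImageStack, out: Path) -> None:
    p = cfg.tfm
    substrate = tr.SubstrateSpec(
        shear_modulus=float(p["gprime_pa"]), poisson_ratio=float(p["poisson"]),
        thickness_um=float(p["thickness_um"]),
    )
    tractions = [
        tr.reconstruct_traction(f, substrate, reg=p["reg"],
                                finite_thickness=p["finite_thickness"])
        for f in fields
    ]
    pd.concat([t.to_frame() for t in tractions]).to_csv(out / "tractions.csv", index=False)
    times_h = [f.frame * stack.frame_interval / 60.0 for f in fields]
    summary = tr.stress_summary(tractions, times_h=times_h, whiskers=p["whiskers"])
    summary["median_strain"] = tr.strain_from_stress(
        summary["median_Pa"].to_numpy(), substrate)
    summary["chosen_reg"] = [t.reg for t in tractions]
    summary.to_csv(out / "stress_summary.csv", index=False)


# --------------------------------------------------------------------------
# Orchestration
# --------------------------------------------------------------------------
def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute (optional) synth → track → piv → tfm → figures; return the manifest.

    Any stage failure aborts with an exception naming the stage.  All numeric
    outputs (CSV/TIFF/JSON/HDF5) are checksummed into the manifest; figures
    are excluded from checksumming (raster encoding is not part of the
    numeric contract).
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings_sink: list[str] = []

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as e:
            raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e

    colony_stack = bead_stack = None
    if config.synth is not None:
        colony_stack, bead_stack = stage("synth", _synth_stage, config, out)
    if colony_stack is None and config.colony_tiff:
        colony_stack = ImageStack.load(config.colony_tiff, config.pixel_size,
                                       config.frame_interval, "brightfield")
    if bead_stack is None and config.bead_tiff:
        bead_stack = ImageStack.load(config.bead_tiff, config.pixel_size,
                                     config.frame_interval, "beads")

    if colony_stack is not None:
        stage("track", _track_stage, config, colony_stack, out)
        log.info("track: %d frames processed", colony_stack.n_frames)
    fields = None
    if bead_stack is not None:
        fields = stage("piv", _piv_stage, config, bead_stack, out, warnings_sink)
        frac = np.mean([1 - f.mask.mean() for f in fields])
        log.info("piv: %d fields, masked-vector fraction %.3f", len(fields), frac)
        if config.tfm.get("enabled"):
            stage("tfm", _tfm_stage, config, fields, bead_stack, out)
    if config.figures:
        stage("figures", render_figures, out)

    checksums = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.suffix in {".csv", ".tif", ".h5", ".json", ".yaml"}
        and p.name != "run_manifest.json"
    }
    manifest = RunManifest(ARTIFACT_VERSION, config.config_hash(), checksums, warnings_sink)
    manifest.save(out / "run_manifest.json")
    return manifest


# --------------------------------------------------------------------------
# Figures
# --------------------------------------------------------------------------
def render_figures(output_dir) -> list[Path]:
    """Render the standard panels from a run's CSV outputs.

    Produces whichever of these the outputs support: boundary-overlay
    montage, expansion velocity vs. time with SEM bars, displacement quiver
    over magnitude heatmap, traction magnitude heatmap, and stress
    box–whisker per timepoint.  Missing or empty inputs are skipped with a
    warning.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import tifffile

    out = Path(output_dir)
    figdir = out / "figures"
    figdir.mkdir(exist_ok=True)
    written: list[Path] = []

    def save(fig, name):
        p = figdir / name
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    bpath, cpath = out / "boundaries.csv", out / "colony.tif"
    if bpath.exists() and cpath.exists():
        bnd = pd.read_csv(bpath)
        frames = tifffile.imread(cpath)
        if frames.ndim == 2:
            frames = frames[None]
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.imshow(frames[-1], cmap="gray")
        for fr, grp in bnd.groupby("frame"):
            ax.plot(grp["x_px"], grp["y_px"], lw=0.8)
        ax.set_title("colony boundaries (all frames)")
        ax.set_axis_off()
        save(fig, "boundaries.png")

    epath = out / "expansion_summary.csv"
    if epath.exists():
        summ = pd.read_csv(epath)
        if summ.empty:
            log.warning("figures: expansion summary empty; skipping velocity plot")
        else:
            fig, ax = plt.subplots(figsize=(5, 3.5))
            ax.errorbar(summ["time_min"], summ["mean_mm_per_h"],
                        yerr=summ["sem_mm_per_h"], fmt="o-", capsize=3)
            ax.set_xlabel("time (min)")
            ax.set_ylabel("expansion velocity (mm/h)")
            fig.tight_layout()
            save(fig, "expansion_velocity.png")

    dpath = out / "displacements.csv"
    if dpath.exists():
        disp = pd.read_csv(dpath)
        if not disp.empty:
            last = disp[disp["frame"] == disp["frame"].max()]
            piv_x = np.sort(last["x_um"].unique())
            piv_y = np.sort(last["y_um"].unique())
            U = last.pivot_table(index="y_um", columns="x_um", values="ux_um").to_numpy()
            V = last.pivot_table(index="y_um", columns="x_um", values="uy_um").to_numpy()
            mag = np.hypot(U, V)
            fig, ax = plt.subplots(figsize=(5, 4.5))
            im = ax.pcolormesh(piv_x, piv_y, mag, shading="nearest", cmap="viridis")
            ax.quiver(last["x_um"], last["y_um"], last["ux_um"], last["uy_um"],
                      color="w", scale_units="xy")
            fig.colorbar(im, ax=ax, label="|u| (µm)")
            ax.set_aspect("equal")
            ax.invert_yaxis()
            fig.tight_layout()
            save(fig, "displacement_map.png")

    tpath = out / "tractions.csv"
    if tpath.exists():
        trc = pd.read_csv(tpath)
        if not trc.empty:
            last = trc[trc["frame"] == trc["frame"].max()]
            T = last.pivot_table(index="y_um", columns="x_um", values="tmag_Pa")
            fig, ax = plt.subplots(figsize=(5, 4.5))
            im = ax.pcolormesh(np.sort(last["x_um"].unique()),
                               np.sort(last["y_um"].unique()),
                               T.to_numpy(), shading="nearest", cmap="inferno")
            fig.colorbar(im, ax=ax, label="|τ| (Pa)")
            ax.set_aspect("equal")
            ax.invert_yaxis()
            fig.tight_layout()
            save(fig, "traction_map.png")

    spath = out / "stress_summary.csv"
    if spath.exists():
        summ = pd.read_csv(spath)
        if not summ.empty:
            fig, ax = plt.subplots(figsize=(5, 3.5))
            stats = [
                {"med": r.median_Pa, "q1": r.q1_Pa, "q3": r.q3_Pa,
                 "whislo": r.whisker_lo_Pa, "whishi": r.whisker_hi_Pa,
                 "label": f"{r.time_h:.1f} h"}
                for r in summ.itertuples()
            ]
            ax.bxp(stats, showfliers=False)
            ax.set_ylabel("|τ| (Pa)")
            fig.tight_layout()
            save(fig, "stress_boxes.png")

    return written
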