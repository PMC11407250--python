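"""Config-driven orchestration of the full sensitivity-analysis pipeline.

Runs phantom generation, optical-property assignment, forward solves at both
cardiac phases, Jacobian/ranking analysis, flat-field reconstruction, and
pulse/noise metrics over a grid of wavelengths, writing plain-text outputs
plus a checksummed manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .flatfield import (PerturbationSpec, classify_feasibility,
                        difference_data, grouped_flatfield_map, perturb_field,
                        reconstruct)
from .forward import SurfaceSampler, assemble, build_patch, make_source, solve
from .io import channels_to_frame, layout_to_json, write_vtu
from .optics import DEFAULT_WAVELENGTHS, CardiacPhase, assign_properties
from .phantom import (PhantomSpec, TissueLabel, build_phantom,
                      build_probe_layout, group_channels, select_channels)
from .pulse_noise import (NoiseModel, averaged_noisy_metrics, delta_od,
                          dynamic_range)
from .sensitivity import (brain_sensitivity_scores, jacobian,
                          rank_top_channels, total_normalized_jacobian)

logger = logging.getLogger("fetaldot")


@dataclass
class RunConfig:
    """Validated pipeline configuration with paper-scale defaults."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    wavelengths: tuple[float, ...] = DEFAULT_WAVELENGTHS
    grid_shape: tuple[int, int] = (6, 6)
    grid_extent: tuple[float, float] = (100.0, 70.0)
    channel_min_distance: float = 20.0
    channel_max_distance: float = 120.0
    bin_edges: tuple[float, ...] = (20.0, 40.0, 60.0, 80.0, 100.0, 120.0)
    detector_side: float = 10.0
    patch_spacing: float = 0.4
    noise: NoiseModel = field(default_factory=NoiseModel)
    use_noise: bool = True
    run_jacobian: bool = True
    run_flatfield: bool = True
    run_pulse: bool = True
    run_ranking: bool = True
    top_k: int = 10
    export_fields: bool = False
    outdir: Path = Path("fetaldot_out")
    seed: int = 0

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        self.wavelengths = tuple(float(w) for w in self.wavelengths)
        if not self.wavelengths:
            raise ValueError("at least one wavelength required")
        if not (self.run_jacobian or self.run_flatfield or self.run_pulse
                or self.run_ranking):
            raise ValueError("at least one analysis must be enabled")
        if self.run_ranking and not self.run_jacobian:
            raise ValueError("ranking requires the Jacobian analysis")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "phantom" in raw:
            ph = dict(raw["phantom"])
            for key in ("lateral_extent",):
                if key in ph:
                    ph[key] = tuple(ph[key])
            raw["phantom"] = PhantomSpec(**ph)
        if "noise" in raw:
            raw["noise"] = NoiseModel(**raw["noise"])
        for key in ("wavelengths", "bin_edges"):
            if key in raw:
                raw[key] = tuple(raw[key])
        for key in ("grid_shape", "grid_extent"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["outdir"] = str(self.outdir)
        return out


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    stage_seconds: dict[str, float]
    outputs: dict[str, str]  # relative path -> sha256

    def write(self, path: Path) -> Path:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                   default=str))
        return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the configured analyses and write all outputs.

    Deterministic for a fixed config + seed (output checksums included in
    the manifest).  Returns the manifest.
    """
    rng = np.random.default_rng(config.seed)
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    stage_seconds: dict[str, float] = {}
    outputs: list[Path] = []

    def timed(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s started", name)

            def __exit__(self, *exc):
                stage_seconds[name] = round(time.perf_counter() - self.t0, 3)
                logger.info("stage %s finished in %.2fs", name,
                            stage_seconds[name])

        return _T()

    with timed("phantom"):
        mesh = build_phantom(config.phantom, seed=config.seed)
        layout = build_probe_layout(mesh, config.grid_shape,
                                    config.grid_extent)
        channels = select_channels(layout, config.channel_min_distance,
                                   config.channel_max_distance)
        groups = group_channels(channels, config.bin_edges)
        channels = [ch for g in groups for ch in g.channels]
        brain_nodes = mesh.nodes_with_label(TissueLabel.FETAL_BRAIN)
        sampler = SurfaceSampler(mesh)
        outputs.append(layout_to_json(layout, outdir / "layout.json"))
        ch_frame = channels_to_frame(channels, groups)
        ch_path = outdir / "channels.csv"
        ch_frame.to_csv(ch_path, index=False)
        outputs.append(ch_path)
        if config.export_fields:
            outputs.append(write_vtu(outdir / "phantom.vtu", mesh))

    metrics_rows: list[dict] = []
    ranking_rows: list[dict] = []
    feasibility: dict[str, list[dict]] = {}

    for lam in config.wavelengths:
        with timed(f"forward_{lam:g}nm"):
            props_d = assign_properties(mesh, lam, CardiacPhase.DIASTOLE)
            system_d = assemble(mesh, props_d)
            sources = [make_source(mesh, props_d, p)
                       for p in layout.source_positions]
            patches = [build_patch(sampler, p, side=config.detector_side,
                                   dx=config.patch_spacing,
                                   dy=config.patch_spacing)
                       for p in layout.detector_positions]
            J = jacobian(system_d, sources, patches, channels)
            phi_d = J.fluences

            props_s = assign_properties(mesh, lam, CardiacPhase.SYSTOLE)
            system_s = assemble(mesh, props_s)
            sols_s = {
                s: solve(system_s, sources[s], source_id=s)
                for s in {ch.source_id for ch in channels}
            }
            phi_s = np.array([
                float((patches[ch.detector_id].weights
                       @ sols_s[ch.source_id].phi)[0])
                for ch in channels
            ])

        scores = None
        if config.run_jacobian:
            with timed(f"sensitivity_{lam:g}nm"):
                scores = brain_sensitivity_scores(J, brain_nodes)
                jac_maps = {
                    g.label: total_normalized_jacobian(J, g).values
                    for g in groups if g.nm
                }

        if config.run_ranking and scores is not None:
            for g in groups:
                if g.nm == 0:
                    logger.warning("group %s empty; skipped", g.label)
                    continue
                ranking = rank_top_channels(scores, J, g, k=config.top_k)
                for e in ranking.entries:
                    ranking_rows.append({
                        "wavelength_nm": lam,
                        "group": g.label,
                        "rank": e.rank,
                        "source_id": e.channel.source_id,
                        "detector_id": e.channel.detector_id,
                        "distance_mm": e.channel.distance,
                        "score": e.score,
                    })

        if config.run_pulse:
            with timed(f"pulse_{lam:g}nm"):
                for i, ch in enumerate(channels):
                    dod = delta_od(phi_d[i], phi_s[i])
                    dr = dynamic_range(phi_d[i], phi_s[i], strict=False)
                    if config.use_noise:
                        nm = averaged_noisy_metrics(
                            phi_d[i], phi_s[i], ch.distance, config.noise, rng
                        )
                        if not nm.finite:
                            logger.warning(
                                "noisy dynamic range overflow on channel "
                                "(%d, %d) at %g nm", ch.source_id,
                                ch.detector_id, lam)
                        dod_noisy, dr_noisy = nm.delta_od, nm.dynamic_range
                    else:
                        dod_noisy, dr_noisy = dod, dr
                    metrics_rows.append({
                        "wavelength_nm": lam,
                        "source_id": ch.source_id,
                        "detector_id": ch.detector_id,
                        "distance_mm": ch.distance,
                        "group": groups[ch.group_id].label,
                        "phi_diastole": phi_d[i],
                        "phi_systole": phi_s[i],
                        "delta_od": dod,
                        "dynamic_range": dr,
                        "delta_od_noisy": dod_noisy,
                        "dynamic_range_noisy": dr_noisy,
                        "seed": config.seed,
                    })

        if config.run_flatfield:
            with timed(f"flatfield_{lam:g}nm"):
                props_p = perturb_field(props_d, PerturbationSpec())
                system_p = assemble(mesh, props_p)
                sols_p = {
                    s: solve(system_p, sources[s], source_id=s)
                    for s in {ch.source_id for ch in channels}
                }
                phi_p = np.array([
                    float((patches[ch.detector_id].weights
                           @ sols_p[ch.source_id].phi)[0])
                    for ch in channels
                ])
                distances = np.array([ch.distance for ch in channels])
                dphi = difference_data(
                    phi_d, phi_p, distances,
                    config.noise if config.use_noise else None, rng)
                recons = [reconstruct(J.values[i], dphi[i])
                          for i in range(len(channels))]
                feas = []
                ff_maps = {}
                for g in groups:
                    if g.nm == 0:
                        continue
                    idx = [i for i, ch in enumerate(channels)
                           if ch.group_id == g.channels[0].group_id]
                    ff_maps[g.label] = grouped_flatfield_map(
                        [recons[i] for i in idx])
                    if config.run_jacobian:
                        feas.append(classify_feasibility(
                            jac_maps[g.label], ff_maps[g.label], brain_nodes,
                            group_label=g.label).as_dict())
                feasibility[f"{lam:g}"] = feas
                if config.export_fields:
                    pd_ = {f"jacobian_{k}": v for k, v in jac_maps.items()} \
                        if config.run_jacobian else {}
                    pd_.update({f"flatfield_{k}": v
                                for k, v in ff_maps.items()})
                    outputs.append(write_vtu(
                        outdir / f"maps_{lam:g}nm.vtu", mesh, point_data=pd_))

    with timed("export"):
        metrics_df = pd.DataFrame(metrics_rows)
        rankings_df = pd.DataFrame(ranking_rows)
        if len(metrics_rows):
            p = outdir / "metrics.csv"
            metrics_df.to_csv(p, index=False)
            outputs.append(p)
        if len(ranking_rows):
            p = outdir / "rankings.csv"
            rankings_df.to_csv(p, index=False)
            outputs.append(p)
        if feasibility:
            p = outdir / "feasibility.json"
            p.write_text(json.dumps(feasibility, indent=2))
            outputs.append(p)
        if len(metrics_rows) and len(ranking_rows):
            summary = summarize_groups(metrics_df, rankings_df)
            p = outdir / "summary.csv"
            summary.to_csv(p, index=False)
            outputs.append(p)

    manifest = RunManifest(
        config=config.to_dict(),
        version=__version__,
        seed=config.seed,
        stage_seconds=stage_seconds,
        outputs={str(p.relative_to(outdir)): _sha256(p) for p in outputs},
    )
    manifest.write(outdir / "manifest.json")
    return manifest


def summarize_groups(metrics: pd.DataFrame,
                     rankings: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- std over each group's top-ranked channels.

    One row per (wavelength, group) with statistics of brain sensitivity,
    pulse amplitude, max fluence, pulsatile fluence difference, and dynamic
    range — the five panels of the per-group comparison.
    """
    merged = rankings.merge(
        metrics,
        on=["wavelength_nm", "group", "source_id", "detector_id"],
        suffixes=("", "_m"),
    )
    merged["phi_diff"] = merged["phi_diastole"] - merged["phi_systole"]
    rows = []
    for (lam, grp), sub in merged.groupby(["wavelength_nm", "group"],
                                          sort=True):
        row = {"wavelength_nm": lam, "group": grp, "n_channels": len(sub)}
        for col in ("score", "delta_od_noisy", "phi_diastole", "phi_diff",
                    "dynamic_range_noisy"):
            row[f"{col}_mean"] = sub[col].mean()
            row[f"{col}_std"] = sub[col].std(ddof=0)
        rows.append(row)
    return pd.DataFrame(rows)
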