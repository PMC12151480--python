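"""Scenario configuration: one YAML/JSON-serialisable bundle per run.

A :class:`ScenarioConfig` references every model input (mask, cavity,
layout, synthetic face, fluid, fabric, breath, clip, losses, solver knobs)
plus run metadata, and knows how to build the geometry/gap objects it
describes.  Round-tripping through ``to_dict``/``from_dict`` is stable,
which the CLI uses for config hashing and provenance logs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from maskflow import __version__ as _pkg_version
from maskflow.channel import FabricModel, FluidProperties
from maskflow.gaps import (
    FeatureSpec,
    GapProfileSet,
    GeneratorConfig,
    feature_gaps,
    mean_face_gaps,
    read_gaps,
)
from maskflow.geometry import (
    INCH,
    CavitySpec,
    ChannelGeometry,
    ChannelLayout,
    MaskSpec,
    build_channels,
    scale_cavity,
)
from maskflow.network import BreathSpec, ClipSpec, SolverOptions


class ConfigError(ValueError):
    """Invalid or inconsistent scenario configuration."""


@dataclass
class ScenarioConfig:
    """Everything needed to reproduce one network solve."""

    mask: MaskSpec = field(default_factory=MaskSpec)
    cavity_y_offset: float = 0.0       # m
    cavity_area_scale: float = 0.0     # fractional change of the cavity area
    layout: ChannelLayout = field(default_factory=ChannelLayout)
    face: FeatureSpec = field(default_factory=FeatureSpec)
    gap_file: str | None = None        # overrides the synthetic generator
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    fluid: FluidProperties = field(default_factory=FluidProperties)
    fabric: FabricModel = field(default_factory=FabricModel)
    breath: BreathSpec = field(default_factory=BreathSpec)
    clip: ClipSpec = field(default_factory=ClipSpec)
    edge_k_L_exhale: float = 0.0
    edge_k_L_inhale: float = 0.5
    solver: SolverOptions = field(default_factory=SolverOptions)
    label: str = "scenario"
    seed: int = 1
    version: str = _pkg_version

    # -- construction helpers ----------------------------------------------
    def cavity_spec(self) -> CavitySpec:
        cav = CavitySpec.default_for(self.mask, y_offset=self.cavity_y_offset)
        if self.cavity_area_scale:
            cav = scale_cavity(cav, self.cavity_area_scale)
        return cav

    def build_channels(self) -> list[ChannelGeometry]:
        return build_channels(self.mask, self.cavity_spec(), self.layout)

    def build_gaps(self, channels: list[ChannelGeometry]) -> GapProfileSet:
        if self.gap_file is not None:
            return read_gaps(self.gap_file, channels)
        base = mean_face_gaps(channels, self.face.seed or self.seed,
                              self.generator)
        return feature_gaps(base, self.face, self.generator)

    @property
    def edge_k_L(self) -> float:
        if self.breath.direction == "inhale":
            return self.edge_k_L_inhale
        return self.edge_k_L_exhale

    # -- (de)serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "seed": self.seed,
            "version": self.version,
            "mask": {"L1_in": self.mask.L1 / INCH,
                     "L2_in": self.mask.L2 / INCH,
                     "tuck_ratio": self.mask.tuck_ratio},
            "cavity": {"y_offset_mm": self.cavity_y_offset * 1e3,
                       "area_scale": self.cavity_area_scale},
            "layout": {"n_nose": self.layout.n_nose,
                       "n_chin": self.layout.n_chin,
                       "n_cheek_per_side": self.layout.n_cheek_per_side,
                       "symmetry": self.layout.use_symmetry},
            "face": {"feature": self.face.feature, "alpha": self.face.alpha,
                     "seed": self.face.seed},
            "gaps": {"file": self.gap_file,
                     "modulation_amplitude": self.generator.modulation_amplitude,
                     "n_harmonics": self.generator.n_harmonics,
                     "taper_cavity_factor": self.generator.taper_cavity_factor,
                     "grid_size": self.generator.grid_size},
            "fluid": {"rho": self.fluid.rho, "mu": self.fluid.mu},
            "fabric": {"ck": self.fabric.c_k},
            "breath": {"Q_lps": self.breath.Q_breath * 1e3,
                       "direction": self.breath.direction},
            "clip": {"kL": self.clip.k_L_clip,
                     "region": self.clip.target_region},
            "edge_loss": {"kL_exhale": self.edge_k_L_exhale,
                          "kL_inhale": self.edge_k_L_inhale},
            "solver": {"eps": self.solver.eps, "step_a": self.solver.step_a,
                       "max_iter": self.solver.max_iter},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        try:
            mask_d = d.get("mask", {})
            mask = MaskSpec(L1=mask_d.get("L1_in", 9.0) * INCH,
                            L2=mask_d.get("L2_in", 5.4) * INCH,
                            tuck_ratio=mask_d.get("tuck_ratio", 0.5))
            cav_d = d.get("cavity", {})
            lay_d = d.get("layout", {})
            layout = ChannelLayout(
                n_nose=lay_d.get("n_nose", 16),
                n_chin=lay_d.get("n_chin", 16),
                n_cheek_per_side=lay_d.get("n_cheek_per_side", 8),
                use_symmetry=lay_d.get("symmetry", True))
            face_d = d.get("face", {})
            face = FeatureSpec(feature=face_d.get("feature", "mean_face"),
                               alpha=face_d.get("alpha", 0.0),
                               seed=face_d.get("seed", d.get("seed", 1)))
            gap_d = d.get("gaps", {})
            gen = GeneratorConfig(
                modulation_amplitude=gap_d.get("modulation_amplitude", 0.15),
                n_harmonics=gap_d.get("n_harmonics", 3),
                taper_cavity_factor=gap_d.get("taper_cavity_factor", 1.0),
                grid_size=gap_d.get("grid_size", 101))
            fl_d = d.get("fluid", {})
            fb_d = d.get("fabric", {})
            br_d = d.get("breath", {})
            cl_d = d.get("clip", {})
            el_d = d.get("edge_loss", {})
            so_d = d.get("solver", {})
            return cls(
                mask=mask,
                cavity_y_offset=cav_d.get("y_offset_mm", 0.0) * 1e-3,
                cavity_area_scale=cav_d.get("area_scale", 0.0),
                layout=layout,
                face=face,
                gap_file=gap_d.get("file"),
                generator=gen,
                fluid=FluidProperties(rho=fl_d.get("rho", 1.2),
                                      mu=fl_d.get("mu", 1.8e-5)),
                fabric=FabricModel(c_k=fb_d.get("ck", 500.0)),
                breath=BreathSpec(Q_breath=br_d.get("Q_lps", 0.5) * 1e-3,
                                  direction=br_d.get("direction", "exhale")),
                clip=ClipSpec(k_L_clip=cl_d.get("kL", 0.0),
                              target_region=cl_d.get("region", "nose")),
                edge_k_L_exhale=el_d.get("kL_exhale", 0.0),
                edge_k_L_inhale=el_d.get("kL_inhale", 0.5),
                solver=SolverOptions(eps=so_d.get("eps", 1e-6),
                                     step_a=so_d.get("step_a", 0.3),
                                     max_iter=so_d.get("max_iter", 500)),
                label=d.get("label", "scenario"),
                seed=d.get("seed", 1),
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid scenario config: {exc}") from exc

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("scenario config must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def with_updates(self, **kwargs) -> "ScenarioConfig":
        return replace(self, **kwargs)
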