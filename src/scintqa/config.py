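"""YAML configuration: beams, materials, cameras, pipeline parameters.

One YAML file can describe everything a command-line run needs; each
section is optional and falls back to the study defaults (60 MeV beam,
BC-408 block, camera at 500 mm). Example::

    beam: {mean_energy: 60.0, energy_sigma: 0.36, n_protons: 100000}
    scintillator: {material: BC-408, depth_mm: 100.0}
    quench: {kB: 0.154}
    camera: {r: 500.0, pixel_pitch_mm: 0.1, bit_depth: 14}
    pipeline:
      roi: [0, 320, 0, 480]
      median_kernel: 3
      band_halfwidth_px: 20
      entrance_px: 24
      field_diameter_mm: 25.0
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .camera_optics import CameraModel
from .image_pipeline import ROI, PipelineConfig
from .quenching import QuenchModel
from .transport import BeamSpec, Material, MaterialStack, get_material


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(cfg, dict):
        raise ValueError("top-level YAML must be a mapping")
    return cfg


def beam_from_config(cfg: dict) -> BeamSpec:
    return BeamSpec(**cfg.get("beam", {}))


def material_from_config(section: dict) -> Material:
    """A built-in material by name, or a fully custom one."""
    if "composition" in section:
        return Material(
            name=section.get("name", "custom"),
            density=section["density"],
            composition=[tuple(p) for p in section["composition"]],
            mean_excitation_energy=section["mean_excitation_energy"],
            refractive_index=section.get("refractive_index", 1.0),
        )
    return get_material(section.get("material", "BC-408"))


def stack_from_config(cfg: dict) -> MaterialStack:
    """Scintillator (plus optional upstream degraders) as a MaterialStack."""
    layers = []
    for layer in cfg.get("degraders", []):
        layers.append((material_from_config(layer), float(layer["thickness_mm"])))
    scint = cfg.get("scintillator", {})
    layers.append((material_from_config(scint),
                   float(scint.get("depth_mm", 100.0))))
    return MaterialStack(layers)


def quench_from_config(cfg: dict) -> QuenchModel:
    q = cfg.get("quench", {})
    return QuenchModel(kB=q.get("kB", 0.154), L0=q.get("L0", 1.0))


def camera_from_config(cfg: dict) -> CameraModel:
    return CameraModel(**cfg.get("camera", {}))


def pipeline_from_config(cfg: dict) -> PipelineConfig:
    p = dict(cfg.get("pipeline", {}))
    if "roi" not in p:
        raise ValueError("pipeline config requires an roi: [r0, r1, c0, c1]")
    roi = ROI(*p.pop("roi"))
    cam = camera_from_config(cfg)
    return PipelineConfig(cam=cam, roi=roi, **p)
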