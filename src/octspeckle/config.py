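"""Tissue/system configuration as a YAML/JSON-friendly block.

Bundles the layer stack, detector, source and depth grid together with the
photon budget and master seed, so a whole simulation setup travels as one
document.  Defaults reproduce the corneal imaging configuration: a single
600 um stromal layer (n = 1.376) between air and aqueous humor, an 850/50 nm
source, 2.7 um axial pixels and a 0.2 cm detector disc 100 um above the
surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .mc_transport import DetectorSpec, LayerStack, OpticalProperties
from .oct_synthesis import DEFAULT_N_ASCANS, DepthGrid, SourceSpec

__all__ = ["SimulationConfig", "load_config", "dump_config"]


@dataclass
class SimulationConfig:
    stack: LayerStack = field(default_factory=LayerStack)
    detector: DetectorSpec = field(default_factory=DetectorSpec)
    source: SourceSpec = field(default_factory=SourceSpec)
    depth_grid: DepthGrid = field(default_factory=DepthGrid)
    n_ascans: int = DEFAULT_N_ASCANS
    n_packets: int = 15_000_000
    seed: int = 0

    @classmethod
    def from_dict(cls, doc: dict) -> "SimulationConfig":
        cfg = cls()
        layers = doc.get("layers")
        if layers is not None:
            parsed = tuple(
                (
                    float(layer["thickness_um"]),
                    OpticalProperties(
                        mu_s=float(layer["mu_s"]),
                        mu_a=float(layer.get("mu_a", 0.0)),
                        g=float(layer["g"]),
                        n=float(layer.get("n", 1.376)),
                    ),
                )
                for layer in layers
            )
            cfg.stack = LayerStack(
                layers=parsed,
                n_above=float(doc.get("n_above", 1.0)),
                n_below=float(doc.get("n_below", 1.33)),
            )
        det = doc.get("detector", {})
        cfg.detector = DetectorSpec(
            radius_cm=float(det.get("radius_cm", 0.2)),
            height_um=float(det.get("height_um", 100.0)),
        )
        src = doc.get("source", {})
        cfg.source = SourceSpec(
            lambda0_nm=float(src.get("lambda0_nm", 850.0)),
            delta_lambda_nm=float(src.get("dlambda_nm", 50.0)),
        )
        grid = doc.get("depth_grid", {})
        cfg.depth_grid = DepthGrid(
            pixel_um=float(grid.get("pixel_um", 2.7)),
            n_pixels=int(grid.get("n_pixels", 223)),
            sample_n=float(grid.get("sample_n", 1.376)),
        )
        cfg.n_ascans = int(doc.get("n_ascans", DEFAULT_N_ASCANS))
        cfg.n_packets = int(doc.get("n_packets", 15_000_000))
        cfg.seed = int(doc.get("seed", 0))
        return cfg

    def to_dict(self) -> dict:
        return {
            "layers": [
                {
                    "thickness_um": thickness,
                    "mu_s": props.mu_s,
                    "mu_a": props.mu_a,
                    "g": props.g,
                    "n": props.n,
                }
                for thickness, props in self.stack.layers
            ],
            "n_above": self.stack.n_above,
            "n_below": self.stack.n_below,
            "detector": {
                "radius_cm": self.detector.radius_cm,
                "height_um": self.detector.height_um,
            },
            "source": {
                "lambda0_nm": self.source.lambda0_nm,
                "dlambda_nm": self.source.delta_lambda_nm,
            },
            "depth_grid": {
                "pixel_um": self.depth_grid.pixel_um,
                "n_pixels": self.depth_grid.n_pixels,
                "sample_n": self.depth_grid.sample_n,
            },
            "n_ascans": self.n_ascans,
            "n_packets": self.n_packets,
            "seed": self.seed,
        }


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return SimulationConfig.from_dict(doc)


def dump_config(cfg: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
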