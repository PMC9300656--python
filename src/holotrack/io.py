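"""File formats and run configuration.

Images travel as 8/16-bit grayscale TIFF (single frame or stack); positions,
tracks and ground truth as CSV with an embedded config-hash header line; fit
results as JSON.  Run configuration is a YAML or TOML file collecting the
optical parameters, reconstruction grid, detection parameters and analysis
gates; every output carries the SHA-256 hash of its canonical form so two
outputs with equal hashes were produced by identical parameters.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .config import ConfigError, OpticalConfig, ZGrid
from .holography import DataError
from .localize import DetectionParams, Position3D

__all__ = [
    "RunConfig",
    "read_stack",
    "write_stack",
    "positions_to_frame",
    "write_positions_csv",
    "read_positions_csv",
]


@dataclass(frozen=True)
class RunConfig:
    """Everything a reproducible run needs, loadable from YAML or TOML."""

    optics: OpticalConfig
    zgrid: ZGrid
    detection: DetectionParams = field(default_factory=DetectionParams)
    lowpass_sigma: float | None = None
    pad_factor: int = 1
    seed: int = 0
    fps: float = 2.0
    gate_nm: float = 1000.0

    @classmethod
    def from_mapping(cls, m: dict) -> "RunConfig":
        try:
            optics = OpticalConfig(
                wavelength=float(m["wavelength_nm"]),
                refractive_index=float(m["refractive_index"]),
                pixel_spacing=float(m["pixel_spacing_nm"]),
            )
            zgrid = ZGrid.from_range(
                float(m["z_min_nm"]), float(m["z_max_nm"]), float(m["z_step_nm"])
            )
        except KeyError as err:
            raise ConfigError(f"missing config key: {err}") from err
        det_kwargs = {
            k: m[k]
            for k in (
                "intensity_threshold",
                "min_separation",
                "edge_margin",
                "column_width",
                "mask_tolerance",
                "max_iterations",
            )
            if k in m
        }
        if "cuboid_size" in m:
            det_kwargs["cuboid_size"] = tuple(m["cuboid_size"])
        return cls(
            optics=optics,
            zgrid=zgrid,
            detection=DetectionParams(**det_kwargs),
            lowpass_sigma=m.get("lowpass_sigma"),
            pad_factor=int(m.get("pad_factor", 1)),
            seed=int(m.get("seed", 0)),
            fps=float(m.get("fps", 2.0)),
            gate_nm=float(m.get("gate_nm", 1000.0)),
        )

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            with path.open() as fh:
                return cls.from_mapping(yaml.safe_load(fh))
        if path.suffix == ".toml":
            with path.open("rb") as fh:
                return cls.from_mapping(tomllib.load(fh))
        raise ConfigError(f"unknown config format {path.suffix!r}")

    def to_mapping(self) -> dict:
        d = self.detection
        return {
            "wavelength_nm": self.optics.wavelength,
            "refractive_index": self.optics.refractive_index,
            "pixel_spacing_nm": self.optics.pixel_spacing,
            "z_min_nm": float(self.zgrid.z_values[0]),
            "z_max_nm": float(self.zgrid.z_values[-1]),
            "z_step_nm": self.zgrid.spacing,
            "intensity_threshold": d.intensity_threshold,
            "min_separation": d.sep,
            "edge_margin": d.margin,
            "column_width": d.column_width,
            "cuboid_size": list(d.cuboid_size),
            "mask_tolerance": d.mask_tolerance,
            "max_iterations": d.max_iterations,
            "lowpass_sigma": self.lowpass_sigma,
            "pad_factor": self.pad_factor,
            "seed": self.seed,
            "fps": self.fps,
            "gate_nm": self.gate_nm,
        }

    @property
    def config_hash(self) -> str:
        canonical = json.dumps(self.to_mapping(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def read_stack(path: str | Path) -> np.ndarray:
    """Read a TIFF as a (frames, ny, nx) array of unsigned-integer counts.

    Accepts single-frame or multi-frame 8/16-bit grayscale; RGB or float
    TIFFs raise an explicit format error.
    """
    arr = tifffile.imread(str(path))
    if arr.dtype not in (np.uint8, np.uint16):
        raise DataError(
            f"unsupported TIFF dtype {arr.dtype}; expected 8/16-bit grayscale"
        )
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise DataError(f"unsupported TIFF layout with shape {arr.shape} (RGB?)")
    return arr


def write_stack(path: str | Path, frames: np.ndarray, dtype=np.uint16) -> None:
    """Write frames (2D or 3D array) as a grayscale TIFF of ``dtype`` counts."""
    frames = np.asarray(frames)
    info = np.iinfo(dtype)
    frames = np.clip(np.rint(frames), info.min, info.max).astype(dtype)
    tifffile.imwrite(str(path), frames)


def positions_to_frame(
    positions: list[Position3D], excluded_reasons: dict[int, str] | None = None
) -> pd.DataFrame:
    rows = [
        {
            "frame": p.frame_index,
            "candidate_id": p.candidate_id,
            "x_nm": p.x,
            "y_nm": p.y,
            "z_nm": p.z,
            "converged": p.converged,
            "n_iterations": p.n_iterations,
            "excluded_reason": "",
            "flags": ";".join(p.flags),
        }
        for p in positions
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "frame",
            "candidate_id",
            "x_nm",
            "y_nm",
            "z_nm",
            "converged",
            "n_iterations",
            "excluded_reason",
            "flags",
        ],
    )


def write_positions_csv(
    path: str | Path, df: pd.DataFrame, config_hash: str = ""
) -> None:
    """Write a positions table with a self-describing header comment."""
    with Path(path).open("w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def read_positions_csv(path: str | Path) -> tuple[pd.DataFrame, str]:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        config_hash = ""
        if first.startswith("#"):
            config_hash = first.strip().split("config_hash=")[-1]
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    return df, config_hash
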