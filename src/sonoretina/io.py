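"""File I/O: HDF5 fields and B-mode stacks, CSV/JSON drives, PNG/CSV target
patterns, and the YAML run configuration."""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml
from imageio.v3 import imread, imwrite
from numpy.typing import NDArray

from .alignment import BModeImage, EyePhantomSpec
from .dosimetry import PulseParams
from .holography import ArraySpec, DriveSolution, TargetPattern
from .propagation import ComplexField, Grid2D, MediumProps


def write_field(path: str | Path, field: ComplexField) -> None:
    """Serialize a complex field to HDF5 (datasets ``real``/``imag``, grid
    and plane metadata as attributes)."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("real", data=field.values.real)
        h5.create_dataset("imag", data=field.values.imag)
        h5.attrs.update(
            dx=field.grid.dx, dy=field.grid.dy, z=field.z, f=field.f,
            nx=field.grid.nx, ny=field.grid.ny,
        )


def read_field(path: str | Path) -> ComplexField:
    with h5py.File(path, "r") as h5:
        for key in ("real", "imag"):
            if key not in h5:
                raise ValueError(f"{path}: missing dataset '{key}'")
        vals = h5["real"][()] + 1j * h5["imag"][()]
        a = h5.attrs
        grid = Grid2D(int(a["nx"]), int(a["ny"]), float(a["dx"]), float(a["dy"]))
        return ComplexField(grid, vals, float(a["z"]), float(a["f"]))


def write_field_csv(path: str | Path, field: ComplexField) -> None:
    """Magnitude-only CSV export (one row per grid row)."""
    np.savetxt(path, field.magnitude, delimiter=",")


def write_magnitude_png(path: str | Path, field: ComplexField) -> None:
    """8-bit normalized |p| image."""
    mag = field.magnitude
    peak = mag.max()
    img = np.zeros_like(mag, dtype=np.uint8) if peak == 0 else (255 * mag / peak)
    imwrite(path, np.asarray(img, dtype=np.uint8))


def write_drive(path: str | Path, drive: DriveSolution) -> None:
    """Drive as CSV (row, col, amplitude, phase_rad) or JSON by extension."""
    path = Path(path)
    ny, nx = drive.amplitude.shape
    rows, cols = np.divmod(np.arange(ny * nx), nx)
    if path.suffix.lower() == ".json":
        payload = {
            "n_elem_y": ny,
            "n_elem_x": nx,
            "amplitude": drive.amplitude.tolist(),
            "phase_rad": drive.phase.tolist(),
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        df = pd.DataFrame(
            {
                "row": rows,
                "col": cols,
                "amplitude": drive.amplitude.ravel(),
                "phase_rad": drive.phase.ravel(),
            }
        )
        df.to_csv(path, index=False)


def read_drive(path: str | Path) -> DriveSolution:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        return DriveSolution(
            np.asarray(payload["amplitude"], dtype=float),
            np.asarray(payload["phase_rad"], dtype=float),
        )
    df = pd.read_csv(path)
    for col in ("row", "col", "amplitude", "phase_rad"):
        if col not in df.columns:
            raise ValueError(f"{path}: malformed drive CSV, missing column '{col}'")
    ny, nx = int(df["row"].max()) + 1, int(df["col"].max()) + 1
    amp = np.zeros((ny, nx))
    phi = np.zeros((ny, nx))
    amp[df["row"], df["col"]] = df["amplitude"]
    phi[df["row"], df["col"]] = df["phase_rad"]
    return DriveSolution(amp, phi)


def read_pattern(path: str | Path, Li: float, z: float) -> TargetPattern:
    """Load a target pattern from a grayscale PNG or a CSV matrix.

    Images are converted to float intensity in [0, 1]; non-square inputs are
    zero-padded to square (centered) and the padding recorded in the returned
    pattern's ``meta``.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        img = np.loadtxt(path, delimiter=",", dtype=float)
    else:
        raw = imread(path)
        if raw.ndim == 3:
            raw = raw[..., :3].mean(axis=-1)
        img = raw.astype(float)
        if img.max() > 0:
            img = img / img.max()
    meta = {"source": str(path), "original_shape": list(img.shape)}
    h, w = img.shape
    if h != w:
        n = max(h, w)
        padded = np.zeros((n, n), dtype=float)
        r0, c0 = (n - h) // 2, (n - w) // 2
        padded[r0 : r0 + h, c0 : c0 + w] = img
        img = padded
        meta["padded_to"] = [n, n]
        meta["pad_offset"] = [r0, c0]
    return TargetPattern(img, Li=Li, z=z, meta=meta)


def write_bmode_stack(path: str | Path, slices: list[BModeImage]) -> None:
    with h5py.File(path, "w") as h5:
        for i, s in enumerate(slices):
            ds = h5.create_dataset(f"slice_{i:03d}", data=s.intensity)
            ds.attrs.update(dz=s.dz, dx=s.dx, y=s.y)


def read_bmode_stack(path: str | Path) -> list[BModeImage]:
    out = []
    with h5py.File(path, "r") as h5:
        for name in sorted(h5):
            ds = h5[name]
            out.append(
                BModeImage(ds[()], float(ds.attrs["dz"]), float(ds.attrs["dx"]),
                           y=float(ds.attrs["y"]))
            )
    return out


@dataclass(frozen=True)
class RunConfig:
    """Everything a reproducible run needs: geometry, media, pulse, seeds."""

    array: ArraySpec = ArraySpec()
    medium: MediumProps = MediumProps()
    eye: EyePhantomSpec = EyePhantomSpec()
    pulse: PulseParams = PulseParams(npp=1.0, f=4.5)
    target_li: float = 4.0
    n_slices: int = 9
    seed: int = 0
    outdir: str = "demo_out"

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return RunConfig.from_dict(raw)

    @staticmethod
    def from_dict(raw: dict) -> "RunConfig":
        def build(cls, key):
            sub = raw.get(key, {})
            if not isinstance(sub, dict):
                raise ValueError(f"config section '{key}' must be a mapping")
            try:
                return cls(**sub)
            except TypeError as exc:
                raise ValueError(f"config section '{key}': {exc}") from None
        known = {"array", "medium", "eye", "pulse", "target_li", "n_slices",
                 "seed", "outdir"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return RunConfig(
            array=build(ArraySpec, "array"),
            medium=build(MediumProps, "medium"),
            eye=build(EyePhantomSpec, "eye"),
            pulse=build(PulseParams, "pulse") if "pulse" in raw
            else PulseParams(npp=1.0, f=4.5),
            target_li=float(raw.get("target_li", 4.0)),
            n_slices=int(raw.get("n_slices", 9)),
            seed=int(raw.get("seed", 0)),
            outdir=str(raw.get("outdir", "demo_out")),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
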