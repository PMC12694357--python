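"""Synthetic phantom generators: every input the pipeline needs, from code.

* 2D layered optical phantom — polyurethane encapsulant, cerebrospinal
  fluid, gray/white matter and cerebellum layers (thicknesses 0.8 / 0.5 /
  2.5 / 3.5 mm from the packaged property table, total depth 7.3 mm) with
  a blood vessel embedded in the gray matter.  Interfaces are flat by
  default (analytic test oracles) with an optional curvature preset
  mimicking curved cortical anatomy.

* 3D voxel head phantom — hemispherical brain (default radius 7 cm, dome
  up), a 0.7 cm head shell over the dome, and a 1 cm^3 photonics device
  sitting on the shell apex with the receiving coil inside, voxelized at
  2 mm (about 10^5 tissue voxels).

* ``make_fixtures`` — writes small deterministic text fixtures (property
  tables, waveform series, phantom descriptions, a toy SAR map with known
  averaged values) plus a SHA-256 manifest.

All generators are pure functions of (config, seed); the defaults carry no
randomness at all, so the seed only matters for user-randomized variants.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import spectra
from .hemodynamics import ModulationModel, PressureWaveform, sample_waveform, write_waveform_csv
from .photon_transport import LayeredPhantom2D
from .sar import VoxelPhantom3D
from .spectra import BloodState, default_em_props, default_tissue_props

__all__ = [
    "Phantom2DConfig",
    "Phantom3DConfig",
    "make_phantom_2d",
    "make_phantom_3d",
    "make_fixtures",
]


@dataclass(frozen=True)
class Phantom2DConfig:
    """Configuration of the 2D layered optical phantom."""

    layer_order: tuple[str, ...] = ("polyurethane", "csf", "gray_white_matter", "cerebellum")
    thickness_overrides_mm: dict[str, float] = field(default_factory=dict)
    curvature_radius_mm: float = math.inf  # inf = flat interfaces
    vessel_depth_mm: float = 2.5
    vessel_diameter_mm: float = 0.5
    blood: BloodState = field(default_factory=BloodState)
    width_mm: float = 20.0
    ambient_index: float = 1.0


@dataclass(frozen=True)
class Phantom3DConfig:
    """Configuration of the 3D voxel head phantom."""

    brain_radius_m: float = 0.07
    shell_thickness_m: float = 0.007
    device_size_m: tuple[float, float, float] = (0.01, 0.01, 0.01)
    voxel_m: float = 0.002
    margin_m: float = 0.006

    def __post_init__(self) -> None:
        if self.brain_radius_m <= 0 or self.shell_thickness_m < 0 or self.voxel_m <= 0:
            raise ValueError("phantom dimensions must be positive")
        if any(d <= 0 for d in self.device_size_m):
            raise ValueError("device dimensions must be positive")


def make_phantom_2d(cfg: Phantom2DConfig | None = None, seed: int = 0) -> LayeredPhantom2D:
    """Build the layered 2D phantom from packaged tissue properties."""
    cfg = cfg or Phantom2DConfig()
    props = default_tissue_props()
    layers = []
    for name in cfg.layer_order:
        p = props[name]
        if name in cfg.thickness_overrides_mm:
            from dataclasses import replace

            p = replace(p, thickness=cfg.thickness_overrides_mm[name])
        layers.append(p)
    return LayeredPhantom2D(
        layers=tuple(layers),
        vessel_depth_mm=cfg.vessel_depth_mm,
        vessel_diameter_mm=cfg.vessel_diameter_mm,
        blood=cfg.blood,
        ambient_index=cfg.ambient_index,
        width_mm=cfg.width_mm,
        curvature_radius_mm=cfg.curvature_radius_mm,
    )


def make_phantom_3d(cfg: Phantom3DConfig | None = None, seed: int = 0) -> VoxelPhantom3D:
    """Voxelize the hemispherical head-and-implant geometry.

    Geometry (z up): brain hemisphere dome over z >= 0 centred at the
    origin, head shell over the dome, device box on the shell apex with
    the coil axis vertical.
    """
    cfg = cfg or Phantom3DConfig()
    r_b = cfg.brain_radius_m
    r_h = r_b + cfg.shell_thickness_m
    dx, dy, dz = cfg.device_size_m
    m = cfg.margin_m
    s = cfg.voxel_m

    x_lo, x_hi = -(r_h + m), r_h + m
    z_lo, z_hi = -m, r_h + dz + m
    nx = int(math.ceil((x_hi - x_lo) / s))
    nz = int(math.ceil((z_hi - z_lo) / s))
    origin = (x_lo, x_lo, z_lo)

    xs = x_lo + (np.arange(nx) + 0.5) * s
    zs = z_lo + (np.arange(nz) + 0.5) * s
    X, Y, Z = np.meshgrid(xs, xs, zs, indexing="ij")
    r2 = X**2 + Y**2 + Z**2

    labels = np.zeros((nx, nx, nz), dtype=np.uint8)
    dome = Z >= 0.0
    labels[dome & (r2 <= r_h**2)] = 2  # head shell
    labels[dome & (r2 <= r_b**2)] = 3  # brain
    dev_center = (0.0, 0.0, r_h + dz / 2.0)
    in_dev = (
        (np.abs(X - dev_center[0]) <= dx / 2.0)
        & (np.abs(Y - dev_center[1]) <= dy / 2.0)
        & (np.abs(Z - dev_center[2]) <= dz / 2.0)
    )
    labels[in_dev] = 1  # photonics

    if not np.any(labels == 2) and not np.any(labels == 3):
        raise ValueError("configuration produced no tissue voxels")
    if (
        dev_center[2] + dz / 2.0 > z_hi
        or abs(dev_center[0]) + dx / 2.0 > x_hi
    ):
        raise ValueError("device placement outside the domain")

    return VoxelPhantom3D(
        spacing=s,
        labels=labels,
        label_names={0: "air", 1: "photonics", 2: "head", 3: "brain"},
        props=default_em_props(),
        origin=origin,
        coil_center=dev_center,
        coil_axis=(0.0, 0.0, 1.0),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_fixtures(out_dir: str | Path, seed: int = 0) -> dict:
    """Write the deterministic text fixture set and its checksum manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    # 1. packaged spectral table
    spec_path = out / "hemoglobin_absorption.csv"
    spectra.load_spectra().to_csv(spec_path)
    written.append(spec_path)

    # 2-3. tissue and EM property tables
    tissue_path = out / "tissue_optical.cfg"
    spectra.write_tissue_config(default_tissue_props(), tissue_path)
    written.append(tissue_path)
    em_path = out / "em_properties.csv"
    rows = ["name,sigma_S_per_m,rho_kg_per_m3"]
    for p in default_em_props().values():
        rows.append(f"{p.name},{p.sigma!r},{p.rho!r}")
    em_path.write_text("\n".join(rows) + "\n")
    written.append(em_path)

    # 4. default cardiac waveform series
    w = PressureWaveform()
    times, press = sample_waveform(w)
    mod = ModulationModel()
    wf_path = out / "pressure_waveform.csv"
    write_waveform_csv(wf_path, times, press, np.asarray(mod.volume_fraction(press)))
    written.append(wf_path)

    # 5. small 2D phantom description
    ph2 = make_phantom_2d(seed=seed)
    ph2_path = out / "phantom2d.json"
    ph2_path.write_text(
        json.dumps(
            {
                "layers": [
                    {"name": l.name, "thickness_mm": l.thickness} for l in ph2.layers
                ],
                "vessel_depth_mm": ph2.vessel_depth_mm,
                "vessel_diameter_mm": ph2.vessel_diameter_mm,
                "so2": ph2.blood.so2,
                "volume_fraction": ph2.blood.volume_fraction,
                "total_thickness_mm": ph2.total_thickness_mm,
            },
            indent=2,
        )
        + "\n"
    )
    written.append(ph2_path)

    # 6. small 3D phantom summary (coarse voxels keep the fixture tiny)
    ph3 = make_phantom_3d(Phantom3DConfig(voxel_m=0.008), seed=seed)
    counts = {
        name: int((ph3.labels == code).sum()) for code, name in ph3.label_names.items()
    }
    ph3_path = out / "phantom3d_summary.json"
    ph3_path.write_text(
        json.dumps({"spacing_m": ph3.spacing, "voxel_counts": counts}, indent=2) + "\n"
    )
    written.append(ph3_path)

    # 7. toy SAR map with a single hot voxel: the 10 g average at the hot
    # voxel is (voxel mass / target mass) analytically
    from .sar import AveragingKernel, SARMap, mass_averaged_sar
    from .spectra import EMTissueProps

    n = 12
    labels = np.full((n, n, n), 3, dtype=np.uint8)
    toy = VoxelPhantom3D(
        spacing=0.004,
        labels=labels,
        label_names={0: "air", 3: "brain"},
        props={"brain": EMTissueProps("brain", 0.12, 1050.0)},
        tissue_label_names=("brain",),
    )
    sar_grid = np.zeros((n, n, n))
    sar_grid[n // 2, n // 2, n // 2] = 1.0
    avg = mass_averaged_sar(
        SARMap(sar=sar_grid, frequency_hz=1.35e6),
        toy,
        AveragingKernel(shape="adaptive"),
    )
    toy_path = out / "toy_sar.json"
    vox_mass = toy.voxel_volume * 1050.0
    toy_path.write_text(
        json.dumps(
            {
                "spacing_m": toy.spacing,
                "hot_voxel": [n // 2] * 3,
                "peak_10g_average": avg.peak,
                "expected_peak": vox_mass / avg.realized_mass_at_peak_kg,
                "realized_mass_kg": avg.realized_mass_at_peak_kg,
            },
            indent=2,
        )
        + "\n"
    )
    written.append(toy_path)

    manifest = {
        "seed": seed,
        "files": {p.name: _sha256(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
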