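"""Tissue and blood optical/electrical property tables and spectral lookup.

The packaged hemoglobin absorption table gives the wavelength-dependent
absorption coefficients of oxy- (HbO2) and deoxyhemoglobin (Hb) on a
10 nm grid from 400 to 890 nm.  Mixed whole-blood absorption at an oxygen
saturation SO2 is the linear Beer-Lambert combination

    mua_blood(lambda, SO2) = SO2 * mua_HbO2(lambda) + (1 - SO2) * mua_Hb(lambda)

with piecewise-linear interpolation for off-grid wavelengths.  The table's
coefficient scale (order 0.1-1.7 per metre) is taken at face value as the
normative dataset; the reflectance engines consume it through an explicit
normalized blood-path calibration (see :mod:`implumen.photon_transport`).

Tissue optical/thermal and electromagnetic property sets (layer refractive
indices, absorption/scattering coefficients, conductivities, densities) are
packaged as module-level dictionaries and round-trip through a small
key-value block config format.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "HemoglobinSpectrum",
    "TissueOpticalProps",
    "EMTissueProps",
    "BloodState",
    "load_spectra",
    "blood_mua",
    "default_tissue_props",
    "default_em_props",
    "write_tissue_config",
    "read_tissue_config",
    "SPECTRUM_COLUMNS",
]

SPECTRUM_COLUMNS = ("wavelength_nm", "mua_hbo2_per_m", "mua_hb_per_m")


@dataclass(frozen=True)
class HemoglobinSpectrum:
    """Wavelength-gridded absorption coefficients for HbO2 and Hb (1/m)."""

    wavelengths_nm: np.ndarray
    mua_hbo2: np.ndarray
    mua_hb: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        hbo2 = np.asarray(self.mua_hbo2, dtype=float)
        hb = np.asarray(self.mua_hb, dtype=float)
        if wl.ndim != 1 or wl.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1-D array")
        if hbo2.shape != wl.shape or hb.shape != wl.shape:
            raise ValueError("HbO2 and Hb grids must match the wavelength grid")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(hbo2 <= 0) or np.any(hb <= 0):
            raise ValueError("absorption coefficients must be positive")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "mua_hbo2", hbo2)
        object.__setattr__(self, "mua_hb", hb)

    @property
    def lambda_min(self) -> float:
        return float(self.wavelengths_nm[0])

    @property
    def lambda_max(self) -> float:
        return float(self.wavelengths_nm[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wavelength_nm": self.wavelengths_nm,
                "mua_hbo2_per_m": self.mua_hbo2,
                "mua_hb_per_m": self.mua_hb,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class TissueOpticalProps:
    """Optical, thermal and electrical properties of one tissue layer.

    Thermal fields (conductivity, density, heat capacity) are stored for
    completeness but consumed by no operation here: thermal modelling is
    out of scope.
    """

    name: str
    refractive_index: float
    mua: float  # absorption coefficient, 1/m
    mus: float  # scattering coefficient, 1/m
    thickness: float  # mm
    thermal_conductivity: float = 0.0  # W/(m K)
    density: float = 1000.0  # kg/m3
    heat_capacity: float = 0.0  # J/(kg K)
    electrical_conductivity: float = 0.0  # S/m

    def __post_init__(self) -> None:
        if self.refractive_index < 1.0:
            raise ValueError(f"{self.name}: refractive index must be >= 1")
        for attr in (
            "mua",
            "mus",
            "thickness",
            "thermal_conductivity",
            "density",
            "heat_capacity",
            "electrical_conductivity",
        ):
            if getattr(self, attr) < 0:
                raise ValueError(f"{self.name}: {attr} must be >= 0")


@dataclass(frozen=True)
class EMTissueProps:
    """Electrical conductivity and density of one labelled region."""

    name: str
    sigma: float  # S/m
    rho: float  # kg/m3

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"{self.name}: sigma must be >= 0")
        if self.rho <= 0:
            raise ValueError(f"{self.name}: rho must be > 0")


@dataclass(frozen=True)
class BloodState:
    """Oxygen saturation and blood volume fraction of the vessel contents."""

    so2: float = 0.97
    volume_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.so2 <= 1.0:
            raise ValueError("so2 must lie in [0, 1]")
        if not 0.0 <= self.volume_fraction <= 1.0:
            raise ValueError("volume_fraction must lie in [0, 1]")


def _packaged_spectrum_text() -> str:
    return resources.files("implumen.data").joinpath("hemoglobin_absorption.csv").read_text()


def load_spectra(source: str | Path | pd.DataFrame | None = None) -> HemoglobinSpectrum:
    """Load a hemoglobin absorption spectrum table.

    Parameters
    ----------
    source
        ``None`` for the packaged default table, a path to a comma- or
        tab-separated file with header ``wavelength_nm,mua_hbo2_per_m,
        mua_hb_per_m``, or an equivalent DataFrame.
    """
    if source is None:
        df = pd.read_csv(io.StringIO(_packaged_spectrum_text()))
    elif isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep=None, engine="python")
    if df.empty:
        raise ValueError("spectrum table is empty")
    missing = [c for c in SPECTRUM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spectrum table missing columns: {missing}")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    if np.unique(wl).size != wl.size:
        raise ValueError("duplicated wavelengths in spectrum table")
    order = np.argsort(wl)
    return HemoglobinSpectrum(
        wavelengths_nm=wl[order],
        mua_hbo2=df["mua_hbo2_per_m"].to_numpy(dtype=float)[order],
        mua_hb=df["mua_hb_per_m"].to_numpy(dtype=float)[order],
    )


def blood_mua(
    spectrum: HemoglobinSpectrum,
    lambda_nm: float | np.ndarray,
    state: BloodState,
) -> float | np.ndarray:
    """Whole-blood absorption coefficient (1/m) at ``lambda_nm``.

    Linear interpolation on the spectrum grid; convex SO2-weighted
    combination of the HbO2 and Hb columns.
    """
    lam = np.asarray(lambda_nm, dtype=float)
    if np.any(lam < spectrum.lambda_min) or np.any(lam > spectrum.lambda_max):
        raise ValueError(
            f"wavelength outside spectral range "
            f"[{spectrum.lambda_min}, {spectrum.lambda_max}] nm"
        )
    hbo2 = np.interp(lam, spectrum.wavelengths_nm, spectrum.mua_hbo2)
    hb = np.interp(lam, spectrum.wavelengths_nm, spectrum.mua_hb)
    out = state.so2 * hbo2 + (1.0 - state.so2) * hb
    return float(out) if np.isscalar(lambda_nm) or out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Packaged layer / region property sets
# ---------------------------------------------------------------------------

_LAYER_ROWS: tuple[tuple, ...] = (
    # name, n, mua, mus, thickness_mm, k, rho, c, sigma
    ("polyurethane", 1.6, 0.0001, 0.5, 0.8, 0.15, 1200, 1800, 1e-5),
    ("csf", 1.33, 0.0013, 0.01, 0.5, 0.5, 1007, 3850, 0.12),
    ("gray_white_matter", 1.5, 0.0009, 0.05, 2.5, 0.5, 1045, 3500, 0.12),
    ("cerebellum", 1.42, 0.0002, 0.1, 3.5, 0.51, 1045, 3653, 0.45),
)

_EM_ROWS: tuple[tuple, ...] = (
    ("photonics", 1e-5, 1300),
    ("head", 0.15, 1100),
    ("brain", 0.12, 1050),
)


def default_tissue_props() -> dict[str, TissueOpticalProps]:
    """The packaged per-layer optical/thermal/electrical property set."""
    return {
        row[0]: TissueOpticalProps(
            name=row[0],
            refractive_index=row[1],
            mua=row[2],
            mus=row[3],
            thickness=row[4],
            thermal_conductivity=row[5],
            density=row[6],
            heat_capacity=row[7],
            electrical_conductivity=row[8],
        )
        for row in _LAYER_ROWS
    }


def default_em_props() -> dict[str, EMTissueProps]:
    """The packaged electromagnetic (sigma, rho) region property set."""
    return {name: EMTissueProps(name, sigma, rho) for name, sigma, rho in _EM_ROWS}


_TISSUE_FIELDS = (
    "refractive_index",
    "mua",
    "mus",
    "thickness",
    "thermal_conductivity",
    "density",
    "heat_capacity",
    "electrical_conductivity",
)


def write_tissue_config(props: Mapping[str, TissueOpticalProps], path: str | Path) -> None:
    """Write tissue property sets as key-value blocks, one per tissue."""
    lines: list[str] = []
    for name, p in props.items():
        lines.append(f"[{name}]")
        for f_ in _TISSUE_FIELDS:
            lines.append(f"{f_} = {getattr(p, f_)!r}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_tissue_config(path: str | Path) -> dict[str, TissueOpticalProps]:
    """Read tissue property sets written by :func:`write_tissue_config`."""
    out: dict[str, TissueOpticalProps] = {}
    block_name: str | None = None
    fields: dict[str, float] = {}

    def flush() -> None:
        nonlocal fields
        if block_name is not None:
            out[block_name] = TissueOpticalProps(name=block_name, **fields)
        fields = {}

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            flush()
            block_name = line[1:-1]
        else:
            key, _, val = line.partition("=")
            fields[key.strip()] = float(val.strip())
    flush()
    return out
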