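"""Resonant inductive link design: LC resonance, S11 spectrum, return loss.

The receiving coil (default inductance 15 uH) is tuned to the 1.35 MHz
operating frequency by back-calculating the capacitance from the LC
resonance relation f0 = 1 / (2 pi sqrt(L C)).  The reflection coefficient
against a real reference impedance z0 (default 50 ohm) is

    S11(f) = (Z(f) - z0) / (Z(f) + z0)

with Z(f) the series R-L-C impedance (the simplest single-dip model; a
parallel-tank alternative is available via ``topology="parallel"``).  The
default equivalent series resistance 53.31 ohm is a documented calibration
constant: it sets the resonance dip depth to |S11| = 3.31/103.31 = 0.032
(-29.87 dB return loss).  Note that tuning 15 uH to 1.35 MHz requires
about 927 pF, not the ~100 pF a compact-capacitor reading would suggest;
``design_report`` flags that inconsistency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CoilSpec",
    "ResonantCircuit",
    "S11Spectrum",
    "resonance_frequency",
    "required_capacitance",
    "s11_spectrum",
    "return_loss_db",
    "s11_magnitude_from_return_loss",
    "delivered_power_fraction",
    "design_report",
    "write_touchstone",
    "write_s11_csv",
    "DEFAULT_FREQS",
]

DEFAULT_FREQS = np.linspace(0.5e6, 3.0e6, 2001)


@dataclass(frozen=True)
class CoilSpec:
    """Receiving coil: lumped inductance plus geometry for field computation."""

    inductance: float = 15e-6  # H
    esr: float = 53.31  # ohm, calibrated to the -29.87 dB dip depth
    n_turns: int = 30
    radius: float = 0.005  # m
    turn_spacing: float = 0.0003  # m, axial pitch
    segments_per_turn: int = 64

    def __post_init__(self) -> None:
        if self.inductance <= 0:
            raise ValueError("inductance must be positive")
        if self.esr < 0:
            raise ValueError("ESR must be >= 0")
        if self.radius <= 0:
            raise ValueError("coil radius must be positive")
        if self.n_turns < 1 or self.segments_per_turn < 3:
            raise ValueError("need >= 1 turn and >= 3 segments per turn")


@dataclass(frozen=True)
class ResonantCircuit:
    """Tuned coil against a real reference impedance."""

    coil: CoilSpec = field(default_factory=CoilSpec)
    capacitance: float = 926.6e-12  # F, tunes 15 uH to 1.35 MHz
    z0: float = 50.0  # ohm
    topology: str = "series"  # "series" or "parallel"

    def __post_init__(self) -> None:
        if self.capacitance <= 0:
            raise ValueError("capacitance must be positive")
        if self.z0 <= 0:
            raise ValueError("reference impedance must be positive")
        if self.topology not in ("series", "parallel"):
            raise ValueError("topology must be 'series' or 'parallel'")

    def impedance(self, freqs: np.ndarray) -> np.ndarray:
        w = 2.0 * math.pi * np.asarray(freqs, dtype=float)
        if np.any(w <= 0):
            raise ValueError("frequencies must be positive")
        zl = self.coil.esr + 1j * w * self.coil.inductance
        zc = 1.0 / (1j * w * self.capacitance)
        if self.topology == "series":
            return zl + zc
        return zl * zc / (zl + zc)


@dataclass(frozen=True)
class S11Spectrum:
    """Complex reflection coefficient over a frequency sweep."""

    freqs: np.ndarray
    s11: np.ndarray
    z0: float

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.s11)

    @property
    def resonance_freq(self) -> float:
        """Frequency of minimal |S11| (the matching dip)."""
        return float(self.freqs[int(np.argmin(self.magnitude))])

    @property
    def min_return_loss_db(self) -> float:
        return return_loss_db(float(self.magnitude.min()))


def resonance_frequency(inductance: float, capacitance: float) -> float:
    """LC resonance frequency f0 = 1/(2 pi sqrt(L C)) in Hz."""
    if inductance <= 0 or capacitance <= 0:
        raise ValueError("L and C must be positive")
    return 1.0 / (2.0 * math.pi * math.sqrt(inductance * capacitance))


def required_capacitance(inductance: float, f0: float) -> float:
    """Capacitance (F) tuning ``inductance`` to resonate at ``f0`` (Hz)."""
    if inductance <= 0 or f0 <= 0:
        raise ValueError("L and f0 must be positive")
    return 1.0 / (inductance * (2.0 * math.pi * f0) ** 2)


def s11_spectrum(circuit: ResonantCircuit, freqs: np.ndarray | None = None) -> S11Spectrum:
    """Reflection coefficient spectrum of the tuned coil."""
    f = np.asarray(DEFAULT_FREQS if freqs is None else freqs, dtype=float)
    z = circuit.impedance(f)
    s11 = (z - circuit.z0) / (z + circuit.z0)
    return S11Spectrum(freqs=f, s11=s11, z0=circuit.z0)


def return_loss_db(s11_magnitude: float) -> float:
    """Return loss in dB, -20 log10 |S11|."""
    if s11_magnitude <= 0:
        raise ValueError("|S11| must be positive")
    if s11_magnitude > 1:
        raise ValueError("|S11| > 1 is non-passive")
    return -20.0 * math.log10(s11_magnitude)


def s11_magnitude_from_return_loss(rl_db: float) -> float:
    """Inverse of :func:`return_loss_db`."""
    return 10.0 ** (-rl_db / 20.0)


def delivered_power_fraction(s11_magnitude: float) -> float:
    """Fraction of incident power accepted by the coil, 1 - |S11|^2."""
    if not 0.0 <= s11_magnitude <= 1.0:
        raise ValueError("|S11| must lie in [0, 1]")
    return 1.0 - s11_magnitude**2


def design_report(
    inductance: float = 15e-6,
    target_freq: float = 1.35e6,
    esr: float = 53.31,
    z0: float = 50.0,
    freqs: np.ndarray | None = None,
) -> dict:
    """Back-calculate the tuning capacitor and characterize the S11 dip."""
    cap = required_capacitance(inductance, target_freq)
    circuit = ResonantCircuit(
        coil=CoilSpec(inductance=inductance, esr=esr), capacitance=cap, z0=z0
    )
    spec = s11_spectrum(circuit, freqs)
    mag_min = float(spec.magnitude.min())
    report = {
        "inductance_H": inductance,
        "target_frequency_hz": target_freq,
        "capacitance_F": cap,
        "resonance_frequency_hz": spec.resonance_freq,
        "min_s11_magnitude": mag_min,
        "min_return_loss_db": return_loss_db(mag_min),
        "delivered_power_fraction": delivered_power_fraction(mag_min),
        "notes": [],
    }
    # a nominal ~100 pF capacitor does NOT tune 15 uH to 1.35 MHz
    f_100pF = resonance_frequency(inductance, 100e-12)
    if abs(cap - 100e-12) / cap > 0.05:
        report["notes"].append(
            f"100 pF with L={inductance * 1e6:.3g} uH resonates at "
            f"{f_100pF / 1e6:.3f} MHz, not {target_freq / 1e6:.3f} MHz; "
            f"the LC relation requires {cap * 1e12:.1f} pF."
        )
    return report


def write_touchstone(spec: S11Spectrum, path: str | Path) -> None:
    """Write a Touchstone 1.0 one-port file (MA format, Hz)."""
    lines = [
        "! 1-port S-parameters of the tuned receiving coil",
        f"# Hz S MA R {spec.z0:g}",
    ]
    for f, s in zip(spec.freqs, spec.s11):
        lines.append(f"{f:.6f} {abs(s):.9e} {math.degrees(np.angle(s)):.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_s11_csv(spec: S11Spectrum, path: str | Path) -> None:
    """Columnar text export ``freq_hz,s11_db``."""
    lines = ["freq_hz,s11_db"]
    for f, m in zip(spec.freqs, spec.magnitude):
        lines.append(f"{f:.6f},{-return_loss_db(m):.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
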