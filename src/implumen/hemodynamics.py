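"""Cardiac pressure waveform and its mapping to pulsatile blood optical state.

The simulated window lasts 1.5 s.  A non-physiological ramp occupies
[0, 0.5] s (numerical initialization only) and the pulsatile cardiac phase
occupies [0.5, 1.5] s:

    ramp:   P(t) = (1 - alpha) * sin(pi * (t - t_ramp_start))
    pulse:  P(t) = (1 - alpha) * cos(2*pi * (t - t_pulse_start))

where ``alpha`` reflects the systolic fraction of the cardiac cycle
(default 1/3, systole ~33.3% of the cycle).  The two phases are continuous
at t = 0.5 s for every alpha since sin(pi/2) = cos(0) = 1.  P is normalized
and dimensionless, bounded by 1 - alpha in magnitude.

A ``ModulationModel`` maps normalized pressure to vessel blood volume
fraction, f(t) = f0 * (1 + beta * P(t)); f0 and beta are documented
calibration constants (defaults 0.05 and 0.15).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .spectra import BloodState

__all__ = [
    "PressureWaveform",
    "ModulationModel",
    "pressure",
    "sample_waveform",
    "blood_state_series",
    "write_waveform_csv",
]


@dataclass(frozen=True)
class PressureWaveform:
    """Piecewise normalized cardiac pressure waveform.

    ``pulse_shape`` selects the pulsatile-phase function: the printed cosine
    (default) or a triangular waveform of the same amplitude, period and
    phase (maximum at pulse start).
    """

    alpha: float = 1.0 / 3.0
    ramp_start: float = 0.0
    ramp_end: float = 0.5
    pulse_start: float = 0.5
    pulse_end: float = 1.5
    dt: float = 0.01
    pulse_shape: str = "cosine"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.ramp_end != self.pulse_start:
            raise ValueError("ramp_end must equal pulse_start")
        if not self.ramp_start < self.ramp_end < self.pulse_end:
            raise ValueError("phase boundaries must be increasing")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.pulse_shape not in ("cosine", "triangular"):
            raise ValueError("pulse_shape must be 'cosine' or 'triangular'")

    @property
    def amplitude(self) -> float:
        return 1.0 - self.alpha


def _triangular(phase: np.ndarray) -> np.ndarray:
    # period-1 triangle with maximum +1 at phase 0 and minimum -1 at phase 0.5
    frac = np.mod(phase, 1.0)
    return 1.0 - 4.0 * np.minimum(frac, 1.0 - frac)


def pressure(t: float | np.ndarray, w: PressureWaveform) -> float | np.ndarray:
    """Normalized pressure P(t); t may be scalar or array, within the window."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < w.ramp_start) or np.any(t_arr > w.pulse_end):
        raise ValueError(
            f"t outside simulated window [{w.ramp_start}, {w.pulse_end}] s"
        )
    amp = w.amplitude
    ramp = amp * np.sin(math.pi * (t_arr - w.ramp_start))
    if w.pulse_shape == "cosine":
        pulse = amp * np.cos(2.0 * math.pi * (t_arr - w.pulse_start))
    else:
        pulse = amp * _triangular(t_arr - w.pulse_start)
    out = np.where(t_arr < w.pulse_start, ramp, pulse)
    return float(out) if out.ndim == 0 else out


def sample_waveform(w: PressureWaveform) -> tuple[np.ndarray, np.ndarray]:
    """Sample P(t) over [ramp_start, pulse_end] at step dt.

    The endpoint is always included; the phase boundary belongs to the
    pulsatile definition (the two definitions agree there by construction).
    """
    times = np.arange(w.ramp_start, w.pulse_end, w.dt)
    times = np.unique(np.concatenate([times, [w.pulse_end]]))
    return times, np.asarray(pressure(times, w))


@dataclass(frozen=True)
class ModulationModel:
    """Linear pressure-to-blood-volume-fraction coupling.

    f(t) = f0 * (1 + beta * P(t)).  With |P| <= 1 - alpha the modulated
    fraction must stay inside [0, 1].
    """

    f0: float = 0.05
    beta: float = 0.15

    def __post_init__(self) -> None:
        if not 0.0 < self.f0 < 1.0:
            raise ValueError("f0 must lie in (0, 1)")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")

    def volume_fraction(self, p: float | np.ndarray) -> float | np.ndarray:
        f = self.f0 * (1.0 + self.beta * np.asarray(p, dtype=float))
        if np.any(f < 0.0) or np.any(f > 1.0):
            raise ValueError("modulated volume fraction leaves [0, 1]")
        return float(f) if f.ndim == 0 else f

    def extremes(self, w: PressureWaveform) -> tuple[float, float]:
        """(diastolic, systolic) volume fractions at the pressure extremes."""
        amp = w.amplitude
        return (
            float(self.volume_fraction(-amp)),
            float(self.volume_fraction(amp)),
        )


def blood_state_series(
    times: Iterable[float],
    pressures: Iterable[float],
    m: ModulationModel,
    so2: float = 0.97,
) -> list[tuple[float, BloodState]]:
    """Map a sampled pressure series to per-time blood states (constant SO2)."""
    out = []
    for t, p in zip(times, pressures):
        out.append((float(t), BloodState(so2=so2, volume_fraction=float(m.volume_fraction(p)))))
    return out


def write_waveform_csv(
    path: str | Path,
    times: np.ndarray,
    pressures: np.ndarray,
    volume_fractions: np.ndarray | None = None,
) -> None:
    """Columnar export ``t_s,pressure_norm,volume_fraction``."""
    lines = ["t_s,pressure_norm,volume_fraction"]
    vf = volume_fractions if volume_fractions is not None else np.full_like(times, np.nan)
    for t, p, f in zip(times, pressures, vf):
        lines.append(f"{t:.6f},{p:.9f},{f:.9f}")
    Path(path).write_text("\n".join(lines) + "\n")
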