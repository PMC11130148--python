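"""Exposure metrics and the stimulation-threshold model.

Implements the standard acoustic-output indices for a pulsed stimulus —
mechanical index, pulse- and temporal-average intensities, soft-tissue
thermal index — plus the acoustic radiation force (ARF) body-force density
and a power-law fit of activation-threshold pressure versus frequency.

Attenuation coefficients are stored in Np·m⁻¹·MHz⁻¹; helpers convert from
the dB·cm⁻¹·MHz⁻¹ values tabulated in the tissue literature
(1 Np = 8.6859 dB, 100 cm = 1 m).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy.optimize import curve_fit

from .propagation import MediumProps, WATER

NP_TO_DB = 20.0 / np.log(10.0)  # 8.6859 dB per neper


def db_cm_to_np_m(alpha_db_cm: float) -> float:
    """Convert attenuation from dB·cm⁻¹·MHz⁻¹ to Np·m⁻¹·MHz⁻¹."""
    return alpha_db_cm * 100.0 / NP_TO_DB


def np_m_to_db_cm(alpha_np_m: float) -> float:
    return alpha_np_m * NP_TO_DB / 100.0


@dataclass(frozen=True)
class PulseParams:
    """One stimulation pulse: negative peak pressure (MPa), frequency (MHz),
    pulse duration (ms) and repetition period (s)."""

    npp: float
    f: float
    duration_ms: float = 10.0
    period_s: float = 6.0

    def __post_init__(self) -> None:
        if min(self.npp, self.f, self.duration_ms, self.period_s) <= 0:
            raise ValueError("all pulse parameters must be positive")
        if self.duty > 1.0 + 1e-12:
            raise ValueError("pulse duration exceeds the repetition period")

    @property
    def duty(self) -> float:
        """Duty cycle = pulse duration / repetition period, in (0, 1]."""
        return min(self.duration_ms * 1e-3 / self.period_s, 1.0)


@dataclass(frozen=True)
class ExposureMetrics:
    """Derived exposure indices for one pulse specification."""

    mi: float
    isppa_w_cm2: float
    ispta_mw_cm2: float
    ti: float
    power_mw: float

    def as_dict(self) -> dict[str, float]:
        return {
            "MI": self.mi,
            "I_SPPA_W_cm2": self.isppa_w_cm2,
            "I_SPTA_mW_cm2": self.ispta_mw_cm2,
            "TI": self.ti,
            "acoustic_power_mW": self.power_mw,
        }


@dataclass(frozen=True)
class ThresholdCurve:
    """Power-law fit p = a·f^b of activation threshold vs frequency."""

    freqs: NDArray[np.float64]  # MHz
    thresholds: NDArray[np.float64]  # MPa
    a: float
    b: float
    rmse: float  # MPa

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        p = np.asarray(self.thresholds, dtype=float)
        if len(f) < 2 or len(np.unique(f)) != len(f) or np.any(f <= 0):
            raise ValueError("need ≥ 2 distinct positive frequencies")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "thresholds", p)

    def predict(self, f: NDArray[np.float64] | float) -> NDArray[np.float64]:
        return self.a * np.asarray(f, dtype=float) ** self.b


def mechanical_index(pulse: PulseParams) -> float:
    """MI = NPP(MPa) / sqrt(f(MHz)) — the cavitation-risk proxy."""
    return pulse.npp / np.sqrt(pulse.f)


def intensities(pulse: PulseParams, medium: MediumProps = WATER) -> tuple[float, float]:
    """Spatial-peak intensities (I_SPPA in W/cm², I_SPTA in mW/cm²).

    I_SPPA = NPP²/(2ρc) for a sinusoidal pulse of peak pressure NPP;
    I_SPTA = I_SPPA × duty cycle.
    """
    npp_pa = pulse.npp * 1e6
    isppa_w_m2 = npp_pa**2 / (2.0 * medium.rho * medium.c)
    isppa_w_cm2 = isppa_w_m2 * 1e-4
    ispta_mw_cm2 = isppa_w_cm2 * 1e3 * pulse.duty
    return isppa_w_cm2, ispta_mw_cm2


def thermal_index(power_mw: float, ispta_mw_cm2: float, f: float) -> float:
    """Soft-tissue thermal index for a small aperture.

    TI = min(W, I_SPTA·1 cm²)·f / 210 mW·MHz: the emitted (or beam-limited)
    acoustic power scaled by frequency against the 210 mW·MHz reference power
    that would raise tissue temperature by 1 °C.
    """
    if power_mw < 0 or ispta_mw_cm2 < 0:
        raise ValueError("power and intensity must be non-negative")
    if f <= 0:
        raise ValueError("frequency must be positive")
    return min(power_mw, ispta_mw_cm2 * 1.0) * f / 210.0


def arf_force(
    p_pa: float, alpha_np_m: float, f: float, medium: MediumProps = WATER
) -> float:
    """Acoustic radiation body force F = p²·α·f/(ρ·c²) in N/m³.

    ``alpha_np_m`` is the attenuation slope in Np·m⁻¹·MHz⁻¹ so that α·f is
    the absorption at the working frequency; quadratic in pressure, linear in
    absorption — momentum transferred from the attenuated beam to the tissue.
    """
    if p_pa < 0 or alpha_np_m < 0 or f <= 0:
        raise ValueError("pressure, attenuation must be ≥ 0 and frequency > 0")
    return p_pa**2 * alpha_np_m * f / (medium.rho * medium.c**2)


def exposure_metrics(
    pulse: PulseParams,
    medium: MediumProps = WATER,
    power_mw: float | None = None,
) -> ExposureMetrics:
    """All exposure indices for one pulse.

    ``power_mw`` is the emitted acoustic power entering the thermal index;
    if omitted, the beam-limited branch I_SPTA·1 cm² is used alone (the min
    in the TI formula then always selects it).
    """
    isppa, ispta = intensities(pulse, medium)
    w = power_mw if power_mw is not None else np.inf
    ti = thermal_index(min(w, ispta), ispta, pulse.f)
    return ExposureMetrics(
        mi=mechanical_index(pulse),
        isppa_w_cm2=isppa,
        ispta_mw_cm2=ispta,
        ti=ti,
        power_mw=float(w) if np.isfinite(w) else ispta,
    )


def fit_threshold_curve(
    freqs: NDArray[np.float64],
    thresholds: NDArray[np.float64],
    model: str = "fixed",
    exponent: float = -1.0,
) -> ThresholdCurve:
    """Least-squares power-law fit of threshold pressure vs frequency.

    ``model="fixed"`` fits p = a·f^b with the exponent pinned (default
    b = −1, the inverse-proportionality model; b = −1/2 is the constant-ARF
    prediction, since ARF ∝ p²·f).  ``model="free"`` fits both a and b
    (requires ≥ 3 points).  The fit minimizes residuals in pressure units;
    RMSE is reported in MPa over the data.
    """
    f = np.asarray(freqs, dtype=float)
    p = np.asarray(thresholds, dtype=float)
    if f.ndim != 1 or f.shape != p.shape:
        raise ValueError("freqs and thresholds must be matching 1D arrays")
    if len(np.unique(f)) < 2:
        raise ValueError("all frequencies equal: singular design")
    if model == "fixed":
        basis = f**exponent
        a = float(np.dot(p, basis) / np.dot(basis, basis))
        b = float(exponent)
    elif model == "free":
        if len(f) < 3:
            raise ValueError("free-exponent fit needs ≥ 3 points")
        # log-space start, refined in pressure units
        lg = np.polyfit(np.log(f), np.log(np.maximum(p, 1e-12)), 1)
        (a, b), _ = curve_fit(
            lambda x, a, b: a * x**b, f, p, p0=[float(np.exp(lg[1])), float(lg[0])]
        )
        a, b = float(a), float(b)
    else:
        raise ValueError("model must be 'fixed' or 'free'")
    rmse = float(np.sqrt(np.mean((p - a * f**b) ** 2)))
    return ThresholdCurve(f, p, a, b, rmse)
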