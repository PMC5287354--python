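"""Contrast transfer function model, local defocus and phase flipping.

Sign convention: defocus is positive for underfocus, and

    CTF(f) = -[ sqrt(1 - w^2) sin(chi(f)) + w cos(chi(f)) ],
    chi(f) = pi lambda dz f^2 - (pi/2) Cs lambda^3 f^4,

so the CTF starts negative at low frequency and phase flipping is
multiplication of Fourier components by sign(CTF). ``lambda`` is the
relativistic electron wavelength. Astigmatism and envelope damping are not
modelled; resolution loss is carried by the simulator's noise model.

Defocus varies across a tilted specimen: a point at in-plane distance ``d``
from the tilt axis changes height by ``d * tan(tilt)``, so its local
defocus is ``nominal + d * tan(tilt)``. Phase flipping supports both a
single per-tilt defocus (the default, "global" mode) and per-strip
correction that applies this gradient across each image.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .errors import ParameterError
from .maps import TiltSeries

__all__ = [
    "CTFParams",
    "electron_wavelength",
    "ctf_value",
    "local_defocus",
    "phase_flip_tilt_series",
    "apply_ctf_to_tilt_series",
    "first_zero_frequency",
]

# physical constants (CODATA): h c / e and electron rest energy
_HC_OVER_E = 12.2639  # Å * sqrt(V), h / sqrt(2 m e)
_REL = 0.97845e-6  # e / (2 m c^2) in 1/V


@dataclasses.dataclass
class CTFParams:
    """Microscope and imaging parameters for the CTF model."""

    voltage: float = 300.0  # keV
    cs: float = 2.0  # spherical aberration, mm
    amplitude_contrast: float = 0.07  # fraction in [0, 1)
    defocus: float = 52_000.0  # Å, positive = underfocus
    pixel_size: float = 1.0  # Å

    def __post_init__(self):
        if not self.voltage > 0:
            raise ParameterError("voltage must be > 0")
        if not self.pixel_size > 0:
            raise ParameterError("pixel_size must be > 0")
        if not 0 <= self.amplitude_contrast < 1:
            raise ParameterError("amplitude_contrast must lie in [0, 1)")

    @property
    def wavelength(self) -> float:
        return electron_wavelength(self.voltage)


def electron_wavelength(voltage_kev: float) -> float:
    """Relativistic electron wavelength in Å (~0.01969 Å at 300 keV)."""
    v = voltage_kev * 1e3
    return _HC_OVER_E / math.sqrt(v * (1.0 + _REL * v))


def ctf_value(freq, params: CTFParams, defocus: float | None = None):
    """CTF at spatial frequency ``freq`` (1/Å); accepts arrays."""
    freq = np.asarray(freq, dtype=float)
    if np.any(freq < 0):
        raise ParameterError("frequency must be >= 0")
    lam = params.wavelength
    dz = params.defocus if defocus is None else defocus
    cs_A = params.cs * 1e7  # mm -> Å
    chi = math.pi * lam * dz * freq ** 2 - 0.5 * math.pi * cs_A * lam ** 3 * freq ** 4
    w = params.amplitude_contrast
    out = -(math.sqrt(1.0 - w * w) * np.sin(chi) + w * np.cos(chi))
    return out if out.ndim else float(out)


def first_zero_frequency(params: CTFParams, defocus: float | None = None) -> float:
    """First zero of the CTF in 1/Å, found numerically from the model."""
    dz = params.defocus if defocus is None else defocus
    approx = 1.0 / math.sqrt(params.wavelength * dz)
    freqs = np.linspace(1e-5, 2.5 * approx, 20_000)
    vals = ctf_value(freqs, params, defocus=dz)
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_change) == 0:
        raise ParameterError("CTF has no zero in the searched band")
    i = sign_change[0]
    f0, f1, v0, v1 = freqs[i], freqs[i + 1], vals[i], vals[i + 1]
    return float(f0 - v0 * (f1 - f0) / (v1 - v0))


def local_defocus(nominal: float, tilt_angle: float, offset_perp: float) -> float:
    """Defocus of a point ``offset_perp`` Å from the tilt axis at the given
    tilt (degrees): ``nominal + offset_perp * tan(tilt)``."""
    if not abs(tilt_angle) < 90:
        raise ParameterError("requires |tilt_angle| < 90")
    return nominal + offset_perp * math.tan(math.radians(tilt_angle))


def _tilt_defoci(ts: TiltSeries, params: CTFParams) -> np.ndarray:
    if ts.defoci is not None:
        return np.asarray(ts.defoci, dtype=float)
    if params.defocus is None:
        raise ParameterError("no defocus available for the tilt series")
    return np.full(len(ts), float(params.defocus))


def _freq_grid(nx: int, ny: int, pixel_size: float) -> np.ndarray:
    fx = np.fft.fftfreq(nx, d=pixel_size)
    fy = np.fft.rfftfreq(ny, d=pixel_size)
    return np.sqrt(fx[:, None] ** 2 + fy[None, :] ** 2)


def _apply_fourier_factor(image: np.ndarray, factor: np.ndarray) -> np.ndarray:
    spec = np.fft.rfft2(image)
    return np.fft.irfft2(spec * factor, s=image.shape).astype(np.float32)


def phase_flip_tilt_series(ts: TiltSeries, params: CTFParams, strips: bool = False,
                           strip_width: int = 32) -> TiltSeries:
    """Multiply each image's Fourier components by sign(CTF).

    Amplitudes are untouched, so flipping twice is the identity. With
    ``strips=True`` the image is corrected in bands perpendicular to the
    tilt axis, each with the local defocus of its centre (the tilt-induced
    defocus gradient); bands are reassembled without feathering.
    """
    defoci = _tilt_defoci(ts, params)
    out = ts.copy()
    nx, ny = ts.images.shape[1:]
    freq = _freq_grid(nx, ny, ts.pixel_size)
    for i in range(len(ts)):
        if not strips:
            sign = np.sign(ctf_value(freq, params, defocus=defoci[i]))
            sign[sign == 0] = 1.0
            out.images[i] = _apply_fourier_factor(ts.images[i], sign)
        else:
            corrected = np.empty_like(ts.images[i])
            for x0 in range(0, nx, strip_width):
                x1 = min(x0 + strip_width, nx)
                offset_perp = ((x0 + x1 - 1) / 2.0 - (nx - 1) / 2.0) * ts.pixel_size
                dz = local_defocus(defoci[i], ts.angles[i], offset_perp)
                sign = np.sign(ctf_value(freq, params, defocus=dz))
                sign[sign == 0] = 1.0
                corrected[x0:x1] = _apply_fourier_factor(ts.images[i], sign)[x0:x1]
            out.images[i] = corrected
    out.defoci = defoci
    return out


def apply_ctf_to_tilt_series(ts: TiltSeries, params: CTFParams) -> TiltSeries:
    """Forward model: multiply each image by its signed CTF in Fourier
    space (used to emulate defocused acquisition on synthetic data)."""
    defoci = _tilt_defoci(ts, params)
    out = ts.copy()
    nx, ny = ts.images.shape[1:]
    freq = _freq_grid(nx, ny, ts.pixel_size)
    for i in range(len(ts)):
        out.images[i] = _apply_fourier_factor(ts.images[i], ctf_value(freq, params, defocus=defoci[i]))
    out.defoci = defoci
    return out
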