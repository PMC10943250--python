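"""Off-axis interferogram synthesis and Fourier-sideband demodulation.

Digital twin of the recording arm: the two analyzer-resolved interferograms
(analyzer at 0 deg and 90 deg) mix each object-field component with the
matching component of a tilted right-circular reference beam; a single 2D FFT,
a cosine-tapered window around the carrier sideband, and an inverse FFT
recover the complex amplitudes.

Coordinate convention: row-major rasters, origin top-left, x = column index,
spatial frequencies in cycles/pixel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from polholo.polarization import CIRCULAR_JONES
from polholo.phantom import ComplexField, DEFAULT_PIXEL_PITCH

__all__ = [
    "Interferogram",
    "ReconstructedField",
    "record_interferograms",
    "fourier_demodulate",
]


@dataclass(frozen=True)
class Interferogram:
    """Single analyzer-resolved off-axis interferogram."""

    intensity: np.ndarray
    analyzer_omega: int  # 0 or 90 (degrees)
    carrier: tuple  # (u0, v0) cycles/pixel
    ref_amplitude: float
    quantize_bits: int | None = None

    def __post_init__(self):
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")
        u0, v0 = self.carrier
        if not (abs(u0) < 0.5 and abs(v0) < 0.5):
            raise ValueError("carrier must be below Nyquist")
        if self.analyzer_omega not in (0, 90):
            raise ValueError("analyzer_omega must be 0 or 90")


@dataclass(frozen=True)
class ReconstructedField(ComplexField):
    """Demodulated complex field plus a demodulation quality metric."""

    residual: float = 0.0


def _carrier_phase(shape, carrier):
    m, n = shape
    y, x = np.mgrid[0:m, 0:n]
    u0, v0 = carrier
    return 2 * np.pi * (u0 * x + v0 * y)


def _quantize(i: np.ndarray, bits: int) -> np.ndarray:
    levels = 2**bits - 1
    top = i.max()
    if top <= 0:
        return i
    return np.round(i / top * levels) / levels * top


def record_interferograms(
    field: ComplexField,
    ref_amplitude: float = 1.0,
    carrier=(0.125, 0.125),
    quantize_bits: int | None = None,
    ensemble_k: int | None = None,
):
    """Record the two analyzer-resolved off-axis interferograms of a field.

    ``I_Ω = |component_Ω(field) + ref_amplitude · e^{i2π(u0·x + v0·y)} ·
    component_Ω(circular reference)|²`` for Ω in {0°, 90°}; optional CCD-style
    quantization (8 bit by default on real cameras).

    A depolarized background carried by the field (``bg_ux``/``bg_uy``) is
    mutually incoherent with the reference: its interference terms average
    out over the recording ensemble and only its intensity is added.
    ``ensemble_k=None`` takes the exact infinite-ensemble limit; a finite K
    emulates averaging K phase-randomized exposures (residual cross-talk
    ~1/sqrt(K)).
    """
    if ref_amplitude <= 0:
        raise ValueError("ref_amplitude must be > 0")
    u0, v0 = carrier
    if not (abs(u0) < 0.5 and abs(v0) < 0.5):
        raise ValueError("carrier at/above Nyquist")
    phase = np.exp(1j * _carrier_phase(field.shape, carrier))
    rng = np.random.default_rng(0xB0) if ensemble_k else None
    pair = []
    for omega, comp, bg, ref_c in (
        (0, field.ux, field.bg_ux, CIRCULAR_JONES[0]),
        (90, field.uy, field.bg_uy, CIRCULAR_JONES[1]),
    ):
        coherent = comp + ref_amplitude * ref_c * phase
        if bg is None:
            i = np.abs(coherent) ** 2
        elif ensemble_k is None:
            i = np.abs(coherent) ** 2 + np.abs(bg) ** 2
        else:
            thetas = rng.uniform(0, 2 * np.pi, size=ensemble_k)
            i = np.mean(
                [np.abs(coherent + bg * np.exp(1j * t)) ** 2 for t in thetas], axis=0
            )
        if quantize_bits is not None:
            i = _quantize(i, quantize_bits)
        pair.append(
            Interferogram(
                intensity=i,
                analyzer_omega=omega,
                carrier=(u0, v0),
                ref_amplitude=ref_amplitude,
                quantize_bits=quantize_bits,
            )
        )
    return tuple(pair)


def _sideband_window(shape, carrier, radius):
    m, n = shape
    fu = np.fft.fftfreq(n)[None, :]
    fv = np.fft.fftfreq(m)[:, None]
    u0, v0 = carrier
    # select the sideband at -carrier, which carries obj * conj(ref)

    def dist(du, dv):
        # wrap-aware frequency distance
        du = (du + 0.5) % 1.0 - 0.5
        dv = (dv + 0.5) % 1.0 - 0.5
        return np.hypot(du, dv)

    r = dist(fu + u0, fv + v0)
    w = np.where(r < radius, 0.5 * (1 + np.cos(np.pi * r / radius)), 0.0)
    return w


def fourier_demodulate(
    interferograms,
    carrier=None,
    filter_radius: float | None = None,
    fix_gauge: bool = False,
    pixel_pitch: float | None = None,
) -> ReconstructedField:
    """Recover the complex field from the analyzer-resolved interferogram pair.

    2D FFT → cosine-tapered circular window on the sideband at −carrier →
    inverse FFT → carrier removal and division by the known reference
    component.  The Ω=0° channel yields ``ux``; the Ω=90° channel yields
    ``uy`` with the inter-component phase preserved relative to ``ux``.

    With ``fix_gauge=True`` the (physically arbitrary) global phase is fixed
    by zeroing the spatial median phase of the ``ux`` channel; by default the
    digital reference phase is known so the field is recovered absolutely.
    """
    by_omega = {ig.analyzer_omega: ig for ig in interferograms}
    if set(by_omega) != {0, 90}:
        raise ValueError("need one 0-deg and one 90-deg interferogram")
    ig0 = by_omega[0]
    carrier = tuple(carrier) if carrier is not None else ig0.carrier
    cmag = float(np.hypot(*carrier))
    if filter_radius is None:
        filter_radius = cmag / 2.0
    if filter_radius >= cmag:
        warnings.warn("sideband window reaches DC; reconstruction degraded", stacklevel=2)
    shape = ig0.intensity.shape
    window = _sideband_window(shape, carrier, filter_radius)
    phase = np.exp(1j * _carrier_phase(shape, carrier))
    comps = {}
    for omega, ref_c in ((0, CIRCULAR_JONES[0]), (90, CIRCULAR_JONES[1])):
        ig = by_omega[omega]
        f = np.fft.fft2(ig.intensity)
        side = np.fft.ifft2(f * window)
        comps[omega] = side * phase / (ig.ref_amplitude * np.conj(ref_c))
    ux, uy = comps[0], comps[90]
    if fix_gauge:
        mag = np.abs(ux)
        sel = mag > 0.1 * np.sqrt(np.mean(mag**2))
        if sel.any():
            g = np.exp(-1j * np.median(np.angle(ux[sel])))
            ux = ux * g
            uy = uy * g
    # residual: normalized RMS mismatch between the recorded 0-deg pattern and
    # its re-synthesis from the recovered field
    resynth = np.abs(ux + ig0.ref_amplitude * CIRCULAR_JONES[0] * phase) ** 2
    residual = float(
        np.sqrt(np.mean((resynth - ig0.intensity) ** 2)) / (np.mean(ig0.intensity) + 1e-300)
    )
    return ReconstructedField(
        ux=ux,
        uy=uy,
        pixel_pitch=pixel_pitch if pixel_pitch is not None else DEFAULT_PIXEL_PITCH,
        residual=residual,
    )
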