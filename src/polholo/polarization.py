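"""Stokes/Mueller/Jones algebra for linear-birefringence (LB) elements.

Conventions
-----------
* Stokes components ``(s1, s2, s3, s4)`` = (intensity, horizontal/vertical
  balance, +45/−45 balance, circular balance).  From complex amplitudes
  ``(ux, uy)``: ``s1=|ux|²+|uy|²``, ``s2=|ux|²−|uy|²``, ``s3=2·Re(ux*·uy)``,
  ``s4=2·Im(ux*·uy)``.  Right circular light is ``(1, 0, 0, 1)``.
* Azimuth ``alpha`` ∈ [−π/2, π/2) is measured from the laboratory x axis,
  resolved with the two-argument arctangent; ellipticity ``beta`` ∈
  [−π/4, π/4].
* An LB element is parametrized by its optical-axis orientation ``rho``
  (reduced mod π) and retardance ``delta = 2π·Δn·d/λ`` ≥ 0.

The Mueller matrix is the declared ground truth; the Jones layer exists so
coherent fields can be cascaded, and the two are tied together by a
conversion-equivalence test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StokesVector",
    "PolarizationState",
    "LBMuellerMatrix",
    "LBJonesMatrix",
    "CIRCULAR_STOKES",
    "CIRCULAR_JONES",
    "lb_mueller",
    "lb_jones",
    "jones_to_mueller",
    "apply_mueller",
    "stokes_from_amplitudes",
    "stokes_to_polarization",
    "amplitudes_to_polarization",
    "interference_polarization",
]

#: tolerance below which |s2|,|s3| (relative to s1) flag the azimuth undefined
_CIRCULAR_TOL = 1e-12


@dataclass(frozen=True)
class StokesVector:
    """Four-component polarization state at a point."""

    s1: float
    s2: float
    s3: float
    s4: float

    def as_array(self) -> np.ndarray:
        return np.array([self.s1, self.s2, self.s3, self.s4], dtype=float)

    @staticmethod
    def from_array(v: np.ndarray) -> "StokesVector":
        v = np.asarray(v, dtype=float)
        if v.shape != (4,):
            raise ValueError(f"Stokes vector must have 4 components, got {v.shape}")
        return StokesVector(*v)

    @property
    def degree_of_polarization(self) -> float:
        return float(np.hypot(np.hypot(self.s2, self.s3), self.s4) / self.s1)

    def normalized(self) -> "StokesVector":
        if not self.s1 > 0:
            raise ValueError("cannot normalize a Stokes vector with s1 <= 0")
        return StokesVector(1.0, self.s2 / self.s1, self.s3 / self.s1, self.s4 / self.s1)


@dataclass(frozen=True)
class PolarizationState:
    """Polarization-ellipse parameters at a point.

    ``alpha`` is the major-axis azimuth in [−π/2, π/2); ``beta`` the
    ellipticity angle in [−π/4, π/4].  For (near-)circular states the azimuth
    is geometrically undefined; ``alpha_defined`` is then False and ``alpha``
    is the reproducible reference value 0.
    """

    alpha: float
    beta: float
    alpha_defined: bool = True


@dataclass(frozen=True)
class LBMuellerMatrix:
    """4×4 Mueller matrix of a linear-birefringence element."""

    rho: float
    delta: float
    elements: np.ndarray = field(repr=False)

    def __matmul__(self, other):
        if isinstance(other, LBMuellerMatrix):
            return self.elements @ other.elements
        return self.elements @ np.asarray(other)


@dataclass(frozen=True)
class LBJonesMatrix:
    """2×2 complex Jones matrix of the same (rho, delta) element."""

    rho: float
    delta: float
    elements: np.ndarray = field(repr=False)


#: Stokes vector of the right-circular illumination beam.
CIRCULAR_STOKES = StokesVector(1.0, 0.0, 0.0, 1.0)

#: Jones vector of the right-circular illumination beam (unit intensity).
CIRCULAR_JONES = np.array([1.0, 1.0j]) / np.sqrt(2.0)


def _check_finite(name: str, *values) -> None:
    for v in values:
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{name}: non-finite input")


def lb_mueller(rho: float, delta: float) -> LBMuellerMatrix:
    """Mueller matrix of a linear retarder with axis at ``rho``, retardance ``delta``.

    Equals the rotation–retarder composition on the Poincaré sphere; acting on
    right-circular light it produces ``(1, sin2ρ·sinδ, cos2ρ·sinδ, cosδ)``.

    Parameters may be scalars or broadcastable arrays; for array input the
    ``elements`` attribute gains trailing axes.
    """
    _check_finite("lb_mueller", rho, delta)
    rho = np.mod(rho, np.pi)
    if np.any(np.asarray(delta) < 0):
        raise ValueError("lb_mueller: delta must be >= 0")
    c = np.cos(2 * rho)
    s = np.sin(2 * rho)
    cd = np.cos(delta)
    sd = np.sin(delta)
    one = np.ones(np.broadcast(c, cd).shape)
    zero = np.zeros_like(one)
    m = np.array(
        [
            [one, zero, zero, zero],
            [zero, c * c + s * s * cd, -c * s * (1 - cd), s * sd],
            [zero, -c * s * (1 - cd), s * s + c * c * cd, c * sd],
            [zero, -s * sd, -c * sd, cd * one],
        ]
    )
    return LBMuellerMatrix(rho=float(np.mean(rho)), delta=float(np.mean(delta)), elements=m)


def _rot2(phi: float) -> np.ndarray:
    c, s = np.cos(phi), np.sin(phi)
    return np.array([[c, -s], [s, c]])


def lb_jones(rho: float, delta: float) -> LBJonesMatrix:
    """Jones matrix of the same LB element, ``R(−ρ)·diag(e^{iδ/2}, e^{−iδ/2})·R(ρ)``.

    The phase split is symmetric so the matrix is unitary with det 1; the
    handedness is chosen so the induced Mueller matrix equals
    :func:`lb_mueller` element-wise.
    """
    _check_finite("lb_jones", rho, delta)
    if delta < 0:
        raise ValueError("lb_jones: delta must be >= 0")
    d = np.diag([np.exp(1j * delta / 2), np.exp(-1j * delta / 2)])
    j = _rot2(-rho) @ d @ _rot2(rho)
    return LBJonesMatrix(rho=float(np.mod(rho, np.pi)), delta=float(delta), elements=j)


# Pauli-like basis ordered to match (s1, s2, s3, s4).
_SIGMA = np.array(
    [
        [[1, 0], [0, 1]],
        [[1, 0], [0, -1]],
        [[0, 1], [1, 0]],
        [[0, -1j], [1j, 0]],
    ]
)


def jones_to_mueller(j: LBJonesMatrix | np.ndarray) -> np.ndarray:
    """Convert a 2×2 Jones matrix to its 4×4 Mueller matrix.

    Uses ``M_ij = Tr(σ_i · J · σ_j · J†) / 2`` in the package's Stokes basis.
    """
    jm = j.elements if isinstance(j, LBJonesMatrix) else np.asarray(j)
    jd = jm.conj().T
    m = np.empty((4, 4))
    for a in range(4):
        for b in range(4):
            m[a, b] = 0.5 * np.real(np.trace(_SIGMA[a] @ jm @ _SIGMA[b] @ jd))
    return m


def apply_mueller(m: LBMuellerMatrix | np.ndarray, s: StokesVector | np.ndarray) -> StokesVector:
    """Matrix–vector product ``M·S`` (Eq.-(3)-style single interaction)."""
    mm = m.elements if isinstance(m, LBMuellerMatrix) else np.asarray(m)
    sv = s.as_array() if isinstance(s, StokesVector) else np.asarray(s, dtype=float)
    if mm.shape != (4, 4) or sv.shape != (4,):
        raise ValueError(f"shape mismatch: M {mm.shape}, S {sv.shape}")
    return StokesVector.from_array(mm @ sv)


def stokes_from_amplitudes(ux: complex, uy: complex) -> StokesVector:
    """Stokes vector of the coherent field with orthogonal amplitudes (ux, uy)."""
    ux = complex(ux)
    uy = complex(uy)
    z = np.conj(ux) * uy
    return StokesVector(
        abs(ux) ** 2 + abs(uy) ** 2,
        abs(ux) ** 2 - abs(uy) ** 2,
        2 * z.real,
        2 * z.imag,
    )


def stokes_to_polarization(s: StokesVector) -> PolarizationState:
    """Azimuth/ellipticity of a Stokes vector.

    ``alpha = 0.5·atan2(s3, s2)`` (two-argument form; the single-argument
    arctan is ambiguous by π/2), ``beta = 0.5·arcsin(s4/s1)`` with the ratio
    clamped to [−1, 1].  When ``s2 = s3 = 0`` the azimuth is undefined and the
    state is returned flagged with ``alpha = 0``.
    """
    if not s.s1 > 0:
        raise ValueError("stokes_to_polarization: s1 must be > 0")
    beta = 0.5 * np.arcsin(np.clip(s.s4 / s.s1, -1.0, 1.0))
    if np.hypot(s.s2, s.s3) <= _CIRCULAR_TOL * s.s1:
        return PolarizationState(alpha=0.0, beta=float(beta), alpha_defined=False)
    alpha = 0.5 * np.arctan2(s.s3, s.s2)
    if alpha >= np.pi / 2:  # fold the closed endpoint of atan2's range
        alpha -= np.pi
    return PolarizationState(alpha=float(alpha), beta=float(beta))


def amplitudes_to_polarization(ux: complex, uy: complex) -> PolarizationState:
    """Azimuth/ellipticity straight from complex amplitudes.

    Direct amplitude forms:
    ``alpha = 0.5·atan2(ux·uy* + ux*·uy, ux·ux* − uy·uy*)`` and
    ``beta  = 0.5·arcsin(i·(ux·uy* − ux*·uy) / (ux·ux* + uy·uy*))``.
    Agrees with :func:`stokes_to_polarization` of the induced Stokes vector.
    """
    ux = complex(ux)
    uy = complex(uy)
    intensity = abs(ux) ** 2 + abs(uy) ** 2
    if intensity == 0:
        raise ValueError("amplitudes_to_polarization: ux and uy are both zero")
    num_a = (ux * np.conj(uy) + np.conj(ux) * uy).real
    den_a = abs(ux) ** 2 - abs(uy) ** 2
    num_b = (1j * (ux * np.conj(uy) - np.conj(ux) * uy)).real
    beta = 0.5 * np.arcsin(np.clip(num_b / intensity, -1.0, 1.0))
    if np.hypot(num_a, den_a) <= _CIRCULAR_TOL * intensity:
        return PolarizationState(alpha=0.0, beta=float(beta), alpha_defined=False)
    alpha = 0.5 * np.arctan2(num_a, den_a)
    if alpha >= np.pi / 2:
        alpha -= np.pi
    return PolarizationState(alpha=float(alpha), beta=float(beta))


def interference_polarization(ux_mag: float, uy_mag: float, delta_xy: float) -> PolarizationState:
    """Polarization of the wave formed by two phase-shifted orthogonal components.

    Canonical amplitude path: identical to
    ``amplitudes_to_polarization(ux_mag, uy_mag·e^{i·delta_xy})``.
    """
    if ux_mag < 0 or uy_mag < 0:
        raise ValueError("interference_polarization: magnitudes must be >= 0")
    return amplitudes_to_polarization(ux_mag, uy_mag * np.exp(1j * delta_xy))


def polarization_maps_from_field(ux: np.ndarray, uy: np.ndarray):
    """Vectorized azimuth/ellipticity maps from amplitude rasters.

    Returns ``(alpha, beta, defined)`` arrays; ``defined`` is False where the
    state is circular/degenerate (azimuth set to 0 there).
    """
    ux = np.asarray(ux, dtype=complex)
    uy = np.asarray(uy, dtype=complex)
    z = np.conj(ux) * uy
    s1 = np.abs(ux) ** 2 + np.abs(uy) ** 2
    s2 = np.abs(ux) ** 2 - np.abs(uy) ** 2
    s3 = 2 * z.real
    s4 = 2 * z.imag
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = 0.5 * np.arcsin(np.clip(np.where(s1 > 0, s4 / np.where(s1 > 0, s1, 1.0), 0.0), -1, 1))
    defined = np.hypot(s2, s3) > _CIRCULAR_TOL * np.maximum(s1, 1e-300)
    alpha = np.where(defined, 0.5 * np.arctan2(s3, s2), 0.0)
    alpha = np.where(alpha >= np.pi / 2, alpha - np.pi, alpha)
    return alpha, beta, defined & (s1 > 0)
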