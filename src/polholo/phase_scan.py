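"""Phase scanning of the reconstructed field and single-scattering detection.

The inter-component phase ``arg(uy · conj(ux))`` (wrapped to [0, 2π)) is
scanned with a cumulative bound δt: each phase section keeps the pixels whose
phase lies at or below the bound, the azimuth/ellipticity maps are evaluated
on that mask, and first- to fourth-order moments are tracked along the scan.
The single-scattering plane δt* is the end of the initial plateau over which
all moments stay constant within a relative tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from polholo.phantom import ComplexField
from polholo.polarization import polarization_maps_from_field

__all__ = [
    "PolarizationMap",
    "MomentSet",
    "PhaseScanResult",
    "EmptySectionError",
    "PlateauNotFoundError",
    "inter_component_phase",
    "section_map",
    "moments",
    "phase_scan",
    "find_single_scatter_plane",
]

DEFAULT_DSTEP = np.pi / 40


class EmptySectionError(ValueError):
    """Raised when a phase section contains no valid pixels."""


class PlateauNotFoundError(LookupError):
    """Raised when no initial moment plateau of at least two steps exists."""


@dataclass(frozen=True)
class PolarizationMap:
    """Azimuth/ellipticity rasters with the validity mask of one phase section."""

    alpha_map: np.ndarray
    beta_map: np.ndarray
    mask: np.ndarray
    delta_t: float

    def __post_init__(self):
        if not (self.alpha_map.shape == self.beta_map.shape == self.mask.shape):
            raise ValueError("map shapes differ")


@dataclass(frozen=True)
class MomentSet:
    """First- to fourth-order moments of a masked sample.

    ``paper`` mode is the literal printed form: Z1 = mean, Z2 = mean of
    squares, Z3 = mean of cubes / Z2³, Z4 = mean of fourth powers / Z2⁴.
    ``standard`` mode is the textbook central form: mean, variance,
    skewness m3/σ³, kurtosis m4/σ⁴.
    """

    z1: float
    z2: float
    z3: float
    z4: float
    mode: str = "paper"
    higher_defined: bool = True

    def as_tuple(self):
        return (self.z1, self.z2, self.z3, self.z4)


def moments(values: np.ndarray, mode: str = "paper") -> MomentSet:
    """Statistical moments Z1..Z4 of a 1D sample (masked raster values)."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 values")
    if mode == "paper":
        z1 = float(np.mean(v))
        z2 = float(np.mean(v**2))
        if z2 == 0:
            return MomentSet(z1, z2, float("nan"), float("nan"), mode, False)
        z3 = float(np.mean(v**3) / z2**3)
        z4 = float(np.mean(v**4) / z2**4)
        return MomentSet(z1, z2, z3, z4, mode)
    if mode == "standard":
        z1 = float(np.mean(v))
        c = v - z1
        z2 = float(np.mean(c**2))
        if z2 == 0:
            return MomentSet(z1, z2, float("nan"), float("nan"), mode, False)
        sd = np.sqrt(z2)
        z3 = float(np.mean(c**3) / sd**3)
        z4 = float(np.mean(c**4) / sd**4)
        return MomentSet(z1, z2, z3, z4, mode)
    raise ValueError(f"unknown mode {mode!r}")


def inter_component_phase(field: ComplexField, amp_tol: float = 1e-3):
    """Per-pixel phase of uy relative to ux, wrapped to [0, 2π).

    Returns ``(phase, valid)``; pixels where either component magnitude is
    below ``amp_tol`` times the RMS amplitude are flagged invalid.
    """
    ax = np.abs(field.ux)
    ay = np.abs(field.uy)
    rms = np.sqrt(np.mean(ax**2 + ay**2) / 2)
    if rms == 0:
        raise ValueError("all-zero field")
    phase = np.mod(np.angle(field.uy * np.conj(field.ux)), 2 * np.pi)
    valid = (ax > amp_tol * rms) & (ay > amp_tol * rms)
    return phase, valid


def section_map(field: ComplexField, delta_t: float) -> PolarizationMap:
    """Polarization map of the cumulative phase section ``phase <= delta_t``."""
    if not (0 < delta_t <= 2 * np.pi + 1e-12):
        raise ValueError("delta_t must be in (0, 2*pi]")
    phase, valid = inter_component_phase(field)
    mask = valid & (phase <= delta_t)
    if not mask.any():
        raise EmptySectionError(f"no pixels with inter-component phase <= {delta_t:.4f}")
    alpha, beta, defined = polarization_maps_from_field(field.ux, field.uy)
    return PolarizationMap(alpha_map=alpha, beta_map=beta, mask=mask & defined, delta_t=float(delta_t))


@dataclass(frozen=True)
class PhaseScanResult:
    """Moment trajectories along the cumulative phase scan."""

    delta_t_grid: np.ndarray
    alpha_moments: tuple  # MomentSet | None per step
    beta_moments: tuple
    counts: np.ndarray
    mode: str
    min_count: int
    delta_t_star: float | None = None


def phase_scan(
    field: ComplexField,
    dstep: float = DEFAULT_DSTEP,
    mode: str = "paper",
    min_count: int = 16,
) -> PhaseScanResult:
    """Stepwise cumulative phase scan with per-section moments of alpha and beta.

    Steps whose mask holds fewer than ``min_count`` pixels record no moments
    (the scan "has not started" there).
    """
    if not (0 < dstep <= np.pi):
        raise ValueError("dstep must be in (0, pi]")
    phase, valid = inter_component_phase(field)
    alpha, beta, defined = polarization_maps_from_field(field.ux, field.uy)
    usable = valid & defined
    grid = np.arange(dstep, 2 * np.pi + dstep / 2, dstep)
    grid = grid[grid <= 2 * np.pi + 1e-12]
    a_moms, b_moms, counts = [], [], []
    for dt in grid:
        mask = usable & (phase <= dt)
        n = int(mask.sum())
        counts.append(n)
        if n < max(min_count, 2):
            a_moms.append(None)
            b_moms.append(None)
        else:
            a_moms.append(moments(alpha[mask], mode))
            b_moms.append(moments(beta[mask], mode))
    return PhaseScanResult(
        delta_t_grid=grid,
        alpha_moments=tuple(a_moms),
        beta_moments=tuple(b_moms),
        counts=np.array(counts),
        mode=mode,
        min_count=min_count,
    )


def _rel_changes(prev: MomentSet, cur: MomentSet, floor: float = 1e-3):
    out = []
    for p, c in zip(prev.as_tuple(), cur.as_tuple()):
        if not (np.isfinite(p) and np.isfinite(c)):
            continue
        out.append(abs(c - p) / max(abs(p), floor))
    return out


def find_single_scatter_plane(
    scan: PhaseScanResult,
    rel_tol: float = 0.05,
    cap: float | None = None,
) -> float:
    """Detect the single-scattering plateau bound δt*.

    Returns the largest grid δt such that every moment (Z1..Z4, alpha and
    beta) changes by at most ``rel_tol`` between all consecutive populated
    steps at or below δt.  With ``cap`` set, the result is clipped to the cap
    (the π/8 working-plane flag).  Raises :class:`PlateauNotFoundError` when
    no plateau of at least two steps exists.
    """
    if len(scan.delta_t_grid) < 3:
        raise ValueError("need at least 3 grid steps")
    idx = [i for i, m in enumerate(scan.alpha_moments) if m is not None]
    if len(idx) < 2:
        raise PlateauNotFoundError("fewer than two populated scan steps")
    last_ok = idx[0]
    ok_steps = 1
    for prev_i, cur_i in zip(idx[:-1], idx[1:]):
        changes = _rel_changes(scan.alpha_moments[prev_i], scan.alpha_moments[cur_i]) + _rel_changes(
            scan.beta_moments[prev_i], scan.beta_moments[cur_i]
        )
        if changes and max(changes) <= rel_tol:
            last_ok = cur_i
            ok_steps += 1
        else:
            break
    if ok_steps < 2:
        raise PlateauNotFoundError("moments drift from the first step on")
    dt_star = float(scan.delta_t_grid[last_ok])
    if cap is not None:
        dt_star = min(dt_star, float(cap))
    return dt_star
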