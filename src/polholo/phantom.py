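"""Synthetic birefringent fibrillar phantoms and their coherent object fields.

A phantom is built from per-pixel optical-axis orientation (``rho``) and
retardance (``delta``) rasters.  Elongated fibril strokes with preset-specific
widths and orientation concentration are drawn over a weak parenchymal floor.
The coherent object field under right-circular illumination is obtained by a
per-pixel Jones cascade over one or more (laterally decorrelated) layers, and
a calibrated spatially depolarized speckle background can be mixed in.

Every stochastic operation takes an explicit integer seed; identical seeds
produce bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter, maximum_filter
from scipy.optimize import brentq

from polholo.polarization import CIRCULAR_JONES, polarization_maps_from_field

__all__ = [
    "FibrilLayer",
    "ScatteringStack",
    "PhantomPreset",
    "ComplexField",
    "PhantomBundle",
    "PRESETS",
    "DEFAULT_PIXEL_PITCH",
    "generate_fibril_layer",
    "layer_jones_components",
    "cascade_field",
    "single_scatter_truth",
    "add_depolarized_background",
    "measure_depolarization",
    "estimate_fibril_width",
    "estimate_orientation_order",
    "generate_phantom",
    "BimodalPhantom",
    "generate_bimodal_phantom",
]

#: CCD pixel 4.65 um / 4x objective magnification.
DEFAULT_PIXEL_PITCH = 4.65 / 4.0


@dataclass(frozen=True)
class FibrilLayer:
    """Per-pixel optical-axis orientation and retardance maps for one layer."""

    rho_map: np.ndarray
    delta_map: np.ndarray
    pixel_pitch: float = DEFAULT_PIXEL_PITCH

    def __post_init__(self):
        if self.rho_map.shape != self.delta_map.shape:
            raise ValueError("rho_map and delta_map shapes differ")
        if not np.all(np.isfinite(self.delta_map)) or np.any(self.delta_map < 0):
            raise ValueError("delta_map must be finite and >= 0")

    @property
    def shape(self):
        return self.rho_map.shape


@dataclass(frozen=True)
class ScatteringStack:
    """Ordered sequence of layers traversed by the beam.

    ``layer_shift`` is the lateral decorrelation offset (pixels) applied
    cumulatively: layer j is rolled by ``j * layer_shift`` columns.
    """

    layers: tuple
    layer_shift: int = 0

    def __post_init__(self):
        if len(self.layers) < 1:
            raise ValueError("stack needs at least one layer")
        shapes = {l.shape for l in self.layers}
        if len(shapes) != 1:
            raise ValueError("all layers must share one shape")


@dataclass(frozen=True)
class PhantomPreset:
    """Morphology/optics parameters for one specimen group."""

    name: str
    fibril_width_um: tuple  # (low, high)
    orientation_kappa: float  # von Mises concentration of stroke orientations
    orientation_mu: float  # mean stroke orientation, radians in [0, pi)
    delta_peak: float  # retardance at stroke core, radians
    n_fibrils: int
    n_layers: int
    depol_degree: float  # target depolarization fraction of the object field
    delta_floor: float = 0.1  # parenchymal background retardance

    def __post_init__(self):
        if not (self.fibril_width_um[0] > 0 and self.fibril_width_um[1] >= self.fibril_width_um[0]):
            raise ValueError("fibril widths must be positive and ordered")
        if not (0 <= self.depol_degree < 1):
            raise ValueError("depol_degree must be in [0, 1)")


# Width/kappa from observed morphology (ACI 15-20 um ordered, CHD ~10 um
# disordered, PF 5-10 um, BA weak parenchyma); delta peaks are declared
# modeling assumptions, config-exposed.  Depolarization midpoints: 0.50
# myocardium, 0.57 lung.
PRESETS = {
    "myocardium_chd": PhantomPreset(
        "myocardium_chd", (8.5, 11.5), 1.0, np.pi / 3, 0.75, 30, 3, 0.50
    ),
    "myocardium_aci": PhantomPreset(
        "myocardium_aci", (15.0, 20.0), 8.0, np.pi / 3, 0.9, 14, 3, 0.50
    ),
    "lung_ba": PhantomPreset("lung_ba", (5.0, 10.0), 3.0, np.pi / 3, 0.1, 0, 3, 0.57),
    "lung_pf": PhantomPreset("lung_pf", (5.0, 10.0), 3.0, np.pi / 3, 0.8, 30, 3, 0.57),
}


@dataclass(frozen=True)
class ComplexField:
    """Two co-registered rasters of orthogonal complex amplitudes.

    ``bg_ux``/``bg_uy``, when set, hold a second component that is mutually
    incoherent with the main one (and with any holographic reference): the
    depolarized multiple-scattering background.  Incoherent light adds in
    intensity/Stokes, not in amplitude, so it is carried separately.
    """

    ux: np.ndarray
    uy: np.ndarray
    pixel_pitch: float = DEFAULT_PIXEL_PITCH
    bg_ux: np.ndarray | None = None
    bg_uy: np.ndarray | None = None

    def __post_init__(self):
        if self.ux.shape != self.uy.shape:
            raise ValueError("ux and uy shapes differ")
        if not (np.all(np.isfinite(self.ux)) and np.all(np.isfinite(self.uy))):
            raise ValueError("field must be finite")
        if (self.bg_ux is None) != (self.bg_uy is None):
            raise ValueError("bg_ux and bg_uy must be set together")
        if self.bg_ux is not None and self.bg_ux.shape != self.ux.shape:
            raise ValueError("background shape differs from field shape")

    @property
    def shape(self):
        return self.ux.shape

    @property
    def has_background(self) -> bool:
        return self.bg_ux is not None

    @property
    def intensity(self) -> np.ndarray:
        i = np.abs(self.ux) ** 2 + np.abs(self.uy) ** 2
        if self.bg_ux is not None:
            i = i + np.abs(self.bg_ux) ** 2 + np.abs(self.bg_uy) ** 2
        return i

    def stokes_components(self):
        """Pointwise Stokes rasters of the (incoherent) mixture."""
        z = np.conj(self.ux) * self.uy
        s1 = np.abs(self.ux) ** 2 + np.abs(self.uy) ** 2
        s2 = np.abs(self.ux) ** 2 - np.abs(self.uy) ** 2
        s3, s4 = 2 * z.real, 2 * z.imag
        if self.bg_ux is not None:
            zb = np.conj(self.bg_ux) * self.bg_uy
            s1 = s1 + np.abs(self.bg_ux) ** 2 + np.abs(self.bg_uy) ** 2
            s2 = s2 + np.abs(self.bg_ux) ** 2 - np.abs(self.bg_uy) ** 2
            s3, s4 = s3 + 2 * zb.real, s4 + 2 * zb.imag
        return s1, s2, s3, s4


def _smooth_unit_field(shape, rng, sigma):
    """Smooth random raster rescaled to (0, 1)."""
    g = gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    lo, hi = g.min(), g.max()
    return (g - lo) / (hi - lo + 1e-30)


def _smooth_uniform_field(shape, rng, sigma):
    """Smooth random raster with ~uniform(0, 1) marginal (Gaussian CDF map)."""
    from scipy.special import erf

    g = gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    g = (g - g.mean()) / (g.std() + 1e-30)
    return 0.5 * (1.0 + erf(g / np.sqrt(2.0)))


def _draw_stroke(rho_map, delta_map, theta, width_px, length_px, center, delta_peak):
    """Rasterize one elongated fibril stroke.

    The retardance profile is flat over the inner 70% of the width and rolls
    off with a half-cosine to zero at the nominal edge, so threshold-based
    width estimates recover approximately the programmed width.
    """
    m, n = rho_map.shape
    half = length_px / 2.0
    d = np.array([np.cos(theta), np.sin(theta)])  # (dy, dx) along the stroke
    p0 = np.asarray(center) - half * d
    p1 = np.asarray(center) + half * d
    pad = width_px / 2.0 + 1.5
    r0 = int(max(0, np.floor(min(p0[0], p1[0]) - pad)))
    r1 = int(min(m, np.ceil(max(p0[0], p1[0]) + pad) + 1))
    c0 = int(max(0, np.floor(min(p0[1], p1[1]) - pad)))
    c1 = int(min(n, np.ceil(max(p0[1], p1[1]) + pad) + 1))
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    rel_y = yy - p0[0]
    rel_x = xx - p0[1]
    t = np.clip((rel_y * d[0] + rel_x * d[1]) / (2 * half + 1e-30), 0.0, 1.0)
    proj_y = p0[0] + t * (p1[0] - p0[0])
    proj_x = p0[1] + t * (p1[1] - p0[1])
    dist = np.hypot(yy - proj_y, xx - proj_x)
    w2 = width_px / 2.0
    core = 0.85 * w2
    profile = np.where(
        dist <= core,
        1.0,
        np.where(dist <= w2, 0.5 * (1 + np.cos(np.pi * (dist - core) / (w2 - core + 1e-30))), 0.0),
    )
    val = delta_peak * profile
    sub_d = delta_map[r0:r1, c0:c1]
    sub_r = rho_map[r0:r1, c0:c1]
    takeover = val > sub_d
    sub_r[takeover] = theta % np.pi
    np.maximum(sub_d, val, out=sub_d)


def generate_fibril_layer(
    preset: PhantomPreset,
    seed: int,
    shape=(256, 256),
    pixel_pitch: float = DEFAULT_PIXEL_PITCH,
    background_sigma: float = 8.0,
    map_smooth_sigma: float = 1.0,
) -> FibrilLayer:
    """Generate one seeded fibrillar layer for a preset.

    Stroke orientations are drawn from a von Mises distribution on the
    doubled angle (concentration ``orientation_kappa``) halved back to
    [0, pi); widths are uniform over the preset's micron range, converted by
    ``pixel_pitch``.  The background is a smooth orientation field over a
    retardance floor, and the final maps are lightly smoothed
    (``map_smooth_sigma`` pixels; the orientation raster through its doubled-
    angle order parameter) so the optical maps stay within the holographic
    sideband bandwidth.
    """
    if shape[0] <= 0 or shape[1] <= 0 or pixel_pitch <= 0:
        raise ValueError("non-positive dimensions")
    rng = np.random.default_rng(seed)
    m, n = shape
    rho = np.pi * _smooth_unit_field(shape, rng, background_sigma)
    floor_mod = 0.8 + 0.4 * _smooth_unit_field(shape, rng, background_sigma)
    delta = preset.delta_floor * floor_mod
    min_dim = min(m, n)
    for _ in range(preset.n_fibrils):
        theta = 0.5 * rng.vonmises(2 * preset.orientation_mu, preset.orientation_kappa)
        width_px = rng.uniform(*preset.fibril_width_um) / pixel_pitch
        length_px = rng.uniform(0.3, 0.8) * min_dim
        center = rng.uniform(0, m), rng.uniform(0, n)
        _draw_stroke(rho, delta, theta % np.pi, width_px, length_px, center, preset.delta_peak)
    if map_smooth_sigma > 0:
        delta = gaussian_filter(delta, map_smooth_sigma, mode="wrap")
        rho = np.mod(
            0.5 * np.angle(gaussian_filter(np.exp(2j * rho), map_smooth_sigma, mode="wrap")),
            np.pi,
        )
    return FibrilLayer(rho_map=rho, delta_map=delta, pixel_pitch=pixel_pitch)


def layer_jones_components(layer: FibrilLayer):
    """Per-pixel Jones-matrix entries of a layer (closed form of the LB element)."""
    rho = layer.rho_map
    delta = layer.delta_map
    c2 = np.cos(2 * rho)
    s2 = np.sin(2 * rho)
    ch = np.cos(delta / 2)
    sh = np.sin(delta / 2)
    jxx = ch + 1j * sh * c2
    jxy = -1j * sh * s2
    jyy = ch - 1j * sh * c2
    return jxx, jxy, jyy


def cascade_field(stack: ScatteringStack, illumination=CIRCULAR_JONES) -> ComplexField:
    """Coherent field after the ordered per-pixel Jones cascade of a stack.

    Layer ``j`` (0-based) is laterally rolled by ``j * layer_shift`` columns
    before application; for a single layer this reduces exactly to the
    single-scattering field.
    """
    first = stack.layers[0]
    shape = first.shape
    ex = np.full(shape, illumination[0], dtype=complex)
    ey = np.full(shape, illumination[1], dtype=complex)
    for j, layer in enumerate(stack.layers):
        shift = j * stack.layer_shift
        if shift:
            layer = FibrilLayer(
                np.roll(layer.rho_map, shift, axis=1),
                np.roll(layer.delta_map, shift, axis=1),
                layer.pixel_pitch,
            )
        jxx, jxy, jyy = layer_jones_components(layer)
        ex, ey = jxx * ex + jxy * ey, jxy * ex + jyy * ey
    return ComplexField(ux=ex, uy=ey, pixel_pitch=first.pixel_pitch)


def single_scatter_truth(layer: FibrilLayer):
    """Exact single-scatter azimuth/ellipticity maps for a layer.

    Closed forms for circular illumination:
    ``alpha = 0.5·atan2(cos2ρ·sinδ, sin2ρ·sinδ)`` folded to [−π/2, π/2) and
    ``beta = 0.5·arcsin(cosδ)``.  Where ``sinδ ≈ 0`` the state is circular and
    the azimuth is flagged undefined.
    """
    sd = np.sin(layer.delta_map)
    alpha = 0.5 * np.arctan2(np.cos(2 * layer.rho_map) * sd, np.sin(2 * layer.rho_map) * sd)
    alpha = np.where(alpha >= np.pi / 2, alpha - np.pi, alpha)
    beta = 0.5 * np.arcsin(np.clip(np.cos(layer.delta_map), -1, 1))
    defined = np.abs(sd) > 1e-12
    alpha = np.where(defined, alpha, 0.0)
    return alpha, beta, defined


def measure_depolarization(field: ComplexField, window: int = 16) -> float:
    """Windowed spatial depolarization degree of a coherent field, in [0, 1].

    Per sliding window the polarized part is the vector mean of the pointwise
    Stokes components; the estimate is
    ``1 − Σ_w |mean (s2,s3,s4)| / Σ_w mean s1``.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    from scipy.ndimage import uniform_filter

    s1, s2, s3, s4 = field.stokes_components()
    f = lambda a: uniform_filter(a, size=window, mode="reflect")
    pol = np.sqrt(f(s2) ** 2 + f(s3) ** 2 + f(s4) ** 2)
    total = f(s1)
    return float(np.clip(1.0 - pol.sum() / (total.sum() + 1e-300), 0.0, 1.0))


def _speckle_background(shape, rng, grain_sigma: float = 0.0):
    """Fully developed speckle with per-pixel random polarization, unit mean power.

    ``grain_sigma = 0`` gives delta-correlated (finest-grain) speckle.
    """

    def _g(a):
        return gaussian_filter(a, grain_sigma, mode="wrap") if grain_sigma > 0 else a

    bx = _g(rng.standard_normal(shape)) + 1j * _g(rng.standard_normal(shape))
    by = _g(rng.standard_normal(shape)) + 1j * _g(rng.standard_normal(shape))
    power = 0.5 * (np.mean(np.abs(bx) ** 2) + np.mean(np.abs(by) ** 2))
    scale = 1.0 / np.sqrt(2 * power)
    return bx * scale, by * scale


def add_depolarized_background(
    field: ComplexField, delta_pct: float, seed: int, window: int = 16
) -> ComplexField:
    """Mix in a depolarized speckle background to a target depolarization degree.

    The background (one fully developed fine-grained speckle realization with
    per-pixel random polarization) is mutually incoherent with the object
    field and is carried on the ``bg_ux``/``bg_uy`` channels; its power
    fraction is calibrated by scalar root finding so the windowed estimator of
    :func:`measure_depolarization` returns ``delta_pct`` within ±0.03 on the
    mixture.  ``delta_pct = 0`` returns the field unchanged; a target below
    the field's intrinsic depolarization raises ``ValueError``.
    """
    if not (0 <= delta_pct < 1):
        raise ValueError("delta_pct must be in [0, 1)")
    if delta_pct == 0:
        return field
    if field.has_background:
        raise ValueError("field already carries a background component")
    rng = np.random.default_rng(seed)
    bx, by = _speckle_background(field.shape, rng)
    sig_power = float(np.mean(field.intensity))
    bx = bx * np.sqrt(sig_power)
    by = by * np.sqrt(sig_power)

    def mixed(f):
        return ComplexField(
            np.sqrt(1 - f) * field.ux,
            np.sqrt(1 - f) * field.uy,
            field.pixel_pitch,
            bg_ux=np.sqrt(f) * bx,
            bg_uy=np.sqrt(f) * by,
        )

    def err(f):
        return measure_depolarization(mixed(f), window) - delta_pct

    lo, hi = 0.0, 0.999
    e_lo, e_hi = err(lo), err(hi)
    if e_lo > 0:
        if e_lo <= 0.03:
            warnings.warn("intrinsic depolarization already at target; field unchanged")
            return field
        raise ValueError(
            f"target depolarization {delta_pct:.2f} below intrinsic level {e_lo + delta_pct:.2f}"
        )
    if e_hi < 0:
        f_star = hi
    else:
        f_star = brentq(err, lo, hi, xtol=1e-4)
    return mixed(f_star)


def estimate_fibril_width(layer: FibrilLayer, threshold: float | None = None) -> float:
    """Blind median stroke width (pixels) from the retardance raster.

    Thresholds the map above the parenchymal floor, computes the Euclidean
    distance transform, and takes twice the median ridge distance (local
    maxima of the EDT inside strokes).
    """
    d = layer.delta_map
    if threshold is None:
        threshold = 0.5 * (np.percentile(d, 10) + np.percentile(d, 99.5))
    mask = d > threshold
    if mask.sum() < 10:
        raise ValueError("no stroke pixels above threshold")
    edt = distance_transform_edt(mask)
    ridge = mask & (edt >= maximum_filter(edt, size=3) - 1e-9) & (edt > 1.0)
    if ridge.sum() < 5:
        raise ValueError("no ridge pixels found")
    return float(2.0 * np.median(edt[ridge]))


def estimate_orientation_order(layer: FibrilLayer, threshold: float | None = None) -> float:
    """Blind orientation order parameter |<e^{2iρ}>| over stroke pixels, in [0, 1]."""
    d = layer.delta_map
    if threshold is None:
        threshold = 0.5 * (np.percentile(d, 10) + np.percentile(d, 99.5))
    mask = d > threshold
    if mask.sum() < 10:
        raise ValueError("no stroke pixels above threshold")
    return float(np.abs(np.mean(np.exp(2j * layer.rho_map[mask]))))


@dataclass(frozen=True)
class BimodalPhantom:
    """Two-population phase phantom for single-scattering plane detection.

    The ``single`` population is a genuine single-scatter fibril field whose
    inter-component phases fall in a tight band below π/8; the ``multi``
    population carries engineered large phase shifts well above π/8.  The
    regions are split by a smooth 50/50 blob mask, and a calibrated
    depolarized background can be mixed in.
    """

    field: ComplexField
    layer: FibrilLayer
    alpha_truth: np.ndarray
    beta_truth: np.ndarray
    single_mask: np.ndarray  # True where the single-scatter population lives


def generate_bimodal_phantom(
    seed: int,
    shape=(256, 256),
    single_delta: float = 1.38,
    rho_spread: float = 0.05,
    multi_phase_range=(0.47, 1.1),
    depol_degree: float = 0.5,
    pixel_pitch: float = DEFAULT_PIXEL_PITCH,
) -> BimodalPhantom:
    """Construct a bimodal phase phantom with known single-scatter truth.

    The single-scatter layer has retardance ``single_delta`` (±1.5%) and
    optical-axis orientations within ±``rho_spread`` of zero, pinning its
    inter-component phase ``atan2(cosδ, sinδ·cos2ρ)`` in a narrow band near
    0.19 rad (< π/8).  The multiple-scattering population carries smooth
    engineered phases over ``multi_phase_range`` (≫ π/8) and amplitude ratios
    that push its polarization statistics far from the single population's.
    The two regions split the raster roughly 50/50 through a smooth blob mask.
    """
    rng = np.random.default_rng(seed)
    rho = np.mod(2 * rho_spread * (_smooth_unit_field(shape, rng, 6.0) - 0.5), np.pi)
    delta = single_delta * (1.0 + 0.03 * (_smooth_unit_field(shape, rng, 6.0) - 0.5))
    layer = FibrilLayer(rho, delta, pixel_pitch)
    single = cascade_field(ScatteringStack((layer,)))
    alpha_t, beta_t, _ = single_scatter_truth(layer)
    # engineered multiple-scattering population: smooth phase maps over
    # multi_phase_range, with the amplitude ratio solved per pixel so the
    # multi ellipticity matches the single cluster's (transition pixels then
    # stay near the cluster's beta statistics; the plateau break at the flood
    # comes from the azimuth, which differs strongly between populations)
    lo, hi = multi_phase_range
    phi = lo + (hi - lo) * _smooth_uniform_field(shape, rng, 4.0)
    s_beta = np.sin(2 * 0.5 * np.arcsin(np.cos(single_delta)))
    sphi = np.maximum(np.sin(phi), s_beta + 1e-3)
    ratio = (sphi - np.sqrt(sphi**2 - s_beta**2)) / s_beta
    global_phase = 2 * np.pi * _smooth_unit_field(shape, rng, 6.0)
    mux = np.exp(1j * global_phase)
    muy = ratio * np.exp(1j * (global_phase + phi))
    # smooth 50/50 region split with a narrow transition
    blob = gaussian_filter(rng.standard_normal(shape), 12.0, mode="wrap")
    level = np.median(blob)
    w = 1.0 / (1.0 + np.exp(-(blob - level) / (0.02 * blob.std() + 1e-30)))
    ux = w * single.ux + (1 - w) * mux
    uy = w * single.uy + (1 - w) * muy
    field = ComplexField(ux, uy, pixel_pitch)
    if depol_degree > 0:
        field = add_depolarized_background(field, depol_degree, seed=seed + 7919)
    return BimodalPhantom(
        field=field,
        layer=layer,
        alpha_truth=alpha_t,
        beta_truth=beta_t,
        single_mask=w > 0.9,
    )


@dataclass(frozen=True)
class PhantomBundle:
    """One generated phantom with its ground truth and field components."""

    preset: PhantomPreset
    seed: int
    layer: FibrilLayer
    alpha_truth: np.ndarray
    beta_truth: np.ndarray
    truth_defined: np.ndarray
    field_single: ComplexField
    field: ComplexField  # combined field incl. multiple scattering + background


def generate_phantom(
    preset: PhantomPreset | str,
    seed: int,
    shape=(256, 256),
    pixel_pitch: float = DEFAULT_PIXEL_PITCH,
    multi_weight: float = 0.35,
    layer_shift: int = 7,
    depol_degree: float | None = None,
) -> PhantomBundle:
    """Full phantom: layer, single-scatter field/truth, multi-scatter mix, background.

    The combined field is ``field_single + multi_weight · field_multi`` with
    the multiple-scattering component produced by a ``n_layers`` cascade over
    laterally shifted copies of the layer, then mixed with a depolarized
    background at the preset's (or overridden) depolarization degree.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    layer = generate_fibril_layer(preset, seed, shape=shape, pixel_pitch=pixel_pitch)
    alpha_t, beta_t, defined = single_scatter_truth(layer)
    field_single = cascade_field(ScatteringStack((layer,)))
    if preset.n_layers > 1 and multi_weight > 0:
        stack = ScatteringStack(tuple([layer] * preset.n_layers), layer_shift=layer_shift)
        field_multi = cascade_field(stack)
        combined = ComplexField(
            field_single.ux + multi_weight * field_multi.ux,
            field_single.uy + multi_weight * field_multi.uy,
            pixel_pitch,
        )
    else:
        combined = field_single
    target = preset.depol_degree if depol_degree is None else depol_degree
    if target > 0:
        combined = add_depolarized_background(combined, target, seed=seed + 104729)
    return PhantomBundle(
        preset=preset,
        seed=seed,
        layer=layer,
        alpha_truth=alpha_t,
        beta_truth=beta_t,
        truth_defined=defined,
        field_single=field_single,
        field=combined,
    )
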