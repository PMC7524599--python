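"""Synthetic targets and the forward acquisition model.

This module generates the ground-truth objects (calibration charts, vessel
phantoms) and simulates how a MEMS-scanned OR-PAM system detects them.  The
detected volume is the composition

    I' = (((I + N1) (*) K_laser) . M_map + N2) + baseline,

where ``I`` is the ground truth, ``N1`` the laser/matter interaction noise,
``K_laser`` the spot-size point-spread kernel, ``M_map`` the location-mapping
matrix equal to the cumulative integral of the (nonlinear) mirror velocity,
``N2`` the sensor noise and ``baseline`` a per-A-line constant offset.

The mirror velocity slows near the turning points of each B-scan, so sample
positions cluster there: features near the B-scan ends appear stretched in
the raster image.  Because a point absorber launches a bipolar (N-shaped)
pressure transient, the axial component of the default kernel is the
derivative of a Gaussian; the lateral component is a unit-sum Gaussian whose
FWHM equals the Airy-disk diameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import ScanGeometry
from .volume import PAVolume

__all__ = [
    "ReferenceImage",
    "DistortionModel",
    "NoiseModel",
    "LaserKernel",
    "make_grid_chart",
    "make_ring_chart",
    "make_vessel_phantom",
    "make_laser_kernel",
    "mems_distortion",
    "simulate_acquisition",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ReferenceImage:
    """A known calibration target: pixels in [0, 1] plus corner ground truth."""

    pixels: np.ndarray
    pitch: float
    corner_truth: np.ndarray  # (n, 2) array of (row, col)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("reference image must be 2-D")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("reference pixels must lie in [0, 1]")
        self.corner_truth = np.asarray(self.corner_truth, dtype=float).reshape(-1, 2)
        if len(self.corner_truth):
            r, c = self.corner_truth[:, 0], self.corner_truth[:, 1]
            h, w = self.pixels.shape
            if r.min() < 0 or c.min() < 0 or r.max() > h - 1 or c.max() > w - 1:
                raise ValueError("corner_truth outside image bounds")


@dataclass
class DistortionModel:
    """Nonlinear fast-axis scan map.

    ``velocity[i]`` is the dimensionless mirror speed at detected sample
    ``i`` (mean 1); ``map[i]`` is its cumulative integral rescaled to span
    the image, i.e. the true fast-axis position sampled at detector index
    ``i``.  The map is strictly monotone, hence invertible.
    """

    velocity: np.ndarray
    map: np.ndarray

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.map = np.asarray(self.map, dtype=float)
        if self.map.ndim != 1 or self.velocity.shape != self.map.shape:
            raise ValueError("velocity and map must be matching 1-D arrays")
        if np.any(np.diff(self.map) <= 0):
            raise ValueError("location map must be strictly monotone")

    @property
    def n_fast(self) -> int:
        return self.map.size

    @property
    def displacement(self) -> np.ndarray:
        """Per-pixel displacement map - identity."""
        return self.map - np.arange(self.n_fast)

    def inverse(self, x: np.ndarray) -> np.ndarray:
        """Detector index at which true position ``x`` was sampled."""
        x = np.asarray(x, dtype=float)
        return np.interp(x, self.map, np.arange(self.n_fast, dtype=float))

    def is_identity(self, tol: float = 1e-12) -> bool:
        return bool(np.max(np.abs(self.displacement)) <= tol)

    def warp_volume(self, data: np.ndarray) -> np.ndarray:
        """Resample a (fast, slow, time) array at the distorted positions."""
        if data.shape[0] != self.n_fast:
            raise ValueError(
                f"fast-axis length {data.shape[0]} does not match map length {self.n_fast}")
        pos = np.clip(self.map, 0, self.n_fast - 1)
        lo = np.floor(pos).astype(int)
        hi = np.minimum(lo + 1, self.n_fast - 1)
        frac = (pos - lo).reshape(-1, *([1] * (data.ndim - 1)))
        return (1.0 - frac) * data[lo] + frac * data[hi]

    def warp_image(self, image: np.ndarray) -> np.ndarray:
        """Distort a (slow, fast) image: columns are the fast axis."""
        return self.warp_volume(np.asarray(image, dtype=float).T[:, :, None])[:, :, 0].T


@dataclass
class NoiseModel:
    """Additive noise of the acquisition chain.

    ``sigma1`` perturbs the source before the optical blur (laser/matter
    interaction), ``sigma2`` perturbs the detected samples (sensor noise),
    and each A-line additionally receives a constant baseline offset drawn
    from N(baseline_mean, baseline_std).
    """

    sigma1: float = 0.0
    sigma2: float = 0.0
    baseline_mean: float = 0.0
    baseline_std: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma1 < 0 or self.sigma2 < 0 or self.baseline_std < 0:
            raise ValueError("noise standard deviations must be non-negative")


@dataclass
class LaserKernel:
    """Spot-size point-spread kernel of the excitation/reception chain."""

    psf: np.ndarray
    airy_um: float = 12.5

    def __post_init__(self) -> None:
        self.psf = np.asarray(self.psf, dtype=float)
        if self.psf.ndim != 3:
            raise ValueError("PSF must be a 3-D (fast, slow, time) kernel")
        lateral = self.psf.sum(axis=2)
        if not np.isclose(lateral.sum(), 1.0, atol=1e-6) and not np.isclose(
                np.abs(self.psf).sum(), 1.0, atol=1e-6):
            raise ValueError("kernel must be normalized (lateral sum or L1 norm of 1)")


# ---------------------------------------------------------------------------
# targets
# ---------------------------------------------------------------------------

def make_grid_chart(n_rows: int, n_cols: int, pitch_px: int, line_width_px: int) -> ReferenceImage:
    """A binary grid resolution chart with known line intersections.

    Lines are laid out at ``pitch_px`` spacing starting half a pitch from
    the border; every horizontal/vertical crossing is recorded in
    ``corner_truth`` at the sub-pixel centre of the crossing.
    """
    if n_rows <= 0 or n_cols <= 0:
        raise ValueError("chart dimensions must be positive")
    if not (pitch_px > line_width_px >= 1):
        raise ValueError("require pitch_px > line_width_px >= 1")
    img = np.zeros((n_rows, n_cols))
    row_pos = np.arange(pitch_px // 2, n_rows - line_width_px + 1, pitch_px)
    col_pos = np.arange(pitch_px // 2, n_cols - line_width_px + 1, pitch_px)
    for r in row_pos:
        img[r:r + line_width_px, :] = 1.0
    for c in col_pos:
        img[:, c:c + line_width_px] = 1.0
    centre = (line_width_px - 1) / 2.0
    corners = [(r + centre, c + centre) for r in row_pos for c in col_pos]
    return ReferenceImage(pixels=img, pitch=float(pitch_px), corner_truth=np.array(corners).reshape(-1, 2))


def make_ring_chart(n: int, ring_radii_px: list[float], width_px: int = 2) -> ReferenceImage:
    """Concentric-ring resolution chart (no corner ground truth)."""
    if n <= 0:
        raise ValueError("chart size must be positive")
    radii = sorted(float(r) for r in ring_radii_px)
    for r in radii:
        if r <= 0 or r + width_px / 2.0 >= n / 2.0:
            raise ValueError(f"ring radius {r} out of bounds for size {n}")
    for a, b in zip(radii, radii[1:]):
        if b - a < width_px:
            raise ValueError("overlapping rings")
    img = np.zeros((n, n))
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    dist = np.hypot(yy - c, xx - c)
    for r in radii:
        img[np.abs(dist - r) <= width_px / 2.0] = 1.0
    return ReferenceImage(pixels=img, pitch=float(n), corner_truth=np.empty((0, 2)))


def make_vessel_phantom(n: int, seed: int, n_branches: int = 6,
                        n_time: int = 48,
                        depth_band: tuple[int, int] | None = None) -> np.ndarray:
    """Sparse tubular 3-D phantom emulating a microvascular network.

    Each branch is a smooth lateral random walk whose depth drifts slowly
    inside ``depth_band`` (default: the middle of the time axis, clear of
    the leading baseline window); voxels within the tube radius are set to
    an amplitude in (0.5, 1].  Deterministic for a given seed; the nonzero
    fraction stays well below 10 %.
    """
    if n <= 0 or n_time <= 0:
        raise ValueError("phantom dimensions must be positive")
    if n_branches < 0:
        raise ValueError("n_branches must be non-negative")
    rng = np.random.default_rng(seed)
    vol = np.zeros((n, n, n_time), dtype=float)
    if depth_band is None:
        depth_band = (int(0.25 * n_time), int(0.85 * n_time))
    k_lo, k_hi = depth_band
    k_hi = min(k_hi, n_time - 1)
    if k_hi - k_lo < 5:
        k_lo, k_hi = max(n_time // 4, 1), n_time - 2
    if k_hi - k_lo < 5:
        raise ValueError(f"time axis too short for a vessel phantom: {n_time}")
    for _ in range(n_branches):
        # start on a random border, walk across the field of view
        x = rng.uniform(0, n - 1)
        y = rng.uniform(0, n - 1)
        angle = rng.uniform(0, 2 * np.pi)
        depth = rng.uniform(k_lo + 2, k_hi - 2)
        amp = rng.uniform(0.6, 1.0)
        radius = rng.uniform(1.0, 2.0)
        n_steps = int(2.5 * n)
        for _ in range(n_steps):
            angle += rng.normal(0, 0.12)
            depth = np.clip(depth + rng.normal(0, 0.08), k_lo, k_hi)
            x += np.cos(angle)
            y += np.sin(angle)
            if not (0 <= x < n and 0 <= y < n):
                break
            i0, j0, k0 = int(round(x)), int(round(y)), int(round(depth))
            r = int(np.ceil(radius))
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    if di * di + dj * dj <= radius * radius:
                        ii, jj = i0 + di, j0 + dj
                        if 0 <= ii < n and 0 <= jj < n:
                            vol[ii, jj, k0] = max(vol[ii, jj, k0], amp)
    return vol


# ---------------------------------------------------------------------------
# forward model components
# ---------------------------------------------------------------------------

def make_laser_kernel(airy_um: float = 12.5,
                      step_fast_um: float = 4.0,
                      step_slow_um: float = 6.0,
                      axial_sigma_samples: float = 1.0,
                      axial: str = "bipolar") -> LaserKernel:
    """Separable PSF: lateral Gaussian blur x axial reception profile.

    The lateral FWHM equals the Airy-disk diameter expressed in pixels per
    axis (12.5 um -> ~3.1 px fast, ~2.1 px slow at 4/6 um steps) and the
    lateral kernel is normalized to unit sum.  The axial profile models the
    reception-time spread of a point absorber: ``"bipolar"`` (default) is
    the derivative of a Gaussian (the N-shaped pressure transient),
    ``"gaussian"`` a unipolar envelope, ``"delta"`` no axial spread.
    """
    if airy_um <= 0:
        raise ValueError("airy_um must be positive")

    def gauss1d(sigma):
        if sigma <= 0:
            return np.array([1.0])
        half = max(1, int(np.ceil(3 * sigma)))
        x = np.arange(-half, half + 1, dtype=float)
        g = np.exp(-0.5 * (x / sigma) ** 2)
        return g / g.sum()

    fwhm_to_sigma = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sig_f = airy_um / step_fast_um * fwhm_to_sigma
    sig_s = airy_um / step_slow_um * fwhm_to_sigma
    gf = gauss1d(sig_f)
    gs = gauss1d(sig_s)

    if axial == "delta":
        ax = np.array([1.0])
    elif axial == "gaussian":
        ax = gauss1d(axial_sigma_samples)
    elif axial == "bipolar":
        sigma = max(axial_sigma_samples, 1e-6)
        half = max(2, int(np.ceil(3 * sigma)))
        t = np.arange(-half, half + 1, dtype=float)
        ax = -t * np.exp(-0.5 * (t / sigma) ** 2)
        ax = ax / np.abs(ax).sum()  # unit L1; sums to zero by antisymmetry
    else:
        raise ValueError(f"unknown axial profile {axial!r}")

    psf = gf[:, None, None] * gs[None, :, None] * ax[None, None, :]
    return LaserKernel(psf=psf, airy_um=airy_um)


def delta_kernel() -> LaserKernel:
    """Identity PSF, useful for isolating other parts of the forward model."""
    return LaserKernel(psf=np.ones((1, 1, 1)), airy_um=1e-9)


def _end_slowdown(s: np.ndarray, width: float, w_start: float, w_end: float) -> np.ndarray:
    """Bump profile in [0, 1] concentrated at both ends of the B-scan."""
    b = w_start * np.exp(-0.5 * (s / width) ** 2) + w_end * np.exp(-0.5 * ((1 - s) / width) ** 2)
    return np.clip(b, 0.0, 1.0)


def mems_distortion(geometry_or_n, nonlinearity: float,
                    kind: str = "electrothermal") -> DistortionModel:
    """Velocity profile and location map of a nonlinear MEMS B-scan.

    The mirror slows near the turning points; the electrothermal profile is
    stronger and asymmetric (worse at the end of the sweep), the
    electrostatic one mild and symmetric.  ``nonlinearity`` in [0, 1) scales
    the maximum fractional slowdown; 0 yields the identity map.
    """
    if not (0 <= nonlinearity < 1):
        raise ValueError("nonlinearity must be in [0, 1)")
    if isinstance(geometry_or_n, ScanGeometry):
        g = geometry_or_n
        n = int(round(g.scan_area_mm[0] * 1e3 / g.step_fast_um))
    else:
        n = int(geometry_or_n)
    if n < 2:
        raise ValueError("need at least two fast-axis samples")
    s = np.linspace(0.0, 1.0, n)
    if kind == "electrothermal":
        bump = _end_slowdown(s, width=0.12, w_start=0.6, w_end=1.0)
    elif kind == "electrostatic":
        bump = _end_slowdown(s, width=0.10, w_start=0.35, w_end=0.35)
    else:
        raise ValueError(f"unknown MEMS kind {kind!r}")
    v = 1.0 - nonlinearity * bump
    cum = np.concatenate([[0.0], np.cumsum((v[1:] + v[:-1]) / 2.0)])
    mp = cum * (n - 1) / cum[-1]
    velocity = np.gradient(mp)
    return DistortionModel(velocity=velocity, map=mp)


def identity_distortion(n: int) -> DistortionModel:
    return mems_distortion(n, 0.0)


# ---------------------------------------------------------------------------
# the forward model
# ---------------------------------------------------------------------------

def simulate_acquisition(truth, kernel: LaserKernel, dist: DistortionModel,
                         noise: NoiseModel,
                         geometry: ScanGeometry | None = None) -> PAVolume:
    """Detect a ground-truth volume through the full forward model.

    Composition order: source noise, optical blur, location mapping, sensor
    noise, per-A-line baseline offset.  With zero noise, an identity map and
    a delta kernel the output equals the input exactly.
    """
    data = truth.data if isinstance(truth, PAVolume) else np.asarray(truth, dtype=float)
    if data.ndim != 3:
        raise ValueError("truth must be a 3-D (fast, slow, time) array")
    if any(k > s for k, s in zip(kernel.psf.shape, data.shape)):
        raise ValueError(
            f"kernel {kernel.psf.shape} larger than volume {data.shape}")
    if data.shape[0] != dist.n_fast:
        raise ValueError("distortion map length does not match the fast axis")

    rng = np.random.default_rng(noise.seed)
    out = data.astype(float)
    if noise.sigma1 > 0:
        out = out + rng.normal(0.0, noise.sigma1, out.shape)
    if kernel.psf.size > 1:
        out = ndimage.convolve(out, kernel.psf, mode="constant", cval=0.0)
    out = dist.warp_volume(out)
    if noise.sigma2 > 0:
        out = out + rng.normal(0.0, noise.sigma2, out.shape)
    if noise.baseline_std > 0 or noise.baseline_mean != 0:
        offsets = rng.normal(noise.baseline_mean, noise.baseline_std, out.shape[:2])
        out = out + offsets[:, :, None]

    if geometry is not None:
        return PAVolume(out, geometry.step_fast_um, geometry.step_slow_um,
                        geometry.sample_rate_hz)
    if isinstance(truth, PAVolume):
        return truth.with_data(out)
    return PAVolume(out)
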