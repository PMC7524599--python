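"""Layer 2 of the reconstruction: feature-based distortion correction.

Corner features detected on the distorted chart are matched to the corners
of the reference chart by mutual nearest neighbours, a geometric transform
(projective, polynomial, or local weighted mean) is fitted to the sparse
correspondence by least squares, and the distorted image/volume is warped
onto the reference grid by inverse-mapping resampling.  Registration is
accepted when the normalized mutual information between the warped image
and the reference exceeds a threshold epsilon (default 0.48, evaluated on
two-level histograms); otherwise manually supplied point pairs are folded
in and the fit is retried.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial.distance import cdist
from skimage.transform import ProjectiveTransform

from . import metrics
from .features import (FeaturePointSet, OVMRFConfig, anms, centroid_refine,
                       harris_corners, ovmrf_label, sobel_verify)
from .phantom import ReferenceImage
from .volume import PAVolume

__all__ = [
    "PointPairs",
    "GeometricTransform",
    "RegistrationError",
    "match_points",
    "add_manual_pairs",
    "fit_transform",
    "warp_image",
    "register_chart",
    "apply_to_volume",
    "extract_chart_corners",
]

MIN_PAIRS = {"projective": 4, "polynomial2": 6, "polynomial3": 10, "lwm": 12}


class RegistrationError(RuntimeError):
    """Raised when the chart registration cannot reach the NMI threshold."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


# ---------------------------------------------------------------------------
# point pairs
# ---------------------------------------------------------------------------

@dataclass
class PointPairs:
    """Matched (row, col) correspondences, distorted -> reference."""

    src: np.ndarray
    dst: np.ndarray
    origin: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.src = np.asarray(self.src, dtype=float).reshape(-1, 2)
        self.dst = np.asarray(self.dst, dtype=float).reshape(-1, 2)
        if len(self.src) != len(self.dst):
            raise ValueError("src/dst length mismatch")
        if not self.origin:
            self.origin = ["auto"] * len(self.src)
        if len(self.origin) != len(self.src):
            raise ValueError("origin flags length mismatch")
        if len(self.src):
            uniq = np.unique(self.src, axis=0)
            if len(uniq) != len(self.src):
                raise ValueError("duplicate src points")

    def __len__(self) -> int:
        return len(self.src)


def match_points(src_pts: FeaturePointSet, dst_pts: FeaturePointSet,
                 max_dist_px: float) -> PointPairs:
    """Mutual-nearest-neighbour matching under a Euclidean cutoff."""
    if len(src_pts) == 0 or len(dst_pts) == 0:
        raise ValueError("cannot match empty point sets")
    d = cdist(src_pts.points, dst_pts.points)
    nn_src = d.argmin(axis=1)
    nn_dst = d.argmin(axis=0)
    src_idx = np.arange(len(src_pts))
    mutual = nn_dst[nn_src] == src_idx
    close = d[src_idx, nn_src] <= max_dist_px
    keep = mutual & close
    if not keep.any():
        raise RegistrationError(
            "no mutual matches within the distance cutoff; increase "
            "max_dist_px or supply manual point pairs")
    return PointPairs(src=src_pts.points[keep], dst=dst_pts.points[nn_src[keep]])


def add_manual_pairs(pairs: PointPairs, extra: PointPairs) -> PointPairs:
    """Union of automatic and manually selected pairs (manual flag kept)."""
    if len(extra) == 0:
        return pairs
    origin = list(pairs.origin) + ["manual"] * len(extra)
    return PointPairs(src=np.vstack([pairs.src, extra.src]),
                      dst=np.vstack([pairs.dst, extra.dst]),
                      origin=origin)


# ---------------------------------------------------------------------------
# transform families
# ---------------------------------------------------------------------------

def _poly_exponents(degree: int) -> list[tuple[int, int]]:
    return [(a, b) for a, b in itertools.product(range(degree + 1), repeat=2)
            if a + b <= degree]


def _poly_design(pts: np.ndarray, exponents) -> np.ndarray:
    r, c = pts[:, 0], pts[:, 1]
    return np.stack([(r ** a) * (c ** b) for a, b in exponents], axis=1)


def _fit_poly(src: np.ndarray, dst: np.ndarray, degree: int) -> np.ndarray:
    exps = _poly_exponents(degree)
    A = _poly_design(src, exps)
    coeffs, _, rank, _ = np.linalg.lstsq(A, dst, rcond=None)
    if rank < len(exps):
        raise ValueError("degenerate point configuration for the polynomial fit")
    return coeffs  # (n_terms, 2)


def _eval_poly(pts: np.ndarray, coeffs: np.ndarray, degree: int) -> np.ndarray:
    return _poly_design(pts, _poly_exponents(degree)) @ coeffs


def _fit_lwm(src: np.ndarray, dst: np.ndarray, n_local: int = 12):
    """Local-weighted-mean model: a degree-2 polynomial per control point."""
    n = len(src)
    n_local = min(n_local, n)
    d = cdist(src, src)
    models, radii = [], []
    for i in range(n):
        idx = np.argsort(d[i])[:n_local]
        coeffs = _fit_poly(src[idx], dst[idx], degree=2)
        models.append(coeffs)
        radii.append(d[i, idx].max())
    return {"centers": src.copy(), "coeffs": np.array(models), "radii": np.array(radii)}


def _eval_lwm(pts: np.ndarray, model) -> np.ndarray:
    centers, coeffs, radii = model["centers"], model["coeffs"], model["radii"]
    d = cdist(pts, centers)
    with np.errstate(invalid="ignore"):
        rho = d / radii[None, :]
    w = np.where(rho < 1.0, 1.0 - 3.0 * rho ** 2 + 2.0 * rho ** 3, 0.0)
    out = np.zeros((len(pts), 2))
    local = np.stack([_eval_poly(pts, c, 2) for c in coeffs], axis=1)  # (npts, ncenters, 2)
    wsum = w.sum(axis=1)
    covered = wsum > 0
    if covered.any():
        out[covered] = (w[covered, :, None] * local[covered]).sum(axis=1) / wsum[covered, None]
    if (~covered).any():
        nearest = d[~covered].argmin(axis=1)
        out[~covered] = local[~covered, nearest]
    return out


@dataclass
class GeometricTransform:
    """Fitted mapping between distorted and reference pixel coordinates.

    ``forward`` maps distorted (src) points to reference (dst) coordinates;
    ``inverse`` maps reference points back to the distorted frame and is
    what inverse-mapping warps sample with.  Both directions are fitted to
    the same point pairs.  Points are (row, col) arrays.
    """

    family: str
    _fwd: object
    _inv: object
    residual_rms: float = 0.0

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        return self._apply(self._fwd, pts)

    def inverse_points(self, pts: np.ndarray) -> np.ndarray:
        return self._apply(self._inv, pts)

    def _apply(self, model, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float).reshape(-1, 2)
        if self.family == "projective":
            h = np.column_stack([pts, np.ones(len(pts))]) @ np.asarray(model).T
            return h[:, :2] / h[:, 2:3]
        if self.family in ("polynomial2", "polynomial3"):
            return _eval_poly(pts, np.asarray(model), int(self.family[-1]))
        if self.family == "lwm":
            return _eval_lwm(pts, model)
        raise ValueError(f"unknown family {self.family!r}")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        def enc(model):
            if self.family == "lwm":
                return {k: np.asarray(v).tolist() for k, v in model.items()}
            return np.asarray(model).tolist()
        return {"family": self.family, "forward": enc(self._fwd),
                "inverse": enc(self._inv), "residual_rms": self.residual_rms}

    @classmethod
    def from_dict(cls, d: dict) -> "GeometricTransform":
        def dec(model):
            if d["family"] == "lwm":
                return {k: np.asarray(v) for k, v in model.items()}
            return np.asarray(model)
        return cls(family=d["family"], _fwd=dec(d["forward"]),
                   _inv=dec(d["inverse"]), residual_rms=float(d["residual_rms"]))


def _check_foldover(transform: GeometricTransform, src: np.ndarray, n_grid: int = 12) -> None:
    """Reject fits whose forward map folds over the control-point domain."""
    lo = src.min(axis=0)
    hi = src.max(axis=0)
    span = np.maximum(hi - lo, 1.0)
    rr, cc = np.meshgrid(np.linspace(lo[0], hi[0], n_grid),
                         np.linspace(lo[1], hi[1], n_grid), indexing="ij")
    pts = np.column_stack([rr.ravel(), cc.ravel()])
    h = 1e-3 * span
    dr = (transform(pts + [h[0], 0]) - transform(pts - [h[0], 0])) / (2 * h[0])
    dc = (transform(pts + [0, h[1]]) - transform(pts - [0, h[1]])) / (2 * h[1])
    det = dr[:, 0] * dc[:, 1] - dr[:, 1] * dc[:, 0]
    if np.any(det <= 0):
        raise ValueError("fitted transform folds over the image domain")


def fit_transform(pairs: PointPairs, family: str = "auto") -> GeometricTransform:
    """Least-squares fit of dst = T(src) in the requested family.

    ``family='auto'`` picks polynomial degree 3 when at least 10 pairs are
    available (the MEMS distortion is smooth but non-projective) and falls
    back to projective for sparse sets.  Both mapping directions are fitted;
    the fold-over of the forward map is checked on the control-point domain.
    """
    aliases = {"poly2": "polynomial2", "poly3": "polynomial3"}
    family = aliases.get(family, family)
    if family == "auto":
        family = "polynomial3" if len(pairs) >= MIN_PAIRS["polynomial3"] else "projective"
    if family not in MIN_PAIRS:
        raise ValueError(f"unknown family {family!r}")
    if len(pairs) < MIN_PAIRS[family]:
        raise ValueError(
            f"{family} needs >= {MIN_PAIRS[family]} pairs, got {len(pairs)}")

    src, dst = pairs.src, pairs.dst
    if family == "projective":
        # skimage works in (x, y) = (col, row)
        fwd_t = ProjectiveTransform.from_estimate(src[:, ::-1], dst[:, ::-1])
        if not fwd_t or not np.all(np.isfinite(fwd_t.params)):
            raise ValueError("degenerate point configuration for the projective fit")
        inv_params = np.linalg.inv(fwd_t.params)
        P = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)  # (x,y)->(r,c) basis swap
        fwd = P @ fwd_t.params @ P
        inv = P @ inv_params @ P
    elif family in ("polynomial2", "polynomial3"):
        degree = int(family[-1])
        fwd = _fit_poly(src, dst, degree)
        inv = _fit_poly(dst, src, degree)
    else:  # lwm
        fwd = _fit_lwm(src, dst)
        inv = _fit_lwm(dst, src)

    t = GeometricTransform(family=family, _fwd=fwd, _inv=inv)
    t.residual_rms = float(np.sqrt(np.mean(np.sum((t(src) - dst) ** 2, axis=1))))
    _check_foldover(t, src)
    return t


# ---------------------------------------------------------------------------
# warping
# ---------------------------------------------------------------------------

def warp_image(image: np.ndarray, transform: GeometricTransform,
               interp: str = "bilinear") -> np.ndarray:
    """Inverse-mapping resample of a (row, col) image onto the reference grid."""
    orders = {"nearest": 0, "bilinear": 1}
    if interp not in orders:
        raise ValueError(f"unknown interpolation {interp!r}")
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    src = transform.inverse_points(np.column_stack([rr.ravel(), cc.ravel()]))

    def snap(x, hi):
        # fit residue of a near-identity transform must not fall off the grid
        x = np.where(np.abs(x) < 1e-3, 0.0, x)
        return np.where(np.abs(x - hi) < 1e-3, float(hi), x)

    return map_coordinates(image,
                           [snap(src[:, 0], h - 1).reshape(h, w),
                            snap(src[:, 1], w - 1).reshape(h, w)],
                           order=orders[interp], mode="constant", cval=0.0)


def apply_to_volume(vol: PAVolume, transform: GeometricTransform,
                    interp: str = "bilinear") -> PAVolume:
    """Warp every time slice with the same lateral 2-D transform."""
    out = np.empty_like(vol.data, dtype=float)
    for k in range(vol.n_time):
        out[:, :, k] = warp_image(vol.lateral_slice(k), transform, interp).T
    return vol.with_data(out)


# ---------------------------------------------------------------------------
# chart registration
# ---------------------------------------------------------------------------

def extract_chart_corners(image: np.ndarray, n_keep: int = 400,
                          mrf: OVMRFConfig | None = None,
                          sobel_radius: int = 2,
                          refine_radius: int = 5) -> tuple[FeaturePointSet, np.ndarray]:
    """Full feature chain on a chart image.

    MRF foreground labelling, Harris corners on the mask, iterated
    intensity-centroid refinement on the grayscale chart, adaptive
    non-maximal suppression, and Sobel two-direction verification.
    Returns the verified corner set and the binary mask used to find it.
    """
    image = np.asarray(image, dtype=float)
    span = image.max() - image.min()
    if span > 0:
        image = (image - image.min()) / span
    mask = ovmrf_label(image, mrf).labels.astype(float)
    pts = harris_corners(mask)
    pts = centroid_refine(image, pts, radius=refine_radius)
    pts = anms(pts, n_keep)
    pts = sobel_verify(mask, pts, radius_px=sobel_radius)
    return pts, mask


def register_chart(distorted: np.ndarray, reference: ReferenceImage,
                   epsilon: float = 0.48, manual: PointPairs | None = None,
                   family: str = "auto", max_dist_px: float | None = None,
                   nmi_bins: int = 2, mrf: OVMRFConfig | None = None,
                   n_keep: int = 400) -> tuple[GeometricTransform, dict]:
    """Estimate the distortion-correcting transform from a chart acquisition.

    Runs the feature chain on both images, matches mutual nearest
    neighbours, fits the transform and accepts it when the NMI between the
    warped chart and the reference reaches ``epsilon``.  If the automatic
    fit falls short and manual pairs are available they are folded in for
    one retry; a persistent failure raises :class:`RegistrationError`
    carrying the diagnostics.
    """
    distorted = np.asarray(distorted, dtype=float)
    ref_img = reference.pixels
    if distorted.shape != ref_img.shape:
        raise ValueError(f"image sizes differ: {distorted.shape} vs {ref_img.shape}")

    src_pts, _ = extract_chart_corners(distorted, n_keep=n_keep, mrf=mrf)
    if len(reference.corner_truth):
        dst_pts = FeaturePointSet(reference.corner_truth,
                                  np.ones(len(reference.corner_truth)))
    else:
        dst_pts, _ = extract_chart_corners(ref_img, n_keep=n_keep, mrf=mrf)

    if max_dist_px is None:
        if len(dst_pts) > 1:
            d = cdist(dst_pts.points, dst_pts.points)
            np.fill_diagonal(d, np.inf)
            max_dist_px = float(np.median(d.min(axis=1)) / 2.0)
        else:
            max_dist_px = max(distorted.shape) / 4.0

    diagnostics = {
        "nmi_initial": metrics.nmi(distorted, ref_img, bins=nmi_bins),
        "n_src_points": len(src_pts),
        "n_dst_points": len(dst_pts),
        "max_dist_px": max_dist_px,
        "attempts": 0,
        "converged": False,
    }

    pairs = match_points(src_pts, dst_pts, max_dist_px)
    attempts = [pairs]
    if manual is not None and len(manual):
        attempts.append(add_manual_pairs(pairs, manual))

    transform = None
    for attempt, p in enumerate(attempts, start=1):
        diagnostics["attempts"] = attempt
        diagnostics["n_pairs"] = len(p)
        diagnostics["n_manual"] = sum(1 for o in p.origin if o == "manual")
        transform = fit_transform(p, family=family)
        warped = warp_image(distorted, transform)
        score = metrics.nmi(warped, ref_img, bins=nmi_bins)
        diagnostics["nmi_final"] = score
        diagnostics["residual_rms"] = transform.residual_rms
        if score >= epsilon:
            diagnostics["converged"] = True
            return transform, diagnostics

    raise RegistrationError(
        f"registration NMI {diagnostics.get('nmi_final', float('nan')):.3f} "
        f"below epsilon {epsilon}", diagnostics)
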