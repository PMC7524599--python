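"""Chart segmentation and corner feature extraction.

The calibration chart is first labelled foreground/background with an
ordinal-valued Markov random field whose per-pixel objective switches
between a data term and an 8-neighbourhood smoothness term,

    E(L_p) = min_w  w |L_p - I_p| + sum_nb ((1-w)/8) |L_p - I_nb|,   w in {0, 1},

with L the binary label field and I the observed image rescaled so that the
bi-Gaussian intensity threshold maps to 1/2.  The labelling is initialized
by thresholding (the recommended pre-division), refined by annealed
stochastic sweeps with Metropolis acceptance, and finished by a greedy
zero-temperature sweep, so the final energy never exceeds the initial one.

Corners of the labelled grid are then detected with the Harris-Stephens
response, spatially spread by adaptive non-maximal suppression, and
verified by requiring that both a fast-axis and a slow-axis Sobel edge pass
near the point (a genuine line intersection).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist
from skimage.feature import corner_harris, corner_peaks

__all__ = [
    "OVMRFConfig",
    "BinaryMask",
    "FeaturePointSet",
    "bigaussian_init",
    "ovmrf_energy",
    "ovmrf_label",
    "harris_corners",
    "anms",
    "sobel_verify",
]


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class OVMRFConfig:
    """Settings of the annealed MRF labelling."""

    mu1: float | None = None          # bi-Gaussian means; estimated when None
    mu2: float | None = None
    max_iter: int = 20                # annealing sweeps
    t0: float | None = None           # initial temperature; default 0.1 * E0 / n_pixels
    decay: float = 0.9                # temperature decay per sweep
    tol: float = 1e-6                 # stop when |dE| falls below tol
    seed: int = 0
    w: float | None = None            # force the switch (w=1: pure data term)

    def __post_init__(self) -> None:
        if self.mu1 is not None and self.mu2 is not None and not (self.mu1 < self.mu2):
            raise ValueError("require mu1 < mu2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.t0 is not None and self.t0 <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class BinaryMask:
    labels: np.ndarray
    energy: float
    energy_initial: float = float("nan")

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")
        if not np.isfinite(self.energy):
            raise ValueError("energy must be finite")


@dataclass
class FeaturePointSet:
    """Detected corners: (row, col) sub-pixel coordinates with responses."""

    points: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.responses = np.asarray(self.responses, dtype=float).ravel()
        if len(self.points) != len(self.responses):
            raise ValueError("points/responses length mismatch")
        if len(self.responses) and not np.all(self.responses > 0):
            raise ValueError("responses must be positive")

    def __len__(self) -> int:
        return len(self.points)

    def subset(self, idx) -> "FeaturePointSet":
        return FeaturePointSet(self.points[idx], self.responses[idx])


# ---------------------------------------------------------------------------
# bi-Gaussian intensity model
# ---------------------------------------------------------------------------

def bigaussian_init(image: np.ndarray, max_iter: int = 200,
                    tol: float = 1e-10) -> tuple[float, float, float]:
    """Fit an equal-variance two-component Gaussian mixture to intensities.

    EM is initialized deterministically at the 25th/75th percentiles.
    Returns ``(mu1, mu2, threshold)`` with ``mu1 < mu2``; the threshold is
    the point of equal posterior probability between the two components.
    """
    x = np.asarray(image, dtype=float).ravel()
    if np.unique(x).size < 2:
        raise ValueError("image has fewer than two distinct values")
    mu = np.percentile(x, [25.0, 75.0]).astype(float)
    if mu[0] == mu[1]:
        mu = np.array([x.min(), x.max()], dtype=float)
    pi = np.array([0.5, 0.5])
    sigma2 = max(x.var() / 4.0, 1e-12)
    for _ in range(max_iter):
        # E-step (log-domain for stability)
        d = (x[:, None] - mu[None, :]) ** 2
        logp = np.log(pi)[None, :] - d / (2.0 * sigma2)
        logp -= logp.max(axis=1, keepdims=True)
        r = np.exp(logp)
        r /= r.sum(axis=1, keepdims=True)
        # M-step, shared variance
        nk = r.sum(axis=0)
        mu_new = (r * x[:, None]).sum(axis=0) / np.maximum(nk, 1e-300)
        sigma2_new = max(float((r * (x[:, None] - mu_new[None, :]) ** 2).sum() / x.size), 1e-12)
        pi_new = nk / x.size
        shift = np.max(np.abs(mu_new - mu))
        mu, sigma2, pi = mu_new, sigma2_new, pi_new
        if shift < tol:
            break
    order = np.argsort(mu)
    mu1, mu2 = float(mu[order[0]]), float(mu[order[1]])
    pi1, pi2 = float(pi[order[0]]), float(pi[order[1]])
    if mu2 - mu1 < 1e-12:
        thr = mu1
    else:
        # equal-posterior crossing of two equal-variance components
        thr = (mu1 + mu2) / 2.0 + sigma2 * np.log(max(pi1, 1e-300) / max(pi2, 1e-300)) / (mu2 - mu1)
        thr = float(np.clip(thr, mu1, mu2))
    return mu1, mu2, thr


# ---------------------------------------------------------------------------
# ordinal-valued MRF
# ---------------------------------------------------------------------------

_SHIFTS = [(dm, dn) for dm in (-1, 0, 1) for dn in (-1, 0, 1) if (dm, dn) != (0, 0)]


def _neighbor_sum_count(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sum of the 8 observed neighbours and the valid-neighbour count."""
    h, w = image.shape
    acc = np.zeros_like(image, dtype=float)
    cnt = np.zeros_like(image, dtype=float)
    for dm, dn in _SHIFTS:
        src = image[max(dm, 0):h + min(dm, 0), max(dn, 0):w + min(dn, 0)]
        tgt_r = slice(max(-dm, 0), h + min(-dm, 0))
        tgt_c = slice(max(-dn, 0), w + min(-dn, 0))
        acc[tgt_r, tgt_c] += src
        cnt[tgt_r, tgt_c] += 1.0
    return acc, cnt


def ovmrf_energy(labels: np.ndarray, image: np.ndarray, w: float) -> float:
    """Objective of a binary labelling against an observed image.

    ``w`` weights the data term; the complementary smoothness term compares
    each label to the observed 8-neighbourhood with per-neighbour weight
    (1-w)/8.  Border pixels use truncated neighbourhoods with the weights
    renormalized to sum to (1-w).
    """
    labels = np.asarray(labels, dtype=float)
    image = np.asarray(image, dtype=float)
    if labels.shape != image.shape:
        raise ValueError(f"shape mismatch {labels.shape} vs {image.shape}")
    if not (0.0 <= w <= 1.0):
        raise ValueError("w must lie in [0, 1]")
    data = np.abs(labels - image).sum()
    # |L - I_nb| summed over neighbours: L is 0/1 so expand the absolute value
    nb_sum, nb_cnt = _neighbor_sum_count(image)
    # for L=1: sum |1 - I_nb| = cnt - nb_sum ; for L=0: sum |I_nb| = nb_sum (image >= 0)
    abs_sum = np.where(labels >= 0.5, nb_cnt - nb_sum, nb_sum)
    smooth = (abs_sum / nb_cnt).sum()
    return float(w * data + (1.0 - w) * smooth)


def _pixel_energies(image: np.ndarray, w: float | None):
    """Per-pixel energies e0/e1 for labels 0/1 under the switch objective."""
    nb_sum, nb_cnt = _neighbor_sum_count(image)
    s0 = nb_sum / nb_cnt          # smoothness cost of label 0
    s1 = 1.0 - s0                 # and of label 1 (image in [0, 1])
    d0 = image
    d1 = 1.0 - image
    if w is None:                 # per-pixel switch: the cheaper branch wins
        e0 = np.minimum(d0, s0)
        e1 = np.minimum(d1, s1)
    else:
        e0 = w * d0 + (1.0 - w) * s0
        e1 = w * d1 + (1.0 - w) * s1
    return e0, e1, s0, s1


def ovmrf_label(image: np.ndarray, cfg: OVMRFConfig | None = None) -> BinaryMask:
    """Label chart foreground by the annealed switch-objective MRF.

    The image must be normalized to [0, 1].  It is affinely rescaled so the
    bi-Gaussian threshold maps to 1/2 (hence the pure-data-term limit
    reproduces plain thresholding exactly), labelled by thresholding, then
    refined by ``max_iter`` annealed Metropolis sweeps and a final greedy
    sweep.  Energy ties are broken toward the smoothness branch, which is
    what removes isolated impulse outliers.
    """
    cfg = cfg or OVMRFConfig()
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D image")
    if image.min() < 0 or image.max() > 1:
        raise ValueError("image must be normalized to [0, 1]")

    if cfg.mu1 is not None and cfg.mu2 is not None:
        thr = (cfg.mu1 + cfg.mu2) / 2.0
    else:
        _, _, thr = bigaussian_init(image)
    thr = float(np.clip(thr, 1e-9, 1.0 - 1e-9))
    # piecewise-linear rescale sending the threshold to 1/2
    scaled = np.where(image <= thr,
                      0.5 * image / thr,
                      0.5 + 0.5 * (image - thr) / (1.0 - thr))

    e0, e1, s0, s1 = _pixel_energies(scaled, cfg.w)
    labels = (scaled > 0.5).astype(np.int8)
    e_cur = np.where(labels == 1, e1, e0)
    energy0 = float(e_cur.sum())

    rng = np.random.default_rng(cfg.seed)
    n_pix = image.size
    temp = cfg.t0 if cfg.t0 is not None else max(0.1 * energy0 / n_pix, 1e-12)
    prev_total = energy0
    for _ in range(cfg.max_iter):
        e_flip = np.where(labels == 1, e0, e1)
        delta = e_flip - e_cur
        accept = (delta < 0) | (rng.random(image.shape) < np.exp(-np.maximum(delta, 0.0) / temp))
        labels = np.where(accept, 1 - labels, labels)
        e_cur = np.where(labels == 1, e1, e0)
        total = float(e_cur.sum())
        temp *= cfg.decay
        if abs(total - prev_total) < cfg.tol:
            prev_total = total
            break
        prev_total = total

    # zero-temperature sweep: exact minimizer of the decoupled objective
    pick1 = e1 < e0
    tie = e1 == e0
    if cfg.w is None:
        # break ties toward the smoothness branch (neighbourhood-consistent label)
        labels = np.where(pick1 | (tie & (s1 < s0)), 1,
                          np.where(tie & (s1 == s0), labels, 0)).astype(np.int8)
    else:
        labels = np.where(pick1 | (tie & (labels == 1)), 1, 0).astype(np.int8)
    energy = float(np.where(labels == 1, e1, e0).sum())
    return BinaryMask(labels=labels.astype(np.uint8), energy=energy, energy_initial=energy0)


# ---------------------------------------------------------------------------
# corners
# ---------------------------------------------------------------------------

def _subpixel_refine(response: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    """Quadratic (parabolic) refinement of peak locations on the response."""
    refined = peaks.astype(float).copy()
    h, w = response.shape
    for idx, (r, c) in enumerate(peaks):
        if 0 < r < h - 1:
            denom = response[r - 1, c] - 2.0 * response[r, c] + response[r + 1, c]
            if denom < 0:
                off = 0.5 * (response[r - 1, c] - response[r + 1, c]) / denom
                refined[idx, 0] = r + np.clip(off, -0.5, 0.5)
        if 0 < c < w - 1:
            denom = response[r, c - 1] - 2.0 * response[r, c] + response[r, c + 1]
            if denom < 0:
                off = 0.5 * (response[r, c - 1] - response[r, c + 1]) / denom
                refined[idx, 1] = c + np.clip(off, -0.5, 0.5)
    return refined


def _merge_clusters(points: np.ndarray, responses: np.ndarray,
                    radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Single-linkage clustering of nearby peaks into weighted centroids.

    A crossing of two finite-width lines produces a symmetric ring of
    Harris maxima around the true intersection; merging each cluster into
    its response-weighted centroid recovers the junction centre.
    """
    n = len(points)
    adj = cdist(points, points) <= radius
    label = np.full(n, -1, dtype=int)
    n_lab = 0
    for i in range(n):
        if label[i] >= 0:
            continue
        stack = [i]
        label[i] = n_lab
        while stack:
            j = stack.pop()
            for m in np.flatnonzero(adj[j]):
                if label[m] < 0:
                    label[m] = n_lab
                    stack.append(m)
        n_lab += 1
    out_pts = np.empty((n_lab, 2))
    out_resp = np.empty(n_lab)
    for lab in range(n_lab):
        idx = label == lab
        w = responses[idx]
        out_pts[lab] = (points[idx] * w[:, None]).sum(axis=0) / w.sum()
        out_resp[lab] = w.max()
    return out_pts, out_resp


def _moment_refine(response: np.ndarray, points: np.ndarray,
                   window: int = 4, rel: float = 0.3) -> np.ndarray:
    """Refine corner locations by thresholded response moments.

    The centroid of the strong response surface in a small window is far
    less sensitive to single-pixel mask defects than the discrete peaks.
    """
    h, w = response.shape
    out = points.copy()
    for idx, (r, c) in enumerate(points):
        r0, c0 = int(round(r)), int(round(c))
        rr, cc = np.mgrid[max(r0 - window, 0):min(r0 + window + 1, h),
                          max(c0 - window, 0):min(c0 + window + 1, w)]
        patch = np.clip(response[rr, cc], 0.0, None)
        if patch.max() <= 0:
            continue
        patch = np.where(patch > rel * patch.max(), patch, 0.0)
        total = patch.sum()
        out[idx] = ((patch * rr).sum() / total, (patch * cc).sum() / total)
    return out


def harris_corners(image: np.ndarray, k: float = 0.04, rel_threshold: float = 0.01,
                   sigma: float = 1.5, merge_radius: float = 5.0) -> FeaturePointSet:
    """Harris-Stephens corner detection with sub-pixel refinement.

    The response R = det(M) - k tr(M)^2 is computed on the structure tensor
    smoothed with a Gaussian of ``sigma`` pixels; local maxima above
    ``rel_threshold * max(R)`` are refined by a separable parabola fit,
    maxima closer than ``merge_radius`` (the split peaks of one line
    junction) are merged into their response-weighted centroid, and each
    merged corner is recentred on the moments of the thresholded response.
    A blank image yields an empty point set.
    """
    if not (0.0 < rel_threshold < 1.0):
        raise ValueError("rel_threshold must be in (0, 1)")
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D image")
    if image.max() == image.min():
        return FeaturePointSet(np.empty((0, 2)), np.empty(0))
    response = corner_harris(image, method="k", k=k, sigma=sigma)
    peaks = corner_peaks(response, min_distance=1,
                         threshold_rel=rel_threshold, threshold_abs=0.0)
    if len(peaks) == 0:
        return FeaturePointSet(np.empty((0, 2)), np.empty(0))
    responses = response[peaks[:, 0], peaks[:, 1]]
    keep = responses > 0
    peaks, responses = peaks[keep], responses[keep]
    if len(peaks) == 0:
        return FeaturePointSet(np.empty((0, 2)), np.empty(0))
    points = _subpixel_refine(response, peaks)
    if merge_radius > 0:
        points, responses = _merge_clusters(points, responses, merge_radius)
        points = _moment_refine(response, points,
                                window=max(2, int(round(merge_radius)) - 1))
    return FeaturePointSet(points, responses)


def centroid_refine(image: np.ndarray, points: FeaturePointSet,
                    radius: int = 5, iters: int = 8,
                    dedup_px: float = 2.0) -> FeaturePointSet:
    """Refine junction locations by iterated intensity centroids.

    For a cross of two lines under symmetric blur, the intensity centroid
    of a window contracts toward the true crossing with every re-centring,
    so a few iterations converge even from ~2 px off.  The window radius
    must stay below half the grid pitch to exclude neighbouring lines.
    Points that converge onto the same junction (within ``dedup_px``) are
    merged, keeping the strongest response.
    """
    if len(points) == 0:
        return points
    img = np.asarray(image, dtype=float)
    img = np.clip(img - np.median(img), 0.0, None)  # suppress the background pedestal
    h, w = img.shape
    pts = points.points.copy()
    for _ in range(iters):
        for idx, (r, c) in enumerate(pts):
            r0, c0 = int(round(r)), int(round(c))
            rr, cc = np.mgrid[max(r0 - radius - 1, 0):min(r0 + radius + 2, h),
                              max(c0 - radius - 1, 0):min(c0 + radius + 2, w)]
            # triangular taper centred on the fractional estimate: keeps the
            # window effectively symmetric, so the fixed point is the true
            # junction rather than the nearest integer pixel
            taper = (np.clip(1.0 - np.abs(rr - r) / (radius + 0.5), 0.0, None)
                     * np.clip(1.0 - np.abs(cc - c) / (radius + 0.5), 0.0, None))
            wts = img[rr, cc] * taper
            total = wts.sum()
            if total > 0:
                pts[idx] = ((wts * rr).sum() / total, (wts * cc).sum() / total)
    merged_pts, merged_resp = _merge_clusters(pts, points.responses, dedup_px)
    return FeaturePointSet(merged_pts, merged_resp)


def anms(points: FeaturePointSet, n_keep: int) -> FeaturePointSet:
    """Adaptive non-maximal suppression.

    Each point's suppression radius is its distance to the nearest strictly
    stronger point (infinite for the global maximum); the ``n_keep`` points
    with the largest radii are retained, which spreads detections evenly.
    """
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    n = len(points)
    if n <= n_keep:
        return points
    d = cdist(points.points, points.points)
    stronger = points.responses[None, :] > points.responses[:, None]
    d = np.where(stronger, d, np.inf)
    radii = d.min(axis=1)
    # sort by radius, break ties by response
    order = np.lexsort((-points.responses, -radii))
    keep = np.sort(order[:n_keep])
    return points.subset(keep)


def sobel_verify(image: np.ndarray, points: FeaturePointSet, radius_px: int = 2,
                 rel_threshold: float = 0.25) -> FeaturePointSet:
    """Keep only points near an intersection of both Sobel edge directions.

    The fast-axis (column-gradient) and slow-axis (row-gradient) Sobel maps
    are binarized at ``rel_threshold`` of their maxima; a point survives iff
    both maps contain an edge pixel within ``radius_px``.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    if len(points) == 0:
        return points
    image = np.asarray(image, dtype=float)
    edge_fast = np.abs(ndimage.sobel(image, axis=1))
    edge_slow = np.abs(ndimage.sobel(image, axis=0))
    fast_hit = edge_fast >= rel_threshold * edge_fast.max() if edge_fast.max() > 0 else np.zeros_like(image, bool)
    slow_hit = edge_slow >= rel_threshold * edge_slow.max() if edge_slow.max() > 0 else np.zeros_like(image, bool)
    h, w = image.shape
    keep = np.zeros(len(points), dtype=bool)
    for i, (r, c) in enumerate(points.points):
        r0, r1 = int(max(0, np.floor(r - radius_px))), int(min(h, np.ceil(r + radius_px) + 1))
        c0, c1 = int(max(0, np.floor(c - radius_px))), int(min(w, np.ceil(c + radius_px) + 1))
        keep[i] = fast_hit[r0:r1, c0:c1].any() and slow_hit[r0:r1, c0:c1].any()
    return points.subset(keep)
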