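"""Independent brute-force reference implementations.

Each function re-derives a quantity with plain loops and no shared code
path with the package, so the fast vectorized implementations can be
checked against them on small inputs.
"""

import numpy as np


def brute_force_joint_counts(a, b, bins):
    """Double-loop joint intensity binning."""
    def edges(x):
        lo, hi = x.min(), x.max()
        if hi <= lo:
            hi = lo + 1.0
        return np.linspace(lo, hi, bins + 1)
    ea, eb = edges(a), edges(b)
    counts = np.zeros((bins, bins), dtype=int)
    for x, y in zip(a.ravel(), b.ravel()):
        i = min(np.searchsorted(ea, x, side="right") - 1, bins - 1)
        j = min(np.searchsorted(eb, y, side="right") - 1, bins - 1)
        counts[max(i, 0), max(j, 0)] += 1
    return counts


def brute_force_entropy(counts):
    total = float(np.sum(counts))
    h = 0.0
    for c in np.asarray(counts, dtype=float).ravel():
        if c > 0:
            p = c / total
            h -= p * np.log2(p)
    return h


def brute_force_mi(a, b, bins):
    counts = brute_force_joint_counts(a, b, bins)
    return (brute_force_entropy(counts.sum(axis=1))
            + brute_force_entropy(counts.sum(axis=0))
            - brute_force_entropy(counts))


def brute_force_nmi(a, b, bins):
    counts = brute_force_joint_counts(a, b, bins)
    ha = brute_force_entropy(counts.sum(axis=1))
    hb = brute_force_entropy(counts.sum(axis=0))
    if ha == 0.0 or hb == 0.0:
        return 0.0
    return (ha + hb - brute_force_entropy(counts)) / np.sqrt(ha * hb)


def brute_force_psnr(img, ref, peak=1.0):
    diff = (np.asarray(img, float) - np.asarray(ref, float)).ravel()
    mse = sum(d * d for d in diff) / diff.size
    return 10.0 * np.log10(peak * peak / mse)


def brute_force_ovmrf_energy(labels, image, w):
    """Double-loop switch-objective evaluation."""
    h, wd = image.shape
    total = 0.0
    for m in range(h):
        for n in range(wd):
            total += w * abs(labels[m, n] - image[m, n])
            nb = []
            for dm in (-1, 0, 1):
                for dn in (-1, 0, 1):
                    if (dm, dn) == (0, 0):
                        continue
                    mm, nn = m + dm, n + dn
                    if 0 <= mm < h and 0 <= nn < wd:
                        nb.append(abs(labels[m, n] - image[mm, nn]))
            total += (1.0 - w) * sum(nb) / len(nb)
    return total


def brute_force_anms(points, responses, n_keep):
    """O(n^2) suppression-radius ranking; returns sorted kept indices."""
    n = len(points)
    radii = np.full(n, np.inf)
    for i in range(n):
        for j in range(n):
            if responses[j] > responses[i]:
                radii[i] = min(radii[i], np.hypot(*(points[i] - points[j])))
    order = sorted(range(n), key=lambda i: (-radii[i], -responses[i]))
    return sorted(order[:n_keep])


def naive_guided_filter(p, guide, radius, eps):
    """Per-window least-squares guided filter."""
    h, w = p.shape

    def box(a):
        out = np.empty_like(a, dtype=float)
        for i in range(h):
            for j in range(w):
                win = a[max(i - radius, 0):i + radius + 1,
                        max(j - radius, 0):j + radius + 1]
                out[i, j] = win.mean()
        return out

    mean_i, mean_p = box(guide), box(p)
    var_i = box(guide * guide) - mean_i ** 2
    cov = box(guide * p) - mean_i * mean_p
    a = cov / (var_i + eps)
    b = mean_p - a * mean_i
    return box(a) * guide + box(b)


def loop_das(vol, geometry, region):
    """Per-voxel triple-loop modified delay-and-sum."""
    from swmpam.deconv import _sensor_distances

    data = vol.data.astype(float)
    nx, ny, nt = data.shape
    d, rho2, x, z, (ox, oy, oz) = _sensor_distances(data.shape, geometry)
    dz = geometry.axial_step_mm
    g = np.abs(np.gradient(data, axis=2) / np.gradient(d, axis=2))
    amp = np.abs(data)
    half = region.half_height_samples(geometry)
    offsets = region.lateral_offsets()
    out = np.zeros_like(data)
    for i in range(nx):
        for j in range(ny):
            for k in range(nt):
                target = d[i, j, k]
                raw_w, contrib = [], []
                for di, dj in offsets:
                    ii, jj = i + di, j + dj
                    if not (0 <= ii < nx and 0 <= jj < ny):
                        continue
                    lo, hi = max(k - half, 0), min(k + half, nt - 1)
                    raw_w.append(amp[ii, jj, lo:hi + 1].mean())
                    under = target ** 2 - rho2[ii, jj]
                    if under < 0:
                        contrib.append(None)
                        continue
                    kf = (oz + np.sqrt(under)) / dz
                    if not (-0.5 <= kf <= nt - 0.5):
                        contrib.append(None)
                        continue
                    kf = min(max(kf, 0.0), nt - 1.0)
                    k0 = int(np.floor(kf))
                    k1 = min(k0 + 1, nt - 1)
                    gv = (1 - (kf - k0)) * g[ii, jj, k0] + (kf - k0) * g[ii, jj, k1]
                    contrib.append(gv * (ox - x[ii]) / target / target)
                raw_w = np.array(raw_w, dtype=float)
                total = raw_w.sum()
                n_valid = len(raw_w)
                gain = total / n_valid if n_valid else 0.0
                w_norm = raw_w / total if total > 0 else np.full(n_valid, 1.0 / n_valid)
                num = wsum = 0.0
                for w, c in zip(w_norm, contrib):
                    if c is None:
                        continue
                    num += w * c
                    wsum += w
                out[i, j, k] = gain * num / wsum if wsum > 0 else 0.0
    return out
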