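"""Joint-histogram information metrics and PSNR.

Mutual information between two images A, B is computed from a joint
intensity histogram: I(A, B) = H(A) + H(B) - H(A; B), all entropies in
bits.  The normalized variant divides by the geometric mean of the marginal
entropies, NMI = I / sqrt(H(A) H(B)), which is bounded by 1 and standard in
registration; an arithmetic-mean normalization is available via ``norm``.
Two binning conventions are used in practice: 256 grey levels for image
comparison and 2 levels for the binary-mask check that gates registration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "JointHistogram",
    "joint_histogram",
    "entropy",
    "mutual_information",
    "nmi",
    "psnr",
]


@dataclass
class JointHistogram:
    counts: np.ndarray  # (bins_A, bins_B): A indexes rows, B columns
    bins: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or np.any(self.counts < 0):
            raise ValueError("joint histogram must be a non-negative 2-D array")
        if self.bins < 2:
            raise ValueError("need at least two bins")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def marginal_a(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def marginal_b(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def _bin_edges(x: np.ndarray, bins: int) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        hi = lo + 1.0  # constant image: all mass falls into the first bin
    return np.linspace(lo, hi, bins + 1)


def joint_histogram(a: np.ndarray, b: np.ndarray, bins: int = 256) -> JointHistogram:
    """Exact joint counts under uniform-width binning per image."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    if bins < 2:
        raise ValueError("need at least two bins")
    counts, _, _ = np.histogram2d(a.ravel(), b.ravel(),
                                  bins=[_bin_edges(a, bins), _bin_edges(b, bins)])
    return JointHistogram(counts=counts.astype(np.int64), bins=bins)


def entropy(counts: np.ndarray) -> float:
    """Shannon entropy in bits of a (1-D or 2-D) histogram; 0 log 0 = 0."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative counts")
    total = counts.sum()
    if total == 0:
        raise ValueError("all-zero histogram")
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 256) -> float:
    """I(A, B) = H(A) + H(B) - H(A; B) in bits, from one joint histogram."""
    jh = joint_histogram(a, b, bins)
    return entropy(jh.marginal_a()) + entropy(jh.marginal_b()) - entropy(jh.counts)


def nmi(a: np.ndarray, b: np.ndarray, bins: int = 256, norm: str = "geometric") -> float:
    """Normalized mutual information; 0 when either image is constant."""
    jh = joint_histogram(a, b, bins)
    ha = entropy(jh.marginal_a())
    hb = entropy(jh.marginal_b())
    if ha == 0.0 or hb == 0.0:
        return 0.0
    i = ha + hb - entropy(jh.counts)
    if norm == "geometric":
        return float(i / np.sqrt(ha * hb))
    if norm == "arithmetic":
        return float(2.0 * i / (ha + hb))
    raise ValueError(f"unknown normalization {norm!r}")


def psnr(img: np.ndarray, ref: np.ndarray, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; identical arrays give +inf."""
    img = np.asarray(img, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if img.shape != ref.shape:
        raise ValueError(f"shape mismatch {img.shape} vs {ref.shape}")
    if peak <= 0:
        raise ValueError("peak must be positive")
    mse = float(np.mean((img - ref) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(peak * peak / mse))
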