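"""Per-section contrast normalization and clustering-based global thresholding.

Electron-dense (DAB/osmium) label is *dark*: the foreground of a binarized
section is the low-intensity pixel set. The global threshold is found by
two-class (Otsu-style) between-class-variance maximization over a fixed
histogram, then modulated downward toward the label's known
contrast-enhanced range: tau' = tau*0.82 if tau < 0.6 else tau*0.86.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass(frozen=True)
class ThresholdParams:
    """Parameters of threshold computation and modulation.

    ``cutoff`` selects the modulation branch (strict ``tau < cutoff`` uses
    ``factor_low``, otherwise ``factor_high``); ``n_bins`` is the histogram
    resolution used both for equalization and for the threshold search.
    """

    cutoff: float = 0.6
    factor_low: float = 0.82
    factor_high: float = 0.86
    n_bins: int = 256

    def __post_init__(self) -> None:
        if not 0.0 < self.cutoff < 1.0:
            raise ValueError(f"cutoff must be in (0, 1), got {self.cutoff}")
        for name in ("factor_low", "factor_high"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")


@dataclass
class SectionImage:
    """One aligned grayscale section with its physical geometry.

    ``z_index`` is the physical section number (0-based; gaps allowed when
    sections are missing or subsampled). ``pixel_pitch`` is (x_nm, y_nm) per
    pixel and ``section_spacing_nm`` the z-distance to the next indexed
    section.
    """

    z_index: int
    pixels: np.ndarray
    pixel_pitch: tuple[float, float] = (20.0, 20.0)
    section_spacing_nm: float = 30.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.z_index < 0:
            raise ValueError(f"z_index must be >= 0, got {self.z_index}")
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a nonempty 2D array")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < 0.0 or hi > 1.0:
            raise ValueError(f"intensities must lie in [0, 1], got range [{lo}, {hi}]")


def equalize_histogram(section: SectionImage, n_bins: int = 256) -> SectionImage:
    """Histogram-equalize one section onto [0, 1].

    The mapping is the image's own cumulative histogram evaluated over
    ``n_bins`` bins on [0, 1] — a monotone non-decreasing function of input
    intensity, so pixel ordering is preserved. A constant image maps to a
    constant image.
    """
    img = section.pixels
    hist, bin_edges = np.histogram(img, bins=n_bins, range=(0.0, 1.0))
    cdf = np.cumsum(hist).astype(float)
    cdf /= cdf[-1]
    # piecewise-constant CDF lookup per bin; np.interp over bin centers
    # would also work but constant lookup keeps the constant-image identity
    idx = np.minimum((img * n_bins).astype(int), n_bins - 1)
    out = cdf[idx]
    return replace(section, pixels=out)


def cluster_threshold(section: SectionImage, params: ThresholdParams = ThresholdParams()) -> float:
    """Two-class (Otsu) global threshold of one section.

    Builds an ``n_bins`` histogram on [0, 1] and returns the interior bin
    edge maximizing the between-class variance
    ``w0*w1*(mu0 - mu1)**2`` of the split ``pixel < edge`` vs
    ``pixel >= edge``. Ties break toward the lowest edge (smaller
    foreground). Raises on a degenerate (single-bin) histogram.
    """
    hist, edges = np.histogram(section.pixels, bins=params.n_bins, range=(0.0, 1.0))
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: image has fewer than 2 distinct intensity bins")
    hist = hist.astype(float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = hist.sum()
    # cumulative class statistics for each interior edge t = edges[1..n-1]:
    # class 0 = bins [0, t), class 1 = bins [t, n)
    w0 = np.cumsum(hist)[:-1]
    w1 = total - w0
    m0 = np.cumsum(hist * centers)[:-1]
    m_total = float((hist * centers).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (m_total - m0) / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between = np.where(np.isfinite(var_between), var_between, -np.inf)
    best = int(np.argmax(var_between))  # argmax takes the first (lowest) maximizer
    return float(edges[1:][best])


def modulate_threshold(tau: float, params: ThresholdParams = ThresholdParams()) -> float:
    """Shift the threshold into the label's contrast-enhanced range.

    tau' = tau*factor_low when tau < cutoff (strict), else tau*factor_high.
    Both factors are <= 1, so modulation only tightens the dark-foreground
    criterion.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must lie in [0, 1], got {tau}")
    if tau < params.cutoff:
        return tau * params.factor_low
    return tau * params.factor_high


def binarize(section: SectionImage, tau_prime: float) -> np.ndarray:
    """Binary foreground mask of electron-dense pixels: intensity <= tau'.

    Pixels exactly at the threshold are foreground (closed lower set).
    """
    if not 0.0 <= tau_prime <= 1.0:
        raise ValueError(f"tau_prime must lie in [0, 1], got {tau_prime}")
    return section.pixels <= tau_prime


def cnr(class1: np.ndarray, class2: np.ndarray) -> float:
    """Contrast-to-noise ratio (mu2 - mu1) / sqrt(sigma2^2 + sigma1^2).

    Means and population standard deviations are computed over the two pixel
    sets. Antisymmetric under class swap. If both sigmas are zero with
    distinct means the result is signed infinity.
    """
    c1 = np.asarray(class1, dtype=float).ravel()
    c2 = np.asarray(class2, dtype=float).ravel()
    if c1.size == 0 or c2.size == 0:
        raise ValueError("both pixel classes must be nonempty")
    mu1, mu2 = c1.mean(), c2.mean()
    v1, v2 = c1.var(), c2.var()
    denom = np.sqrt(v1 + v2)
    if denom == 0.0:
        if mu1 == mu2:
            return 0.0
        return float(np.sign(mu2 - mu1)) * float("inf")
    return float((mu2 - mu1) / denom)
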