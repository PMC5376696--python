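"""Brute-force reference quantification used to cross-check the package.

Everything here loops over every pixel of the image with plain Python /
numpy reductions and shares no code with macrospot.quantify; it exists so
the fast implementation can be checked for exact agreement on small images.
"""

from __future__ import annotations

import numpy as np


def brute_disk_median(image: np.ndarray, center: tuple[float, float],
                      radius: float) -> float:
    vals = [image[r, c]
            for r in range(image.shape[0])
            for c in range(image.shape[1])
            if (r - center[0]) ** 2 + (c - center[1]) ** 2 <= radius ** 2]
    return float(np.median(vals))


def brute_annulus_values(image: np.ndarray, center: tuple[float, float],
                         inner: float, outer: float,
                         excluded: np.ndarray | None = None) -> list[float]:
    vals = []
    for r in range(image.shape[0]):
        for c in range(image.shape[1]):
            d2 = (r - center[0]) ** 2 + (c - center[1]) ** 2
            if inner ** 2 < d2 <= outer ** 2:
                if excluded is not None and excluded[r, c]:
                    continue
                vals.append(float(image[r, c]))
    return vals


def brute_background(image: np.ndarray, center: tuple[float, float],
                     inner: float, outer: float,
                     excluded: np.ndarray | None = None,
                     spread_floor: float = 1e-6) -> tuple[float, float]:
    vals = np.array(brute_annulus_values(image, center, inner, outer,
                                         excluded))
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    return med, max(1.4826 * mad, spread_floor)


def brute_spot_z(image: np.ndarray, center: tuple[float, float],
                 spot_radius: float, inner: float, outer: float,
                 excluded: np.ndarray | None = None,
                 spread_floor: float = 1e-6) -> tuple[float, float, float, float]:
    """(raw, background, spread, z) by exhaustive pixel enumeration."""
    raw = brute_disk_median(image, center, spot_radius)
    bg, spread = brute_background(image, center, inner, outer, excluded,
                                  spread_floor)
    return raw, bg, spread, (raw - bg) / spread
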