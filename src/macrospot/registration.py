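"""Grid registration from the central ink guide dots.

Each 3x3 block carries a high-contrast ink dot at its center. Detection
thresholds the image at a robust multiple of the global background spread,
extracts connected components in the plausible dot-area range, and takes
intensity-weighted centroids. The nominal lattice of block centers is then
fitted to the detected dots with a 6-parameter affine map (membranes scanned
flat show translation, rotation and mild scale only, which an affine absorbs
with a closed-form least-squares solution) using iteratively reweighted least
squares so outlier blobs — smears, merged spots — are down-weighted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .design import ArrayDesign
from .errors import DegenerateFitError, RegistrationError

_MIN_DOTS = 3


@dataclass(frozen=True, eq=False)
class Affine:
    """2-D affine map ``y = matrix @ x + offset`` on (row, col) vectors."""

    matrix: np.ndarray  # (2, 2)
    offset: np.ndarray  # (2,)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix.T + self.offset

    @property
    def determinant(self) -> float:
        return float(np.linalg.det(self.matrix))

    def inverse(self) -> "Affine":
        inv = np.linalg.inv(self.matrix)
        return Affine(inv, -inv @ self.offset)

    @classmethod
    def identity(cls) -> "Affine":
        return cls(np.eye(2), np.zeros(2))

    @classmethod
    def from_pose(cls, *, rotation_deg: float = 0.0, scale: float = 1.0,
                  shift: tuple[float, float] = (0.0, 0.0),
                  center: tuple[float, float] = (0.0, 0.0)) -> "Affine":
        """Similarity transform rotating/scaling about `center`, then
        shifting; convenient for simulating scanned-membrane poses."""
        th = np.deg2rad(rotation_deg)
        m = scale * np.array([[np.cos(th), -np.sin(th)],
                              [np.sin(th), np.cos(th)]])
        ctr = np.asarray(center, dtype=float)
        return cls(m, ctr - m @ ctr + np.asarray(shift, dtype=float))


@dataclass(frozen=True)
class RegistrationResult:
    """Fitted design->image map plus fit diagnostics."""

    transform: Affine
    dot_centers: tuple[tuple[float, float], ...]
    residual_rms: float
    n_dots_used: int


@dataclass(frozen=True)
class SpotRef:
    """A located spot: grid address plus image coordinates.

    position 0 is the block's guide dot (excluded from quantification);
    `in_bounds` is False when the mapped center falls outside the image.
    """

    block_row: int
    block_col: int
    position: int
    center: tuple[float, float]
    in_bounds: bool = True


def _robust_scale(values: np.ndarray) -> float:
    med = np.median(values)
    return 1.4826 * float(np.median(np.abs(values - med)))


def detect_guide_dots(image: np.ndarray, design: ArrayDesign, *,
                      threshold_k: float = 5.0,
                      area_bounds: tuple[float, float] = (0.5, 2.0)
                      ) -> np.ndarray:
    """Find guide-dot centers as an (n, 2) array of (row, col).

    Pixels above ``median + threshold_k * (1.4826 * MAD)`` are segmented into
    connected components; components whose area lies within ``area_bounds``
    times the nominal dot area are kept (protein spots are smaller and fall
    below the lower bound), and each surviving blob contributes its
    background-subtracted intensity-weighted centroid.

    Raises :class:`RegistrationError` when fewer than 3 dots are found.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise RegistrationError("empty image")
    bg = float(np.median(img))
    spread = max(_robust_scale(img.ravel()), 1e-12)
    mask = img > bg + threshold_k * spread

    labels, n = ndimage.label(mask)
    if n == 0:
        raise RegistrationError(
            "no guide dots detected: image has no structure above background")

    nominal_area = np.pi * design.guide_dot_radius ** 2
    lo, hi = area_bounds[0] * nominal_area, area_bounds[1] * nominal_area
    areas = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n + 1))
    keep = np.flatnonzero((areas >= lo) & (areas <= hi)) + 1

    centers = []
    weights = np.clip(img - bg, 0, None)
    for lab in keep:
        sel = labels == lab
        w = weights[sel]
        rr, cc = np.nonzero(sel)
        total = w.sum()
        if total <= 0:
            continue
        centers.append((float((rr * w).sum() / total),
                        float((cc * w).sum() / total)))
    if len(centers) < _MIN_DOTS:
        raise RegistrationError(
            f"only {len(centers)} guide dots detected; need >= {_MIN_DOTS}")
    return np.asarray(centers, dtype=float)


def _nominal_lattice(design: ArrayDesign) -> np.ndarray:
    return np.array([design.block_center(br, bc) for br, bc in design.blocks()])


def _check_noncollinear(points: np.ndarray) -> None:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if len(s) < 2 or s[1] <= 1e-6 * max(s[0], 1.0):
        raise DegenerateFitError(
            "guide dots are collinear; affine fit is underdetermined")


def _wlstsq_affine(nominal: np.ndarray, observed: np.ndarray,
                   weights: np.ndarray) -> Affine:
    a = np.hstack([nominal, np.ones((len(nominal), 1))])
    w = np.sqrt(weights)[:, None]
    sol, *_ = np.linalg.lstsq(a * w, observed * w, rcond=None)
    return Affine(sol[:2].T.copy(), sol[2].copy())


def _irls_fit(nominal: np.ndarray, observed: np.ndarray,
              n_iter: int = 10) -> tuple[Affine, np.ndarray]:
    """Tukey-biweight IRLS affine fit; returns (transform, final weights)."""
    weights = np.ones(len(nominal))
    transform = _wlstsq_affine(nominal, observed, weights)
    for _ in range(n_iter):
        resid = np.linalg.norm(observed - transform(nominal), axis=1)
        sigma = max(_robust_scale(resid), 0.5)  # px floor: sub-pixel inliers
        c = 4.685 * sigma
        weights = np.where(resid < c, (1 - (resid / c) ** 2) ** 2, 0.0)
        if weights.sum() < _MIN_DOTS:
            break
        transform = _wlstsq_affine(nominal, observed, weights)
    return transform, weights


def _initial_indices(dots: np.ndarray, design: ArrayDesign
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Assign each detected dot a (block_row, block_col) index.

    Rotation and pitch are estimated from nearest-neighbour displacements
    (angles folded to [-45, 45) degrees, so any grid orientation up to the
    four-fold symmetry is handled); dots are then de-rotated and their
    coordinates rounded to lattice indices anchored at the grid median.
    Returns (valid mask, (n, 2) integer indices).
    """
    if len(dots) >= 2:
        tree = cKDTree(dots)
        dist, idx = tree.query(dots, k=2)
        disp = dots[idx[:, 1]] - dots
        ang = np.arctan2(disp[:, 0], disp[:, 1])
        ang = (ang + np.pi / 4) % (np.pi / 2) - np.pi / 4
        theta = float(np.median(ang))
        pitch = float(np.median(dist[:, 1]))
    else:
        theta, pitch = 0.0, design.block_pitch
    scale = pitch / design.block_pitch if pitch > 0 else 1.0
    c, s = np.cos(theta), np.sin(theta)
    derot = (dots - dots.mean(axis=0)) @ np.array([[c, s], [-s, c]]).T / scale

    frac = derot / design.block_pitch
    n_rows, n_cols = design.n_block_rows, design.n_block_cols
    ir = np.round(frac[:, 0] - np.median(frac[:, 0]) + (n_rows - 1) / 2)
    ic = np.round(frac[:, 1] - np.median(frac[:, 1]) + (n_cols - 1) / 2)
    valid = (ir >= 0) & (ir < n_rows) & (ic >= 0) & (ic < n_cols)
    return valid, np.column_stack([ir, ic]).astype(int)


def fit_grid(dot_centers: Sequence[tuple[float, float]] | np.ndarray,
             design: ArrayDesign) -> RegistrationResult:
    """Fit the affine map from nominal block centers to detected guide dots.

    Two rounds: an initial correspondence from de-rotated lattice rounding,
    then a re-matching of every dot to its nearest predicted lattice node,
    each followed by a Tukey IRLS affine fit. Outlier dots end with weight 0
    and are excluded from `n_dots_used` and `residual_rms`.
    """
    dots = np.asarray(dot_centers, dtype=float).reshape(-1, 2)
    if len(dots) < _MIN_DOTS:
        raise DegenerateFitError(
            f"need >= {_MIN_DOTS} guide dots, got {len(dots)}")
    _check_noncollinear(dots)

    valid, indices = _initial_indices(dots, design)
    if valid.sum() < _MIN_DOTS:
        raise DegenerateFitError("could not index enough guide dots")
    nominal = (design.margin
               + indices[valid] * design.block_pitch).astype(float)
    _check_noncollinear(nominal)
    transform, _ = _irls_fit(nominal, dots[valid])

    # Re-match: map dots back to the nominal frame, snap to the nearest
    # lattice node; where two dots claim one node keep the nearer.
    lattice = _nominal_lattice(design)
    back = transform.inverse()(dots)
    tree = cKDTree(lattice)
    dist, node = tree.query(back)
    ok = dist <= 0.45 * design.block_pitch
    order = np.argsort(dist)
    claimed: dict[int, int] = {}
    for i in order:
        if ok[i] and node[i] not in claimed:
            claimed[node[i]] = i
    matched = np.fromiter(claimed.values(), dtype=int)
    if len(matched) < _MIN_DOTS:
        raise DegenerateFitError("re-matching left too few guide dots")
    nominal = lattice[[node[i] for i in matched]]
    _check_noncollinear(nominal)
    transform, weights = _irls_fit(nominal, dots[matched])

    if abs(transform.determinant) < 1e-9:
        raise DegenerateFitError("fitted transform is singular")

    used = weights > 0.2
    resid = np.linalg.norm(dots[matched][used] - transform(nominal[used]),
                           axis=1)
    rms = float(np.sqrt(np.mean(resid ** 2))) if used.any() else 0.0
    return RegistrationResult(
        transform=transform,
        dot_centers=tuple((float(r), float(c)) for r, c in dots),
        residual_rms=rms,
        n_dots_used=int(used.sum()),
    )


def locate_spots(result: RegistrationResult, design: ArrayDesign,
                 image_shape: tuple[int, int] | None = None
                 ) -> list[SpotRef]:
    """Map every (block, position) to image coordinates.

    Returns 9 refs per block in row-major block order, positions 0-8;
    position 0 is the guide dot, flagged for downstream exclusion. With
    `image_shape` given, refs whose center falls outside are marked
    ``in_bounds=False`` (a flag, not a failure).
    """
    refs: list[SpotRef] = []
    for br, bc in design.blocks():
        for pos in range(9):
            ctr = result.transform(design.spot_center(br, bc, pos))
            inb = True
            if image_shape is not None:
                inb = bool(0 <= ctr[0] <= image_shape[0] - 1
                           and 0 <= ctr[1] <= image_shape[1] - 1)
            refs.append(SpotRef(br, bc, pos, (float(ctr[0]), float(ctr[1])),
                                in_bounds=inb))
    return refs
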