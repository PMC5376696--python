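"""File formats: single-channel TIFF images in, TSV tables out.

All tables are tab-separated with a header row, UTF-8, '.' decimal —
bit-exact and diff-friendly. Images round-trip through tifffile; the
bit depth of an integer scan is recorded so the saturation flag knows the
representable ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .config import GeometryConfig
from .design import ArrayDesign, CLONE_SLOTS
from .errors import FormatError, InvalidDesignError
from .hits import HitList
from .quantify import SpotQuant
from .registration import RegistrationResult
from .simulate import GroundTruth


@dataclass(frozen=True)
class ScanImage:
    """A loaded scan: pixel data plus the dtype's saturation ceiling
    (None for float images, which have no representable maximum)."""

    data: np.ndarray
    saturation_level: float | None


def read_image(path: str | Path) -> ScanImage:
    """Load a single-channel TIFF (8/16-bit integer or 32/64-bit float)."""
    try:
        arr = tifffile.imread(str(path))
    except Exception as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if arr.ndim != 2:
        raise FormatError(
            f"{path}: expected a single-channel 2-D image, got shape "
            f"{arr.shape}")
    if arr.dtype.kind in "ui":
        ceiling: float | None = float(np.iinfo(arr.dtype).max)
    elif arr.dtype.kind == "f":
        ceiling = None
    else:
        raise FormatError(f"{path}: unsupported pixel type {arr.dtype}")
    return ScanImage(data=arr, saturation_level=ceiling)


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a 2-D array as a single-channel float32 TIFF."""
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise FormatError(f"expected 2-D image, got shape {arr.shape}")
    tifffile.imwrite(str(path), arr.astype(np.float32))


# ----------------------------------------------------------------------
# layout
# ----------------------------------------------------------------------

def write_layout(design: ArrayDesign, path: str | Path) -> None:
    """Write the clone layout: one row per spot (two per clone)."""
    rows = []
    for clone_id, pair in sorted(design.clone_spots().items()):
        for (br, bc, pos) in pair:
            rows.append((clone_id, br, bc, pos))
    df = pd.DataFrame(rows, columns=["clone_id", "block_row", "block_col",
                                     "position"])
    df.to_csv(path, sep="\t", index=False)


def read_layout(path: str | Path, geometry: GeometryConfig | None = None
                ) -> ArrayDesign:
    """Rebuild an ArrayDesign from a layout table plus geometry parameters.

    The block-grid extent, the duplicate pairing and the clone table are all
    inferred from the spot rows; each clone must appear exactly twice within
    one block.
    """
    geometry = geometry or GeometryConfig()
    df = pd.read_csv(path, sep="\t")
    required = {"clone_id", "block_row", "block_col", "position"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: layout needs columns {sorted(required)}")

    pairs: dict[str, list[tuple[int, int, int]]] = {}
    for row in df.itertuples(index=False):
        pairs.setdefault(str(row.clone_id), []).append(
            (int(row.block_row), int(row.block_col), int(row.position)))

    seen_pairs: set[tuple[int, int]] = set()
    for clone, spots in pairs.items():
        if len(spots) != 2:
            raise InvalidDesignError(
                f"clone {clone!r} appears {len(spots)} times; duplex "
                "spotting requires exactly 2")
        (br1, bc1, p1), (br2, bc2, p2) = spots
        if (br1, bc1) != (br2, bc2):
            raise InvalidDesignError(
                f"clone {clone!r} spans blocks; replicates must share one")
        seen_pairs.add(tuple(sorted((p1, p2))))

    # slots ordered by the smaller position of each pair
    duplicate_map = {slot: pair for slot, pair
                     in zip(CLONE_SLOTS, sorted(seen_pairs))}
    pair_to_slot = {pair: slot for slot, pair in duplicate_map.items()}

    clone_table = {}
    for clone, spots in pairs.items():
        (br, bc, p1), (_, _, p2) = spots
        slot = pair_to_slot[tuple(sorted((p1, p2)))]
        clone_table[(br, bc, slot)] = clone

    return ArrayDesign(
        n_block_rows=int(df["block_row"].max()),
        n_block_cols=int(df["block_col"].max()),
        block_pitch=geometry.block_pitch,
        spot_pitch=geometry.spot_pitch,
        spot_radius=geometry.spot_radius,
        guide_dot_radius=geometry.guide_dot_radius,
        margin=geometry.margin,
        duplicate_map=duplicate_map,
        clone_table=clone_table,
    )


# ----------------------------------------------------------------------
# stage tables
# ----------------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, design: ArrayDesign,
                       path: str | Path) -> None:
    """Per-spot truth table: clone_id, address, channel, deposited strength
    (0 for failed deposits)."""
    rows = []
    channels = sorted({ch for per in truth.binder_strength.values()
                       for ch in per}
                      | {f[0] for f in truth.failed_spots})
    for clone_id, pair in sorted(design.clone_spots().items()):
        for channel in channels:
            s = truth.strength(clone_id, channel)
            if s <= 0:
                continue
            for (br, bc, pos) in pair:
                failed = (channel, br, bc, pos) in truth.failed_spots
                rows.append((clone_id, br, bc, pos, channel,
                             0.0 if failed else s))
    df = pd.DataFrame(rows, columns=["clone_id", "block_row", "block_col",
                                     "position", "channel", "strength"])
    df.to_csv(path, sep="\t", index=False)


def write_registration(result: RegistrationResult, path: str | Path) -> None:
    """Audit table: the six affine coefficients and the fit diagnostics."""
    m, t = result.transform.matrix, result.transform.offset
    df = pd.DataFrame([{
        "a_rr": m[0, 0], "a_rc": m[0, 1], "a_cr": m[1, 0], "a_cc": m[1, 1],
        "t_r": t[0], "t_c": t[1],
        "residual_rms": result.residual_rms,
        "n_dots_used": result.n_dots_used,
        "n_dots_detected": len(result.dot_centers),
    }])
    df.to_csv(path, sep="\t", index=False)


def quants_to_frame(quants: Sequence[SpotQuant],
                    design: ArrayDesign) -> pd.DataFrame:
    rows = []
    for q in quants:
        s = q.spot
        rows.append({
            "clone_id": design.clone_at(s.block_row, s.block_col, s.position)
                        or "",
            "block_row": s.block_row, "block_col": s.block_col,
            "position": s.position,
            "raw": q.raw, "background": q.background, "spread": q.spread,
            "z": q.z, "flags": ",".join(sorted(q.flags)),
        })
    return pd.DataFrame(rows, columns=["clone_id", "block_row", "block_col",
                                       "position", "raw", "background",
                                       "spread", "z", "flags"])


def write_quants(quants: Sequence[SpotQuant], design: ArrayDesign,
                 path: str | Path) -> None:
    quants_to_frame(quants, design).to_csv(path, sep="\t", index=False)


def hits_to_frame(hits: HitList) -> pd.DataFrame:
    rows = []
    for rank, e in enumerate(hits.entries, start=1):
        z1 = e.replicate_z[0] if len(e.replicate_z) > 0 else None
        z2 = e.replicate_z[1] if len(e.replicate_z) > 1 else None
        rows.append({
            "rank": rank, "clone_id": e.clone_id, "combined": e.combined,
            "z_rep1": float("nan") if z1 is None else z1,
            "z_rep2": float("nan") if z2 is None else z2,
            "channel": hits.channel,
        })
    return pd.DataFrame(rows, columns=["rank", "clone_id", "combined",
                                       "z_rep1", "z_rep2", "channel"])


def write_hits(hits: HitList, path: str | Path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)
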