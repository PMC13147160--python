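"""Per-cell motility and morphology statistics from binary mask series.

Three quantities are computed per cell from superimposed binary masks:

* **cell deformation area** ``A_CD = Area(C_{t+3min} \\ C_t)`` — the area
  newly occupied after a 3-min interval; for purely translational motion the
  gained area equals the lost area, while asymmetry reflects spreading or
  contraction of the contour;
* **centroid displacement** — the Euclidean distance traveled by the mask
  centroid over the same 3-min interval;
* **circularity index** ``perimeter**2 / (4 * pi * area)`` — 1 for an ideal
  circle, larger for irregular contours.

Intervals are taken at consecutive non-overlapping 3-min boundaries: with a
20-s frame interval that is frame pairs (0, 9), (9, 18), ..., giving six
complete pairs out of a 60-frame recording (the trailing five frames are
unused by design).

Perimeter estimation
--------------------
Naive boundary-pixel counting biases circularity far above 1 even for disks,
so the default estimator measures the length of the 0.5 iso-contour of the
Gaussian-smoothed (sigma = 1 px) binary mask — a sub-pixel level-set contour
that removes rasterization staircasing.  Measured accuracy: disk r=50 px
perimeter +0.3%, circularity +0.9%; 100-px square circularity -1.7%;
2:1 rectangle -1.1%; 10-px square perimeter -8.5% (small axis-aligned
squares lose corner length to the smoothing).  Rasterized disks can land up
to ~2% below circularity 1 (epsilon_raster = 0.02).  A Crofton
multi-directional estimator is available as ``method="crofton"``; its name
is recorded in output metadata either way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.measure import find_contours, label as cc_label, perimeter_crofton

from .masks_io import CellTrack

__all__ = [
    "MotilityRecord",
    "deformation_area",
    "centroid",
    "centroid_displacement",
    "perimeter",
    "circularity_index",
    "compute_motility",
    "DEFAULT_PERIMETER_METHOD",
]

DEFAULT_PERIMETER_METHOD = "smooth_contour"

#: documented raster tolerance on circularity >= 1 for near-circular masks
EPSILON_RASTER = 0.02


def deformation_area(
    mask_t: np.ndarray, mask_t_plus: np.ndarray, pixel_size_um: float = 1.0
) -> float:
    """Area newly occupied at t+1 relative to t, on superimposed binary masks.

    Returns ``|{pixels in mask_t_plus and not in mask_t}| * pixel_size_um**2``.
    The area *lost* is the same call with the masks swapped.
    """
    a = np.asarray(mask_t, dtype=bool)
    b = np.asarray(mask_t_plus, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return float(np.count_nonzero(b & ~a)) * pixel_size_um**2


def centroid(mask: np.ndarray, pixel_size_um: float = 1.0) -> np.ndarray:
    """Unweighted mean of foreground pixel centers, as (x_um, y_um).

    Pixel ``(r, c)`` contributes its center ``((c + 0.5) s, (r + 0.5) s)``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("centroid of an empty mask is undefined")
    rc = np.argwhere(mask).mean(axis=0)
    return np.array([(rc[1] + 0.5) * pixel_size_um, (rc[0] + 0.5) * pixel_size_um])


def _interval_pairs(frames: list[int], stride: int) -> list[tuple[int, int]]:
    first = frames[0]
    pairs = []
    t = first
    while t + stride <= frames[-1]:
        pairs.append((t, t + stride))
        t += stride
    return pairs


def _interval_stride(interval_s: float, frame_interval_s: float) -> int:
    stride = interval_s / frame_interval_s
    if abs(stride - round(stride)) > 1e-9:
        raise ValueError(
            f"interval {interval_s} s is not divisible by frame interval {frame_interval_s} s"
        )
    return int(round(stride))


def centroid_displacement(
    track: CellTrack,
    frame_interval_s: float,
    pixel_size_um: float = 1.0,
    interval_s: float = 180.0,
) -> list[float]:
    """Per-pair centroid displacements (um) at non-overlapping 3-min boundaries."""
    stride = _interval_stride(interval_s, frame_interval_s)
    frames = track.frames
    if (frames[-1] - frames[0]) < stride:
        raise ValueError(
            f"track {track.cell_id} spans {frames[-1] - frames[0]} frames, "
            f"shorter than one {interval_s}-s interval ({stride} frames)"
        )
    out = []
    for t0, t1 in _interval_pairs(frames, stride):
        c0 = centroid(track.masks[t0], pixel_size_um)
        c1 = centroid(track.masks[t1], pixel_size_um)
        out.append(float(np.linalg.norm(c1 - c0)))
    return out


def perimeter(
    mask: np.ndarray,
    pixel_size_um: float = 1.0,
    method: str = DEFAULT_PERIMETER_METHOD,
    sigma_px: float = 1.0,
) -> float:
    """Contour length (um) of a single-component binary mask.

    ``method="smooth_contour"`` (default) measures the 0.5 level-set of the
    sigma-smoothed mask; ``method="crofton"`` uses the 4-direction Crofton
    estimator.  Multi-component masks are rejected: callers pass one cell.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("perimeter of an empty mask is undefined")
    n_comp = cc_label(mask, connectivity=2).max()
    if n_comp != 1:
        raise ValueError(f"mask has {n_comp} components; pass a single cell")
    if method == "crofton":
        return float(perimeter_crofton(mask, directions=4)) * pixel_size_um
    if method != "smooth_contour":
        raise ValueError(f"unknown perimeter method {method!r}")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    cropped = mask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    pad = int(np.ceil(4 * sigma_px)) + 1
    f = gaussian_filter(np.pad(cropped.astype(float), pad), sigma_px)
    length = 0.0
    for c in find_contours(f, 0.5):
        d = np.diff(c, axis=0)
        length += float(np.sqrt((d**2).sum(axis=1)).sum())
    return length * pixel_size_um


def circularity_index(
    mask: np.ndarray,
    pixel_size_um: float = 1.0,
    method: str = DEFAULT_PERIMETER_METHOD,
) -> float:
    """``perimeter**2 / (4 pi area)``: 1 for a circle, larger when irregular.

    Scale-invariant: the pixel size cancels between perimeter and area.
    """
    p = perimeter(mask, pixel_size_um, method=method)
    area = float(np.count_nonzero(mask)) * pixel_size_um**2
    return p**2 / (4.0 * np.pi * area)


@dataclass
class MotilityRecord:
    """Per-cell motility statistics at 3-min intervals.

    ``summaries`` holds the arithmetic means of the listed per-pair /
    per-frame values (the per-cell dots of cohort plots).
    """

    cell_id: int
    interval_pairs: list[tuple[int, int]]
    acd_um2: list[float]
    displacement_um: list[float]
    circularity: list[float]
    units: str = "um"
    perimeter_method: str = DEFAULT_PERIMETER_METHOD
    summaries: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.summaries:
            self.summaries = {
                "n_pairs": float(len(self.interval_pairs)),
                "mean_acd_um2": float(np.mean(self.acd_um2)) if self.acd_um2 else np.nan,
                "mean_displacement_um": float(np.mean(self.displacement_um))
                if self.displacement_um
                else np.nan,
                "mean_circularity": float(np.mean(self.circularity)),
            }


def compute_motility(
    track: CellTrack,
    frame_interval_s: float,
    pixel_size_um: float | None = None,
    interval_s: float = 180.0,
    require_included: bool = True,
    perimeter_method: str = DEFAULT_PERIMETER_METHOD,
) -> MotilityRecord:
    """All three statistics for one tracked cell.

    A_CD and centroid displacement are evaluated on non-overlapping
    ``interval_s`` boundary pairs; circularity per frame.  If
    ``pixel_size_um`` is None, outputs are in pixel units (``units="px"``).
    Tracks that failed the inclusion filter are rejected unless
    ``require_included=False``.
    """
    if require_included and track.inclusion_flags and not track.included:
        failed = [k for k, v in track.inclusion_flags.items() if not v]
        raise ValueError(
            f"track {track.cell_id} failed inclusion criteria {failed}; "
            "pass require_included=False to override"
        )
    units = "um" if pixel_size_um is not None else "px"
    s = pixel_size_um if pixel_size_um is not None else 1.0
    stride = _interval_stride(interval_s, frame_interval_s)
    frames = track.frames
    if (frames[-1] - frames[0]) < stride:
        raise ValueError(
            f"track {track.cell_id} is shorter than one {interval_s}-s interval"
        )
    pairs = _interval_pairs(frames, stride)
    acd = [deformation_area(track.masks[t0], track.masks[t1], s) for t0, t1 in pairs]
    disp = centroid_displacement(track, frame_interval_s, s, interval_s)
    circ = [
        circularity_index(track.masks[f], s, method=perimeter_method) for f in frames
    ]
    return MotilityRecord(
        cell_id=track.cell_id,
        interval_pairs=pairs,
        acd_um2=acd,
        displacement_um=disp,
        circularity=circ,
        units=units,
        perimeter_method=perimeter_method,
    )
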