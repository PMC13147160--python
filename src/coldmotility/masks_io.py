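"""Mask-stack I/O, segmentation, overlap tracking and cell-inclusion filtering.

Conventions (fixed across the package): rasters are indexed (row, col) with
the origin at the top-left, 0-based; the center of pixel ``(r, c)`` sits at
``(x, y) = ((c + 0.5) * pixel_size_um, (r + 0.5) * pixel_size_um)``.
Connected components and "touching" tests use 8-connectivity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from scipy.ndimage import binary_dilation
from skimage.morphology import remove_small_objects

__all__ = [
    "MaskFrame",
    "CellTrack",
    "read_mask_stack",
    "write_mask_stack",
    "segment_frame",
    "build_tracks",
    "filter_tracks",
    "inclusion_report",
]

_SIDECAR_REQUIRED = ("frame_interval_s", "pixel_size_um")
_MIN_OBJECT_PX = 20
_FOOTPRINT_3 = np.ones((3, 3), dtype=bool)

#: Inclusion criteria, in reporting order.
INCLUSION_CRITERIA = ("full_duration", "in_field", "non_overlapping")


@dataclass
class MaskFrame:
    """One time point's label (or binary) raster for one field of view."""

    frame_index: int
    time_s: float
    pixels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ValueError(f"frame {self.frame_index}: raster must be 2-D, got shape {self.pixels.shape}")
        if self.pixels.size == 0:
            raise ValueError(f"frame {self.frame_index}: raster is empty")


@dataclass
class CellTrack:
    """One cell's ordered per-frame binary masks over a contiguous frame range."""

    cell_id: int
    masks: dict[int, np.ndarray]
    inclusion_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def frames(self) -> list[int]:
        return sorted(self.masks)

    @property
    def included(self) -> bool:
        return bool(self.inclusion_flags) and all(self.inclusion_flags.values())

    def __post_init__(self) -> None:
        fr = self.frames
        if fr and fr != list(range(fr[0], fr[-1] + 1)):
            raise ValueError(f"track {self.cell_id}: frame range not contiguous: {fr}")
        for f, m in self.masks.items():
            if not np.any(m):
                raise ValueError(f"track {self.cell_id}: empty mask at frame {f}")


def write_mask_stack(
    path: str | Path,
    stack: np.ndarray,
    frame_interval_s: float,
    pixel_size_um: float,
    sidecar_path: str | Path | None = None,
    extra_sidecar: dict | None = None,
) -> Path:
    """Write a (T, H, W) label stack as multi-page 16-bit TIFF + JSON sidecar.

    Returns the sidecar path (default: ``<path>.json``).
    """
    path = Path(path)
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError(f"stack must be (T, H, W), got shape {stack.shape}")
    tifffile.imwrite(path, stack.astype(np.uint16))
    sidecar = {
        "frame_interval_s": frame_interval_s,
        "pixel_size_um": pixel_size_um,
        "n_frames": int(stack.shape[0]),
        "labels": sorted(int(v) for v in np.unique(stack) if v != 0),
    }
    if extra_sidecar:
        sidecar.update(extra_sidecar)
    sidecar_path = Path(sidecar_path) if sidecar_path else path.with_suffix(path.suffix + ".json")
    sidecar_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return sidecar_path


def read_mask_stack(path: str | Path, sidecar: str | Path | dict) -> list[MaskFrame]:
    """Read a multi-page TIFF mask stack into per-frame :class:`MaskFrame` s.

    ``sidecar`` is a JSON path or an already-parsed dict; it must provide
    ``frame_interval_s`` and ``pixel_size_um``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if not isinstance(sidecar, dict):
        sidecar = json.loads(Path(sidecar).read_text())
    missing = [k for k in _SIDECAR_REQUIRED if k not in sidecar]
    if missing:
        raise ValueError(f"sidecar missing required fields: {missing}")
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(f"expected 2-D pages, got stack shape {stack.shape}")
    if stack.shape[0] < 2:
        raise ValueError(f"mask stack must have >= 2 pages, got {stack.shape[0]}")
    dt = float(sidecar["frame_interval_s"])
    s = float(sidecar["pixel_size_um"])
    return [
        MaskFrame(frame_index=t, time_s=t * dt, pixels=stack[t], pixel_size_um=s)
        for t in range(stack.shape[0])
    ]


def segment_frame(
    gray: np.ndarray, method: str = "otsu", min_object_px: int = _MIN_OBJECT_PX
) -> np.ndarray:
    """Threshold-segment one grayscale frame into a binary cell mask.

    Foreground is the bright phase; holes are filled and objects smaller than
    ``min_object_px`` removed.  A blank (constant) frame yields an empty mask
    with a warning rather than an error.
    """
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError(f"expected a single-channel 2-D raster, got shape {gray.shape}")
    if method != "otsu":
        raise ValueError(f"unknown segmentation method {method!r}")
    if np.ptp(gray) == 0:
        warnings.warn("blank frame: returning empty mask", RuntimeWarning, stacklevel=2)
        return np.zeros(gray.shape, dtype=bool)
    mask = gray > threshold_otsu(gray)
    mask = ndimage.binary_fill_holes(mask)
    return remove_small_objects(mask, min_size=min_object_px, connectivity=2)


def _frame_components(frame: MaskFrame) -> dict[int, np.ndarray]:
    """Per-frame component masks keyed by label.

    Integer-labeled rasters keep their labels; binary rasters are labeled
    with 8-connectivity.
    """
    px = frame.pixels
    if px.dtype == bool or set(np.unique(px)) <= {0, 1}:
        lab = cc_label(px > 0, connectivity=2)
    else:
        lab = px
    return {int(v): lab == v for v in np.unique(lab) if v != 0}


def _centroid_px(mask: np.ndarray) -> np.ndarray:
    rc = np.argwhere(mask)
    return rc.mean(axis=0)


def build_tracks(frames: Sequence[MaskFrame]) -> list[CellTrack]:
    """Link per-frame components into tracks by maximal mask overlap (IoU).

    Components in frame t+1 are matched one-to-one to tracks active at frame
    t, greedily by descending IoU; ties broken by smaller centroid distance,
    then smaller label.  Unmatched components start new tracks; tracks with
    no match end.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to build tracks")
    tracks: list[CellTrack] = []
    active: dict[int, np.ndarray] = {}  # track idx -> last mask
    comps0 = _frame_components(frames[0])
    for lab in sorted(comps0):
        tracks.append(CellTrack(cell_id=len(tracks), masks={0: comps0[lab]}))
        active[len(tracks) - 1] = comps0[lab]

    for t in range(1, len(frames)):
        comps = _frame_components(frames[t])
        candidates = []
        for lab in sorted(comps):
            cmask = comps[lab]
            csum = cmask.sum()
            ccen = _centroid_px(cmask)
            for tid, pmask in active.items():
                inter = np.count_nonzero(cmask & pmask)
                if inter == 0:
                    continue
                iou = inter / (csum + pmask.sum() - inter)
                dist = float(np.linalg.norm(ccen - _centroid_px(pmask)))
                candidates.append((-iou, dist, lab, tid))
        candidates.sort()
        new_active: dict[int, np.ndarray] = {}
        used_labels: set[int] = set()
        for _negiou, _dist, lab, tid in candidates:
            if lab in used_labels or tid not in active or tid in new_active:
                continue
            used_labels.add(lab)
            tracks[tid].masks[t] = comps[lab]
            new_active[tid] = comps[lab]
        for lab in sorted(comps):
            if lab not in used_labels:
                tracks.append(CellTrack(cell_id=len(tracks), masks={t: comps[lab]}))
                new_active[len(tracks) - 1] = comps[lab]
        active = new_active
    return tracks


def filter_tracks(
    tracks: Sequence[CellTrack],
    frames: Sequence[MaskFrame],
    min_gap_px: int = 2,
) -> list[CellTrack]:
    """Set per-criterion inclusion flags on every track.

    A track is included iff it (a) spans every frame of the recording
    (``full_duration``), (b) never touches the raster border (``in_field``),
    and (c) never comes within ``min_gap_px`` pixels (Chebyshev) of another
    cell's mask (``non_overlapping``; operationalized as unit dilations of
    both masks not intersecting, i.e. an 8-connectivity gap of >= 2 px).
    Flags are set on (copies of) all tracks so excluded cells stay reportable.
    The operation is idempotent and order-independent over tracks.
    """
    n_frames = len(frames)
    out: list[CellTrack] = []
    dilated: dict[int, dict[int, np.ndarray]] = {}
    for tr in tracks:
        dilated[tr.cell_id] = {}
        for f, m in tr.masks.items():
            dilated[tr.cell_id][f] = binary_dilation(
                m, structure=_FOOTPRINT_3, iterations=max(1, min_gap_px - 1)
            )

    for tr in tracks:
        flags = {}
        flags["full_duration"] = tr.frames == list(range(n_frames))
        border = False
        proximate = False
        for f, m in tr.masks.items():
            if m[0, :].any() or m[-1, :].any() or m[:, 0].any() or m[:, -1].any():
                border = True
            own = dilated[tr.cell_id][f]
            for other in tracks:
                if other.cell_id == tr.cell_id or f not in other.masks:
                    continue
                if np.any(own & dilated[other.cell_id][f]):
                    proximate = True
                    break
            if border and proximate:
                break
        flags["in_field"] = not border
        flags["non_overlapping"] = not proximate
        out.append(CellTrack(cell_id=tr.cell_id, masks=dict(tr.masks), inclusion_flags=flags))
    return out


def inclusion_report(tracks: Sequence[CellTrack]) -> pd.DataFrame:
    """Long-format per-criterion pass/fail table for all tracks."""
    rows = [
        (tr.cell_id, crit, bool(tr.inclusion_flags.get(crit, False)))
        for tr in tracks
        for crit in INCLUSION_CRITERIA
    ]
    return pd.DataFrame(rows, columns=["cell_id", "criterion", "passed"])
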