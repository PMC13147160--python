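"""Ground-truthed synthetic inputs for the motility, flux and DE pipelines.

The motility generator emulates amoeboid T cells crawling on a glass-bottom
dish: each cell is a closed contour whose radius fluctuates around a base
radius (membrane protrusion/retraction) while its centroid performs a
persistent random walk.  Crawling speed and protrusion amplitude are the two
independently tunable knobs that a temperature / cold-acclimation condition
maps onto: warm or acclimated cells are fast and ruffly, acutely cooled cells
are slow and round.

Shape model
-----------
The contour of cell *i* at frame *t* is the polar curve

    r(theta, t) = R * (1 + sum_k a_k(t) * cos(k*theta + phi_k)),   k = 2..K+1

with ``R = base_radius_um``.  Each mode amplitude ``a_k`` follows a
stationary Ornstein--Uhlenbeck process with relaxation rate
``protrusion_rate_per_min`` and stationary standard deviation
``protrusion_amplitude / k`` (higher modes are weaker, as for real membrane
fluctuation spectra).  Mode k = 1 is deliberately excluded: it mostly
translates the contour, so with k >= 2 the programmed walk position stays the
contour centroid to first order and can serve as centroid ground truth.

Motion model
------------
A persistent random walk: the per-frame step length is deterministic,
``mean_speed_um_per_min * frame_interval_s / 60``, and the heading receives a
Gaussian turn of standard deviation ``(1 - persistence) * pi`` per frame.
``persistence = 1`` is the exact ballistic limit (collinear path, displacement
= speed x time); ``persistence = 0`` decorrelates the heading within a frame.

Randomness
----------
One root seed per config.  Every cell draws from its own child stream derived
via ``numpy.random.SeedSequence((seed, cell_index, stream))`` (stream 0 =
shape, 1 = path, 2 = placement), so adding a cell never perturbs the cells
already generated and identical config + seed is bit-identical.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from scipy.ndimage import binary_dilation
from skimage.draw import polygon as draw_polygon

__all__ = [
    "MotilitySimConfig",
    "GroundTruth",
    "FLUX_PHASES",
    "simulate_shape_series",
    "simulate_track",
    "rasterize_movie",
    "simulate_flux_trace",
    "simulate_de_table",
]

#: Injection phases of a mitochondrial stress test, in assay order.
FLUX_PHASES = ("basal", "oligomycin", "FCCP", "rotAA")

_N_CONTOUR_POINTS = 96
_RADIUS_FLOOR_FRACTION = 0.2


@dataclass(frozen=True)
class MotilitySimConfig:
    """Parameters of one synthetic time-lapse condition.

    Defaults mirror a 20-min recording at 20-s intervals with a 40x
    objective-scale pixel (0.25 um/px) of ~10-um-diameter T cells.
    """

    n_cells: int = 10
    n_frames: int = 60
    frame_interval_s: float = 20.0
    pixel_size_um: float = 0.25
    field_size_px: tuple[int, int] = (512, 512)
    mean_speed_um_per_min: float = 2.0
    persistence: float = 0.5
    protrusion_amplitude: float = 0.2
    protrusion_rate_per_min: float = 2.0
    base_radius_um: float = 5.0
    n_fourier_modes: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError(f"n_frames must be >= 2, got {self.n_frames}")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if not 0.0 <= self.persistence <= 1.0:
            raise ValueError(f"persistence must lie in [0, 1], got {self.persistence}")
        if self.base_radius_um <= 0:
            raise ValueError("base_radius_um must be > 0")
        if self.protrusion_amplitude < 0:
            raise ValueError("protrusion_amplitude must be >= 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    def with_(self, **kwargs) -> "MotilitySimConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Programmed truth accompanying a rasterized movie.

    paths_um
        cell_id -> (n_frames, 2) array of programmed centroid positions,
        columns (x_um, y_um) in the field frame.
    gained_area_um2
        cell_id -> (n_frames - 1,) array of true polygon set-difference areas
        Area(C_{t+1} \\ C_t) computed from the continuous contours (shapely),
        independent of rasterization.
    labels
        cell_id -> integer label used in the mask stack (same in every frame).
    """

    paths_um: dict[int, np.ndarray] = field(default_factory=dict)
    gained_area_um2: dict[int, np.ndarray] = field(default_factory=dict)
    labels: dict[int, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (cell_id, frame, x_um, y_um) for CSV export."""
        rows = []
        for cid, path in self.paths_um.items():
            for t, (x, y) in enumerate(path):
                rows.append((cid, t, x, y))
        return pd.DataFrame(rows, columns=["cell_id", "frame", "x_um", "y_um"])


def _rng(config: MotilitySimConfig, cell_index: int, stream: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence((config.seed, cell_index, stream)))
    )


def simulate_shape_series(
    config: MotilitySimConfig, cell_index: int
) -> np.ndarray:
    """Simulate one cell's fluctuating contour, one closed polygon per frame.

    Returns an array of shape ``(n_frames, N, 2)`` of (x_um, y_um) vertices
    relative to the programmed centroid.  With ``protrusion_amplitude == 0``
    every frame is an exact circle of ``base_radius_um``.
    """
    if not 0 <= cell_index < config.n_cells:
        raise ValueError(f"cell_index {cell_index} out of range for n_cells={config.n_cells}")
    rng = _rng(config, cell_index, stream=0)
    R = config.base_radius_um
    modes = np.arange(2, 2 + config.n_fourier_modes)
    sd = config.protrusion_amplitude / modes
    phases = rng.uniform(0.0, 2 * np.pi, size=len(modes))

    lam = config.protrusion_rate_per_min / 60.0  # 1/s
    dt = config.frame_interval_s
    rho = np.exp(-lam * dt)
    innov = np.sqrt(1.0 - rho**2)

    theta = np.linspace(0.0, 2 * np.pi, _N_CONTOUR_POINTS, endpoint=False)
    basis = np.cos(np.outer(modes, theta) + phases[:, None])  # (K, N)

    a = sd * rng.standard_normal(len(modes))  # stationary start
    contours = np.empty((config.n_frames, _N_CONTOUR_POINTS, 2))
    clamped = False
    for t in range(config.n_frames):
        if t > 0:
            a = rho * a + sd * innov * rng.standard_normal(len(modes))
        r = R * (1.0 + a @ basis)
        floor = _RADIUS_FLOOR_FRACTION * R
        if np.any(r < floor):
            clamped = True
            r = np.maximum(r, floor)
        contours[t, :, 0] = r * np.cos(theta)
        contours[t, :, 1] = r * np.sin(theta)
    if clamped:
        warnings.warn(
            "protrusion amplitude drove the contour radius below "
            f"{_RADIUS_FLOOR_FRACTION:.1f}*base_radius; radius clamped",
            RuntimeWarning,
            stacklevel=2,
        )
    return contours


def simulate_track(config: MotilitySimConfig, cell_index: int) -> np.ndarray:
    """Simulate one cell's centroid path as a persistent random walk.

    Returns ``(n_frames, 2)`` positions in um, starting at the origin.  The
    per-frame step length equals ``mean_speed_um_per_min * frame_interval / 60``
    so the frame-to-frame speed is exactly the configured mean.
    """
    if not 0 <= cell_index < config.n_cells:
        raise ValueError(f"cell_index {cell_index} out of range for n_cells={config.n_cells}")
    rng = _rng(config, cell_index, stream=1)
    step = config.mean_speed_um_per_min * config.frame_interval_s / 60.0
    turn_sd = (1.0 - config.persistence) * np.pi

    heading = rng.uniform(0.0, 2 * np.pi)
    turns = turn_sd * rng.standard_normal(config.n_frames - 1)
    headings = heading + np.concatenate([[0.0], np.cumsum(turns)])
    steps = step * np.column_stack([np.cos(headings), np.sin(headings)])
    # origin followed by the cumulative sum of the first n_frames - 1 steps
    path = np.vstack([[0.0, 0.0], np.cumsum(steps[: config.n_frames - 1], axis=0)])
    return path


def _cell_polygons(
    contours: np.ndarray, path: np.ndarray, offset_um: np.ndarray
) -> list[np.ndarray]:
    """Absolute (x_um, y_um) polygons for one cell, one per frame."""
    return [contours[t] + path[t] + offset_um for t in range(len(path))]


def _rasterize_polygon(
    poly_um: np.ndarray, pixel_size_um: float, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    # pixel (r, c) center sits at (x, y) = ((c + .5) s, (r + .5) s)
    rr, cc = draw_polygon(
        poly_um[:, 1] / pixel_size_um - 0.5,
        poly_um[:, 0] / pixel_size_um - 0.5,
        shape=shape,
    )
    return rr, cc


def rasterize_movie(
    config: MotilitySimConfig,
    contours: Sequence[np.ndarray] | None = None,
    paths: Sequence[np.ndarray] | None = None,
    max_placement_retries: int = 500,
) -> tuple[np.ndarray, GroundTruth]:
    """Rasterize all cells into a labeled mask stack plus ground truth.

    Contours/paths default to freshly simulated ones from ``config``.  Each
    cell is placed at a uniformly random offset such that its whole-movie
    footprint (dilated by 2 px) stays inside the field and never comes within
    2 px (Chebyshev) of any other cell in any frame, so masks can never touch
    under 8-connectivity.  Cells are labeled ``cell_index + 1``.
    """
    if contours is None:
        contours = [simulate_shape_series(config, i) for i in range(config.n_cells)]
    if paths is None:
        paths = [simulate_track(config, i) for i in range(config.n_cells)]
    if len(contours) != len(paths):
        raise ValueError("contours and paths must have the same length")
    for c, p in zip(contours, paths):
        if len(c) != len(p):
            raise ValueError("per-cell contour series and path must have equal length")

    H, W = config.field_size_px
    s = config.pixel_size_um
    n_frames = config.n_frames
    stack = np.zeros((n_frames, H, W), dtype=np.uint16)
    footprint_3 = np.ones((3, 3), dtype=bool)
    # occupancy map of already-placed cells, dilated so a 2 px gap is kept
    occupied = np.zeros((H, W), dtype=bool)
    truth = GroundTruth()

    margin_px = 2
    for i, (cont, path) in enumerate(zip(contours, paths)):
        rng = _rng(config, i, stream=2)
        rel = [cont[t] + path[t] for t in range(n_frames)]
        all_xy = np.concatenate(rel, axis=0)
        lo = all_xy.min(axis=0)
        hi = all_xy.max(axis=0)
        extent = hi - lo
        free_x = W * s - extent[0] - 2 * margin_px * s
        free_y = H * s - extent[1] - 2 * margin_px * s
        if free_x <= 0 or free_y <= 0:
            raise ValueError(
                f"field {config.field_size_px} px is too small to contain cell {i}: "
                f"trajectory extent {extent / s} px plus margins exceeds the field"
            )
        placed = False
        for _ in range(max_placement_retries):
            off = np.array(
                [
                    margin_px * s - lo[0] + rng.uniform(0.0, free_x),
                    margin_px * s - lo[1] + rng.uniform(0.0, free_y),
                ]
            )
            frames_rc = [
                _rasterize_polygon(poly + off, s, (H, W))
                for poly in rel
            ]
            union = np.zeros((H, W), dtype=bool)
            for rr, cc in frames_rc:
                union[rr, cc] = True
            grown = binary_dilation(union, structure=footprint_3, iterations=2)
            if not np.any(grown & occupied):
                occupied |= grown
                for t, (rr, cc) in enumerate(frames_rc):
                    stack[t, rr, cc] = i + 1
                truth.paths_um[i] = path + off
                truth.labels[i] = i + 1
                polys = [Polygon(poly + off) for poly in rel]
                gained = np.array(
                    [
                        polys[t + 1].difference(polys[t]).area
                        for t in range(n_frames - 1)
                    ]
                )
                truth.gained_area_um2[i] = gained
                placed = True
                break
        if not placed:
            raise ValueError(
                f"could not place cell {i} without contact after "
                f"{max_placement_retries} retries: field {config.field_size_px} px is "
                f"too crowded for {config.n_cells} cells with this motion range"
            )
    return stack, truth


def simulate_flux_trace(
    phase_levels: Mapping[str, float],
    n_cycles_per_phase: int = 3,
    noise_sd: float = 0.0,
    protein_ug: float = 10.0,
    seed: int = 0,
    well: str = "A1",
    ecar_levels: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Simulate one well's OCR/ECAR trace over the four injection phases.

    ``phase_levels`` maps each of basal, oligomycin, FCCP, rotAA to its true
    OCR level (pmol O2/min).  Measurements are the level plus Gaussian noise
    of ``noise_sd``; a cycle is 3 min mixing + 3 min measurement, so cycle c
    is stamped at ``6 * c`` minutes.  With ``noise_sd = 0`` every measurement
    equals its phase level exactly.
    """
    missing = [p for p in FLUX_PHASES if p not in phase_levels]
    if missing:
        raise ValueError(f"phase_levels missing phases: {missing}")
    for p in FLUX_PHASES:
        if phase_levels[p] < 0:
            raise ValueError(f"phase level for {p!r} must be >= 0, got {phase_levels[p]}")
    if n_cycles_per_phase < 1:
        raise ValueError("n_cycles_per_phase must be >= 1")
    if protein_ug <= 0:
        raise ValueError("protein_ug must be > 0")
    if ecar_levels is None:
        # descriptive-only glycolysis proxy: flat base with a post-oligomycin rise
        base = 10.0
        ecar_levels = {"basal": base, "oligomycin": 1.5 * base, "FCCP": 1.5 * base, "rotAA": 1.2 * base}

    well_key = zlib.crc32(well.encode("utf-8"))  # stable across processes
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, well_key))))
    rows = []
    cycle = 0
    for phase in FLUX_PHASES:
        for _ in range(n_cycles_per_phase):
            cycle += 1
            ocr = phase_levels[phase] + noise_sd * rng.standard_normal()
            ecar = ecar_levels[phase] + 0.2 * noise_sd * rng.standard_normal()
            rows.append((well, cycle, phase, 6.0 * cycle, ocr, ecar, protein_ug))
    return pd.DataFrame(
        rows, columns=["well", "cycle", "phase", "time_min", "ocr", "ecar", "protein_ug"]
    )


def simulate_de_table(
    n_genes: int,
    n_up: int,
    n_down: int,
    lfc_effect: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a per-gene DE result table (gene_id, log2fc, pvalue).

    The first ``n_up`` genes are spiked up (log2FC >= lfc_effect, p ~ 1e-8 or
    smaller), the next ``n_down`` down; the rest are null with |log2FC| ~
    N(0, 0.3) and uniform p-values, so after BH correction the null genes are
    FDR-controlled and essentially never pass the joint |log2FC| >= 1,
    FDR < 0.05 rule.
    """
    if n_up + n_down > n_genes:
        raise ValueError("n_up + n_down must not exceed n_genes")
    if lfc_effect <= 1:
        raise ValueError("lfc_effect must be > 1 so spiked genes clear the |log2FC| >= 1 rule")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, 0xDE))))

    n_null = n_genes - n_up - n_down
    lfc = np.concatenate(
        [
            lfc_effect + np.abs(0.5 * rng.standard_normal(n_up)),
            -(lfc_effect + np.abs(0.5 * rng.standard_normal(n_down))),
            0.3 * rng.standard_normal(n_null),
        ]
    )
    pval = np.concatenate(
        [
            10.0 ** (-rng.uniform(8.0, 30.0, size=n_up + n_down)),
            rng.uniform(0.0, 1.0, size=n_null),
        ]
    )
    table = pd.DataFrame(
        {
            "gene_id": [f"gene{i:06d}" for i in range(n_genes)],
            "log2fc": lfc,
            "pvalue": pval,
        }
    )
    # shuffle so spiked genes are not positionally identifiable downstream
    order = rng.permutation(n_genes)
    return table.iloc[order].reset_index(drop=True)
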