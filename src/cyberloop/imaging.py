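"""Microscopy quantification chain.

Synthetic phase-contrast/fluorescence frame rendering plus the
segmentation pipeline used as the loop's sensor: Otsu binarization of
the phase image, convex hulls of the connected foreground components to
limit the search, a circular Hough transform for cell centers and radii,
and population-average fluorescence over the detected-cell mask.

Rendering emulates a yeast monolayer in the trap: dark roughly circular
cell bodies with a bright phase halo on a gray background, and a
fluorescence channel where each cell glows at its expression level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from matplotlib.path import Path as MplPath
from scipy.spatial import ConvexHull, QhullError
from skimage import feature, measure, transform
from skimage.draw import disk as disk_coords
import imageio.v3 as iio


# --------------------------------------------------------------------------
# synthetic scenes
# --------------------------------------------------------------------------

@dataclass
class SyntheticScene:
    """Ground-truth description of one rendered frame.

    ``cells`` rows are (center_row, center_col, radius_px, intensity).
    """

    shape: tuple[int, int]
    cells: np.ndarray                  # (n, 4)
    background_phase: float = 0.55
    cell_body: float = 0.25
    halo: float = 0.85
    background_fluo: float = 0.02
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=float).reshape(-1, 4)
        if np.any(self.cells[:, 2] <= 0):
            raise ValueError("cell radii must be positive")
        if np.any(self.cells[:, 3] < 0):
            raise ValueError("fluorescence intensities must be >= 0")
        h, w = self.shape
        r, c = self.cells[:, 0], self.cells[:, 1]
        if np.any((r < 0) | (r >= h) | (c < 0) | (c >= w)):
            raise ValueError("cell centers must lie inside the frame")

    @property
    def true_mean_fluorescence(self) -> float:
        """Mean per-cell intensity (the quantity the pipeline reads
        out as the population average)."""
        if self.cells.shape[0] == 0:
            return 0.0
        return float(np.mean(self.cells[:, 3]))


def random_scene(n_cells: int, seed: int, shape: tuple[int, int] = (256, 256),
                 radius_range: tuple[float, float] = (5.0, 8.0),
                 intensity_mean: float = 0.6, intensity_cv: float = 0.1,
                 contact: float = 0.0, noise_sd: float = 0.02,
                 max_tries: int = 20000) -> SyntheticScene:
    """Seeded random monolayer scene.

    Cells are placed by rejection sampling with a minimum center
    distance of ``(1 - contact) * (r_i + r_j)``; ``contact = 0`` keeps
    cells just touching at most.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    rows, cols, radii = [], [], []
    tries = 0
    while len(rows) < n_cells and tries < max_tries:
        tries += 1
        r_px = rng.uniform(*radius_range)
        margin = r_px + 2
        cr = rng.uniform(margin, h - margin)
        cc = rng.uniform(margin, w - margin)
        ok = True
        for r0, c0, rr in zip(rows, cols, radii):
            min_d = (1.0 - contact) * (rr + r_px)
            if (cr - r0) ** 2 + (cc - c0) ** 2 < min_d ** 2:
                ok = False
                break
        if ok:
            rows.append(cr)
            cols.append(cc)
            radii.append(r_px)
    if len(rows) < n_cells:
        raise RuntimeError(f"could only place {len(rows)} of {n_cells} cells; "
                           "enlarge the frame or allow more contact")
    inten = np.maximum(
        rng.normal(intensity_mean, intensity_cv * intensity_mean, n_cells),
        0.05)
    cells = np.column_stack([rows, cols, radii, inten])
    return SyntheticScene(shape=shape, cells=cells, noise_sd=noise_sd,
                          seed=seed)


@dataclass
class ImagePair:
    """Matched phase-contrast and fluorescence rasters."""

    phase: np.ndarray
    fluo: np.ndarray

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        self.fluo = np.asarray(self.fluo, dtype=float)
        if self.phase.shape != self.fluo.shape:
            raise ValueError("phase and fluorescence images must have equal "
                             "shapes")
        if not (np.all(np.isfinite(self.phase))
                and np.all(np.isfinite(self.fluo))):
            raise ValueError("images must be finite")

    @classmethod
    def read(cls, phase_path: str | Path, fluo_path: str | Path) -> "ImagePair":
        def load(p):
            raw = np.asarray(iio.imread(p))
            img = raw.astype(float)
            if img.ndim == 3:
                img = img.mean(axis=2)
            if np.issubdtype(raw.dtype, np.integer):
                img = img / np.iinfo(raw.dtype).max
            return img
        return cls(load(phase_path), load(fluo_path))

    def write(self, phase_path: str | Path, fluo_path: str | Path) -> None:
        for img, path in ((self.phase, phase_path), (self.fluo, fluo_path)):
            arr = np.clip(img, 0.0, 1.0)
            iio.imwrite(path, (arr * 65535).astype(np.uint16))


def render_scene(scene: SyntheticScene) -> ImagePair:
    """Render the phase/fluorescence pair (deterministic under the
    scene's seed).

    Phase: dark cell bodies with a one-pixel bright halo ring on a gray
    background.  Fluorescence: each cell's disk at its intensity.
    Overlapping cells are rendered anyway — monolayer crowding is
    realistic; later cells overwrite earlier pixels.
    """
    h, w = scene.shape
    phase = np.full((h, w), scene.background_phase)
    fluo = np.full((h, w), scene.background_fluo)
    for cr, cc, r_px, inten in scene.cells:
        rr, cc_ = disk_coords((cr, cc), r_px, shape=(h, w))
        phase[rr, cc_] = scene.cell_body
        fluo[rr, cc_] = inten
        ring, ringc = disk_coords((cr, cc), r_px + 1.5, shape=(h, w))
        d = np.hypot(ring - cr, ringc - cc)
        on_rim = d >= r_px
        phase[ring[on_rim], ringc[on_rim]] = scene.halo
    rng = np.random.default_rng(scene.seed)
    if scene.noise_sd > 0:
        phase = phase + rng.normal(0.0, scene.noise_sd, phase.shape)
        fluo = fluo + rng.normal(0.0, scene.noise_sd, fluo.shape)
    return ImagePair(phase, fluo)


# --------------------------------------------------------------------------
# Otsu threshold
# --------------------------------------------------------------------------

def otsu_threshold(image: np.ndarray) -> float:
    """Threshold maximizing between-class variance over the exact value
    histogram.

    Computed directly on the sorted distinct pixel values (no fixed-bin
    quantization), so adding a constant to every pixel shifts the
    threshold by exactly that constant.  The returned threshold is the
    midpoint of the optimal class gap; classify as ``image > t``.
    """
    values, counts = np.unique(np.asarray(image).ravel(), return_counts=True)
    if values.size < 2:
        raise ValueError("Otsu threshold is undefined for a constant image")
    w = counts.astype(float)
    total = w.sum()
    cum_w = np.cumsum(w)[:-1]                       # class 0: values[:i+1]
    cum_m = np.cumsum(w * values)[:-1]
    mean = float((w * values).sum() / total)
    w0 = cum_w / total
    w1 = 1.0 - w0
    mu0 = cum_m / cum_w
    mu1 = (mean * total - cum_m) / (total - cum_w)
    between = w0 * w1 * (mu0 - mu1) ** 2
    i = int(np.argmax(between))
    return float(0.5 * (values[i] + values[i + 1]))


# --------------------------------------------------------------------------
# convex hulls of foreground components
# --------------------------------------------------------------------------

def convex_hull_regions(binary_mask: np.ndarray,
                        min_area: int = 4) -> list[np.ndarray]:
    """Convex hull polygon of every connected foreground component.

    Returns one ``(k, 2)`` array of hull vertices (row, col) per
    component, in component-label order; degenerate (collinear)
    components fall back to their bounding-box corners.  An empty mask
    yields an empty list.
    """
    mask = np.asarray(binary_mask).astype(bool)
    labels = measure.label(mask, connectivity=2)
    hulls: list[np.ndarray] = []
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        pts = region.coords.astype(float)
        try:
            hull = ConvexHull(pts)
            hulls.append(pts[hull.vertices])
        except QhullError:
            r0, c0, r1, c1 = region.bbox
            hulls.append(np.array([[r0, c0], [r0, c1 - 1],
                                   [r1 - 1, c1 - 1], [r1 - 1, c0]], float))
    return hulls


# --------------------------------------------------------------------------
# circular Hough transform
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ImagingConfig:
    """Pipeline knobs (documented defaults; the radius range matches
    yeast at the usual magnification)."""

    r_min: float = 4.0
    r_max: float = 12.0
    radius_step: float = 1.0
    canny_sigma: float = 1.5
    peak_threshold: float = 0.35    # fraction of a full circle's evidence
    min_center_distance: float = 7.0
    mask_inset: float = 0.0         # px shaved off detected radii for the
                                    # fluorescence mask
    hull_pad: float = 14.0          # bbox padding around each hull, px
    foreground: str = "dark"        # cells darker than background in phase

    def __post_init__(self) -> None:
        if not (0 < self.r_min < self.r_max):
            raise ValueError("need 0 < r_min < r_max")
        if self.foreground not in ("dark", "bright"):
            raise ValueError("foreground must be 'dark' or 'bright'")


def hough_circles(image: np.ndarray, hull_regions: list[np.ndarray],
                  r_min: float, r_max: float,
                  cfg: ImagingConfig | None = None) -> np.ndarray:
    """Accumulator-based circle detection restricted to the hull
    bounding regions.

    Edges come from a Canny detector inside each (padded) hull bounding
    box; peaks above ``peak_threshold`` (normalized accumulator: 1 is a
    complete circle) are kept and non-maximum-suppressed by center
    distance.  Returns an ``(n, 3)`` array of (row, col, radius).
    """
    if not (r_min < r_max):
        raise ValueError("degenerate radius range")
    cfg = cfg or ImagingConfig(r_min=r_min, r_max=r_max)
    h, w = image.shape
    radii = np.arange(r_min, r_max + cfg.radius_step / 2, cfg.radius_step)
    found: list[tuple[float, float, float, float]] = []  # strength, r, c, rad
    for hull in hull_regions:
        r0 = max(int(np.floor(hull[:, 0].min() - cfg.hull_pad)), 0)
        r1 = min(int(np.ceil(hull[:, 0].max() + cfg.hull_pad)) + 1, h)
        c0 = max(int(np.floor(hull[:, 1].min() - cfg.hull_pad)), 0)
        c1 = min(int(np.ceil(hull[:, 1].max() + cfg.hull_pad)) + 1, w)
        sub = image[r0:r1, c0:c1]
        if min(sub.shape) < 3:
            continue
        edges = feature.canny(sub, sigma=cfg.canny_sigma)
        if not edges.any():
            continue
        hspaces = transform.hough_circle(edges, radii)
        accums, cxs, cys, rads = transform.hough_circle_peaks(
            hspaces, radii, min_xdistance=int(cfg.min_center_distance),
            min_ydistance=int(cfg.min_center_distance),
            threshold=cfg.peak_threshold,
            num_peaks=np.inf, total_num_peaks=np.inf)
        hull_path = MplPath(hull)
        for a, cx, cy, rad in zip(accums, cxs, cys, rads):
            center = (cy + r0, cx + c0)
            # a center must come from this hull's own component, not the
            # padding (which may clip a neighboring cell into an arc)
            if not (hull_path.contains_point(center)
                    or np.min(np.hypot(hull[:, 0] - center[0],
                                       hull[:, 1] - center[1])) <= 2.0):
                continue
            found.append((float(a), center[0], center[1], float(rad)))
    # global non-maximum suppression (hulls may abut)
    found.sort(reverse=True)
    kept: list[tuple[float, float, float]] = []
    for a, rr, cc, rad in found:
        if all((rr - kr) ** 2 + (cc - kc) ** 2
               >= cfg.min_center_distance ** 2 for kr, kc, _ in kept):
            kept.append((rr, cc, rad))
    return np.asarray(kept, dtype=float).reshape(-1, 3)


# --------------------------------------------------------------------------
# the composite pipeline
# --------------------------------------------------------------------------

@dataclass
class SegmentationResult:
    """Binary mask, detected circles and the per-frame fluorescence
    readout of one frame."""

    mask: np.ndarray
    circles: np.ndarray              # (n, 3): row, col, radius
    mean_fluorescence: float
    flagged: bool = False            # zero detections: caller should hold
                                     # the previous measurement

    @property
    def n_cells(self) -> int:
        return int(self.circles.shape[0])

    def circles_to_csv(self, path: str | Path, frame: int = 0) -> None:
        n = self.circles.shape[0]
        data = np.column_stack([np.full(n, frame), self.circles[:, 1],
                                self.circles[:, 0], self.circles[:, 2]])
        np.savetxt(path, data, delimiter=",", header="frame,cx,cy,r",
                   comments="", fmt="%.10g")


def segment_and_quantify(pair: ImagePair,
                         cfg: ImagingConfig | None = None
                         ) -> SegmentationResult:
    """Run the full chain on one frame: Otsu binarization of the phase
    image, convex hulls of the components, circle detection, then the
    population-average fluorescence over the final mask — the union of
    detected circle disks intersected with the Otsu foreground, i.e. the
    Hough output localizes cells and the intersection keeps only pixels
    that actually belong to cell bodies (excluding the phase halo and
    any background swept in by a center/radius error).

    With zero detections the frame is flagged and the measurement set to
    NaN; the caller holds the previous value so the loop never crashes.
    """
    cfg = cfg or ImagingConfig()
    phase = pair.phase
    try:
        thr = otsu_threshold(phase)
    except ValueError:
        return SegmentationResult(np.zeros(phase.shape, bool),
                                  np.empty((0, 3)), math.nan, flagged=True)
    fg = phase < thr if cfg.foreground == "dark" else phase > thr
    hulls = convex_hull_regions(fg)
    circles = hough_circles(phase, hulls, cfg.r_min, cfg.r_max, cfg)
    mask = np.zeros(phase.shape, dtype=bool)
    for rr, cc, rad in circles:
        rs, cs = disk_coords((rr, cc), max(rad - cfg.mask_inset, 1.0),
                             shape=phase.shape)
        mask[rs, cs] = True
    mask &= fg
    if circles.shape[0] == 0 or not mask.any():
        return SegmentationResult(mask, circles, math.nan, flagged=True)
    return SegmentationResult(mask, circles,
                              float(pair.fluo[mask].mean()))


def match_detections(true_cells: np.ndarray, circles: np.ndarray,
                     tol: float = 2.0) -> tuple[int, int, int, np.ndarray]:
    """Greedy nearest matching of detections to ground-truth centers.

    Returns (true positives, false positives, false negatives, center
    errors of the matched pairs).
    """
    true_pts = np.asarray(true_cells, float).reshape(-1, 4)[:, :2]
    det = np.asarray(circles, float).reshape(-1, 3)[:, :2]
    unmatched = list(range(det.shape[0]))
    errors = []
    fn = 0
    for pt in true_pts:
        if not unmatched:
            fn += 1
            continue
        d = np.hypot(det[unmatched, 0] - pt[0], det[unmatched, 1] - pt[1])
        j = int(np.argmin(d))
        if d[j] <= tol:
            errors.append(float(d[j]))
            unmatched.pop(j)
        else:
            fn += 1
    tp = len(errors)
    fp = len(unmatched)
    return tp, fp, fn, np.asarray(errors)
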