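"""Sparse optical-flow feature extraction for two-tool surgical video.

The data-generation stage of the pipeline: frames are preprocessed
(grayscale → median blur → adaptive threshold) to sharpen trackable
structure, corners are seeded inside user-given per-tool regions of
interest with the Shi–Tomasi min-eigenvalue criterion, and the seeds are
tracked through the clip with a pyramidal Lucas–Kanade solver.  Each frame
after the first contributes one row of ``4 × n_points × 2`` features —
sub-pixel positions (x, y) and per-frame displacements (dx, dy) for every
point of both tools; with the default 30 points per tool that is 240
columns.

The brightness-constancy model underlying the tracker,
``I(x, y, t) = I(x + dx, y + dy, t + dt)``, linearises to the optical-flow
constraint ``Ix·vx + Iy·vy + It = 0``, which is solved per point by
least squares over a local integration window under the assumption that
nearby pixels share one velocity, coarse-to-fine over an image pyramid.

Tracking runs on the unmodified grayscale frames; the binarised image is
used only to seed the detector (configurable via ``track_on_binary``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import corner_peaks, corner_shi_tomasi

from .synth import read_frames

N_POINTS_DEFAULT = 30


@dataclass(frozen=True)
class Roi:
    """Half-open axis-aligned region [x, x+w) × [y, y+h), 0-based pixels."""

    tool_id: str  # "left" or "right"
    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.tool_id not in ("left", "right"):
            raise ValueError("tool_id must be 'left' or 'right'")
        if self.w <= 0 or self.h <= 0:
            raise ValueError("ROI must have positive extent")

    def validate_in(self, shape: tuple[int, int]) -> None:
        hh, ww = shape
        if self.x < 0 or self.y < 0 or self.x + self.w > ww or self.y + self.h > hh:
            raise ValueError(f"ROI {self} not fully inside frame {ww}x{hh}")

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        return (
            (pts[:, 0] >= self.x)
            & (pts[:, 0] < self.x + self.w)
            & (pts[:, 1] >= self.y)
            & (pts[:, 1] < self.y + self.h)
        )


@dataclass
class PointSet:
    """Tracked point coordinates for one tool (sub-pixel, x-y order)."""

    tool_id: str
    coords: np.ndarray  # (n_points, 2) float
    status: np.ndarray  # (n_points,) bool, True = tracked

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.status = np.asarray(self.status, dtype=bool)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be (n, 2)")


@dataclass(frozen=True)
class LKParams:
    """Pyramidal Lucas–Kanade solver settings (standard defaults)."""

    window: int = 15
    pyramid_levels: int = 3
    max_iter: int = 10
    eps: float = 0.03
    min_eig_threshold: float = 1e-4


@dataclass(frozen=True)
class PreprocessParams:
    median_kernel: int = 5
    block_size: int = 11
    offset: float = 2.0


def to_gray(frame: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) frame to single-channel float."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.size == 0:
        raise ValueError("empty frame")
    if frame.ndim == 3:
        frame = frame[..., :3] @ np.array([0.299, 0.587, 0.114])
    if frame.ndim != 2:
        raise ValueError("frame must be 2D or 3D")
    return frame


def preprocess_frame(frame: np.ndarray, params: PreprocessParams | None = None) -> np.ndarray:
    """Grayscale → odd-kernel median blur → adaptive (local-mean) threshold.

    Returns a uint8 image with values in {0, 255}.  Pixels brighter than the
    local mean (over ``block_size``) minus ``offset`` (in 8-bit units) are
    foreground, mirroring the usual adaptive-mean thresholding convention.
    """
    params = params or PreprocessParams()
    if params.median_kernel % 2 == 0:
        raise ValueError("median kernel must be odd")
    gray = to_gray(frame)
    if gray.max() <= 1.5:  # normalise to 8-bit scale for the offset to mean something
        gray = gray * 255.0
    blurred = ndimage.median_filter(gray, size=params.median_kernel, mode="nearest")
    local_mean = ndimage.uniform_filter(blurred, size=params.block_size, mode="nearest")
    binary = (blurred > local_mean - params.offset).astype(np.uint8) * 255
    return binary


def shi_tomasi_response(image: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """min(λ1, λ2) of the local gradient structure tensor at every pixel."""
    return corner_shi_tomasi(np.asarray(image, dtype=np.float64), sigma=sigma)


def detect_initial_points(
    binary_frame: np.ndarray,
    roi: Roi,
    n_points: int = N_POINTS_DEFAULT,
    min_distance: int = 2,
    sigma: float = 1.0,
) -> PointSet:
    """Top-``n_points`` Shi–Tomasi corners inside ``roi``, ranked by score.

    Raises if fewer than ``n_points`` corners are detectable: the feature
    layout downstream requires a full set per tool.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    frame = np.asarray(binary_frame, dtype=np.float64)
    roi.validate_in(frame.shape)
    response = shi_tomasi_response(frame, sigma=sigma)
    masked = np.full_like(response, -np.inf)
    masked[roi.y : roi.y + roi.h, roi.x : roi.x + roi.w] = response[
        roi.y : roi.y + roi.h, roi.x : roi.x + roi.w
    ]
    peaks = corner_peaks(
        masked, min_distance=min_distance, threshold_abs=1e-12, num_peaks=np.inf
    )  # (n, (row, col)) sorted by decreasing response
    if len(peaks) < n_points:
        raise ValueError(
            f"Shi–Tomasi found only {len(peaks)} corners in {roi.tool_id} ROI, "
            f"need {n_points} (shortfall {n_points - len(peaks)})"
        )
    sel = peaks[:n_points]
    coords = np.stack([sel[:, 1], sel[:, 0]], axis=1).astype(float)  # -> (x, y)
    return PointSet(tool_id=roi.tool_id, coords=coords, status=np.ones(n_points, dtype=bool))


def _pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    pyr = [np.asarray(img, dtype=np.float64)]
    for _ in range(1, levels):
        sm = ndimage.gaussian_filter(pyr[-1], 1.0, mode="nearest")
        pyr.append(sm[::2, ::2])
    return pyr


def _bilinear(img: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(img, [ys.ravel(), xs.ravel()], order=1,
                                   mode="nearest").reshape(xs.shape)


def track_step(
    prev_gray: np.ndarray,
    next_gray: np.ndarray,
    points: PointSet,
    params: LKParams | None = None,
) -> tuple[PointSet, np.ndarray]:
    """One pyramidal Lucas–Kanade step for all points of one tool.

    Returns the updated :class:`PointSet` (with lost points flagged) and the
    per-point displacement ``new − old``.  Points whose integration window
    has a near-singular structure tensor, or which land outside the frame,
    are marked lost; their reported displacement is whatever the solver last
    produced and should be handled by the caller's lost-point policy.
    """
    params = params or LKParams()
    prev_gray = to_gray(prev_gray)
    next_gray = to_gray(next_gray)
    if prev_gray.shape != next_gray.shape:
        raise ValueError("frame shapes differ")

    pts = np.asarray(points.coords, dtype=float)
    n = len(pts)
    r = params.window // 2
    off = np.mgrid[-r : r + 1, -r : r + 1].reshape(2, -1).T.astype(float)  # (w², (dy,dx))
    off_y, off_x = off[:, 0], off[:, 1]

    prev_pyr = _pyramid(prev_gray, params.pyramid_levels)
    next_pyr = _pyramid(next_gray, params.pyramid_levels)

    g = np.zeros((n, 2), dtype=float)  # accumulated guess (x, y)
    min_eig = np.zeros(n)
    for level in range(params.pyramid_levels - 1, -1, -1):
        scale = 2.0**level
        pl = pts / scale
        img_p, img_n = prev_pyr[level], next_pyr[level]
        gy, gx = np.gradient(img_p)
        sx = pl[:, 0:1] + off_x[None, :]
        sy = pl[:, 1:2] + off_y[None, :]
        T = _bilinear(img_p, sx, sy)
        Ix = _bilinear(gx, sx, sy)
        Iy = _bilinear(gy, sx, sy)
        gxx = np.sum(Ix * Ix, axis=1)
        gxy = np.sum(Ix * Iy, axis=1)
        gyy = np.sum(Iy * Iy, axis=1)
        det = gxx * gyy - gxy * gxy
        trace = gxx + gyy
        # smaller eigenvalue of the 2x2 structure tensor, per unit window area
        min_eig = (trace / 2 - np.sqrt(np.maximum(trace * trace / 4 - det, 0.0))) / off.shape[0]
        ok = det > 1e-12
        d = np.zeros((n, 2), dtype=float)
        for _ in range(params.max_iter):
            wx = sx + (g[:, 0:1] + d[:, 0:1])
            wy = sy + (g[:, 1:2] + d[:, 1:2])
            diff = _bilinear(img_n, wx, wy) - T
            bx = -np.sum(Ix * diff, axis=1)
            by = -np.sum(Iy * diff, axis=1)
            ddx = np.where(ok, (gyy * bx - gxy * by) / np.where(ok, det, 1.0), 0.0)
            ddy = np.where(ok, (gxx * by - gxy * bx) / np.where(ok, det, 1.0), 0.0)
            d[:, 0] += ddx
            d[:, 1] += ddy
            if np.all(np.hypot(ddx, ddy) < params.eps):
                break
        g = (g + d) * (2.0 if level > 0 else 1.0)

    new = pts + g
    h, w = next_gray.shape
    inside = (
        (new[:, 0] >= 0) & (new[:, 0] <= w - 1) & (new[:, 1] >= 0) & (new[:, 1] <= h - 1)
    )
    status = (
        points.status
        & inside
        & np.isfinite(new).all(axis=1)
        & (min_eig >= params.min_eig_threshold)
    )
    disp = new - pts
    return PointSet(tool_id=points.tool_id, coords=new, status=status), disp


@dataclass
class FlowRecord:
    """Positions and displacements of both tools at one frame transition."""

    frame_index: int
    left: PointSet
    right: PointSet
    disp_left: np.ndarray
    disp_right: np.ndarray


def build_feature_row(record: FlowRecord, n_points: int = N_POINTS_DEFAULT) -> np.ndarray:
    """Flatten one :class:`FlowRecord` to the fixed-width feature row.

    Layout (point-major): left positions (x0,y0,…), left displacements
    (dx0,dy0,…), then the same two blocks for the right tool — 4·n_points
    values per tool, 240 with the default 30 points.
    """
    parts = []
    for ps, disp in ((record.left, record.disp_left), (record.right, record.disp_right)):
        if len(ps.coords) != n_points or len(disp) != n_points:
            raise ValueError(
                f"{ps.tool_id} tool has {len(ps.coords)} points, expected {n_points}"
            )
        parts.append(np.asarray(ps.coords, dtype=float).ravel())
        parts.append(np.asarray(disp, dtype=float).ravel())
    return np.concatenate(parts)


def feature_columns(n_points: int = N_POINTS_DEFAULT) -> list[str]:
    cols: list[str] = []
    for side in ("left", "right"):
        cols += [f"{side}_p{i:02d}_{a}" for i in range(n_points) for a in ("x", "y")]
        cols += [f"{side}_p{i:02d}_{a}" for i in range(n_points) for a in ("dx", "dy")]
    return cols


@dataclass
class FeatureMatrix:
    """Per-frame feature rows plus the raw tracking buffer and a loss log."""

    values: np.ndarray  # (n_frames - 1 - start, 4 * n_points * 2)
    columns: list[str]
    raw: np.ndarray  # (frames_traversed, n_points, 2 tools, 2 coords)
    lost_counts: dict[str, int]
    start_frame: int
    params: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.columns)

    def save(self, csv_path: str | Path) -> None:
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False)
        sidecar = dict(start_frame=self.start_frame, lost_counts=self.lost_counts,
                       params=self.params, n_rows=int(self.values.shape[0]))
        csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def extract_features(
    video: str | Path | np.ndarray,
    roi_left: Roi,
    roi_right: Roi,
    start_frame: int = 0,
    n_points: int = N_POINTS_DEFAULT,
    lk: LKParams | None = None,
    pre: PreprocessParams | None = None,
    track_on_binary: bool = False,
) -> FeatureMatrix:
    """Run the full per-video stage: seed on ``start_frame``, track to the end.

    Seeding uses the preprocessed binary image; tracking uses the raw
    grayscale frames (or the binary ones if ``track_on_binary``).  Lost
    points carry their last known position forward with zero displacement —
    there is no re-detection — and the per-tool loss counts are logged in
    the result.  Only positions and first-difference displacements are
    computed; no higher-order kinematics.
    """
    frames = read_frames(video)
    if frames.ndim == 4:  # RGB clip
        frames = np.stack([to_gray(f) for f in frames])
    n_frames = frames.shape[0]
    if not 0 <= start_frame < n_frames - 1:
        raise ValueError(f"start_frame {start_frame} out of range for {n_frames} frames")
    lk = lk or LKParams()
    pre = pre or PreprocessParams()
    shape = frames.shape[1:3]
    roi_left.validate_in(shape)
    roi_right.validate_in(shape)

    binary0 = preprocess_frame(frames[start_frame], pre)
    left = detect_initial_points(binary0, roi_left, n_points)
    right = detect_initial_points(binary0, roi_right, n_points)

    def img(i: int) -> np.ndarray:
        return preprocess_frame(frames[i], pre).astype(np.float64) if track_on_binary else frames[i]

    n_steps = n_frames - 1 - start_frame
    rows = np.empty((n_steps, 8 * n_points), dtype=float)
    raw = np.empty((n_steps + 1, n_points, 2, 2), dtype=float)
    raw[0, :, 0, :] = left.coords
    raw[0, :, 1, :] = right.coords
    lost_counts = {"left": 0, "right": 0}
    prev = img(start_frame)
    for k, t in enumerate(range(start_frame + 1, n_frames)):
        nxt = img(t)
        new_sets = []
        disps = []
        for ps in (left, right):
            tracked, disp = track_step(prev, nxt, ps, lk)
            # lost-point policy: freeze at last position, zero displacement
            lost = ps.status & ~tracked.status
            lost_counts[ps.tool_id] += int(lost.sum())
            frozen = ~tracked.status
            coords = np.where(frozen[:, None], ps.coords, tracked.coords)
            disp = np.where(frozen[:, None], 0.0, disp)
            disp = coords - ps.coords  # exact identity with stored positions
            new_sets.append(PointSet(ps.tool_id, coords, tracked.status))
            disps.append(disp)
        left, right = new_sets
        rec = FlowRecord(frame_index=t, left=left, right=right,
                         disp_left=disps[0], disp_right=disps[1])
        rows[k] = build_feature_row(rec, n_points)
        raw[k + 1, :, 0, :] = left.coords
        raw[k + 1, :, 1, :] = right.coords
        prev = nxt

    return FeatureMatrix(
        values=rows,
        columns=feature_columns(n_points),
        raw=raw,
        lost_counts=lost_counts,
        start_frame=start_frame,
        params=dict(
            n_points=n_points,
            lk=vars(lk) if not isinstance(lk, dict) else lk,
            preprocess=vars(pre) if not isinstance(pre, dict) else pre,
            track_on_binary=track_on_binary,
        ),
    )
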