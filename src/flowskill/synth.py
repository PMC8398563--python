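"""Synthetic two-tool endoscopy-like scenes with ground-truth motion.

Generates videos of two independently moving, textured, corner-rich blobs
("tools") over a noisy background.  Skill level is encoded purely in motion
statistics — trajectory jitter, path directness and pausing — never in
appearance, so a downstream classifier can only succeed by learning motion.
Cohorts are organised as subjects × repeated trials with one skill per
subject, which makes leave-one-super-trial-out folds well defined.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

SKILLS = ("novice", "intermediate", "expert")

#: Default motion presets.  Novice jitter is >5× expert jitter so the two
#: classes' step-length distributions are disjoint; directness orders
#: expert > intermediate > novice.  All values are per-frame pixel units.
SKILL_PRESETS: dict[str, dict[str, float]] = {
    "novice": dict(jitter_sd=2.5, speed_mean=2.0, path_directness=0.35, pause_prob=0.15),
    "intermediate": dict(jitter_sd=1.2, speed_mean=2.0, path_directness=0.65, pause_prob=0.07),
    "expert": dict(jitter_sd=0.4, speed_mean=2.0, path_directness=0.95, pause_prob=0.02),
}


@dataclass(frozen=True)
class MotionParams:
    """Per-skill motion statistics driving a tool trajectory."""

    skill: str
    jitter_sd: float
    speed_mean: float
    path_directness: float
    pause_prob: float

    def __post_init__(self) -> None:
        if self.skill not in SKILLS:
            raise ValueError(f"unknown skill {self.skill!r}; expected one of {SKILLS}")
        vals = (self.jitter_sd, self.speed_mean, self.path_directness, self.pause_prob)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("motion parameters must be finite")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if not 0.0 <= self.path_directness <= 1.0:
            raise ValueError("path_directness must lie in [0, 1]")
        if not 0.0 <= self.pause_prob <= 1.0:
            raise ValueError("pause_prob must lie in [0, 1]")

    @classmethod
    def preset(cls, skill: str) -> "MotionParams":
        return cls(skill=skill, **SKILL_PRESETS[skill])


@dataclass(frozen=True)
class SceneSpec:
    """Geometry, texture and noise parameters of one rendered clip."""

    width: int = 160
    height: int = 120
    n_frames: int = 100
    tool_radius: int = 18
    background_noise_sd: float = 0.02
    texture_contrast: float = 0.7
    texture_period: float = 4.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 64 or self.height < 64:
            raise ValueError("frame must be at least 64x64 px")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")


@dataclass
class GroundTruth:
    """Exact per-frame tool centers and rigidly attached seed points.

    ``centers`` has shape (n_frames, 2, 2): frame × tool(left, right) × (x, y).
    ``points`` has shape (n_frames, 2, n_points, 2).  Differencing consecutive
    point positions reproduces the commanded per-frame displacement to
    floating-point roundoff: the bookkeeping is independent of rendering and
    never quantised to pixels.
    """

    centers: np.ndarray
    points: np.ndarray
    out_of_bounds: bool = False


def _rot(v: np.ndarray, ang: float) -> np.ndarray:
    c, s = math.cos(ang), math.sin(ang)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def generate_trajectory(
    params: MotionParams,
    n_frames: int,
    start,
    goal,
    seed: int,
    bounds: tuple[float, float, float, float] | None = None,
) -> np.ndarray:
    """Goal-directed drift plus Gaussian jitter; returns (n_frames, 2) path.

    The heading each frame blends the direction to the goal (weight
    ``path_directness``) with a smoothly wandering direction; with
    probability ``pause_prob`` the drift is suppressed for that frame.
    Deterministic for a fixed seed.  ``bounds`` = (xmin, ymin, xmax, ymax)
    clips the path.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    start = np.asarray(start, dtype=float)
    goal = np.asarray(goal, dtype=float)
    if np.allclose(start, goal):
        raise ValueError("start and goal must differ")
    if not (np.all(np.isfinite(start)) and np.all(np.isfinite(goal))):
        raise ValueError("start/goal must be finite")

    rng = np.random.default_rng(seed)
    pos = start.copy()
    wander = _rot(np.array([1.0, 0.0]), rng.uniform(0, 2 * math.pi))
    path = np.empty((n_frames, 2), dtype=float)
    path[0] = pos
    for t in range(1, n_frames):
        to_goal = goal - pos
        dist = float(np.hypot(*to_goal))
        goal_dir = to_goal / dist if dist > 1e-9 else np.zeros(2)
        wander = _rot(wander, rng.normal(0.0, 0.6))
        heading = params.path_directness * goal_dir + (1.0 - params.path_directness) * wander
        hn = float(np.hypot(*heading))
        heading = heading / hn if hn > 1e-9 else goal_dir
        paused = rng.random() < params.pause_prob
        step = 0.0 if paused else min(params.speed_mean, dist) if dist > 0 else 0.0
        jitter = rng.normal(0.0, params.jitter_sd, size=2) if params.jitter_sd > 0 else np.zeros(2)
        pos = pos + step * heading + jitter
        if bounds is not None:
            pos = np.clip(pos, [bounds[0], bounds[1]], [bounds[2], bounds[3]])
        path[t] = pos
    return path


def _seed_point_offsets(radius: float, n_points: int = 9) -> np.ndarray:
    """A small rigid grid of offsets well inside the tool disc."""
    side = int(math.ceil(math.sqrt(n_points)))
    span = radius * 0.55
    g = np.linspace(-span, span, side)
    xx, yy = np.meshgrid(g, g)
    offs = np.stack([xx.ravel(), yy.ravel()], axis=1)[:n_points]
    return offs


def _tool_layer(shape: tuple[int, int], center: np.ndarray, radius: float,
                contrast: float, period: float, phase: float) -> tuple[np.ndarray, np.ndarray]:
    """Procedural texture evaluated in tool coordinates (subpixel exact)."""
    h, w = shape
    y0 = max(0, int(center[1] - radius - 2))
    y1 = min(h, int(center[1] + radius + 3))
    x0 = max(0, int(center[0] - radius - 2))
    x1 = min(w, int(center[0] + radius + 3))
    if y0 >= y1 or x0 >= x1:
        z = np.zeros((0, 0))
        return z, z
    ys, xs = np.mgrid[y0:y1, x0:x1]
    u = xs - center[0]
    v = ys - center[1]
    r = np.sqrt(u * u + v * v)
    # smooth grid-of-blobs texture: strong gradients in both directions
    tex = 0.5 + 0.5 * contrast * np.sin(2 * np.pi * u / period + phase) * np.sin(
        2 * np.pi * v / period + phase
    )
    mask = 1.0 / (1.0 + np.exp((r - radius) / 0.8))
    return tex, mask


def render_video(
    traj_left: np.ndarray,
    traj_right: np.ndarray,
    scene: SceneSpec,
    n_seed_points: int = 9,
) -> tuple[np.ndarray, GroundTruth]:
    """Render float frames in [0, 1] of shape (n_frames, H, W) plus ground truth."""
    traj_left = np.asarray(traj_left, dtype=float)
    traj_right = np.asarray(traj_right, dtype=float)
    if len(traj_left) != scene.n_frames or len(traj_right) != scene.n_frames:
        raise ValueError("trajectories must have length scene.n_frames")

    rng = np.random.default_rng(scene.seed)
    h, w = scene.height, scene.width
    frames = np.empty((scene.n_frames, h, w), dtype=np.float32)
    offsets = _seed_point_offsets(scene.tool_radius, n_seed_points)
    centers = np.stack([traj_left, traj_right], axis=1)  # (T, 2, 2)
    points = centers[:, :, None, :] + offsets[None, None, :, :]

    oob = False
    r = scene.tool_radius
    for tool_traj in (traj_left, traj_right):
        if (
            np.any(tool_traj[:, 0] - r < 0)
            or np.any(tool_traj[:, 0] + r > w - 1)
            or np.any(tool_traj[:, 1] - r < 0)
            or np.any(tool_traj[:, 1] + r > h - 1)
        ):
            oob = True

    for t in range(scene.n_frames):
        frame = np.full((h, w), 0.35, dtype=np.float64)
        if scene.background_noise_sd > 0:
            frame += rng.normal(0.0, scene.background_noise_sd, size=(h, w))
        for k, traj in enumerate((traj_left, traj_right)):
            c = traj[t]
            y0 = max(0, int(c[1] - r - 2))
            y1 = min(h, int(c[1] + r + 3))
            x0 = max(0, int(c[0] - r - 2))
            x1 = min(w, int(c[0] + r + 3))
            if y0 >= y1 or x0 >= x1:
                continue
            tex, mask = _tool_layer((h, w), c, r, scene.texture_contrast,
                                    scene.texture_period, phase=0.7 * k)
            sub = frame[y0:y1, x0:x1]
            frame[y0:y1, x0:x1] = sub * (1 - mask) + tex * mask
        frames[t] = np.clip(frame, 0.0, 1.0)

    return frames, GroundTruth(centers=centers, points=points, out_of_bounds=oob)


@dataclass
class CohortItem:
    subject: str
    task: str
    trial: int
    skill: str
    roi_left: tuple[int, int, int, int]
    roi_right: tuple[int, int, int, int]
    frames: np.ndarray | None
    truth: GroundTruth
    video_path: str = ""


def _roi_around(center: np.ndarray, radius: int, shape: tuple[int, int],
                margin: int = 4) -> tuple[int, int, int, int]:
    h, w = shape
    x0 = max(0, int(math.floor(center[0] - radius - margin)))
    y0 = max(0, int(math.floor(center[1] - radius - margin)))
    x1 = min(w, int(math.ceil(center[0] + radius + margin)) + 1)
    y1 = min(h, int(math.ceil(center[1] + radius + margin)) + 1)
    return (x0, y0, x1 - x0, y1 - y0)


def assign_skills(n_subjects: int, proportions: dict[str, float] | None = None) -> list[str]:
    """Deterministic skill assignment matching requested proportions.

    Counts follow the largest-remainder rule.  Every represented class needs
    at least two subjects for leave-one-super-trial-out evaluation to be
    meaningful; if rounding would strand a class with a single subject, the
    assignment falls back to an even novice/expert split.
    """
    if proportions is None:
        proportions = {"novice": 3 / 8, "intermediate": 2 / 8, "expert": 3 / 8}
    exact = {s: p * n_subjects for s, p in proportions.items()}
    counts = {s: int(math.floor(v)) for s, v in exact.items()}
    leftovers = sorted(exact, key=lambda s: exact[s] - counts[s], reverse=True)
    for s in leftovers[: n_subjects - sum(counts.values())]:
        counts[s] += 1
    represented = [c for c in counts.values() if c > 0]
    if represented and min(represented) < 2:
        counts = {"novice": (n_subjects + 1) // 2, "expert": n_subjects // 2}
    skills: list[str] = []
    for s in SKILLS:
        skills.extend([s] * counts.get(s, 0))
    return skills[:n_subjects]


def generate_cohort(
    n_subjects: int = 8,
    trials_per_subject: int = 5,
    task_names: tuple[str, ...] = ("knot_tying",),
    seed: int = 0,
    scene: SceneSpec | None = None,
    proportions: dict[str, float] | None = None,
    out_dir: str | Path | None = None,
    keep_frames: bool = True,
) -> tuple[list[CohortItem], pd.DataFrame]:
    """Generate a subjects × trials × tasks cohort with a manifest.

    One skill per subject across all trials (as in real training cohorts), so
    that holding out a trial index keeps every subject in both train and test.
    If ``out_dir`` is given, each clip is written as a PNG frame directory and
    the manifest as ``manifest.csv``.
    """
    if trials_per_subject < 2:
        raise ValueError("trials_per_subject must be >= 2 (LOSO needs >= 2 super-trials)")
    skills = assign_skills(n_subjects, proportions)
    present = set(skills)
    for s in present:
        if skills.count(s) < 2:
            raise ValueError(f"need >= 2 subjects for represented skill {s!r}")

    scene = scene or SceneSpec()
    h, w, r = scene.height, scene.width, scene.tool_radius
    margin = r + 2.0
    items: list[CohortItem] = []
    rows = []
    for si in range(n_subjects):
        subject = f"S{si + 1:02d}"
        params = MotionParams.preset(skills[si])
        for ti, task in enumerate(task_names):
            for trial in range(1, trials_per_subject + 1):
                ss = np.random.SeedSequence([seed, si, ti, trial])
                s_traj_l, s_traj_r, s_scene = [int(c) for c in ss.generate_state(3) >> 1]
                rng = np.random.default_rng(ss.generate_state(4)[3])
                # left tool lives in the left half, right tool in the right
                half = w / 2.0
                start_l = np.array([rng.uniform(margin, half * 0.6),
                                    rng.uniform(margin, h - margin)])
                goal_l = np.array([rng.uniform(margin, half - margin),
                                   rng.uniform(margin, h - margin)])
                start_r = np.array([rng.uniform(half * 1.4, w - margin),
                                    rng.uniform(margin, h - margin)])
                goal_r = np.array([rng.uniform(half + margin, w - margin),
                                   rng.uniform(margin, h - margin)])
                bounds_l = (margin, margin, half - margin, h - 1 - margin)
                bounds_r = (half + margin, margin, w - 1 - margin, h - 1 - margin)
                traj_l = generate_trajectory(params, scene.n_frames, start_l, goal_l,
                                             s_traj_l, bounds=bounds_l)
                traj_r = generate_trajectory(params, scene.n_frames, start_r, goal_r,
                                             s_traj_r, bounds=bounds_r)
                sc = dataclasses.replace(scene, seed=s_scene)
                frames, truth = render_video(traj_l, traj_r, sc)
                roi_l = _roi_around(traj_l[0], r, (h, w))
                roi_r = _roi_around(traj_r[0], r, (h, w))
                video_path = ""
                if out_dir is not None:
                    vdir = Path(out_dir) / "videos" / f"{subject}_{task}_T{trial}"
                    write_frames(frames, vdir)
                    video_path = str(vdir)
                items.append(CohortItem(subject, task, trial, skills[si], roi_l, roi_r,
                                        frames if keep_frames else None, truth, video_path))
                rows.append(dict(subject=subject, task=task, trial=trial, skill=skills[si],
                                 roi_left=_fmt_roi(roi_l), roi_right=_fmt_roi(roi_r),
                                 video_path=video_path))
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(Path(out_dir) / "manifest.csv", index=False)
    return items, manifest


def _fmt_roi(roi: tuple[int, int, int, int]) -> str:
    return "{}:{}:{}:{}".format(*roi)


def parse_roi(text: str) -> tuple[int, int, int, int]:
    x, y, w, h = (int(v) for v in str(text).split(":"))
    return (x, y, w, h)


def write_frames(frames: np.ndarray, out_dir: str | Path) -> None:
    """Write a clip as a directory of 8-bit PNG frames."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, f in enumerate(np.asarray(frames)):
        iio.imwrite(out / f"frame_{i:04d}.png", (np.clip(f, 0, 1) * 255).astype(np.uint8))


def read_frames(video: str | Path | np.ndarray) -> np.ndarray:
    """Load a clip from an ndarray, a PNG-frame directory, or a video file."""
    if isinstance(video, np.ndarray):
        return video
    p = Path(video)
    if p.is_dir():
        files = sorted(p.glob("frame_*.png"))
        if not files:
            raise FileNotFoundError(f"no frame_*.png files in {p}")
        return np.stack([iio.imread(f) for f in files]).astype(np.float32) / 255.0
    if not p.exists():
        raise FileNotFoundError(str(p))
    arr = iio.imread(p)  # multi-frame container
    arr = np.asarray(arr, dtype=np.float32)
    if arr.max() > 1.5:
        arr = arr / 255.0
    return arr
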