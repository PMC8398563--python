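"""Shared fixtures: small rendered scenes and a full default cohort dataset.

The cohort fixture runs the real pipeline (render → track → window) once per
session; tests that exercise the classifiers and the LOSO protocol share it.
"""

from __future__ import annotations

import numpy as np
import pytest

from flowskill.flow import Roi, extract_features
from flowskill.synth import (
    MotionParams,
    SceneSpec,
    generate_cohort,
    generate_trajectory,
    render_video,
)
from flowskill.windows import TWO_CLASS, WindowParams, assemble

COHORT_SEED = 11


@pytest.fixture(scope="session")
def two_tool_scene():
    """One 100-frame default-spec clip with a wandering and a precise tool."""
    scene = SceneSpec(seed=3)
    h, w, r = scene.height, scene.width, scene.tool_radius
    m = r + 2
    tl = generate_trajectory(MotionParams.preset("novice"), scene.n_frames,
                             (40, 60), (60, 40), seed=2, bounds=(m, m, w / 2 - m, h - 1 - m))
    tr = generate_trajectory(MotionParams.preset("expert"), scene.n_frames,
                             (120, 60), (100, 80), seed=4,
                             bounds=(w / 2 + m, m, w - 1 - m, h - 1 - m))
    frames, truth = render_video(tl, tr, scene)
    return dict(scene=scene, traj_left=tl, traj_right=tr, frames=frames, truth=truth)


def roi_for(traj0, radius, shape):
    from flowskill.synth import _roi_around

    return _roi_around(np.asarray(traj0), radius, shape)


@pytest.fixture(scope="session")
def default_cohort():
    """The default study cohort: 8 subjects × 5 trials, one task, in memory."""
    items, manifest = generate_cohort(seed=COHORT_SEED)
    return items, manifest


@pytest.fixture(scope="session")
def cohort_features(default_cohort):
    items, manifest = default_cohort
    feats = {}
    for it in items:
        fm = extract_features(it.frames, Roi("left", *it.roi_left),
                              Roi("right", *it.roi_right))
        feats[(it.subject, it.task, it.trial)] = fm
    return feats, manifest


@pytest.fixture(scope="session")
def two_class_dataset(cohort_features):
    """Windowed two-class dataset (intermediates dropped) from the cohort."""
    feats, manifest = cohort_features
    arrays = {k: fm.values for k, fm in feats.items()}
    return assemble(manifest, arrays, WindowParams(60, 30), TWO_CLASS)["knot_tying"]
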