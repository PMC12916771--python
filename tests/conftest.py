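import numpy as np
import pytest

from vesselperm import leakage, synth


@pytest.fixture(scope="session")
def hypo_scene():
    return synth.make_scene("hypo_wound")


@pytest.fixture(scope="session")
def hypo_movie(hypo_scene):
    return synth.render_movie(hypo_scene)


@pytest.fixture(scope="session")
def no_wound_scene():
    return synth.make_scene("no_wound")


def scene_rois(scene):
    """ROIs matching a synthetic scene's geometry."""
    rois = {}
    if scene.perivascular_region is not None:
        rois["vessel"] = leakage.ROISpec(
            "rectangle", scene.perivascular_region.rect, role="vessel"
        )
    if scene.wound_region is not None:
        rois["wound"] = leakage.ROISpec("rectangle", scene.wound_region.rect, role="wound")
    rois["background"] = leakage.ROISpec("rectangle", (2, 2, 10, 90), role="background")
    if scene.vessel is not None:
        yc = scene.vessel.y_center
        rois["dilation_line"] = leakage.ROISpec(
            "line", (yc - 25, 40, yc + 25, 40), role="dilation_line", line_width=30
        )
    return rois


def iv_tot_from_scene(scene, window=None):
    """Full pipeline: render -> extract -> background-correct -> normalize -> integrate."""
    stack, _ = synth.render_movie(scene)
    rois = scene_rois(scene)
    trace = leakage.extract_trace(stack, rois["vessel"], 0)
    bg = leakage.extract_trace(stack, rois["background"], 0)
    trace = leakage.background_correct(trace, bg)
    norm = leakage.normalize_baseline(trace)
    if window is None:
        window = (0.0, float(stack.times[-1]))
    return leakage.integrate_leakage(norm, window=window)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
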