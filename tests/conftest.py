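"""Shared fixtures: the default design and a few pre-rendered scenes.

Scene fixtures are session-scoped because rendering dominates test time;
tests must not mutate them.
"""

from __future__ import annotations

import numpy as np
import pytest

import uavpheno as up


@pytest.fixture(scope="session")
def design():
    return up.generate_design()


@pytest.fixture(scope="session")
def s1_scene(design):
    """Default-noise S1 scene with its bare-soil reference DSM."""
    truth = up.sample_truth(design, "S1", seed=11)
    dom, dsm, mask = up.render_scene(truth, seed=12)
    _, bare, _ = up.render_bare_scene(design, seed=13)
    return {"truth": truth, "dom": dom, "dsm": dsm, "mask": mask, "bare": bare}


@pytest.fixture(scope="session")
def s1_zero_noise_scene(design):
    """Noise-free S1 scene: DN jitter and DSM noise both zero."""
    truth = up.sample_truth(design, "S1", seed=21, dn_jitter_sd=0.0, dsm_noise_sd=0.0)
    dom, dsm, mask = up.render_scene(truth, seed=22)
    _, bare, _ = up.render_bare_scene(design, seed=23, dn_jitter_sd=0.0, dsm_noise_sd=0.0)
    return {"truth": truth, "dom": dom, "dsm": dsm, "mask": mask, "bare": bare}


@pytest.fixture(scope="session")
def truth_index(s1_scene):
    return s1_scene["truth"].plots.set_index("plot_id")


def point_in_polygon(x: float, y: float, verts: np.ndarray) -> bool:
    """Crossing-number point-in-polygon oracle, independent of shapely."""
    inside = False
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xin = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xin:
                inside = not inside
    return inside
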