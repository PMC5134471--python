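import numpy as np
import pytest

from uwbspeech import (
    estimate_background,
    make_pulse_template,
    make_short_template,
    reduce_clutter,
    simulate_session,
)
from uwbspeech.scene import static_scene, word_scene


@pytest.fixture(scope="session")
def template():
    return make_pulse_template(24)


@pytest.fixture(scope="session")
def short_template(template):
    return make_short_template(template, 0.25)


@pytest.fixture(scope="session")
def two_like_session(template):
    """A 'two'-like articulation session with its background capture."""
    scene = word_scene("two_like", seed=7, rest_range_m=0.132, excursion_m=0.02)
    session, truth = simulate_session(scene, template)
    background_session, _ = simulate_session(scene.background(), template)
    reduced = reduce_clutter(session, estimate_background(background_session))
    return scene, session, truth, reduced


@pytest.fixture(scope="session")
def static_reduced(template):
    scene = static_scene(seed=5)
    session, _ = simulate_session(scene, template)
    background_session, _ = simulate_session(scene.background(), template)
    return reduce_clutter(session, estimate_background(background_session))


def place_pulse(n_bins, template, bin_index, amplitude=1.0):
    """A scan containing one scaled pulse at the given bin."""
    y = np.zeros(n_bins)
    v = template.samples
    stop = min(bin_index + v.size, n_bins)
    y[bin_index:stop] += amplitude * v[: stop - bin_index]
    return y
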