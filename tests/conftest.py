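import numpy as np
import pytest

import rgbtrace as rt


@pytest.fixture
def noiseless_scene():
    """Small noiseless rendered scene whose truth the pipeline must recover.

    Expression strengths and autofluorescence are chosen so that every
    labelled copy pattern clears both the per-channel threshold (40) and
    the luma brightness gate (40): one blue copy gives intensity 200 and
    brightness 0.886*20 + 0.114*200 = 40.5.
    """
    rng = np.random.default_rng(42)
    vectors = rt.VectorSet.from_probabilities(
        0.5, 0.5, 0.5, expr_r=180.0, expr_g=180.0, expr_b=180.0)
    noise = rt.NoiseModel(expr_cv=0.0, channel_cv=0.0, autofluor_mean=20.0)
    population = rt.generate_population(vectors, 60, noise, rng)
    scene = rt.render_scene(population, shape=(360, 360),
                            cell_radius_px=(4.0, 6.0), blur_sigma=0.0,
                            background=0.0, rng=rng)
    return scene
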