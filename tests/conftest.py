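import numpy as np
import pytest

from echodose import LesionModel, SpeckleParams, plant_lesions, simulate_speckle_background


@pytest.fixture(scope="session")
def speckle_frame():
    """Default 256x256 Rayleigh speckle background, fixed seed."""
    return simulate_speckle_background(SpeckleParams(seed=42))


@pytest.fixture(scope="session")
def planted_disc_frame(speckle_frame):
    """Speckle frame with 3 manually planted bright discs (radius 10 px) + truth mask.

    The boost (90 gray levels) is more than 5 background SDs, so every disc
    is unambiguously detectable.
    """
    pixels = speckle_frame.pixels.astype(float)
    yy, xx = np.mgrid[0 : pixels.shape[0], 0 : pixels.shape[1]]
    mask = np.zeros(pixels.shape, dtype=bool)
    for cr, cc in ((60, 60), (60, 180), (180, 120)):
        disc = (yy - cr) ** 2 + (xx - cc) ** 2 <= 100
        pixels[disc] += 90
        mask |= disc
    frame = type(speckle_frame)(
        pixels=np.clip(pixels, 0, 255).astype(np.uint8),
        pixel_spacing=speckle_frame.pixel_spacing,
        dose=2.0,
    )
    return frame, mask


@pytest.fixture(scope="session")
def lesion_dataset():
    """50 seeded frames with well-separated planted foci and ground truth."""
    model = LesionModel(min_separation=0.20)
    out = []
    for seed in range(50):
        bg = simulate_speckle_background(SpeckleParams(seed=seed))
        out.append(plant_lesions(bg, 3.0, model, seed=1000 + seed))
    return out
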