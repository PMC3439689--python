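import numpy as np
import pytest
from hypothesis import settings

from myocfc import (
    Channel,
    ChannelPlane,
    RunConfig,
    SyntheticColonySpec,
    analyze_micrographs,
    generate_colony,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("ci")


def make_plane(pixels, channel=Channel.DAPI_BLUE, image_id="test"):
    return ChannelPlane(
        channel=channel,
        pixels=np.asarray(pixels, dtype=np.float64),
        source_image_id=image_id,
    )


@pytest.fixture(scope="session")
def default_colony():
    """One synthetic colony with its ground truth (fixed seed)."""
    return generate_colony(SyntheticColonySpec(seed=7))


@pytest.fixture(scope="session")
def analyzed_batch():
    """A 10-image synthetic batch run through the in-memory pipeline."""
    micrographs, truths = [], []
    for seed in range(100, 110):
        m, t = generate_colony(SyntheticColonySpec(seed=seed))
        micrographs.append(m)
        truths.append(t)
    config = RunConfig(input_dir=".", output_dir=".")
    batch = analyze_micrographs(micrographs, config)
    return micrographs, truths, batch
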