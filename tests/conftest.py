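import numpy as np
import pytest

from temsig import synthetic


@pytest.fixture(scope="session")
def small_movie():
    """Noise-free 6-cell movie on a 256 px field; shared across tests."""
    spec = synthetic.SceneSpec(field_size_px=(256, 256), n_cells=6,
                               n_frames=8, stimulus_frame=3, seed=11)
    nuc, ktr, truth = synthetic.gen_ktr_movie(spec, "neutrophil",
                                              noise_sd=0.0, background_amp=0.0)
    return spec, nuc, ktr, truth


def make_disk_stack(centers_per_frame, radius, shape=(128, 128)):
    """Label movie of one disk per listed center, one frame per entry."""
    frames = []
    for centers in centers_per_frame:
        lab = np.zeros(shape, dtype=np.int32)
        for k, (r0, c0) in enumerate(centers, start=1):
            rr = np.arange(shape[0])[:, None] - r0
            cc = np.arange(shape[1])[None, :] - c0
            lab[rr * rr + cc * cc <= radius * radius] = k
        frames.append(lab)
    return np.stack(frames)
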