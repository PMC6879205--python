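import numpy as np
import pytest

from ribbonquant import puncta as P
from ribbonquant import synthdata as S
from ribbonquant.synthdata import _render_blob, _sigma_from_area

VOXEL = (0.3, 0.05, 0.05)


def blob_stack(centers_um, areas_um2, amps, shape=(24, 128, 128), channel="ribbon",
               axial_elongation=3.0):
    """Render noise-free Gaussian blobs into a fresh VolumeStack."""
    vox = np.zeros(shape)
    for c, a, amp in zip(centers_um, areas_um2, amps):
        sig = _sigma_from_area(a)
        _render_blob(vox, c, (axial_elongation * sig, sig, sig), amp, VOXEL)
    return P.VolumeStack(vox, VOXEL, channel)


@pytest.fixture(scope="session")
def recovery_phantom():
    """50 ground-truth synapses plus 10 isolated ribbons, noise off."""
    spec = S.ImagePhantomSpec(
        stack_shape=(24, 256, 256), n_cells=10, ribbons_per_cell=6,
        paired_fraction=50 / 60, n_extrasynaptic=0,
        poisson_gain=0.0, gaussian_sd=0.0, background=(5.0, 5.0), seed=11,
    )
    return S.simulate_stack(spec)


from ribbonquant.experiments import segment_channel  # noqa: E402,F401  (shared pipeline helper)
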