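import numpy as np
import pytest

from afmwlc.synthetic_data import Polymer2D, RenderParams, render_afm, sample_wlc_2d
from afmwlc.tracing import TraceResult, segment_molecules, trace_backbone


@pytest.fixture(scope="session")
def noiseless_params() -> RenderParams:
    return RenderParams(noise_sd_nm=0.0)


@pytest.fixture(scope="session")
def rod_setup(noiseless_params):
    """A straight 328 nm rod rendered on a pixel-center row, with its trace."""
    # y = 511 nm lies on a pixel center at 2 nm/px ((r + 0.5) * 2)
    pts = np.column_stack([np.linspace(348.0, 676.0, 165), np.full(165, 511.0)])
    rod = Polymer2D(pts, closed=False, true_lp=1e12, true_contour=328.0, seed=0)
    image = render_afm(rod, noiseless_params, seed=0)
    regions = segment_molecules(image)
    assert len(regions) == 1
    trace = trace_backbone(image, regions[0])
    return rod, image, regions[0], trace


@pytest.fixture(scope="session")
def wlc_truth_traces():
    """Ground-truth open WLC chains (Lp 56 nm, 8 nm segments) as traces.

    The generator's own segment tangents are the oracle for the 2D WLC
    correlation and angle-variance laws.
    """
    traces = []
    for i in range(400):
        poly = sample_wlc_2d(n_segments=114, seg_len=8.0, lp=56.0, seed=10_000 + i)
        traces.append(TraceResult(points=poly.vertices, step_nm=8.0, closed=False))
    return traces
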