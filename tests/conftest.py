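import numpy as np
import pytest

from sporoquant import segmentation, synthetic


@pytest.fixture
def clean_field():
    """Noise-free four-sporangium field with ground truth."""
    params = synthetic.SporangiumImageParams(seed=11, n_sporangia=4)
    stack, truth = synthetic.generate_sporangium_image(params)
    return params, stack, truth


@pytest.fixture
def single_sporangium():
    """Noise-free single sporangium, segmented and paired."""
    params = synthetic.SporangiumImageParams(seed=3, n_sporangia=1)
    stack, truth = synthetic.generate_sporangium_image(params)
    high, low = segmentation.auto_thresholds(stack)
    pairs = segmentation.segment_and_pair(stack, high, low)
    assert len(pairs) == 1
    return params, stack, truth, pairs[0]


def segment_with_auto(stack):
    high, low = segmentation.auto_thresholds(stack)
    forespores, whole = segmentation.segment_membrane(stack, high, low)
    mothers = segmentation.derive_mother_cells(whole, forespores, stack)
    return forespores, mothers


def truth_fs_centroids(truth):
    """Centroids (row, col) of the ground-truth forespore masks by label."""
    out = {}
    for lab in np.unique(truth.fs_labels):
        if lab == 0:
            continue
        rows, cols = np.nonzero(truth.fs_labels == lab)
        out[int(lab)] = np.array([rows.mean(), cols.mean()])
    return out
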