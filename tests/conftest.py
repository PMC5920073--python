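import math
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from ld3d import synthetic
from ld3d.stack_io import Calibration

UNIT_CAL = Calibration(1.0, 1.0, 1.0)


@pytest.fixture
def unit_cal():
    return UNIT_CAL


@pytest.fixture(scope="session")
def tiny_spec():
    """A small multi-cell field with modest droplets; seconds to generate."""
    return synthetic.SyntheticSpec(
        field_shape=(16, 96, 96),
        calibration=synthetic.DESK_CALIBRATION,
        n_cells=4,
        wall_um=4.0,
        droplets_per_cell=12.0,
        diam_lognorm=(math.log(2.2), 0.30),
        diam_range_um=(1.5, 3.5),
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_field(tiny_spec):
    """(fluorescence, brightfield, truth) with blur and noise on."""
    return synthetic.generate_field(tiny_spec)


@pytest.fixture(scope="session")
def tiny_field_clean(tiny_spec):
    """Same scene, rendered without blur or noise."""
    return synthetic.generate_field(synthetic.noise_free(tiny_spec))


def match_labels(truth_labels: np.ndarray, seg_labels: np.ndarray) -> dict:
    """Best Jaccard overlap for each truth label against any segmented label."""
    out = {}
    for tid in np.unique(truth_labels):
        if tid == 0:
            continue
        tm = truth_labels == tid
        overlapping = np.unique(seg_labels[tm])
        best = 0.0
        for sid in overlapping:
            if sid == 0:
                continue
            sm = seg_labels == sid
            best = max(best, np.logical_and(tm, sm).sum() / np.logical_or(tm, sm).sum())
        out[int(tid)] = best
    return out
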