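import numpy as np
import pytest

from radassay import imgseg, synthgen as sg


@pytest.fixture(scope="session")
def timelapse_small():
    """A 50-cell two-group GEDI timelapse with ground truth."""
    params = sg.TimelapseParams(
        n_cells=50,
        field_size=(512, 512),
        hazard_per_group={"control": 0.12, "sev_high": 0.04},
        seed=7,
    )
    frames, truth = sg.gen_timelapse(params)
    return params, frames, truth


@pytest.fixture(scope="session")
def foci_field():
    """A 60-nucleus foci field (lambda = 5) with segmented nuclei."""
    frame, truth = sg.gen_foci_stack(n_cells=60, lambda_per_group=5.0, seed=3)
    nuclei = imgseg.segment_nuclei(frame)
    return frame, truth, nuclei


def match_objects_to_truth(table, truth_cells):
    """Index of the nearest true cell for each segmented object."""
    from scipy.spatial import cKDTree

    tree = cKDTree(truth_cells[["row", "col"]].to_numpy())
    dist, idx = tree.query(table[["centroid_row", "centroid_col"]].to_numpy())
    return dist, idx
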