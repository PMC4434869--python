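import numpy as np
import pytest

from ctcemt.records import REFERENCE_PROFILES
from ctcemt.synthetic import CytospinLayout, generate_cytospin_image


@pytest.fixture(scope="session")
def cytospin_fixture():
    """Default cytospin field (3 CTCs + 10 PBMCs), MCF-7 CTC signal, seed 11."""
    layout = CytospinLayout(seed=11)
    image, truth = generate_cytospin_image(layout, REFERENCE_PROFILES["MCF-7"])
    return layout, image, truth


def match_to_truth(regions_centroids, truth):
    """Index of the nearest planted cell for each segmented centroid."""
    centers = truth[["center_row", "center_col"]].to_numpy()
    out = []
    for r, c in regions_centroids:
        d2 = (centers[:, 0] - r) ** 2 + (centers[:, 1] - c) ** 2
        out.append(int(np.argmin(d2)))
    return out
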