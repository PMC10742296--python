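import numpy as np
import pytest
from shapely.geometry import box

from tilscore.nuclei_io import NucleusRecord, SlideNucleiMap
from tilscore.spatial_clustering import ClusterPartition


def square_contour(cx: float, cy: float, side: float) -> np.ndarray:
    h = side / 2.0
    return np.array(
        [[cx - h, cy - h], [cx + h, cy - h], [cx + h, cy + h], [cx - h, cy + h]]
    )


@pytest.fixture
def toy_slide() -> SlideNucleiMap:
    """Hand-placed slide: 4 tumour + 2 TIL in a 100x100 inner box, 1 tumour
    + 3 TIL in the 50x100 ring to its right, 1 'other' far away.

    Tumour nuclei have area 100 px^2, TILs 30 px^2 (set directly, no
    contours except the intratumoural tumour nuclei which carry 10x10
    squares so morphology is computable).
    """
    nuclei = [
        NucleusRecord("t0", 20, 50, "tumour", contour=square_contour(20, 50, 10)),
        NucleusRecord("t1", 40, 50, "tumour", contour=square_contour(40, 50, 10)),
        NucleusRecord("t2", 60, 50, "tumour", contour=square_contour(60, 50, 10)),
        NucleusRecord("t3", 80, 50, "tumour", contour=square_contour(80, 50, 10)),
        NucleusRecord("t4", 125, 50, "tumour", area=100.0),  # in the ring
        NucleusRecord("l0", 30, 40, "lymphocyte", area=30.0),
        NucleusRecord("l1", 70, 60, "lymphocyte", area=30.0),
        NucleusRecord("l2", 110, 20, "lymphocyte", area=30.0),
        NucleusRecord("l3", 130, 50, "lymphocyte", area=30.0),
        NucleusRecord("l4", 140, 80, "lymphocyte", area=30.0),
        NucleusRecord("o0", 4000, 4000, "other", area=110.0),
    ]
    return SlideNucleiMap(slide_id="toy", nuclei=nuclei)


@pytest.fixture
def toy_partition(toy_slide) -> ClusterPartition:
    """Partition matching ``toy_slide``: inner box [0,100]^2 (area 10000),
    expanded box [0,150]x[0,100] so the outer ring has area 5000.

    The five tumour nuclei map to labels [0, 0, 0, 0, -1]: four clustered,
    one noise sitting in the ring.
    """
    inner = box(0, 0, 100, 100)
    expanded = box(0, 0, 150, 100)
    ring = expanded.difference(inner)
    pts = np.array([[20, 50], [40, 50], [60, 50], [80, 50], [125, 50.0]])
    labels = np.array([0, 0, 0, 0, -1])
    return ClusterPartition(
        points=pts,
        labels=labels,
        inner_regions=[inner],
        expanded_regions=[expanded],
        outer_rings=[ring],
        inner_union=inner,
        expanded_union=expanded,
        ring_union=ring,
    )
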