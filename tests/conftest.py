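import numpy as np
import pytest

from transcallosal import (
    assign_endpoints,
    segment_cc,
    streamline_segments,
    triangle_counts,
)
from transcallosal.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic dataset shared across the suite."""
    return generate_dataset(
        SyntheticConfig(
            seed=11, n_streamlines=2000, mesh_triangles_per_hemisphere=1000
        )
    )


@pytest.fixture(scope="session")
def small_pipeline(small_dataset):
    """Assignment, fields and segment passage for the shared dataset."""
    ds = small_dataset
    assignment = assign_endpoints(ds.tractogram, ds.surfaces)
    fields = tuple(triangle_counts(assignment, s) for s in ds.surfaces)
    segmentation = segment_cc(ds.mask)
    segments = streamline_segments(ds.tractogram, segmentation, ds.mask)
    return {
        "dataset": ds,
        "assignment": assignment,
        "fields": fields,
        "segmentation": segmentation,
        "segments": segments,
    }


@pytest.fixture
def unit_square_surface():
    """Four vertices, two triangles in the z=0 plane (left hemisphere)."""
    from transcallosal import CorticalSurface

    vertices = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [1.0, 1.0, 0.0]]
    )
    triangles = np.array([[0, 1, 2], [1, 3, 2]])
    return CorticalSurface(vertices, triangles, "left")


def surface_pair_from_grids(left_vertices, right_vertices, triangles):
    from transcallosal import CorticalSurface

    return (
        CorticalSurface(left_vertices, triangles, "left"),
        CorticalSurface(right_vertices, triangles, "right"),
    )
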