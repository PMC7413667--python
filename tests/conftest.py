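import numpy as np
import pytest
import trimesh
from hypothesis import HealthCheck, settings

from mitoloc.geometry import CellGeometry, SurfaceMesh

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def icosphere(subdivisions=3, radius=1.0, center=(0, 0, 0), label="cell"):
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(ico.vertices + np.asarray(center, float), ico.faces, label=label)


def unit_cube(label="cell"):
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return SurfaceMesh(box.vertices, box.faces, label=label)


@pytest.fixture(scope="session")
def sphere_cell():
    """Spherical cell (R = 2 µm) with one central spherical mitochondrion
    (r = 0.5 µm): every quantity has a closed form."""
    return CellGeometry(
        cell=icosphere(3, 2.0),
        mitochondria=[icosphere(3, 0.5, label="mitochondrion")],
        cell_id="sphere_cell",
    )


@pytest.fixture(scope="session")
def small_population():
    """A small synthetic population reused by the slower tests."""
    from mitoloc.synthetic import PopulationSpec, generate_cell_population

    spec = PopulationSpec(n_cells=4, volume_fraction_range=(0.08, 0.30), seed=11)
    geoms, summaries = generate_cell_population(spec)
    return spec, geoms, summaries
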