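import warnings

import numpy as np
import pytest

from fetaldot.optics import CardiacPhase, PropertyField
from fetaldot.phantom import PhantomSpec, TetMesh, structured_box_mesh


def homogeneous_box(size, h, mua=0.1, musp=10.0, n=1.4, origin=None):
    """Homogeneous box fixture: (mesh, props)."""
    if origin is None:
        origin = (-size[0] / 2, -size[1] / 2, 0.0)
    nodes, elems = structured_box_mesh(size, h, origin=origin)
    mesh = TetMesh(nodes, elems, np.zeros(len(elems), dtype=np.int64))
    props = PropertyField(
        wavelength=800.0,
        phase=CardiacPhase.STATIC,
        mua=np.full(mesh.num_elements, float(mua)),
        musp=np.full(mesh.num_elements, float(musp)),
        n=np.full(mesh.num_elements, float(n)),
    )
    return mesh, props


@pytest.fixture(scope="session")
def tiny_box():
    """<=500-node homogeneous cube for dense linear-algebra oracles."""
    return homogeneous_box((20.0, 20.0, 20.0), 5.0)


@pytest.fixture(scope="session")
def small_slab():
    """Moderate homogeneous slab for reciprocity/decay/patch tests."""
    return homogeneous_box((80.0, 80.0, 30.0), 4.0)


@pytest.fixture(scope="session")
def fd_box():
    """<=2k-node box for the finite-difference Jacobian oracle."""
    return homogeneous_box((50.0, 50.0, 25.0), 5.0)


@pytest.fixture(scope="session")
def mini_phantom_spec():
    """Scaled-down maternal-fetal phantom spec for fast structural tests."""
    return PhantomSpec(
        fat_thickness=5.0,
        muscle_thickness=5.0,
        fluid_gap=2.0,
        fetal_head_radius=20.0,
        scalp_thickness=1.5,
        skull_thickness=1.5,
        csf_thickness=1.5,
        lateral_extent=(90.0, 70.0),
        depth_extent=45.0,
        target_edge_length=5.0,
    )


@pytest.fixture(scope="session")
def mini_phantom(mini_phantom_spec):
    from fetaldot.phantom import build_phantom

    return build_phantom(mini_phantom_spec, seed=0)


@pytest.fixture(autouse=True)
def _silence_diffusion_warning():
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*low-scattering regions.*"
        )
        yield
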