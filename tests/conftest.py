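import numpy as np
import pytest

from nladmm.ct.forward import (
    ImageGrid,
    ScanGeometry,
    build_projection_matrix,
    expected_counts,
    forward_project,
    simulate_counts,
)
from nladmm.synthetic import (
    CT_MATERIALS,
    Insert,
    PhantomSpec,
    builtin_attenuation,
    generate_phantom,
    generate_spectrum,
)


@pytest.fixture(scope="session")
def tiny_ct():
    """8x8 grid, 12x12 rays, 10 energy bins: a fast but nondegenerate scan."""
    grid = ImageGrid(8, 8, side_cm=10.0)
    geom = ScanGeometry(n_angles=12, n_cells=12, grid=grid)
    P = build_projection_matrix(grid, geom)
    spectrum = generate_spectrum(ni=10, nw=3, total_photons=1e6)
    att = builtin_attenuation(CT_MATERIALS, spectrum.energies)
    phantom = generate_phantom(
        PhantomSpec(
            grid,
            3,
            [
                Insert("disk", (0.0, 0.0), 4.0, 0, 1.0),
                Insert("disk", (-2.0, 0.0), 1.2, 1, 1.0),
                Insert("disk", (2.0, 0.0), 1.2, 2, 1.0),
            ],
        )
    )
    y_true = forward_project(P, phantom)
    mean = expected_counts(y_true, spectrum, att)
    counts = simulate_counts(mean, seed=11)
    return {
        "grid": grid,
        "geometry": geom,
        "P": P,
        "spectrum": spectrum,
        "attenuation": att,
        "phantom": phantom,
        "y_true": y_true,
        "mean": mean,
        "counts": counts,
    }
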