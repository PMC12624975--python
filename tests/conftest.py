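"""Shared fixtures: the expensive mechanical studies are computed once per
session and shared by the acceptance tests."""

import numpy as np
import pytest


@pytest.fixture(scope="session")
def ordering_study():
    """Reduced-grid (4x4) micromotion continuation solve to 50 um with ROI
    tables captured at 1, 5, 10, 20, 50 um, plus 3 um tip submodels at the
    10 um state."""
    from arraystrain.fem import SolverParams
    from arraystrain.studies import strain_ordering_study

    return strain_ordering_study(
        magnitudes=(1.0, 5.0, 10.0, 20.0, 50.0),
        submodel_magnitude=10.0,
        params=SolverParams(n_load_steps=5, newton_rtol=3e-4,
                            krylov_rtol=1e-4),
        sub_params=SolverParams(n_load_steps=2, newton_rtol=1e-4))


@pytest.fixture(scope="session")
def angle_tables(ordering_study):
    """Group-mean ROI strains at 10 um displacement for in-plane angles
    22.5 and 45 degrees (plus the magnitude checkpoints at angle 0)."""
    from arraystrain.fem import SolverParams
    from arraystrain.studies import magnitude_angle_study

    return magnitude_angle_study(
        ordering_study, angles=(22.5, 45.0),
        params=SolverParams(n_load_steps=2, newton_rtol=3e-4,
                            krylov_rtol=1e-4))


@pytest.fixture(scope="session")
def convergence_table():
    """Single-shank tip-edge sweep {3, 2, 1, 0.5} um."""
    from arraystrain.studies import convergence_study

    return convergence_study(edge_sizes=(3.0, 2.0, 1.0, 0.5))
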