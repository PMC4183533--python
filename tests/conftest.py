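"""Shared fixtures.

Heavy objects (the reference domain, its meshes, the reduced simulation
grid) are session-scoped so the whole suite builds them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from dcevox.aif import AIFModel
from dcevox.geometry import TissueDomain, generate_domain, tile_extended_domain
from dcevox.meshing import mesh_ees

REFERENCE_SEED = 1


@pytest.fixture(scope="session")
def aif() -> AIFModel:
    return AIFModel()


@pytest.fixture(scope="session")
def reference_domain() -> TissueDomain:
    """The packed voxel: 250 um side, v_e = 0.39, v_p = 0.03."""
    return generate_domain(seed=REFERENCE_SEED)


@pytest.fixture(scope="session")
def extended_domain(reference_domain):
    return tile_extended_domain(reference_domain)


@pytest.fixture(scope="session")
def reference_mesh(reference_domain):
    """Single-tile mesh at the coarse (6 um) test resolution."""
    return mesh_ees(reference_domain, target_edge=6e-3)


@pytest.fixture(scope="session")
def extended_mesh(extended_domain):
    """Extended 3x3 mesh at the coarse (6 um) test resolution."""
    return mesh_ees(extended_domain, target_edge=6e-3)


@pytest.fixture(scope="session")
def fine_mesh(reference_domain):
    """Single-tile mesh at the high-fidelity 2 um setting."""
    return mesh_ees(reference_domain, target_edge=2e-3)


@pytest.fixture(scope="session")
def square_domain() -> TissueDomain:
    """A plain 100 um square with no cells or vessels (analytic test bed)."""
    return TissueDomain(
        voxel_side=0.1, ve_achieved=1.0, vp_achieved=0.0, veis_achieved=0.0
    )


@pytest.fixture(scope="session")
def square_mesh(square_domain):
    return mesh_ees(square_domain, target_edge=5e-3)


REDUCED_D_SWEEP = (1e-4, 2e-4, 4e-4, 3e-3)
REDUCED_KTRANS = 0.4


@pytest.fixture(scope="session")
def reduced_runs(aif, extended_domain, extended_mesh):
    """Simulations behind the reduced error grid: reference domain,
    K^trans = 0.4 1/min, four diffusion coefficients.

    Returns ``{D: (times, voxel_mean, r1_trajectory)}``.
    """
    from dcevox.experiment import ExperimentConfig, run_cell

    cfg = ExperimentConfig(
        Ktrans_list=(REDUCED_KTRANS,),
        ve_list=(0.39,),
        vp_list=(0.03,),
        D_list=REDUCED_D_SWEEP,
        seed=REFERENCE_SEED,
        aif=aif,
    )
    runs = {}
    for D in REDUCED_D_SWEEP:
        ctc, r1 = run_cell(extended_domain, extended_mesh, REDUCED_KTRANS, D, cfg)
        runs[D] = (ctc.times, ctc.voxel_mean, r1)
    return runs


@pytest.fixture(scope="session")
def reduced_grid(aif, extended_domain, reduced_runs):
    """Fit-error table over the reduced runs x all five sampling intervals."""
    from dcevox.experiment import ExperimentConfig, _fit_rows
    import pandas as pd

    cfg = ExperimentConfig(
        Ktrans_list=(REDUCED_KTRANS,), D_list=REDUCED_D_SWEEP,
        seed=REFERENCE_SEED, aif=aif,
    )
    rows = []
    for D, (times, _, r1) in reduced_runs.items():
        rows.extend(_fit_rows(r1, times, extended_domain, REDUCED_KTRANS, D, cfg))
    return pd.DataFrame(rows)
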