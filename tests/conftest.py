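import numpy as np
import pytest

from vesselrom import (
    MeshResolution,
    RunConfig,
    default_reference_vessels,
    generate_dataset,
    run_pipeline,
    solve_flow,
)

SMALL_RES = MeshResolution(n_axial=21, n_circ=8, n_radial=2)

TINY_CONFIG = RunConfig(
    n_perturb=10,
    n_axial=21,
    n_circ=8,
    n_radial=2,
    perplexity=5.0,
    n_trees=10,
    max_depth=8,
    n_split_repeats=2,
    seed=11,
)


@pytest.fixture(scope="session")
def small_res():
    return SMALL_RES


@pytest.fixture(scope="session")
def small_refs():
    return default_reference_vessels(SMALL_RES.n_axial)


@pytest.fixture(scope="session")
def small_geoms(small_refs):
    """3 parents x 8 perturbations + parents = 27 small meshes."""
    return generate_dataset(small_refs[:3], 8, seed=5, resolution=SMALL_RES)


@pytest.fixture(scope="session")
def small_sols(small_geoms):
    return [solve_flow(g) for g in small_geoms]


@pytest.fixture(scope="session")
def tiny_run(tmp_path_factory):
    """One completed end-to-end pipeline run at reduced scale (77 meshes)."""
    outdir = tmp_path_factory.mktemp("tiny_run")
    result = run_pipeline(TINY_CONFIG, outdir)
    return result, outdir
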