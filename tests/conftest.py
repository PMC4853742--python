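import numpy as np
import pytest

from ticseq.pipeline import RunConfig, run_pipeline
from ticseq.structures import AminoAcidStructure, load_residue_template


@pytest.fixture(scope="session")
def lys():
    return load_residue_template("LYS")


@pytest.fixture(scope="session")
def gly():
    return load_residue_template("GLY")


@pytest.fixture(scope="session")
def glu():
    return load_residue_template("GLU")


@pytest.fixture()
def single_sphere():
    """One vdW sphere of radius 2 A at the origin."""
    return AminoAcidStructure.from_spheres([[0.0, 0.0, 0.0]], [2.0])


@pytest.fixture()
def two_spheres():
    """Two overlapping spheres of radius 1.5 A at z = +/- 1 A."""
    return AminoAcidStructure.from_spheres(
        [[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]], [1.5, 1.5]
    )


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One reduced-scale full pipeline run shared by the slower tests.

    20,000 Monte Carlo samples per residue keeps the run around a minute
    while leaving the empirical current supports stable to ~0.1 nA.
    """
    outdir = tmp_path_factory.mktemp("pipeline")
    cfg = RunConfig(n_samples=20_000, J=1000, m_grid=(1, 50, 175), seed=1)
    return cfg, outdir, run_pipeline(cfg, outdir)


@pytest.fixture(scope="session")
def fixture_distributions(pipeline_run):
    _, _, result = pipeline_run
    return [result["distributions"][c] for c in sorted(result["distributions"])]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
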