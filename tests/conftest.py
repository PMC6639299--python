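import warnings

import numpy as np
import pytest

from npcradiomics.imaging_io import ImageVolume, ROIMask
from npcradiomics.synthetic_data import PhantomSpec, generate_phantom

# coxnet warns whenever the strongest penalty zeroes every coefficient,
# which is by construction true at the top of every path
warnings.filterwarnings("ignore", message="all coefficients are zero")


@pytest.fixture(scope="session")
def e2e_run(tmp_path_factory):
    """One full n=60 synthetic-cohort analysis, run twice with the same
    configuration (for determinism checks), plus its wall-clock time."""
    import time

    from npcradiomics.pipeline import PipelineConfig, run_full_analysis

    root = tmp_path_factory.mktemp("e2e")

    def _config(out):
        return PipelineConfig(
            out_dir=str(out), seed=1, split_fraction=40 / 60,
            n_bootstrap=200,
            synthetic={"n_patients": 60, "n_dual_contoured": 19})

    t0 = time.perf_counter()
    report = run_full_analysis(_config(root / "run1"))
    elapsed = time.perf_counter() - t0
    report2 = run_full_analysis(_config(root / "run2"))
    return {"report": report, "report2": report2, "elapsed": elapsed,
            "dir1": root / "run1", "dir2": root / "run2"}


@pytest.fixture(scope="session")
def phantom_pair():
    """One deterministic smooth phantom (volume, mask)."""
    return generate_phantom(PhantomSpec(phenotype="smooth", seed=11))


@pytest.fixture(scope="session")
def het_phantom_pair():
    return generate_phantom(PhantomSpec(phenotype="heterogeneous", seed=11))


@pytest.fixture
def toy_image():
    """The 4x4 single-slice toy image used for texture-matrix oracles."""
    plane = np.array([[0, 0, 1, 1],
                      [0, 0, 1, 1],
                      [0, 2, 2, 2],
                      [2, 2, 3, 3]], dtype=float)
    volume = ImageVolume(plane[None, :, :])
    mask = ROIMask(np.ones((1, 4, 4), dtype=np.uint8))
    return volume, mask


@pytest.fixture(scope="session")
def sphere_mask():
    """A radius-10 sphere on a 24^3 grid."""
    g = np.mgrid[:24, :24, :24].astype(float)
    d2 = sum((g[i] - 11.5) ** 2 for i in range(3))
    return ROIMask((d2 <= 100).astype(np.uint8))
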