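import numpy as np
import pytest

from mzcanvas.pepcalc import Modification, Peptide
from mzcanvas.spectra_io import read_run
from mzcanvas.synth import NoiseModel, demo_specs, make_run


@pytest.fixture(scope="session")
def clean_run_dir(tmp_path_factory):
    """Zero-noise 10-peptide run: mzML path + spectra + truth table."""
    d = tmp_path_factory.mktemp("clean_run")
    path = str(d / "clean.mzML")
    spectra, truth = make_run(demo_specs(10), seed=11, out_path=path)
    return path, spectra, truth


@pytest.fixture(scope="session")
def clean_run(clean_run_dir):
    path, _, _ = clean_run_dir
    return read_run(path)


@pytest.fixture(scope="session")
def clean_truth(clean_run_dir):
    return clean_run_dir[2]


@pytest.fixture(scope="session")
def noisy_run_dir(tmp_path_factory):
    """Signal-to-noise ~10 run with m/z jitter, fixed seed."""
    d = tmp_path_factory.mktemp("noisy_run")
    path = str(d / "noisy.mzML")
    noise = NoiseModel(baseline_density=20.0, intensity_scale=1e5,
                       mz_jitter_ppm=2.0)
    spectra, truth = make_run(demo_specs(10), noise, seed=7, out_path=path)
    return path, spectra, truth


@pytest.fixture
def phosphopeptide():
    return Peptide("SAMPLESTER", (Modification(7, 79.966331, "phospho"),))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
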