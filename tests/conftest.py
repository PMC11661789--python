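import pytest

from thonring import (
    Micrograph,
    OpticsParams,
    RunConfig,
    SyntheticSpec,
    estimate_ctf,
    synth_micrograph,
)


@pytest.fixture(scope="session")
def optics():
    return OpticsParams()


@pytest.fixture(scope="session")
def tilt20_fixture():
    """Shared 20-degree tilted micrograph with its ground truth.

    2048 px at 2.0 A/px (a ~4100 A field of view, typical of counting-mode
    micrographs) so the defocus gradient across the image is realistic.
    """
    spec = SyntheticSpec(
        size=2048, pixel_size=2.0, defocus_1=10000.0, defocus_2=10000.0,
        tilt_theta_deg=20.0, tilt_phi_deg=120.0, seed=3,
    )
    return spec, synth_micrograph(spec)


@pytest.fixture(scope="session")
def tilt20_estimates(tilt20_fixture):
    """Uncorrected and tilt-corrected estimates of the shared 20-deg fixture."""
    spec, img = tilt20_fixture
    mic = Micrograph(img, spec.pixel_size, spec.optics)
    uncorrected = estimate_ctf(mic, RunConfig(res_high=4.2))
    corrected = estimate_ctf(mic, RunConfig(res_high=4.2, estimate_tilt=True))
    return spec, uncorrected, corrected
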