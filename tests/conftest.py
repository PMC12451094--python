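import numpy as np
import pytest

from pigmentox.dataio import AbsorbanceSpectrum, SampleMeta


@pytest.fixture
def meta():
    return SampleMeta(sample_id="s1", pH=2.0, extract_dose=0.73, replicate=1)


@pytest.fixture
def make_spectrum(meta):
    """Factory for clean synthetic spectra on a 1 nm grid over 380–780 nm."""

    def _make(absorbance, day: float = 0.0, pH: float = 2.0):
        wl = np.arange(380.0, 781.0, 1.0)
        if np.isscalar(absorbance):
            a = np.full_like(wl, float(absorbance))
        elif callable(absorbance):
            a = absorbance(wl)
        else:
            a = np.asarray(absorbance, dtype=float)
        m = SampleMeta(sample_id=meta.sample_id, pH=pH, extract_dose=meta.extract_dose)
        return AbsorbanceSpectrum(meta=m, wavelengths=wl, absorbances=a, day=day)

    return _make


@pytest.fixture
def gaussian_band(make_spectrum):
    """Single Gaussian absorption band: amp·exp(−(λ−center)²/2σ²)."""

    def _make(center: float, amp: float = 1.0, width: float = 40.0, baseline: float = 0.0):
        return make_spectrum(lambda wl: amp * np.exp(-0.5 * ((wl - center) / width) ** 2) + baseline)

    return _make
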