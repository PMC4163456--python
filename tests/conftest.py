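import numpy as np
import pytest

from ramandx import preprocess as pp
from ramandx import synthetic_data as sd
from ramandx.spectra_io import Label, Spectrum, SpectrumMeta, SpectrumSet


@pytest.fixture
def axis():
    return 580.0 + np.arange(1221.0)


@pytest.fixture
def small_set():
    """5 x 50 synthetic set with mixed labels and coordinates."""
    rng = np.random.default_rng(7)
    ax = np.linspace(600.0, 700.0, 50)
    labels = [Label.TUMOR, Label.TUMOR, Label.NORMAL, Label.NORMAL, Label.BORDERLINE]
    metas = [
        SpectrumMeta(
            spectrum_id=f"s{i}",
            sample_id=f"sample{i % 2}",
            label=lab,
            x_um=float(i * 10),
            y_um=0.0,
        )
        for i, lab in enumerate(labels)
    ]
    return SpectrumSet(ax, rng.normal(5.0, 1.0, (5, 50)), metas)


@pytest.fixture
def noiseless_cfg():
    """Band sum only: no baseline, noise, spikes or group effect."""
    return sd.GenerativeConfig(
        bands=sd.default_bands(tumor_effect=2.0),
        baseline_coeffs=(0.0,),
        noise_sd=0.0,
        cosmic_rate=0.0,
        group_sd=0.0,
        seed=0,
    )


@pytest.fixture
def strong_cell_set():
    """Preprocessed strong-effect cell experiment (shared across tests)."""
    cfg = sd.default_config(tumor_effect=2.0, seed=11)
    raw = sd.simulate_cell_experiment(cfg=cfg)
    return pp.preprocess_spectra(raw, pp.PreprocessConfig())


def make_spectrum(ax, y, **meta):
    return Spectrum(ax, y, SpectrumMeta(**{"spectrum_id": "s", **meta}))
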