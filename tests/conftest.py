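import numpy as np
import pytest

from narpam import synthgen as sg


@pytest.fixture(scope="session")
def basic_scene():
    """One 5-s scene with a single 12-click narwhal train at 130 dB_pp."""
    cfg = sg.SceneConfig(
        duration_s=5.0, trains=(sg.NarwhalTrainSpec(start_s=1.0),), seed=11
    )
    audio, truth = sg.gen_scene(cfg)
    return cfg, audio, truth


def make_detections(times_s, peak_khz, ici_s=None, rl_db_pp=130.0, n_spec_bins=201):
    """Construct ImpulseDetection objects with stylized Gaussian-bump spectra.

    Spectrum grid: 500 Hz bins from 0 to 100 kHz.  Lets clustering tests
    control spectral shape and timing exactly without audio synthesis.
    """
    from narpam.clickdet import ImpulseDetection

    freqs_khz = np.arange(n_spec_bins) * 0.5
    dets = []
    for t in np.atleast_1d(times_s):
        spec = -40.0 + 40.0 * np.exp(-((freqs_khz - peak_khz) ** 2) / (2 * 8.0**2))
        dets.append(
            ImpulseDetection(
                time_s=float(t),
                snippet=np.zeros(8),
                duration_us=200.0,
                peak_freq_khz=float(peak_khz),
                rl_db_pp=float(rl_db_pp),
                envelope_ratio=0.0,
                spectrum=spec,
                clipped=False,
            )
        )
    return dets
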