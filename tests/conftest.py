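import numpy as np
import pytest

from ceustic import phantom as ph


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Small noiseless, motionless phantom with a hypoenhanced mass.

    Mass kinetics: gamma-variate with t0=10 s, tp=15 s, A=100, alpha=2 —
    analytic peak of 100 a.u. at exactly 25 s post-injection.
    """
    cls = ph.PerfusionClass("mass", amplitude=100.0, t0=10.0, tp=15.0,
                            alpha=2.0, baseline=5.0)
    classes = dict(ph.DEFAULT_CLASSES)
    classes["cancerous"] = cls
    spec = ph.PhantomSpec(
        shape=(64, 64), mass_center=(32.0, 32.0), mass_axes=(14.0, 10.0),
        parenchyma_box=(4, 20, 4, 20), classes=classes, sigma_speckle=0.0,
    )
    video, masks, label, truth_tics = ph.render_phantom(spec, seed=0)
    return {"spec": spec, "video": video, "masks": masks, "label": label,
            "truth_tics": truth_tics, "mass_class": cls}


@pytest.fixture(scope="session")
def textured_frame():
    """Speckle-like random field with enough structure for corner tracking."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(42)
    return gaussian_filter(rng.normal(size=(96, 96)), 1.5) * 50.0 + 100.0


@pytest.fixture(scope="session")
def default_phantom_small():
    """Default-kinetics phantom at reduced size, mild speckle."""
    spec = ph.PhantomSpec(
        shape=(80, 80), mass_center=(44.0, 44.0), mass_axes=(18.0, 13.0),
        parenchyma_box=(4, 24, 4, 24), sigma_speckle=0.1,
    )
    video, masks, label, truth_tics = ph.render_phantom(spec, seed=3)
    return {"spec": spec, "video": video, "masks": masks, "label": label}
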