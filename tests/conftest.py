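import numpy as np
import pytest

from tpm3d import generate_phantom, make_preset, run_pipeline


@pytest.fixture(scope="session")
def healthy_clean():
    """Noise-free healthy phantom (5 slices, 25 phases, 64^2) + pipeline result."""
    cfg = make_preset(
        "healthy", n_slices=5, grid_size=64, noise_sd_cm_s=0.0, background_plane=None
    )
    ds, truth = generate_phantom(cfg)
    report, curves = run_pipeline(ds)
    return {"cfg": cfg, "ds": ds, "truth": truth, "report": report, "curves": curves}


@pytest.fixture(scope="session")
def preset_reports():
    """Pipeline reports of the three presets under realistic noise (7 slices)."""
    out = {}
    for name, seed in (("healthy", 11), ("dcm_like", 12), ("lbbb_like", 13)):
        cfg = make_preset(name, n_slices=7, grid_size=64, seed=seed)
        ds, _ = generate_phantom(cfg)
        report, _ = run_pipeline(ds)
        out[name] = report
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
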