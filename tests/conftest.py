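import numpy as np
import pytest

import hastf


@pytest.fixture(scope="session")
def tiny_recording():
    """Small DEAP-like recording: 6 trials of 19 s (16 s usable) at 128 Hz."""
    cfg = hastf.deap_like_config(
        n_trials=6, trial_len_s=19.0, baseline_len_s=3.0, seed=7, effect_gain=3.0
    )
    return hastf.generate_recording(cfg)


@pytest.fixture(scope="session")
def tiny_patch_tensor(tiny_recording):
    return hastf.build_patch_tensor(
        tiny_recording, plan=hastf.SegmentationPlan(window_len_s=8)
    )


@pytest.fixture(scope="session")
def tiny_grids(tiny_patch_tensor):
    return hastf.map_to_grid(tiny_patch_tensor, hastf.load_montage("deap32"))


def numeric_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar f at x."""
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = f(x)
        flat[i] = orig - eps
        lo = f(x)
        flat[i] = orig
        gf[i] = (hi - lo) / (2 * eps)
    return g
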