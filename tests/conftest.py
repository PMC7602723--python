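import numpy as np
import pytest

from venomshift.synthetic import PeakSpec, SimConfig, simulate_snake


def make_snake(
    seed=0,
    n_peaks=15,
    n_logistic=0,
    n_linear=0,
    noise_sigma=0.05,
    interval_days=85,
    total_days=1200,
    scale=40.0,
    amplitude=2.0,
    t0=500.0,
):
    """One simulated individual: n samples spanning total_days, bimodal-free
    chromatogram with optional planted logistic/linear peaks."""
    rng = np.random.default_rng(12345)
    bases = rng.normal(0.0, 1.0, n_peaks)
    specs = []
    for i in range(n_peaks):
        if i < n_logistic:
            specs.append(PeakSpec("logistic", base=bases[i], amplitude=amplitude, t0=t0, scale=scale))
        elif i < n_logistic + n_linear:
            specs.append(PeakSpec("linear", base=bases[i], slope=amplitude / total_days))
        else:
            specs.append(PeakSpec("constant", base=bases[i]))
    cfg = SimConfig(
        n_peaks=n_peaks,
        peak_specs=specs,
        noise_sigma=noise_sigma,
        interval_days=interval_days,
        total_days=total_days,
        seed=seed,
        snake_id=f"SIM{seed:04d}",
    )
    return simulate_snake(cfg)


@pytest.fixture
def shifting_snake():
    """An individual with a planted discrete logistic shift (scale 40 d)."""
    return make_snake(seed=11, n_logistic=2, noise_sigma=0.02)


@pytest.fixture
def null_snake():
    """An individual whose every peak is constant (noise only)."""
    return make_snake(seed=7, noise_sigma=0.05)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_compositions(rng, n, d):
    """Strictly positive closed rows for property checks."""
    m = rng.dirichlet(np.full(d, 2.0), size=n)
    return np.clip(m, 1e-9, None) / np.clip(m, 1e-9, None).sum(axis=1, keepdims=True)
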