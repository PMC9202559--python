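import numpy as np
import pytest

from attnseg.attention_unet import NetworkConfig
from attnseg.phantom import PhantomSpec, generate_phantom
from attnseg.pipeline import DataConfig, RunConfig, TrainingConfig


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """32x32x8 phantom that keeps every downstream test fast."""
    return PhantomSpec(
        grid_shape=(32, 32, 8),
        spacing=(1.0, 1.0, 2.0),
        tumor_center=(16, 18, 4),
        region_radii=(6.0, 4.0, 2.0),
        noise_sd=2.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_case(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def clean_case(small_spec):
    """Noise-free variant for alignment/centroid oracles."""
    import dataclasses

    return generate_phantom(dataclasses.replace(small_spec, noise_sd=0.0))


@pytest.fixture(scope="session")
def tiny_run_config() -> RunConfig:
    """Desk-scale training config: 32x32 inputs, 1/8 width."""
    return RunConfig(
        network=NetworkConfig(input_size=32, width_factor=0.125),
        training=TrainingConfig(
            learning_rate=1e-3, batch_size=4, max_steps=120, seed=0
        ),
        data=DataConfig(
            phantom_n=2,
            phantom_spec=PhantomSpec(
                grid_shape=(32, 32, 8),
                spacing=(1.0, 1.0, 2.0),
                tumor_center=(16, 18, 4),
                region_radii=(6.0, 4.0, 2.0),
                noise_sd=2.0,
            ),
            tumor_fraction=0.75,
        ),
        seed=0,
    )


@pytest.fixture(scope="session")
def tiny_trained(tiny_run_config, tmp_path_factory):
    """One short training run shared by pipeline tests."""
    from attnseg.pipeline import load_cases, load_checkpoint, train

    out = tmp_path_factory.mktemp("tiny_run")
    cases = load_cases(tiny_run_config.data, seed=tiny_run_config.seed)
    ckpt, losses = train(tiny_run_config, out, cases=cases)
    net = load_checkpoint(ckpt, tiny_run_config)
    return net, cases, losses, ckpt


def grad_check_params(layer, forward, params, rtol=1e-4, eps=1e-6, n_samples=5):
    """Central-difference gradient check against a fixed linear readout.

    ``forward`` must rerun the layer's forward pass and return its output;
    parameters must already be float64.  Returns the worst relative error.
    """
    out = forward()
    readout = np.random.default_rng(42).normal(size=out.shape)

    def loss() -> float:
        return float((forward() * readout).sum())

    loss()
    for _, p in params:
        p.grad[...] = 0.0
    layer.backward(readout)
    worst = 0.0
    rng = np.random.default_rng(7)
    for _, p in params:
        flat = p.value.ravel()
        for i in rng.choice(flat.size, size=min(n_samples, flat.size), replace=False):
            orig = flat[i]
            flat[i] = orig + eps
            lp = loss()
            flat[i] = orig - eps
            lm = loss()
            flat[i] = orig
            num = (lp - lm) / (2 * eps)
            ana = p.grad.ravel()[i]
            err = abs(num - ana)
            scale = max(abs(num), abs(ana))
            # relative where the gradient is meaningful, absolute near zero
            worst = max(worst, err / scale if scale > 1e-6 else err)
    return worst


def as_float64(layer) -> None:
    for _, p in layer.parameters():
        p.value = p.value.astype(np.float64)
        p.grad = np.zeros_like(p.value)
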