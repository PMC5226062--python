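import numpy as np
import pytest

from tractometry.pipeline import TrackingParams, process_image_subject
from tractometry.synthetic import GeneratorConfig, generate_profile_cohort, straight_tube_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def straight_phantom():
    """Noiseless straight tube along +y on a reduced grid (fast to process)."""
    cfg = GeneratorConfig(mode="image", grid_shape=(24, 48, 24))
    return straight_tube_phantom(cfg, axis="y", radius=4.0)


@pytest.fixture(scope="session")
def straight_phantom_results(straight_phantom):
    """Fitted, tracked and profiled straight-tube phantom."""
    return process_image_subject(straight_phantom, TrackingParams())


@pytest.fixture(scope="session")
def large_cohort():
    """n = 500/group profile cohort with a poor-outcome-only fornix effect.

    Used for the large-n sampling oracles: effect recovery on nodes 1-60 and
    zero-bias of control means.
    """
    from tractometry.synthetic import Effect

    effect = Effect(
        "fimbria_fornix", "ipsilateral", 1, 60, frozenset({"ILAE2plus"}), md_shift=0.2
    )
    cfg = GeneratorConfig(
        seed=42, n_controls=500, n_ilae1=500, n_ilae2plus=500, effect_table=(effect,)
    )
    return generate_profile_cohort(cfg)


def spd_tensor(rng, lo=0.2e-3, hi=2.0e-3):
    """Random SPD tensor with eigenvalues in [lo, hi] mm^2/s."""
    evals = rng.uniform(lo, hi, 3)
    a = rng.normal(size=(3, 3))
    q, _ = np.linalg.qr(a)
    return (q * evals) @ q.T
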