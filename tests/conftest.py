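import numpy as np
import pytest

from specsens import PigmentSpec, ReceptorClass, Tier, EyeModel


@pytest.fixture
def grid_1nm():
    return np.arange(300.0, 701.0, 1.0)


@pytest.fixture
def daphnia_tier():
    """Four-class fused tier with published-style areas, k = 0.008/um."""
    lams = (362.0, 442.0, 518.0, 587.0)
    areas = (0.52, 0.21, 0.12, 0.15)
    return Tier(
        6.0,
        tuple(
            ReceptorClass(PigmentSpec("SSH", lam), a, 0.008)
            for lam, a in zip(lams, areas)
        ),
    )


def random_eye_model(rng: np.random.Generator, max_tiers: int = 3) -> EyeModel:
    """A random valid tiered model for property tests."""
    n_tiers = int(rng.integers(1, max_tiers + 1))
    tiers = []
    for _ in range(n_tiers):
        m = int(rng.integers(1, 5))
        lams = np.sort(rng.uniform(340, 620, m))
        areas = rng.dirichlet(np.ones(m))
        ks = rng.uniform(0.002, 0.02, m)
        length = float(rng.uniform(5.0, 200.0))
        tiers.append(
            Tier(
                length,
                tuple(
                    ReceptorClass(PigmentSpec(rng.choice(["SSH", "GFKRD"]), l), a, k)
                    for l, a, k in zip(lams, areas, ks)
                ),
            )
        )
    return EyeModel(tuple(tiers))


def slab_absorptance(model: EyeModel, grid: np.ndarray, n_slabs: int = 10_000) -> np.ndarray:
    """Independent optics oracle: sequential absorption through thin slabs.

    Each tier is cut into ``n_slabs`` slices; light is propagated slice by
    slice, accumulating the absorbed fraction and attenuating the
    transmitted beam. Exercises the tier-chaining bookkeeping without using
    the closed-form absorptance expression.
    """
    from specsens.optics import _tier_xi_values

    transmitted = np.ones_like(grid)
    absorbed = np.zeros_like(grid)
    for tier in model.tiers:
        xi = _tier_xi_values(tier, grid)
        delta = tier.length_um / n_slabs
        slab_tau = np.exp(-xi * delta)
        slab_abs = 1.0 - slab_tau
        for _ in range(n_slabs):
            absorbed += transmitted * slab_abs
            transmitted *= slab_tau
    return absorbed
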