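import numpy as np
import pytest

from selfrag.frag import fragmentation_by_condition
from selfrag.prep import residualize_ratings
from selfrag.stats import paired_t
from selfrag.synthio import SynthConfig, generate_study


@pytest.fixture(scope="session")
def study7():
    """One full synthetic study at the default (emulated) conditions."""
    return generate_study(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def residuals7(study7):
    return residualize_ratings(study7.ratings)


@pytest.fixture(scope="session")
def frag7(residuals7, study7):
    return fragmentation_by_condition(residuals7, assignment=study7.ratings)


def frag_contrast(seed: int, delta: float):
    """asyncSelf vs syncSelf paired t on the fragmentation index of one
    replicate study at the default study size (33 dyads)."""
    cfg = SynthConfig(seed=seed, frag_effect_delta=delta)
    ds = generate_study(cfg, components=("ratings",))
    res = residualize_ratings(ds.ratings)
    fr = fragmentation_by_condition(res, assignment=ds.ratings)
    dist = fr[fr["target"] == "self"].pivot_table(
        index="participant_id", columns="condition",
        values="mean_cluster_distance")
    return paired_t(dist["asyncSelf"].to_numpy(), dist["syncSelf"].to_numpy())


@pytest.fixture(scope="session")
def null_replicates():
    """200 replicate studies with no planted dispersion effect (delta = 0)."""
    return [frag_contrast(1000 + s, 0.0) for s in range(200)]


@pytest.fixture(scope="session")
def delta25_replicates():
    """100 replicate studies at the default planted effect delta = 0.25."""
    return [frag_contrast(1300 + s, 0.25) for s in range(100)]
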