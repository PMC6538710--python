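import numpy as np
import pandas as pd
import pytest

from qusrim import features, synth


@pytest.fixture(scope="session")
def uniform_fine_scene():
    """Default-resolution homogeneous scene (fully developed speckle)."""
    return synth.make_speckle_rf(synth.SceneSpec(grid_shape=(1560, 510), seed=11))


@pytest.fixture(scope="session")
def coarse_lesion_scene():
    """Coarse two-region scene: pre-Rayleigh interior, post-Rayleigh rim."""
    base = synth.example_scene_spec(coarse=True, seed=7)
    import dataclasses

    return synth.make_speckle_rf(
        dataclasses.replace(base, interior_nak=0.6, rim_nak=1.4)
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Four-lesion coarse cohort with a rim-confined class effect."""
    spec = synth.example_cohort_spec(n_benign=2, n_malignant=2, effect="rim", seed=21)
    return synth.make_cohort(spec)


@pytest.fixture(scope="session")
def small_feature_table(small_cohort):
    return features.extract_features(small_cohort.lesions, overlap=0.25)


def random_feature_table(n=30, m=12, group="internal", seed=0, balance=0.5):
    """Feature table with i.i.d. normal features and arbitrary labels."""
    rng = np.random.default_rng(seed)
    suffix = {"internal": "_int", "external": "_ext"}[group]
    cols = [f"{p}{suffix}" for p in features.PARAMETERS[:m]]
    table = pd.DataFrame(rng.normal(size=(n, m)), columns=cols)
    n_mal = int(round(n * balance))
    table.insert(0, "label", ["malignant"] * n_mal + ["benign"] * (n - n_mal))
    table.insert(0, "lesion_id", [f"lesion_{i:03d}" for i in range(n)])
    return table


@pytest.fixture
def make_random_table():
    return random_feature_table
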