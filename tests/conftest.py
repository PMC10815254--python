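import numpy as np
import pytest

import dlrpmds as d


@pytest.fixture(scope="session")
def small_two_class():
    """Well-separated two-class dataset, small enough for fast tests."""
    benign = d.make_class_spec(
        "benign", n_residues=10, n_variants=4, n_frames_per_variant=60, seed=0
    )
    patho = d.make_class_spec(
        "pathogenic", n_residues=10, separation=60.0, n_variants=4,
        n_frames_per_variant=60, seed=0,
    )
    return d.simulate_class(benign) + d.simulate_class(patho)


@pytest.fixture(scope="session")
def small_latents(small_two_class):
    """Latent set from a quick AE fit on the small two-class data."""
    space = d.fit_feature_space(small_two_class)
    pairs = d.make_lagged_pairs(small_two_class, space)
    ae = d.train_autoencoder(
        pairs,
        d.AEConfig(hidden_widths=[32, 16], latent_dim=4, epochs=15, seed=0),
        space,
    )
    Z, meta = d.standardized_frames(small_two_class, space)
    from dlrpmds.classifier import binary_labels_from_meta

    return d.LabeledLatentSet(
        latents=d.encode(ae, Z),
        labels=binary_labels_from_meta(meta),
        variant_ids=meta["variant_id"].to_numpy(),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
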