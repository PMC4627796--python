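import numpy as np
import pytest

from morf_fuse.simulate import SimSpec, simulate_dataset
from morf_fuse.tracks_io import ResidueTrack, Space


@pytest.fixture(scope="session")
def small_dataset():
    """20-sequence synthetic dataset shared by structural tests."""
    return simulate_dataset(SimSpec(n_sequences=20, seed=101))


@pytest.fixture(scope="session")
def trained_small(small_dataset):
    """(bundle, results) for the small dataset, trained on itself."""
    from morf_fuse.pipeline import fit_bundle, predict

    ds = small_dataset
    bundle = fit_bundle(ds.sequences, ds.profiles, ds.disorder_tracks, ds.chibi_tracks)
    results = predict(
        ds.sequences, ds.profiles, ds.disorder_tracks, ds.chibi_tracks, bundle
    )
    return bundle, results


def normalized_track(values, sid="s", feature=None):
    return ResidueTrack(sid, np.asarray(values, float), Space.NORMALIZED, feature)


def random_normalized(rng, n, sid="s"):
    return normalized_track(rng.uniform(0.01, 0.99, size=n), sid)
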