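import numpy as np
import pytest

import medmir as m


@pytest.fixture(scope="session")
def small_reference():
    """A 20 kb single-contig reference with 4 genes and 2 islands."""
    ref, ann = m.generate_reference(
        seed=11, contig_length=20_000, n_genes=4, n_islands=2
    )
    return ref, ann


@pytest.fixture(scope="session")
def paired_tracks(small_reference):
    """Site count tracks for 3 primary/recurrent pairs with one planted DMR
    (fold 3 over [5000, 6500))."""
    ref, ann = small_reference
    spec = [m.DmrSpec("contig1", 5000, 6500, 3.0)]
    profiles, truth = m.generate_methylomes(
        ref, ann, n_pairs=3, dmr_spec=spec, baseline_beta_params=(2.0, 8.0), seed=21
    )
    tracks = m.tracks_from_profiles(profiles, ref, mean_depth=60, seed=22)
    labels = {p.sample_id: p.group for p in profiles}
    return tracks, labels, spec


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
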