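import numpy as np
import pytest

from repliskew import (ReplicationModel, SkewedGenomeSpec,
                       generate_skewed_genome, simulate_depth_profiles)


@pytest.fixture(scope="session")
def skewed_genome_1mb():
    """1-Mbp genome, ori at 0, ter at 500 kbp, strong skew, frozen seed."""
    spec = SkewedGenomeSpec(1_000_000, 0, 500_000, skew_strength=0.3,
                            gc_content=0.5, seed=1)
    genome, truth = generate_skewed_genome(spec)
    return genome, truth


@pytest.fixture(scope="session")
def single_origin_profiles():
    """Depth pair for a 3-Mbp single-origin model, r=0.5, depth 500."""
    model = ReplicationModel("single_origin", 3_000_000, ori_position=0,
                             replicating_fraction=0.5, seed=7)
    return simulate_depth_profiles(model, window=1000, mean_depth=500.0)


def noiseless_depth_pair(model, window):
    """Expected (not sampled) exponential/stationary window counts."""
    from repliskew import DepthProfile
    from repliskew.genome import n_windows
    from repliskew.synth import expected_relative_copy_number

    n = n_windows(model.genome_length, window)
    centers = (np.arange(n) * window + window / 2.0) % model.genome_length
    m = np.asarray(expected_relative_copy_number(model, centers))
    exp = DepthProfile(window, m, float(m.sum()), model.genome_length, "exponential")
    stat = DepthProfile(window, np.ones(n), float(n), model.genome_length, "stationary")
    return exp, stat
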