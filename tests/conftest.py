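import numpy as np
import pytest

from rnamodnet.dataset import make_splits
from rnamodnet.network import NetworkConfig, build_network, train
from rnamodnet.synthetic import default_spec, generate


@pytest.fixture(scope="session")
def small_windows():
    """250+250 planted-motif windows, small enough for fast module tests."""
    windows, truth = generate(default_spec(n_pos=250, n_neg=250, seed=11))
    return windows, truth


@pytest.fixture(scope="session")
def small_split(small_windows):
    windows, _ = small_windows
    labels = [w.label for w in windows]
    man = make_splits(list(range(len(windows))), labels, test_fraction=0.2,
                      k=5, seed=11)
    tr = [windows[i] for i in man.train_ids]
    te = [windows[i] for i in man.test_ids]
    return tr, te


@pytest.fixture(scope="session")
def small_config():
    return NetworkConfig(conv_filters=32, lstm_units=16, fc_units=32,
                         batch_size=16, learning_rate=3e-3, max_epochs=15,
                         dropout=0.1, seed=3)


@pytest.fixture(scope="session")
def small_trained(small_split, small_config):
    """A quickly trained reduced-width network on the planted-motif data."""
    tr, te = small_split
    return train(build_network(small_config), tr, te)


def sharp_pwm(consensus: str = "UUCGAAUCGG"):
    """A sharp PWM with pairwise-distinct informative columns.

    The off-consensus mass is spread asymmetrically with a per-position
    pattern, so no two columns are affinely related (Pearson correlation
    between distinct columns is strictly below 1 even for repeated bases)
    and a column-permutation null cannot reproduce a perfect self-match by
    exchanging equivalent columns."""
    from rnamodnet.encodings import BASES
    from rnamodnet.interpret import Pwm

    m = np.empty((len(consensus), 4))
    for i, b in enumerate(consensus):
        others = [j for j in range(4) if j != BASES.index(b)]
        weights = np.array([1.0, 2.0, 3.0 + i])
        m[i, others] = 0.12 * weights / weights.sum()
        m[i, BASES.index(b)] = 0.88
    return Pwm(m, source=f"sharp_{consensus}")


@pytest.fixture
def toy_genome():
    rng = np.random.default_rng(5)
    return {
        "chr1": "".join(rng.choice(list("ACGU"), size=400)),
        "chr2": "".join(rng.choice(list("ACGU"), size=300)),
    }
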